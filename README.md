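# radeq

**Do statistically equivalent radiomic models select the same features?**

Radiomic studies extract hundreds to thousands of quantitative image features
from small patient cohorts, train many feature-selection × classifier
combinations, and then read the features selected by the best-performing
model as candidate biomarkers. But with n ≪ d, the "best" model is rarely
*statistically* best: many other models have AUCs that cannot be shown to
differ from it. If those statistically equivalent models select different
features, biomarker claims based on the single best model are fragile.

`radeq` is a benchmarking framework for quantifying exactly that. It

1. trains a full model grid — 8 feature-scoring methods × 7 feature counts
   (N = 1, 2, 4, …, 64) × 8 classifiers with fixed hyperparameter grids,
   3640 configurations per dataset — under stratified 10-fold
   cross-validation with in-fold feature selection and pooled out-of-fold ROC;
2. keeps the best configuration per (scorer, classifier) pair (64 models),
   and compares each to the overall best with a **paired DeLong test**
   (implemented from structural midrank components), collecting the
   *equivalence set*: models with p ≥ 0.05, unadjusted;
3. measures how much those equivalent models agree on features, with three
   statistics on the per-fold binary selection indicator vectors:
   - **stability** of one model: mean Pearson correlation of its indicators
     over all 45 unordered fold pairs;
   - **similarity** of two models: mean Pearson correlation of their
     indicators on matched folds;
   - **feature-set correlation**: mean best-match |Pearson r| between the two
     models' selected features — high when models pick different but nearly
     interchangeable features from the same correlated blocks.

A synthetic-data module generates feature tables with the statistical
signature of real radiomic datasets (equicorrelated feature blocks, a sparse
informative signal with closed-form per-feature AUC Φ(δ/√2), class
imbalance, missing cells), so the whole pipeline can be exercised and
calibrated without external data. Real tables are accepted as CSV
(sample id column, numeric features, binary `outcome` column).

## The statistics at the core

For pooled out-of-fold scores with m events and n non-events, the AUC is the
Mann–Whitney statistic (ties ½). The paired DeLong test uses per-sample
placements: for event i, V10ᵢ = the fraction of non-events it outranks; for
non-event j, V01ⱼ symmetrically. With placement covariance matrices S10, S01
of two models a, b:

    var(ÂUCₐ − ÂUC_b) = (S10ₐₐ + S10_bb − 2·S10ₐ_b)/m + (S01ₐₐ + S01_bb − 2·S01ₐ_b)/n
    z = (ÂUCₐ − ÂUC_b) / √var,   two-sided normal p.

The agreement statistics are Pearson correlations of binary indicator
vectors (stability, similarity) and, for the feature-set correlation,
per fold: mean over A's selected features of max_{g ∈ B} |r(f, g)|,
symmetrized over directions and averaged over folds.

## Worked example

```python
from radeq import (SimulationSpec, generate_radiomic_dataset,
                   StudyConfig, run_study)

datasets = []
for i, eff in enumerate((0.3, 0.8, 1.4)):
    spec = SimulationSpec(n_samples=120, n_features=60, n_informative=4,
                          effect_size=eff, block_sizes=[10] * 4,
                          within_block_rho=0.8, event_rate=0.4,
                          missing_rate=0.01, seed=i)
    datasets.append((f"cohort_{i}", generate_radiomic_dataset(spec)))

config = StudyConfig(fs_methods=("anova", "kendall"), n_grid=(1, 4, 16),
                     classifiers=("lda", "naive_bayes", "logistic"), seed=42)
for s in run_study(datasets, config):
    print(f"{s.dataset_id}: best={s.best_config.key()}  AUC={s.best_auc:.3f}  "
          f"equivalent={s.n_equivalent}/5")
    print(f"  stability={s.stability['mean']:.2f} "
          f"({s.stability['min']:.2f}-{s.stability['max']:.2f})  "
          f"similarity={s.similarity['mean']:.2f}  "
          f"correlation={s.correlation['mean']:.2f}")
```

prints

```
cohort_0: best=anova|16|lda|  AUC=0.519  equivalent=5/5
  stability=0.54 (0.48-0.62)  similarity=0.58  correlation=0.84
cohort_1: best=kendall|16|lda|  AUC=0.920  equivalent=5/5
  stability=0.81 (0.69-1.00)  similarity=0.71  correlation=0.91
cohort_2: best=anova|16|lda|  AUC=0.996  equivalent=5/5
  stability=0.74 (0.60-1.00)  similarity=0.71  correlation=0.90
```

Reading cohort_0: the best model (ANOVA scores, top 16 features, LDA) has a
pooled AUC of 0.52 — essentially no signal — and *all five* other
best-per-pair models are statistically equivalent to it. Their feature sets
overlap only moderately (similarity 0.58), yet the features they pick are
highly inter-correlated (0.84): different models surface different members
of the same correlated blocks. With stronger signal (cohort_2) the best AUC
approaches 1 and selections become more stable. With this tiny demonstration
grid the equivalence counts themselves stay saturated; the negative
AUC-versus-count association emerges on larger grids with more statistical
power (it is asserted as a scenario test in the suite).

The same pipeline is scriptable from a shell:

```bash
radeq simulate --n-samples 120 --n-features 60 --out cohort.csv --seed 1
radeq run cohort.csv --profile smoke --out results/ --seed 42
radeq report results/
```

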