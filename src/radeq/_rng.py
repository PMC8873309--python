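"""Deterministic child-seed derivation.

A study run holds one master seed; every stochastic component (CV split,
stochastic scorers, stochastic classifiers, per-fold perturbations) derives
its own child seed from the master seed plus a string label. The derivation
is a splitmix64 finalizer over a hash of the label, so child seeds are
decorrelated, stable across platforms, and recorded in run manifests.
"""

from __future__ import annotations

_MASK = (1 << 64) - 1


def _splitmix64(x: int) -> int:
    x = (x + 0x9E3779B97F4A7C15) & _MASK
    x = ((x ^ (x >> 30)) * 0xBF58476D1CE4E5B9) & _MASK
    x = ((x ^ (x >> 27)) * 0x94D049BB133111EB) & _MASK
    return (x ^ (x >> 31)) & _MASK


def derive_seed(master: int, *labels) -> int:
    """Derive a child seed (< 2**31) from a master seed and labels.

    Labels may be strings or integers; the same (master, labels) pair always
    yields the same child seed.
    """
    state = _splitmix64(int(master) & _MASK)
    for label in labels:
        if isinstance(label, int):
            data = label.to_bytes(8, "little", signed=True)
        else:
            data = str(label).encode("utf-8")
        for byte in data:
            state = _splitmix64(state ^ byte)
    return state % (1 << 31)
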