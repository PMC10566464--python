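"""Bootstrap-head uncertainty quantification.

An ensemble of B output heads shares one network trunk.  At train time each
molecule is deterministically assigned a subset of heads (each head included
independently with probability ``p_include`` via a seeded hash), and the
loss is computed on the mean over that subset, so each head effectively
trains on a different slice of the data.  At test time all heads are
evaluated; the prediction is their mean and the uncertainty is their sample
standard deviation.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["assign_bootstraps", "subset_train_prediction", "ensemble_predict"]


def _hash_unit(molecule_id: str, head: int, seed: int) -> float:
    """Deterministic uniform draw in [0, 1) from (molecule_id, head, seed)."""
    key = f"{molecule_id}|{head}|{seed}".encode()
    digest = hashlib.sha256(key).digest()
    return int.from_bytes(digest[:8], "big") / 2.0**64


def assign_bootstraps(
    molecule_id: str, n_bootstraps: int, p_include: float = 0.5, seed: int = 0
) -> tuple:
    """Head subset for one molecule: head h is included iff its hash draw is
    below ``p_include``; an empty draw forces in the head with the smallest
    hash so every molecule trains at least one head.  Stable across runs."""
    if n_bootstraps < 1:
        raise ValueError("need at least one bootstrap head")
    if not 0.0 < p_include <= 1.0:
        raise ValueError("p_include must lie in (0, 1]")
    draws = [_hash_unit(molecule_id, h, seed) for h in range(n_bootstraps)]
    subset = tuple(h for h, d in enumerate(draws) if d < p_include)
    if not subset:
        subset = (int(np.argmin(draws)),)
    return subset


def subset_train_prediction(head_outputs: np.ndarray, subset) -> np.ndarray:
    """Mean over the selected heads; axis 0 of ``head_outputs`` indexes heads."""
    subset = tuple(subset)
    if not subset:
        raise ValueError("empty bootstrap subset")
    head_outputs = np.asarray(head_outputs)
    return head_outputs[list(subset)].mean(axis=0)


def ensemble_predict(head_outputs: np.ndarray) -> tuple:
    """Test-time (value, uncertainty) from all heads.

    Value is the head mean; uncertainty is the sample standard deviation
    (ddof=1; zero for a single head).  The mean is computed relative to the
    first head so that identical heads give exactly zero spread.
    """
    h = np.asarray(head_outputs, dtype=np.float64)
    n = h.shape[0]
    dev = h - h[0]
    mean = h[0] + dev.mean(axis=0)
    if n == 1:
        return mean, np.zeros_like(mean)
    centered = h - mean
    std = np.sqrt((centered**2).sum(axis=0) / (n - 1))
    return mean, std
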