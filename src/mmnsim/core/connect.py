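"""Random wiring and heterogeneity sampling helpers."""

from __future__ import annotations

import numpy as np

from .params import ParameterError

__all__ = ["bernoulli_connect", "sample_heterogeneous"]


def bernoulli_connect(n_pre: int, n_post: int, p: float, seed: int) -> np.ndarray:
    """Sample an adjacency list where each ordered pair is present with
    probability ``p``, independently.

    Returns an ``(m, 2)`` int32 array of ``(pre, post)`` indices, sorted
    lexicographically.  The same ``(n_pre, n_post, p, seed)`` always
    yields the identical adjacency.
    """
    if n_pre < 0 or n_post < 0:
        raise ParameterError("population sizes must be non-negative")
    if not (0.0 <= p <= 1.0):
        raise ParameterError(f"p must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_pre, n_post)) < p
    edges = np.argwhere(mask).astype(np.int32)
    return edges


def sample_heterogeneous(mean: float, rel_sd: float, n: int, seed: int) -> np.ndarray:
    """Draw ``n`` positive values with the requested mean and relative SD.

    Values are drawn from a normal distribution and non-positive draws
    are rejected and redrawn, so the realized moments are mildly biased
    for large ``rel_sd``; for the relative SDs used here (<= 0.4) the
    bias is negligible.
    """
    if mean <= 0:
        raise ParameterError(f"mean must be positive, got {mean}")
    if rel_sd < 0:
        raise ParameterError(f"rel_sd must be >= 0, got {rel_sd}")
    if n < 0:
        raise ParameterError("n must be non-negative")
    rng = np.random.default_rng(seed)
    if rel_sd == 0.0:
        return np.full(n, float(mean))
    out = rng.normal(mean, rel_sd * mean, size=n)
    bad = out <= 0
    while np.any(bad):
        out[bad] = rng.normal(mean, rel_sd * mean, size=int(bad.sum()))
        bad = out <= 0
    return out
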