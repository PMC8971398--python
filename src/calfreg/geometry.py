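"""Coarse-geometry diagnostics.

Why do ±1 weights suffice?  Because the three objective metrics depend
only on the *direction* of the weight vector, and the signed sparse
directions available to a coarse model — the rays through the nonzero
points of {-1, 0, +1}^n — crowd the surface of the n-cube exponentially
fast as the dimension grows.  This module quantifies that picture:

* ``ray_ratio``     — (3^n - 1) rays against the n-cube surface area n·2^n;
* ``ray_ratio_bound_holds`` — numerical check that the ratio exceeds
  1.05^n for every dimension from 4 up;
* ``coarsen``       — the three-level map of a real vector to {-1, 0, +1}
  at a symmetric threshold (default: the standard-normal tertile point,
  so each level is hit with probability ~1/3);
* ``dot_product_fidelity`` — Monte-Carlo check that A·B and coarsen(A)·B
  stay tightly correlated for independent Gaussian A, B;
* ``capacity``      — exact counts of L-subsets and signed L-subsets of p
  predictors, the search space a coarse model ranges over.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

#: Standard-normal tertile point: P(|Z| < t) ~ 1/3 on each side,
#: i.e. Phi(t) ~ 2/3.  Exposed as a default, not baked in.
TERTILE_THRESHOLD = 0.4307

__all__ = [
    "TERTILE_THRESHOLD",
    "RayRatio",
    "ray_ratio",
    "ray_ratio_bound_holds",
    "coarsen",
    "dot_product_fidelity",
    "capacity",
]


@dataclass(frozen=True)
class RayRatio:
    """Count of coarse rays relative to the n-cube's surface area."""

    n: int
    n_rays: int          # 3^n - 1, exact
    surface_area: int    # n * 2^n, exact
    ratio: float


def ray_ratio(n: int) -> RayRatio:
    """Rays through the nonzero points of {-1,0,+1}^n versus the
    (n-1)-dimensional surface area of the n-cube."""
    if n < 1:
        raise ValueError("dimension must be >= 1")
    rays = 3**n - 1
    area = n * 2**n
    return RayRatio(n=n, n_rays=rays, surface_area=area, ratio=rays / area)


def ray_ratio_bound_holds(n_max: int) -> bool:
    """True iff (3^n - 1)/(n·2^n) >= 1.05^n for every n in [4, n_max].

    Evaluated in log space so large dimensions never overflow.
    """
    if n_max < 4:
        raise ValueError("the bound concerns dimensions >= 4")
    for n in range(4, n_max + 1):
        log_ratio = _log_big(3**n - 1) - math.log(n) - n * math.log(2.0)
        if log_ratio < n * math.log(1.05):
            return False
    return True


def _log_big(x: int) -> float:
    # math.log handles arbitrary-precision ints exactly enough here
    return math.log(x)


def coarsen(vector: np.ndarray, threshold: float = TERTILE_THRESHOLD) -> np.ndarray:
    """Three-level coarse approximation: -1 below -threshold, +1 above
    +threshold, 0 between.  Odd: coarsen(-v) = -coarsen(v)."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    v = np.asarray(vector, dtype=float)
    out = np.zeros_like(v, dtype=int)
    out[v > threshold] = 1
    out[v < -threshold] = -1
    return out


def dot_product_fidelity(
    n_dim: int,
    n_trials: int,
    seed: int | np.random.Generator = 0,
    threshold: float = TERTILE_THRESHOLD,
) -> tuple[np.ndarray, float]:
    """How well does a coarsened Gaussian vector preserve dot products?

    Per trial draws independent standard-normal A, B of length ``n_dim``
    and records the pair (A·B, coarsen(A)·B).  Returns the (n_trials, 2)
    array of pairs and their Pearson correlation.
    """
    if n_dim < 2:
        raise ValueError("need dimension >= 2")
    if n_trials < 10:
        raise ValueError("need at least 10 trials")
    rng = np.random.default_rng(seed)
    pairs = np.empty((n_trials, 2))
    for t in range(n_trials):
        a = rng.standard_normal(n_dim)
        b = rng.standard_normal(n_dim)
        pairs[t] = (a @ b, coarsen(a, threshold) @ b)
    r = float(np.corrcoef(pairs[:, 0], pairs[:, 1])[0, 1])
    return pairs, r


def capacity(p: int, limit: int) -> tuple[int, int]:
    """Exact counts of the coarse model's search space: C(p, L) subsets
    and C(p, L)·2^L signed weight patterns, as exact integers."""
    if not 1 <= limit <= p:
        raise ValueError("need 1 <= limit <= p")
    subsets = math.comb(p, limit)
    return subsets, subsets * 2**limit
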