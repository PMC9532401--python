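"""Space-filling designs: seeded Latin hypercubes with maximin optimization."""

from __future__ import annotations

import numpy as np

__all__ = ["latin_hypercube", "maximin_criterion"]


def maximin_criterion(unit: np.ndarray) -> float:
    """Minimum pairwise Euclidean distance of points in the unit cube."""
    d = unit[:, None, :] - unit[None, :, :]
    sq = np.sum(d * d, axis=-1)
    np.fill_diagonal(sq, np.inf)
    return float(np.sqrt(sq.min()))


def latin_hypercube(
    n: int,
    ranges,
    seed=0,
    *,
    optimize: bool = True,
    n_iter: int = 2000,
) -> np.ndarray:
    """(n, d) design, one point per axis stratum per dimension.

    Maximin optimization is random within-column swap hill climbing: the
    criterion is non-decreasing over iterations and stratification is
    preserved by construction.
    """
    ranges = np.asarray(ranges, dtype=float)
    if ranges.ndim != 2 or ranges.shape[1] != 2:
        raise ValueError("ranges must be (d, 2) [lo, hi] rows")
    if n < 2:
        raise ValueError("n must be >= 2")
    d = len(ranges)
    rng = np.random.default_rng(seed)

    unit = np.empty((n, d))
    for j in range(d):
        perm = rng.permutation(n)
        unit[:, j] = (perm + rng.uniform(size=n)) / n

    if optimize and n > 2:
        best = maximin_criterion(unit)
        for _ in range(n_iter):
            j = int(rng.integers(d))
            a, b = rng.choice(n, size=2, replace=False)
            unit[[a, b], j] = unit[[b, a], j]
            cand = maximin_criterion(unit)
            if cand >= best:
                best = cand
            else:
                unit[[a, b], j] = unit[[b, a], j]  # revert

    lo, hi = ranges[:, 0], ranges[:, 1]
    return lo + unit * (hi - lo)
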