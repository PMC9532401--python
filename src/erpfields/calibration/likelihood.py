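"""Smoothed top-hat likelihood for interval-censored ERP observations.

An S1S2-type protocol only reveals the grid interval [I, I + width] that
contains ERP.  The top-hat density over that interval is approximated by
an equal-weight mixture of N normals centered on the N sub-intervals,
with sd equal to the sub-interval width; N = width so the sd is 1 ms.
The mixture integrates to 1, has infinite support (gradient-based MCMC
stays finite everywhere) and is approximately flat inside the interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ERPIntervalObservation", "tophat_loglik", "tophat_loglik_grad"]

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


@dataclass(frozen=True)
class ERPIntervalObservation:
    """One interval-censored ERP observation at a mesh vertex.

    protocol is 'S2' (S1S2) or 'S3' (S1S2S3); ERP lies in
    [interval_low, interval_low + interval_width] (ms).
    """

    vertex: int
    protocol: str
    interval_low: float
    interval_width: float

    def __post_init__(self) -> None:
        if self.protocol not in ("S2", "S3"):
            raise ValueError(f"protocol must be 'S2' or 'S3', got {self.protocol!r}")
        if self.interval_width <= 0:
            raise ValueError("interval_width must be positive")
        if self.interval_low <= 0:
            raise ValueError("interval_low must be positive")


def _centers_and_sd(low: float, width: float):
    n = max(1, int(round(width)))  # N = width so each normal has sd ~1 ms
    s = width / n
    centers = low + (np.arange(1, n + 1) - 0.5) * s
    return centers, s, n


def tophat_loglik(pred, low: float, width: float):
    """Log density of the N-normal mixture at predicted ERP value(s)."""
    pred = np.asarray(pred, dtype=float)
    centers, s, n = _centers_and_sd(low, width)
    z = -0.5 * ((pred[..., None] - centers) / s) ** 2
    out = logsumexp(z, axis=-1) - math.log(n) - math.log(s) - _LOG_SQRT_2PI
    return out if out.shape else float(out)


def tophat_loglik_grad(pred, low: float, width: float):
    """(log density, d log density / d pred), both vectorized over pred."""
    pred = np.asarray(pred, dtype=float)
    centers, s, n = _centers_and_sd(low, width)
    z = -0.5 * ((pred[..., None] - centers) / s) ** 2
    zmax = z.max(axis=-1, keepdims=True)
    e = np.exp(z - zmax)
    denom = e.sum(axis=-1)
    ll = np.log(denom) + zmax[..., 0] - math.log(n) - math.log(s) - _LOG_SQRT_2PI
    grad = (e @ centers / denom - pred) / s**2
    return ll, grad


def tophat_loglik_grad_rows(preds: np.ndarray, lows: np.ndarray, width: float):
    """Row-wise variant for a batch of observations sharing one interval
    width: preds[i] against [lows[i], lows[i] + width].  Returns the summed
    log likelihood and the per-row gradient d/d pred."""
    n = max(1, int(round(width)))
    s = width / n
    offsets = (np.arange(1, n + 1) - 0.5) * s
    centers = lows[:, None] + offsets  # (rows, n)
    z = -0.5 * ((preds[:, None] - centers) / s) ** 2
    zmax = z.max(axis=1, keepdims=True)
    e = np.exp(z - zmax)
    denom = e.sum(axis=1)
    ll = np.log(denom) + zmax[:, 0] - math.log(n) - math.log(s) - _LOG_SQRT_2PI
    grad = ((e * centers).sum(axis=1) / denom - preds) / s**2
    return float(ll.sum()), grad
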