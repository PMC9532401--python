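"""Log posterior over latent-field hyperparameters, with analytic gradients.

The sampled vector is z = (m1, m2, log a1, log a2, log r1, log r2,
eta1[K], eta2[K]) for the two EP fields (tau_out, apd_max).  Positive
hyperparameters are sampled on the log scale with the Jacobian included.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.special import gammaln

from ..cable.params import TRANSFORMED_RANGES
from ..manifold.gp import KernelSpec, spectral_weights
from ..manifold.laplacian import LaplacianEigenbasis
from ..surrogate.polynomial import SurrogateFunction
from .likelihood import (
    ERPIntervalObservation,
    tophat_loglik_grad,
    tophat_loglik_grad_rows,
)

__all__ = ["HyperPriors", "PosteriorModel", "log_prior", "FIELD_NAMES"]

FIELD_NAMES = ("tau_out", "apd_max")


@dataclass(frozen=True)
class HyperPriors:
    """rho ~ InvGamma(1.01, 20), alpha ~ InvGamma(1, 5), m improper flat
    (softly bounded to the physical range +- 50% so no-data posteriors stay
    proper), eta ~ N(0, 1)."""

    rho_shape: float = 1.01
    rho_scale: float = 20.0
    alpha_shape: float = 1.0
    alpha_scale: float = 5.0
    m_bound_sd: float = 5.0  # sd (ms) of the soft penalty outside the m bounds

    def m_bounds(self, field_name: str):
        lo, hi = TRANSFORMED_RANGES[field_name]
        span = hi - lo
        return lo - 0.5 * span, hi + 0.5 * span


def _invgamma_logpdf_dx(x: float, a: float, b: float):
    lp = a * math.log(b) - gammaln(a) - (a + 1.0) * math.log(x) - b / x
    dlp = -(a + 1.0) / x + b / x**2
    return lp, dlp


def log_prior(
    m: Sequence[float],
    alpha: Sequence[float],
    rho: Sequence[float],
    eta: Sequence[np.ndarray],
    priors: Optional[HyperPriors] = None,
    field_names: Sequence[str] = FIELD_NAMES,
) -> float:
    """Sum of log prior densities on the natural (not log) scale.

    Returns -inf for non-positive alpha or rho.  The flat prior on m
    contributes 0 inside its bounds.
    """
    priors = priors or HyperPriors()
    lp = 0.0
    for l in range(len(field_names)):
        if alpha[l] <= 0 or rho[l] <= 0:
            return -math.inf
        lp += _invgamma_logpdf_dx(rho[l], priors.rho_shape, priors.rho_scale)[0]
        lp += _invgamma_logpdf_dx(alpha[l], priors.alpha_shape, priors.alpha_scale)[0]
        e = np.asarray(eta[l])
        lp += -0.5 * float(e @ e) - len(e) * 0.5 * math.log(2.0 * math.pi)
        lo, hi = priors.m_bounds(field_names[l])
        if m[l] > hi:
            lp += -0.5 * ((m[l] - hi) / priors.m_bound_sd) ** 2
        elif m[l] < lo:
            lp += -0.5 * ((m[l] - lo) / priors.m_bound_sd) ** 2
    return lp


class PosteriorModel:
    """Assembles the log posterior p(psi | y) for two latent fields observed
    through the ERP surrogates at sparse vertices."""

    def __init__(
        self,
        basis: LaplacianEigenbasis,
        observations: Sequence[ERPIntervalObservation],
        f1: SurrogateFunction,
        f2: SurrogateFunction,
        *,
        kernel_family: str = "rbf",
        priors: Optional[HyperPriors] = None,
        bracket_pad: float = 0.0,
    ):
        self.basis = basis
        self.K = basis.K
        self.f1 = f1
        self.f2 = f2
        self.kernel_family = kernel_family
        self.priors = priors or HyperPriors()
        self.observations = list(observations)
        self.bracket_pad = float(bracket_pad)

        for o in self.observations:
            if not 0 <= o.vertex < basis.n_vertices:
                raise ValueError(
                    f"observation vertex {o.vertex} not on the mesh "
                    f"(n={basis.n_vertices})"
                )
        self.sites = np.unique([o.vertex for o in self.observations]).astype(int)
        site_of = {v: i for i, v in enumerate(self.sites)}
        self.B = basis.scaled_phi[self.sites]  # (n_sites, K), O(1) basis
        # observations grouped by protocol and (padded) interval width so the
        # likelihood evaluates in a few vectorized batches
        self._obs_by_proto = {}
        self._obs_groups = {}
        for proto in ("S2", "S3"):
            obs = [o for o in self.observations if o.protocol == proto]
            self._obs_by_proto[proto] = (
                np.array([site_of[o.vertex] for o in obs], dtype=int),
                [(o.interval_low - bracket_pad,
                  o.interval_width + 2.0 * bracket_pad) for o in obs],
            )
            groups = []
            widths = sorted({o.interval_width for o in obs})
            for wdt in widths:
                sub = [o for o in obs if o.interval_width == wdt]
                groups.append((
                    np.array([site_of[o.vertex] for o in sub], dtype=int),
                    np.array([o.interval_low - bracket_pad for o in sub]),
                    wdt + 2.0 * bracket_pad,
                ))
            self._obs_groups[proto] = groups

    # -- parameter vector layout --------------------------------------------

    @property
    def dim(self) -> int:
        return 6 + 2 * self.K

    def pack(self, m, alpha, rho, eta1, eta2) -> np.ndarray:
        return np.concatenate(
            [
                [m[0], m[1], math.log(alpha[0]), math.log(alpha[1]),
                 math.log(rho[0]), math.log(rho[1])],
                eta1,
                eta2,
            ]
        )

    def unpack(self, z: np.ndarray):
        m = z[0:2]
        alpha = np.exp(z[2:4])
        rho = np.exp(z[4:6])
        eta1 = z[6 : 6 + self.K]
        eta2 = z[6 + self.K :]
        return m, alpha, rho, eta1, eta2

    def initial_position(self, rng: np.random.Generator) -> np.ndarray:
        m0 = [np.mean(TRANSFORMED_RANGES[n]) for n in FIELD_NAMES]
        m = [m0[l] + 0.05 * (TRANSFORMED_RANGES[n][1] - TRANSFORMED_RANGES[n][0])
             * rng.standard_normal() for l, n in enumerate(FIELD_NAMES)]
        alpha = np.exp(rng.uniform(math.log(2.0), math.log(8.0), size=2))
        rho = np.exp(rng.uniform(math.log(5.0), math.log(40.0), size=2))
        eta1 = 0.1 * rng.standard_normal(self.K)
        eta2 = 0.1 * rng.standard_normal(self.K)
        return self.pack(m, alpha, rho, eta1, eta2)

    # -- fields --------------------------------------------------------------

    def fields_at(self, z: np.ndarray, B: Optional[np.ndarray] = None):
        """theta_1, theta_2 evaluated at the rows of B (default: obs sites)."""
        m, alpha, rho, eta1, eta2 = self.unpack(z)
        B = self.B if B is None else B
        th = []
        for l, eta in enumerate((eta1, eta2)):
            w = spectral_weights(
                self.basis, KernelSpec(self.kernel_family, float(rho[l]))
            )
            th.append(m[l] + alpha[l] * (B @ (w * eta)))
        return th[0], th[1]

    def fields_on_mesh(self, z: np.ndarray):
        return self.fields_at(z, B=self.basis.scaled_phi)

    # -- log posterior -------------------------------------------------------

    def log_posterior(self, z: np.ndarray, *, with_grad: bool = True):
        """Log posterior density of z (log-scale Jacobians included) and,
        optionally, its analytic gradient."""
        # guard against overflow/underflow excursions during leapfrog
        if not np.all(np.isfinite(z)) or np.max(np.abs(z[2:6])) > 50.0:
            bad = (-math.inf, np.zeros_like(z))
            return bad if with_grad else bad[0]
        m, alpha, rho, eta1, eta2 = self.unpack(z)
        pri = self.priors
        K = self.K
        lp = 0.0
        grad = np.zeros_like(z) if with_grad else None

        etas = (eta1, eta2)
        ws, dws = [], []
        for l in range(2):
            w, dw = spectral_weights(
                self.basis,
                KernelSpec(self.kernel_family, float(rho[l])),
                with_grad=True,
            )
            ws.append(w)
            dws.append(dw)

        # priors (log-scale parameterization for alpha, rho)
        for l in range(2):
            lp_r, dlp_r = _invgamma_logpdf_dx(rho[l], pri.rho_shape, pri.rho_scale)
            lp_a, dlp_a = _invgamma_logpdf_dx(alpha[l], pri.alpha_shape, pri.alpha_scale)
            lp += lp_r + math.log(rho[l]) + lp_a + math.log(alpha[l])
            e = etas[l]
            lp += -0.5 * float(e @ e) - K * 0.5 * math.log(2.0 * math.pi)
            lo, hi = pri.m_bounds(FIELD_NAMES[l])
            if m[l] > hi:
                lp += -0.5 * ((m[l] - hi) / pri.m_bound_sd) ** 2
            elif m[l] < lo:
                lp += -0.5 * ((m[l] - lo) / pri.m_bound_sd) ** 2
            if with_grad:
                grad[4 + l] += rho[l] * dlp_r + 1.0
                grad[2 + l] += alpha[l] * dlp_a + 1.0
                s = 6 + l * K
                grad[s : s + K] += -e
                if m[l] > hi:
                    grad[l] += -(m[l] - hi) / pri.m_bound_sd**2
                elif m[l] < lo:
                    grad[l] += -(m[l] - lo) / pri.m_bound_sd**2

        if not self.observations:
            return (lp, grad) if with_grad else lp

        # fields at observation sites
        th = [m[l] + alpha[l] * (self.B @ (ws[l] * etas[l])) for l in range(2)]

        # surrogate predictions and observation terms (batched by width)
        g_th = [np.zeros(len(self.sites)), np.zeros(len(self.sites))]
        for proto, f in (("S2", self.f1), ("S3", self.f2)):
            for sidx, lows, width in self._obs_groups[proto]:
                pred = f(th[0][sidx], th[1][sidx])
                ll, dll = tophat_loglik_grad_rows(pred, lows, width)
                lp += ll
                if with_grad:
                    d1, d2 = f.gradient(th[0][sidx], th[1][sidx])
                    np.add.at(g_th[0], sidx, dll * d1)
                    np.add.at(g_th[1], sidx, dll * d2)

        if with_grad:
            for l in range(2):
                gt = g_th[l]
                grad[l] += gt.sum()                                   # d/dm
                grad[2 + l] += float(gt @ (th[l] - m[l]))             # d/dlog alpha
                Bg = self.B.T @ gt                                    # (K,)
                s = 6 + l * K
                grad[s : s + K] += alpha[l] * ws[l] * Bg              # d/deta
                grad[4 + l] += alpha[l] * float((dws[l] * etas[l]) @ Bg)  # d/dlog rho
            return lp, grad
        return lp
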