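"""Seeded Hamiltonian Monte Carlo with warmup adaptation and thinning.

A plain HMC sampler (leapfrog, jittered step count, dual-averaging step
size, diagonal mass matrix estimated during warmup) that is a pure
function of (target, config): identical seeds give identical draws.
Retention follows the burn-in/thinning contract: discard the first
burn-in fraction of each chain and randomly thin the remainder.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = ["MCMCConfig", "PosteriorSampleSet", "run_mcmc", "retained_draw_count"]


@dataclass(frozen=True)
class MCMCConfig:
    iterations: int = 5000
    chains: int = 8
    burn_in_fraction: float = 0.5
    thin: int = 100
    seed: int = 0
    target_accept: float = 0.8
    n_leapfrog: int = 24
    init_step_size: float = 0.1
    max_divergence_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.burn_in_fraction < 1.0:
            raise ValueError("burn_in_fraction must be in [0, 1)")
        if self.iterations < 2 or self.chains < 1 or self.thin < 1:
            raise ValueError("invalid MCMC configuration")


def retained_draw_count(config: MCMCConfig) -> int:
    """Draws retained after burn-in discard and thinning (all chains)."""
    n_burn = int(round(config.iterations * config.burn_in_fraction))
    n_post = config.iterations - n_burn
    return config.chains * (n_post // config.thin)


@dataclass
class PosteriorSampleSet:
    """Retained posterior draws with provenance and diagnostics."""

    draws: np.ndarray        # (n_retained, dim)
    log_posteriors: np.ndarray
    chain_ids: np.ndarray
    draw_indices: np.ndarray  # iteration index within the chain
    config: MCMCConfig
    diagnostics: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.draws)

    @property
    def map_draw(self) -> np.ndarray:
        """The retained draw maximizing the stored log posterior."""
        return self.draws[int(np.argmax(self.log_posteriors))]


def _leapfrog(z, p, grad, step, n_steps, logpost_and_grad, inv_mass):
    lp = None
    p = p + 0.5 * step * grad
    for i in range(n_steps):
        z = z + step * inv_mass * p
        lp, grad = logpost_and_grad(z)
        if not np.isfinite(lp):
            return z, p, lp, grad
        if i < n_steps - 1:
            p = p + step * grad
    p = p + 0.5 * step * grad
    return z, p, lp, grad


def _split_rhat_ess(chains: np.ndarray):
    """Split-Rhat and a bulk ESS estimate per parameter.

    chains: (n_chains, n_draws, dim).  Standard split-chain formulas with a
    Geyer initial-positive-sequence autocorrelation truncation.
    """
    c, n, dim = chains.shape
    half = n // 2
    if half < 2:
        return np.full(dim, np.nan), np.full(dim, np.nan)
    split = chains[:, : 2 * half].reshape(c * 2, half, dim)
    mean = split.mean(axis=1)
    var = split.var(axis=1, ddof=1)
    W = var.mean(axis=0)
    B = half * mean.var(axis=0, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        rhat = np.sqrt(var_plus / W)

    ess = np.empty(dim)
    m, nn = split.shape[0], half
    for j in range(dim):
        if W[j] == 0:
            ess[j] = np.nan
            continue
        rho_sum = 0.0
        prev = 1.0
        centered = split[:, :, j] - mean[:, j : j + 1]
        for t in range(1, nn - 1):
            acov = np.mean(
                np.sum(centered[:, t:] * centered[:, :-t], axis=1) / nn
            )
            rho = 1.0 - (W[j] - acov) / var_plus[j]
            if t % 2 == 0:
                pair = prev + rho
                if pair < 0:
                    break
                rho_sum += pair
            prev = rho
        ess[j] = m * nn / (1.0 + 2.0 * rho_sum)
    return rhat, ess


def run_mcmc(
    logpost_and_grad: Callable[[np.ndarray], tuple],
    dim: int,
    config: MCMCConfig,
    *,
    initial_position: Optional[Callable[[np.random.Generator], np.ndarray]] = None,
) -> PosteriorSampleSet:
    """Sample the target with HMC under the retention contract.

    logpost_and_grad(z) -> (log density, gradient).  initial_position(rng)
    supplies per-chain starting points (default: standard normal).
    """
    n_iter = config.iterations
    n_burn = int(round(n_iter * config.burn_in_fraction))
    n_post = n_iter - n_burn
    keep_per_chain = n_post // config.thin

    all_draws, all_lps, all_chain, all_idx = [], [], [], []
    divergences = 0
    accept_rates = []
    post_store = np.empty((config.chains, n_post, dim))

    for chain in range(config.chains):
        rng = np.random.default_rng([config.seed, chain])
        z = (
            initial_position(rng)
            if initial_position is not None
            else rng.standard_normal(dim)
        )
        lp, grad = logpost_and_grad(z)
        if not np.isfinite(lp):
            raise ValueError("initial position has non-finite log posterior")

        step = config.init_step_size
        mass = np.ones(dim)  # diagonal mass matrix
        # dual-averaging state
        mu = math.log(10.0 * step)
        log_step_bar = 0.0
        h_bar = 0.0
        gamma, t0, kappa = 0.05, 10.0, 0.75
        adapt_end = n_burn
        mass_window_start = max(1, (2 * n_burn) // 5)
        mass_window_end = max(2, (9 * n_burn) // 10)
        window = []
        n_accept = 0

        for it in range(n_iter):
            inv_mass = 1.0 / mass
            p = rng.standard_normal(dim) * np.sqrt(mass)
            n_steps = int(rng.integers(
                max(1, int(0.8 * config.n_leapfrog)),
                int(1.2 * config.n_leapfrog) + 1,
            ))
            H0 = -lp + 0.5 * float(p * inv_mass @ p)
            z_new, p_new, lp_new, grad_new = _leapfrog(
                z.copy(), p, grad.copy(), step, n_steps, logpost_and_grad, inv_mass
            )
            if np.isfinite(lp_new):
                H1 = -lp_new + 0.5 * float(p_new * inv_mass @ p_new)
                dH = H1 - H0
            else:
                dH = math.inf
            if dH > 1000.0 or not math.isfinite(dH):
                accept_prob = 0.0
                if it >= n_burn:
                    divergences += 1
            else:
                accept_prob = 1.0 if dH <= 0.0 else math.exp(-dH)
            if rng.uniform() < accept_prob:
                z, lp, grad = z_new, lp_new, grad_new
                if it >= n_burn:
                    n_accept += 1

            if it < adapt_end:
                # dual averaging toward the target acceptance rate
                frac = 1.0 / (it + 1 + t0)
                h_bar = (1.0 - frac) * h_bar + frac * (config.target_accept - accept_prob)
                log_step = mu - math.sqrt(it + 1.0) / gamma * h_bar
                eta = (it + 1.0) ** -kappa
                log_step_bar = eta * log_step + (1.0 - eta) * log_step_bar
                step = math.exp(log_step)
                if mass_window_start <= it < mass_window_end:
                    window.append(z.copy())
                if it == mass_window_end - 1 and len(window) >= 10:
                    var = np.var(np.asarray(window), axis=0, ddof=1)
                    mass = 1.0 / np.maximum(var, 1e-8)
                    mu = math.log(10.0 * step)  # restart averaging around current step
                    h_bar = 0.0
            elif it == adapt_end:
                step = math.exp(log_step_bar)

            if it >= n_burn:
                post_store[chain, it - n_burn] = z

        accept_rates.append(n_accept / max(1, n_post))

        # random thinning: uniform subsample without replacement, seeded
        thin_rng = np.random.default_rng([config.seed, chain, 977])
        if keep_per_chain > 0:
            sel = np.sort(
                thin_rng.choice(n_post, size=keep_per_chain, replace=False)
            )
        else:
            sel = np.array([], dtype=int)
        for s in sel:
            zc = post_store[chain, s]
            all_draws.append(zc)
            all_lps.append(logpost_and_grad(zc)[0])
            all_chain.append(chain)
            all_idx.append(n_burn + int(s))

    rhat, ess = _split_rhat_ess(post_store)
    div_frac = divergences / max(1, config.chains * n_post)
    diagnostics = {
        "split_rhat": rhat,
        "ess_bulk": ess,
        "divergences": divergences,
        "divergence_fraction": div_frac,
        "accept_rates": accept_rates,
    }
    if div_frac > config.max_divergence_fraction:
        warnings.warn(
            f"divergent-transition fraction {div_frac:.1%} exceeds "
            f"{config.max_divergence_fraction:.0%}; treat results with caution",
            stacklevel=2,
        )

    return PosteriorSampleSet(
        draws=np.asarray(all_draws),
        log_posteriors=np.asarray(all_lps),
        chain_ids=np.asarray(all_chain, dtype=int),
        draw_indices=np.asarray(all_idx, dtype=int),
        config=config,
        diagnostics=diagnostics,
    )
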