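"""High-level calibration workflow shared by the CLI, sweeps and tests."""

from __future__ import annotations

from typing import Optional, Sequence, Tuple

from .calibration.fields import FieldSampleSet, constrain_fields, posterior_fields
from .calibration.hmc import MCMCConfig, PosteriorSampleSet, run_mcmc
from .calibration.likelihood import ERPIntervalObservation
from .calibration.posterior import HyperPriors, PosteriorModel
from .manifold.laplacian import LaplacianEigenbasis
from .surrogate.polynomial import SurrogateFunction

__all__ = ["calibrate"]

DEFAULT_K = 24  # eigenfunctions per field for calibration


def calibrate(
    observations: Sequence[ERPIntervalObservation],
    basis: LaplacianEigenbasis,
    f1: SurrogateFunction,
    f2: SurrogateFunction,
    config: Optional[MCMCConfig] = None,
    *,
    K: int = DEFAULT_K,
    kernel_family: str = "rbf",
    priors: Optional[HyperPriors] = None,
    bracket_pad: float = 0.0,
    constrain: bool = True,
) -> Tuple[PosteriorSampleSet, PosteriorModel, FieldSampleSet]:
    """Run the full calibration: posterior over hyperparameters by HMC,
    per-draw field evaluation on all mesh vertices, and (by default) the
    ERP_S2-ceiling constraint projection of the posterior field samples."""
    config = config or MCMCConfig()
    model = PosteriorModel(
        basis.truncated(min(K, basis.K)),
        observations,
        f1,
        f2,
        kernel_family=kernel_family,
        priors=priors,
        bracket_pad=bracket_pad,
    )
    samples = run_mcmc(
        model.log_posterior,
        model.dim,
        config,
        initial_position=model.initial_position,
    )
    fields = posterior_fields(samples, model)
    if constrain:
        fields, _ = constrain_fields(fields, f1, basis)
    return samples, model, fields
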