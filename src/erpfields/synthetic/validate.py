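"""Validation metrics: RMSE of predicted ERP fields and independent
standard errors (ISE) of the posterior distribution against ground truth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..calibration.fields import FieldSampleSet
from ..surrogate.polynomial import SurrogateFunction
from .truth import GroundTruthScenario

__all__ = ["ValidationMetrics", "erp_draws", "validate"]


@dataclass
class ValidationMetrics:
    rmse_map: dict        # per protocol: RMSE of MAP-predicted ERP over vertices
    rmse_mean: dict       # per protocol: RMSE of posterior-mean ERP
    ise: dict             # per protocol: per-vertex ISE array (NaN where sd == 0)
    ise_below_3: dict     # per protocol: fraction of defined ISE values < 3
    excluded: dict        # per protocol: count of vertices with sd == 0

    @property
    def combined_rmse_map(self) -> float:
        """Pooled RMSE of MAP-predicted ERP over both protocols' fields."""
        return float(np.sqrt(np.mean([r**2 for r in self.rmse_map.values()])))


def erp_draws(
    fields: FieldSampleSet, f1: SurrogateFunction, f2: SurrogateFunction
) -> dict:
    """Per-draw ERP fields computed through the surrogates."""
    return {
        "S2": f1(fields.theta1, fields.theta2),
        "S3": f2(fields.theta1, fields.theta2),
    }


def validate(
    scenario: GroundTruthScenario,
    fields: FieldSampleSet,
    f1: SurrogateFunction,
    f2: SurrogateFunction,
) -> ValidationMetrics:
    """Compare posterior ERP fields with the scenario's true ERP fields.

    ISE = |truth - posterior mean| / posterior sd per vertex; vertices with
    zero posterior sd are excluded (counted, not silently dropped).
    """
    draws = erp_draws(fields, f1, f2)
    truth = {"S2": scenario.erp_s2, "S3": scenario.erp_s3}
    k = fields.map_index

    rmse_map, rmse_mean, ise, frac, excluded = {}, {}, {}, {}, {}
    for proto in ("S2", "S3"):
        d = draws[proto]
        mean = d.mean(axis=0)
        sd = d.std(axis=0, ddof=0)
        rmse_map[proto] = float(np.sqrt(np.mean((d[k] - truth[proto]) ** 2)))
        rmse_mean[proto] = float(np.sqrt(np.mean((mean - truth[proto]) ** 2)))
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.abs(truth[proto] - mean) / sd
        zero = sd == 0
        e[zero] = np.nan
        ise[proto] = e
        excluded[proto] = int(zero.sum())
        defined = e[~zero]
        frac[proto] = float(np.mean(defined < 3.0)) if len(defined) else np.nan
    return ValidationMetrics(
        rmse_map=rmse_map,
        rmse_mean=rmse_mean,
        ise=ise,
        ise_below_3=frac,
        excluded=excluded,
    )
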