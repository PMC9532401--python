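"""Interval-censored ERP observations from a ground-truth scenario."""

from __future__ import annotations

import math
from typing import List

import numpy as np

from ..calibration.likelihood import ERPIntervalObservation
from .sites import ObservationDesign
from .truth import GroundTruthScenario

__all__ = ["observe_erp"]


def _bracket(value: float, resolution: float):
    """Grid interval [I, I + resolution] containing the value (grid at 0)."""
    idx = math.floor(value / resolution)
    if value == idx * resolution:  # exactly on a grid line: take the lower cell
        idx -= 1
    return idx * resolution


def observe_erp(
    scenario: GroundTruthScenario,
    design: ObservationDesign,
    resolution: float = 10.0,
    *,
    protocols=("S2", "S3"),
) -> List[ERPIntervalObservation]:
    """For each site and protocol, the resolution-grid bracket containing the
    surrogate-computed true ERP.  Two observations per site by default."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    obs: List[ERPIntervalObservation] = []
    fields = {"S2": scenario.erp_s2, "S3": scenario.erp_s3}
    for v in design.vertex_ids:
        for proto in protocols:
            val = float(fields[proto][v])
            low = _bracket(val, resolution)
            if low <= 0:
                continue  # outside the measurable grid; flagged by omission
            obs.append(
                ERPIntervalObservation(
                    vertex=int(v),
                    protocol=proto,
                    interval_low=low,
                    interval_width=resolution,
                )
            )
    return obs
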