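"""Training tables: run both pacing protocols over a parameter design."""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .params import TransformedEPParams
from .protocols import PacingProtocol, erp_s1s2, erp_s1s2s3, run_s1_train
from .simulator import CableConfig

__all__ = ["generate_training_table", "TABLE_COLUMNS"]

TABLE_COLUMNS = [
    "cv_max", "tau_in", "tau_out", "tau_open", "apd_max",
    "erp_s2", "erp_s3",
    "erp_s2_lo", "erp_s2_hi", "erp_s3_lo", "erp_s3_hi",
    "flag_s2", "flag_s3",
]

# Surrogate-training convention: these two parameters are held fixed.
SURROGATE_FIXED = {"tau_in": 0.05, "tau_open": 120.0}


def generate_training_table(
    design: Sequence[TransformedEPParams] | np.ndarray,
    cfg: Optional[CableConfig] = None,
    s1s2: Optional[PacingProtocol] = None,
    s1s2s3: Optional[PacingProtocol] = None,
    *,
    progress: bool = False,
) -> pd.DataFrame:
    """One row per design point with ERP_S2 and ERP_S3 (and their brackets).

    design: either TransformedEPParams objects, or an (n, 3) array of
    (cv_max, tau_out, apd_max) columns with tau_in/tau_open at the fixed
    surrogate-training values, or an (n, 5) array of all parameters.
    Failed protocol runs are flagged in flag_s2/flag_s3, never dropped.
    """
    cfg = cfg or CableConfig()
    s1s2 = s1s2 or PacingProtocol(kind="S1S2")
    s1s2s3 = s1s2s3 or PacingProtocol(kind="S1S2S3")
    if s1s2.s1_interval != s1s2s3.s1_interval or s1s2.n_s1 != s1s2s3.n_s1:
        raise ValueError("protocols must share the S1 train")

    points = []
    if isinstance(design, np.ndarray):
        if design.ndim != 2 or design.shape[1] not in (3, 5):
            raise ValueError("design array must be (n, 3) or (n, 5)")
        for row in design:
            if design.shape[1] == 3:
                points.append(TransformedEPParams(
                    cv_max=row[0], tau_out=row[1], apd_max=row[2],
                    **SURROGATE_FIXED,
                ))
            else:
                points.append(TransformedEPParams(*row))
    else:
        points = list(design)

    rows = []
    for idx, p in enumerate(points):
        train = run_s1_train(p, cfg, s1s2)
        r2 = erp_s1s2(p, s1s2, cfg, train=train)
        r3 = erp_s1s2s3(p, s1s2s3, cfg, train=train)
        rows.append({
            "cv_max": p.cv_max, "tau_in": p.tau_in, "tau_out": p.tau_out,
            "tau_open": p.tau_open, "apd_max": p.apd_max,
            "erp_s2": r2.erp if r2.ok else np.nan,
            "erp_s3": r3.erp if r3.ok else np.nan,
            "erp_s2_lo": r2.bracket[0] if r2.ok else np.nan,
            "erp_s2_hi": r2.bracket[1] if r2.ok else np.nan,
            "erp_s3_lo": r3.bracket[0] if r3.ok else np.nan,
            "erp_s3_hi": r3.bracket[1] if r3.ok else np.nan,
            "flag_s2": r2.status, "flag_s3": r3.status,
        })
        if progress:
            print(f"[erp-table] {idx + 1}/{len(points)}", flush=True)
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)
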