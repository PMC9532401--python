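"""Response-surface analyses of the strip simulator.

The S1S2S3 protocol's ERP_S3 response is smooth while the fixed S2 beat is
well clear of refractoriness, but becomes non-monotonic and then breaks
down (S2 capture failure) as ERP_S2 approaches the S2 interval.  The onset
of that discontinuous regime is located by sweeping a path of increasing
ERP_S2 and detecting the trend reversal of ERP_S3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .params import TransformedEPParams
from .protocols import PacingProtocol, erp_s1s2, erp_s1s2s3, run_s1_train
from .simulator import CableConfig

__all__ = ["find_erp_s3_discontinuity", "DiscontinuityResult"]


@dataclass
class DiscontinuityResult:
    erp_s2_at_jump: Optional[float]  # ms; None if no reversal found
    table: pd.DataFrame              # the full sweep (apd_max, erp_s2, erp_s3)


def find_erp_s3_discontinuity(
    *,
    tau_out: float = 10.0,
    tau_in: float = 0.05,
    tau_open: float = 120.0,
    cv_max: float = 0.6,
    apd_grid: Optional[np.ndarray] = None,
    s1: float = 600.0,
    s2: float = 300.0,
    refine_tol: float = 0.5,
    jump_threshold: float = 2.0,
    cfg: Optional[CableConfig] = None,
) -> DiscontinuityResult:
    """Sweep apd_max along a path of increasing ERP_S2 and return the ERP_S2
    level at which the ERP_S3 response reverses trend (the discontinuity
    onset of the S1S2S3 protocol at fixed S2)."""
    cfg = cfg or CableConfig()
    if apd_grid is None:
        apd_grid = np.arange(225.0, 256.0, 2.5)
    p2 = PacingProtocol(kind="S1S2", s1_interval=s1, refine_tol=refine_tol)
    p3 = PacingProtocol(kind="S1S2S3", s1_interval=s1, s2_interval=s2,
                        refine_tol=refine_tol)
    rows = []
    for apd in apd_grid:
        p = TransformedEPParams(cv_max=cv_max, tau_in=tau_in, tau_out=tau_out,
                                tau_open=tau_open, apd_max=float(apd))
        train = run_s1_train(p, cfg, p2)
        r2 = erp_s1s2(p, p2, cfg, train=train)
        r3 = erp_s1s2s3(p, p3, cfg, train=train)
        rows.append({
            "apd_max": float(apd),
            "erp_s2": r2.erp if r2.ok else np.nan,
            "erp_s3": r3.erp if r3.ok else np.nan,
            "s3_status": r3.status,
        })
    table = pd.DataFrame(rows)

    jump = None
    seen_decrease = False
    e3 = table["erp_s3"].to_numpy()
    e2 = table["erp_s2"].to_numpy()
    for i in range(1, len(table)):
        if not (np.isfinite(e3[i - 1]) and np.isfinite(e2[i])):
            # S2 capture failure: a hard discontinuity in itself
            if seen_decrease and jump is None and np.isfinite(e2[i]):
                jump = float(e2[i])
            continue
        if not np.isfinite(e3[i]):
            if jump is None:
                jump = float(e2[i])
            break
        d = e3[i] - e3[i - 1]
        if d < 0:
            seen_decrease = True
        elif seen_decrease and d > jump_threshold:
            jump = float(e2[i])
            break
    return DiscontinuityResult(erp_s2_at_jump=jump, table=table)
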