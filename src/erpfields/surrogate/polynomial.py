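"""Bivariate cubic polynomial surrogates mapping (tau_out, apd_max) -> ERP.

Inputs are standardized to [-1, 1] over the training rectangle; the full
10-term cubic basis is used.  Rows whose ERP_S2 exceeds the validity
ceiling (280 ms by default) are discarded before fitting, and predictions
in that region are flagged rather than raised so samplers can traverse it.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Tuple

import numpy as np
import pandas as pd

__all__ = ["SurrogateFunction", "fit_surrogates", "predict_erp", "ERP_S2_CEILING"]

ERP_S2_CEILING = 280.0

# exponents of the complete bivariate cubic, (i, j) -> x^i y^j
_EXPONENTS = [(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2),
              (3, 0), (2, 1), (1, 2), (0, 3)]


def _design_matrix(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    cols = [x**i * y**j for i, j in _EXPONENTS]
    return np.stack(cols, axis=-1)


def _design_grad(x: np.ndarray, y: np.ndarray):
    """Partial derivatives of the basis wrt x and y."""
    gx = [i * x ** max(i - 1, 0) * y**j for i, j in _EXPONENTS]
    gy = [j * x**i * y ** max(j - 1, 0) for i, j in _EXPONENTS]
    return np.stack(gx, axis=-1), np.stack(gy, axis=-1)


@dataclass(frozen=True)
class SurrogateFunction:
    """A fitted cubic in standardized (tau_out, apd_max)."""

    coefficients: np.ndarray         # length 10
    center: Tuple[float, float]      # standardization centers (tau_out, apd_max)
    halfwidth: Tuple[float, float]   # standardization half-widths
    residual_rms: float
    name: str = "erp"
    mask_ceiling: Optional[float] = None  # ERP_S2 level above which predictions are masked

    def _standardize(self, tau_out, apd_max):
        x = (np.asarray(tau_out, dtype=float) - self.center[0]) / self.halfwidth[0]
        y = (np.asarray(apd_max, dtype=float) - self.center[1]) / self.halfwidth[1]
        return x, y

    def __call__(self, tau_out, apd_max) -> np.ndarray:
        x, y = self._standardize(tau_out, apd_max)
        return _design_matrix(x, y) @ self.coefficients

    def gradient(self, tau_out, apd_max):
        """(d/d tau_out, d/d apd_max) of the prediction (chain rule through
        the standardization)."""
        x, y = self._standardize(tau_out, apd_max)
        gx, gy = _design_grad(x, y)
        return (
            (gx @ self.coefficients) / self.halfwidth[0],
            (gy @ self.coefficients) / self.halfwidth[1],
        )

    def in_training_rectangle(self, tau_out, apd_max) -> np.ndarray:
        x, y = self._standardize(tau_out, apd_max)
        return (np.abs(x) <= 1.0 + 1e-9) & (np.abs(y) <= 1.0 + 1e-9)

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "coefficients": self.coefficients.tolist(),
            "center": list(self.center),
            "halfwidth": list(self.halfwidth),
            "residual_rms": self.residual_rms,
            "mask_ceiling": self.mask_ceiling,
            "basis_exponents": _EXPONENTS,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SurrogateFunction":
        return cls(
            coefficients=np.asarray(d["coefficients"], dtype=float),
            center=tuple(d["center"]),
            halfwidth=tuple(d["halfwidth"]),
            residual_rms=float(d["residual_rms"]),
            name=d.get("name", "erp"),
            mask_ceiling=d.get("mask_ceiling"),
        )


def _fit_one(
    tau_out: np.ndarray, apd_max: np.ndarray, erp: np.ndarray, name: str,
    mask_ceiling: Optional[float],
) -> SurrogateFunction:
    cx = (tau_out.min() + tau_out.max()) / 2.0
    cy = (apd_max.min() + apd_max.max()) / 2.0
    hx = (tau_out.max() - tau_out.min()) / 2.0
    hy = (apd_max.max() - apd_max.min()) / 2.0
    if hx <= 0 or hy <= 0:
        raise ValueError(f"rank-deficient design for {name}: an input is constant")
    x = (tau_out - cx) / hx
    y = (apd_max - cy) / hy
    X = _design_matrix(x, y)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for {name}: rank {rank} < {X.shape[1]} "
            "cubic terms; need a richer design"
        )
    beta, *_ = np.linalg.lstsq(X, erp, rcond=None)
    rms = float(np.sqrt(np.mean((X @ beta - erp) ** 2)))
    return SurrogateFunction(
        coefficients=beta,
        center=(cx, cy),
        halfwidth=(hx, hy),
        residual_rms=rms,
        name=name,
        mask_ceiling=mask_ceiling,
    )


def fit_surrogates(
    table: pd.DataFrame,
    *,
    ceiling: float = ERP_S2_CEILING,
    mask_s2_fit: bool = True,
) -> Tuple[SurrogateFunction, SurrogateFunction]:
    """Fit (f1: ERP_S2, f2: ERP_S3) from a cable training table.

    Rows with ERP_S2 > ceiling are discarded before fitting (both fits by
    default; set mask_s2_fit=False to apply the discard to f2 only).
    """
    ok2 = table["flag_s2"].eq("ok") & np.isfinite(table["erp_s2"])
    ok3 = table["flag_s3"].eq("ok") & np.isfinite(table["erp_s3"])
    below = table["erp_s2"] <= ceiling

    sel1 = ok2 & (below | ~mask_s2_fit)
    sel2 = ok2 & ok3 & below
    for name, sel in (("f1", sel1), ("f2", sel2)):
        if sel.sum() < 20:
            raise ValueError(
                f"only {int(sel.sum())} usable rows for {name} after masking; "
                "need at least 20"
            )
    f1 = _fit_one(
        table.loc[sel1, "tau_out"].to_numpy(),
        table.loc[sel1, "apd_max"].to_numpy(),
        table.loc[sel1, "erp_s2"].to_numpy(),
        "erp_s2",
        mask_ceiling=None,
    )
    f2 = _fit_one(
        table.loc[sel2, "tau_out"].to_numpy(),
        table.loc[sel2, "apd_max"].to_numpy(),
        table.loc[sel2, "erp_s3"].to_numpy(),
        "erp_s3",
        mask_ceiling=ceiling,
    )
    return f1, f2


def predict_erp(
    f: SurrogateFunction,
    tau_out,
    apd_max,
    *,
    f1: Optional[SurrogateFunction] = None,
    warn_extrapolation: bool = False,
):
    """Evaluate the surrogate; returns (prediction, masked) where masked
    marks queries in the surrogate's invalid region (predictions there are
    still finite so samplers are never handed infinities)."""
    pred = f(tau_out, apd_max)
    if f.mask_ceiling is not None and f1 is not None:
        masked = f1(tau_out, apd_max) > f.mask_ceiling
    else:
        masked = np.zeros_like(np.asarray(pred), dtype=bool)
    if warn_extrapolation:
        outside = ~f.in_training_rectangle(tau_out, apd_max)
        if np.any(outside):
            warnings.warn(
                f"{int(np.sum(outside))} queries outside the training rectangle "
                f"of {f.name}", stacklevel=2,
            )
    return pred, masked


def save_surrogates(path, f1: SurrogateFunction, f2: SurrogateFunction) -> None:
    with open(path, "w") as fh:
        json.dump({"f1": f1.to_dict(), "f2": f2.to_dict()}, fh, indent=1)


def load_surrogates(path) -> Tuple[SurrogateFunction, SurrogateFunction]:
    with open(path) as fh:
        d = json.load(fh)
    return SurrogateFunction.from_dict(d["f1"]), SurrogateFunction.from_dict(d["f2"])
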