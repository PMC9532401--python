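"""Parameterizations of the modified Mitchell-Schaeffer (mMS) cell model.

Two coordinate systems are used: the *native* parameters that enter the
reaction-diffusion equations, and a *transformed* set (cv_max, tau_in,
tau_out, tau_open, apd_max) in which convex combinations of valid
parameters remain valid, making spatial interpolation safe.

Units: mm, ms, normalized voltage.  cv_max is quoted in m/s which equals
mm/ms, so no numeric conversion is needed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

__all__ = [
    "NativeMMSParams",
    "TransformedEPParams",
    "TRANSFORMED_RANGES",
    "to_native",
    "to_transformed",
]

#: Valid ranges of the transformed parameters (inclusive).
TRANSFORMED_RANGES = {
    "cv_max": (0.1, 1.5),     # m/s == mm/ms
    "tau_in": (0.01, 0.30),   # ms
    "tau_out": (1.0, 30.0),   # ms
    "tau_open": (65.0, 215.0),  # ms
    "apd_max": (120.0, 270.0),  # ms
}

DEFAULT_V_GATE = 0.1


@dataclass(frozen=True)
class NativeMMSParams:
    """Native mMS parameters: four time constants, diffusivity, gate threshold."""

    tau_in: float     # ms
    tau_out: float    # ms
    tau_open: float   # ms
    tau_close: float  # ms
    D: float          # mm^2/ms
    v_gate: float = DEFAULT_V_GATE

    def __post_init__(self) -> None:
        for name in ("tau_in", "tau_out", "tau_open", "tau_close", "D"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")
        if not 0.0 < self.v_gate < 0.5:
            raise ValueError(f"v_gate must lie in (0, 0.5), got {self.v_gate!r}")


@dataclass(frozen=True)
class TransformedEPParams:
    """Transformed EP parameters; the interpolation-safe coordinate system."""

    cv_max: float    # m/s (= mm/ms)
    tau_in: float    # ms
    tau_out: float   # ms
    tau_open: float  # ms
    apd_max: float   # ms

    def __post_init__(self) -> None:
        for name in ("cv_max", "tau_in", "tau_out", "tau_open", "apd_max"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and positive, got {v!r}")

    def check_ranges(self, *, warn: bool = True) -> bool:
        """Return True if all fields lie in the physiological ranges.

        Out-of-range values only warn: posterior samples slightly outside
        the ranges must still be evaluable.
        """
        ok = True
        for name, (lo, hi) in TRANSFORMED_RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                ok = False
                if warn:
                    warnings.warn(
                        f"{name}={v:g} outside physiological range [{lo:g}, {hi:g}]",
                        stacklevel=2,
                    )
        return ok

    def replace(self, **kw) -> "TransformedEPParams":
        return replace(self, **kw)


def to_native(p: TransformedEPParams, v_gate: float = DEFAULT_V_GATE) -> NativeMMSParams:
    """Invert the reparameterization: recover (D, tau_close) from (cv_max, apd_max).

    cv_max = 0.5 (1 - 2 v_gate) sqrt(2 D / tau_in)
    apd_max = tau_close log(1 + tau_out (1 - v_gate)^2 / (4 tau_in))
    """
    gate = 0.5 * (1.0 - 2.0 * v_gate)
    D = 0.5 * p.tau_in * (p.cv_max / gate) ** 2
    arg = 1.0 + p.tau_out * (1.0 - v_gate) ** 2 / (4.0 * p.tau_in)
    if arg <= 1.0:
        raise ValueError("invalid parameter combination: log argument <= 1")
    tau_close = p.apd_max / math.log(arg)
    return NativeMMSParams(
        tau_in=p.tau_in,
        tau_out=p.tau_out,
        tau_open=p.tau_open,
        tau_close=tau_close,
        D=D,
        v_gate=v_gate,
    )


def to_transformed(p: NativeMMSParams) -> TransformedEPParams:
    """Forward maps from native to transformed parameters."""
    gate = 0.5 * (1.0 - 2.0 * p.v_gate)
    cv_max = gate * math.sqrt(2.0 * p.D / p.tau_in)
    apd_max = p.tau_close * math.log(
        1.0 + p.tau_out * (1.0 - p.v_gate) ** 2 / (4.0 * p.tau_in)
    )
    return TransformedEPParams(
        cv_max=cv_max,
        tau_in=p.tau_in,
        tau_out=p.tau_out,
        tau_open=p.tau_open,
        apd_max=apd_max,
    )
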