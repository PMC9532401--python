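"""Strip-of-tissue simulator: configuration, integration wrapper, trace measurement."""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._kernels import mms_integrate
from .params import NativeMMSParams

__all__ = [
    "CableConfig",
    "SimResult",
    "TraceMeasurement",
    "NumericalBlowupError",
    "simulate_cable",
    "measure_trace",
]

# Recovery thresholds of the normalized action potential: APD_x is the time
# from activation (upstroke through 0.7) until V falls to the given level.
ACTIVATION_LEVEL = 0.7
APD_LEVELS = {"apd20": 0.8, "apd30": 0.7, "apd50": 0.5, "apd90": 0.1}


class NumericalBlowupError(RuntimeError):
    """The integrator left a sane voltage envelope (instability), not a model result."""


@dataclass(frozen=True)
class CableConfig:
    """Geometry, discretization and stimulus settings for the tissue strip.

    The strip is paced from one end (the first ``stim_extent`` mm of nodes)
    and activation is measured at ``measure_frac`` of the length.
    """

    length: float = 20.0          # mm
    dx: float = 0.3               # mm
    dt_diffusion: float = 0.1     # ms
    dt_ionic: float = 0.02        # ms
    stim_extent: float = 0.9      # mm paced at the cable end
    measure_frac: float = 0.5     # measurement site as fraction of length
    stim_amplitude: float = 1.0   # 1/ms, added to dV/dt while active
    stim_duration: float = 2.0    # ms

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.length <= 0:
            raise ValueError("length and dx must be positive")
        n_sub = self.dt_diffusion / self.dt_ionic
        if abs(n_sub - round(n_sub)) > 1e-9:
            raise ValueError("dt_ionic must divide dt_diffusion")
        if not 0.0 < self.measure_frac < 1.0:
            raise ValueError("measurement site must be strictly inside the cable")
        if self.stim_extent <= 0 or self.stim_extent >= self.length:
            raise ValueError("stim_extent must lie in (0, length)")

    @property
    def n_nodes(self) -> int:
        return int(round(self.length / self.dx)) + 1

    @property
    def n_sub(self) -> int:
        return int(round(self.dt_diffusion / self.dt_ionic))

    @property
    def n_stim_nodes(self) -> int:
        return max(1, int(round(self.stim_extent / self.dx)))

    @property
    def measure_node(self) -> int:
        return int(round(self.measure_frac * (self.n_nodes - 1)))


@dataclass
class SimResult:
    """Output of a cable run: the measurement-site trace and optional full fields."""

    times: np.ndarray            # trace sample times (end of each diffusion step)
    trace: np.ndarray            # V at the measurement node
    V: Optional[np.ndarray]      # (n_steps, n_nodes) if recorded
    h: Optional[np.ndarray]
    final_V: np.ndarray
    final_h: np.ndarray


@dataclass(frozen=True)
class TraceMeasurement:
    local_activation_time: Optional[float]
    apd20: Optional[float] = None
    apd30: Optional[float] = None
    apd50: Optional[float] = None
    apd90: Optional[float] = None
    activation_success: bool = False


def simulate_cable(
    p: NativeMMSParams,
    stimuli: Sequence[float],
    cfg: CableConfig,
    duration: float,
    *,
    V0: Optional[np.ndarray] = None,
    h0: Optional[np.ndarray] = None,
    t0: float = 0.0,
    record_full: bool = False,
) -> SimResult:
    """Integrate the mMS monodomain equations on the strip.

    stimuli are pulse onset times (ms, absolute); each pulse lasts
    cfg.stim_duration and is applied to the paced end of the strip.
    """
    stim_times = np.asarray(sorted(stimuli), dtype=float)
    n = cfg.n_nodes
    V = np.zeros(n) if V0 is None else np.array(V0, dtype=float)
    h = np.ones(n) if h0 is None else np.array(h0, dtype=float)
    if V.shape != (n,) or h.shape != (n,):
        raise ValueError("initial state shape does not match the grid")

    n_steps = int(round(duration / cfg.dt_diffusion))
    trace = np.empty(n_steps)
    if record_full:
        full_V = np.empty((n_steps, n))
        full_h = np.empty((n_steps, n))
    else:
        full_V = np.empty((0, 0))
        full_h = np.empty((0, 0))

    r = p.D * cfg.dt_diffusion / cfg.dx**2
    bad = mms_integrate(
        V,
        h,
        t0,
        n_steps,
        cfg.dt_diffusion,
        cfg.n_sub,
        r,
        p.tau_in,
        p.tau_out,
        p.tau_open,
        p.tau_close,
        p.v_gate,
        stim_times,
        cfg.stim_duration,
        cfg.stim_amplitude,
        cfg.n_stim_nodes,
        cfg.measure_node,
        trace,
        full_V,
        full_h,
        record_full,
    )
    if bad >= 0:
        raise NumericalBlowupError(
            f"voltage diverged at t={t0 + bad * cfg.dt_diffusion:g} ms; "
            "unstable configuration"
        )
    times = t0 + cfg.dt_diffusion * (np.arange(n_steps) + 1)
    return SimResult(
        times=times,
        trace=trace,
        V=full_V if record_full else None,
        h=full_h if record_full else None,
        final_V=V,
        final_h=h,
    )


def _up_crossing(times: np.ndarray, v: np.ndarray, level: float, t_after: float) -> Optional[float]:
    """First upward crossing of level strictly after t_after, linearly interpolated."""
    mask = times > t_after
    if not mask.any():
        return None
    i0 = int(np.argmax(mask))
    prev = v[i0 - 1] if i0 > 0 else v[i0]
    for i in range(i0, len(v)):
        cur = v[i]
        if prev < level <= cur:
            t_prev = times[i - 1] if i > 0 else t_after
            frac = (level - prev) / (cur - prev)
            return float(t_prev + frac * (times[i] - t_prev))
        prev = cur
    return None


def _down_crossing(times: np.ndarray, v: np.ndarray, level: float, t_after: float) -> Optional[float]:
    """First downward crossing of level strictly after t_after."""
    mask = times > t_after
    if not mask.any():
        return None
    i0 = int(np.argmax(mask))
    prev = v[i0 - 1] if i0 > 0 else v[i0]
    for i in range(i0, len(v)):
        cur = v[i]
        if prev > level >= cur:
            t_prev = times[i - 1] if i > 0 else t_after
            frac = (prev - level) / (prev - cur)
            return float(t_prev + frac * (times[i] - t_prev))
        prev = cur
    return None


def measure_trace(
    times: np.ndarray,
    v: np.ndarray,
    *,
    window_start: float = -math.inf,
    window_end: float = math.inf,
) -> TraceMeasurement:
    """Measure activation and APD recovery levels from a voltage trace.

    Activation is the first upward crossing of 0.7 inside the window;
    APD20/30/50/90 are the first downward crossings of 0.8/0.7/0.5/0.1
    after activation (absent, not zero, if repolarization is not reached
    within the trace).
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    lat = _up_crossing(times, v, ACTIVATION_LEVEL, max(window_start, times[0] - 1e-12))
    if lat is None or lat > window_end:
        return TraceMeasurement(local_activation_time=None, activation_success=False)
    apds = {}
    for name, level in APD_LEVELS.items():
        t_rec = _down_crossing(times, v, level, lat)
        apds[name] = None if t_rec is None else t_rec - lat
    return TraceMeasurement(
        local_activation_time=lat,
        activation_success=True,
        **apds,
    )
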