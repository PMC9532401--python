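"""S1S2 and S1S2S3 pacing protocols and ERP measurement on the strip.

ERP is the shortest extra-stimulus coupling interval that still elicits a
propagated activation at the measurement site.  The scan descends from the
preceding pacing interval in steps of the configured resolution; the
bracket is then optionally refined by bisection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .params import NativeMMSParams, TransformedEPParams, to_native
from .simulator import (
    ACTIVATION_LEVEL,
    CableConfig,
    _down_crossing,
    _up_crossing,
    simulate_cable,
)

__all__ = [
    "PacingProtocol",
    "ErpResult",
    "S1TrainState",
    "run_s1_train",
    "erp_s1s2",
    "erp_s1s2s3",
]


@dataclass(frozen=True)
class PacingProtocol:
    """Protocol settings.  kind 'S1S2' scans the S2 interval after a train of
    S1 beats; 'S1S2S3' fixes one premature S2 beat and scans the S3 interval."""

    kind: str = "S1S2"
    s1_interval: float = 600.0
    n_s1: int = 8
    s2_interval: float = 300.0  # used by S1S2S3 only
    scan_resolution: float = 10.0
    scan_min: float = 20.0
    refine_tol: Optional[float] = 1.0  # ms; None disables bisection refinement

    def __post_init__(self) -> None:
        if self.kind not in ("S1S2", "S1S2S3"):
            raise ValueError(f"unknown protocol kind {self.kind!r}")
        if self.n_s1 < 1:
            raise ValueError("n_s1 must be >= 1")
        if self.scan_resolution <= 0:
            raise ValueError("scan_resolution must be positive")
        if self.kind == "S1S2S3" and not self.s1_interval > self.s2_interval:
            raise ValueError("need s1_interval > s2_interval")


@dataclass
class ErpResult:
    """Outcome of an ERP scan.

    status: 'ok', 'above_range' (no scanned interval captured),
    'below_range' (every scanned interval captured), or 's2_no_capture'
    (S1S2S3 only: the fixed S2 beat failed, protocol invalid).
    """

    erp: Optional[float]                       # refined (continuous) estimate, ms
    bracket: Optional[Tuple[float, float]]     # [largest failing, smallest capturing]
    status: str = "ok"
    n_runs: int = 0

    @property
    def ok(self) -> bool:
        return self.status == "ok"


@dataclass
class S1TrainState:
    """Tissue state immediately before the final S1 stimulus of the train."""

    V: np.ndarray
    h: np.ndarray
    native: NativeMMSParams
    cfg: CableConfig
    s1_interval: float


def run_s1_train(
    p: TransformedEPParams,
    cfg: CableConfig,
    proto: PacingProtocol,
) -> S1TrainState:
    """Pace the rested strip with n_s1 - 1 beats; the final S1 beat is applied
    per scan candidate so the saved state is candidate-independent."""
    native = to_native(p)
    n_pre = proto.n_s1 - 1
    if n_pre == 0:
        n = cfg.n_nodes
        return S1TrainState(np.zeros(n), np.ones(n), native, cfg, proto.s1_interval)
    stimuli = [i * proto.s1_interval for i in range(n_pre)]
    res = simulate_cable(native, stimuli, cfg, duration=n_pre * proto.s1_interval)
    return S1TrainState(res.final_V, res.final_h, native, cfg, proto.s1_interval)


#: A new activation at the measurement site only counts if the site first
#: repolarized below this level after the test stimulus; plateau-level
#: wiggles from stimulating refractory tissue are not capture.
REARM_LEVEL = 0.5

#: Margin (ms) separating a genuine test-beat activation from the arrival
#: of the preceding beat's own wavefront (which a test stimulus cannot
#: overtake on the cable).
BASELINE_MARGIN = 2.0


def _all_up_crossings(times: np.ndarray, v: np.ndarray, level: float) -> list:
    above = v >= level
    idx = np.flatnonzero(~above[:-1] & above[1:]) + 1
    out = []
    for i in idx:
        frac = (level - v[i - 1]) / (v[i] - v[i - 1])
        out.append(float(times[i - 1] + frac * (times[i] - times[i - 1])))
    return out


def _baseline_crossings(state: S1TrainState, offsets, duration: float) -> list:
    """Activation times at the measurement site when the test beat is absent
    (prior stimuli only); used to reject misattributed captures."""
    res = simulate_cable(
        state.native, list(offsets), state.cfg, duration=duration,
        V0=state.V, h0=state.h,
    )
    return _all_up_crossings(res.times, res.trace, ACTIVATION_LEVEL)


def _test_capture(
    state: S1TrainState,
    offsets,
    test_offset: float,
    window: float,
    baseline: list,
) -> bool:
    """Apply stimuli at the given offsets (relative to the saved state) and
    report whether the beat at test_offset itself propagates to the
    measurement site within the window.

    Two guards against false positives: the site must repolarize below
    REARM_LEVEL after the test stimulus before an activation counts, and
    activations coinciding with (or earlier than) the latest baseline
    arrival are attributed to the preceding beats, not the test beat.
    """
    duration = test_offset + window
    res = simulate_cable(
        state.native, list(offsets), state.cfg, duration=duration,
        V0=state.V, h0=state.h,
    )
    t_after = test_offset
    prior = [t for t in baseline if t <= duration + BASELINE_MARGIN]
    if prior:
        t_after = max(t_after, prior[-1] + BASELINE_MARGIN)
    idx = min(np.searchsorted(res.times, t_after), len(res.trace) - 1)
    if res.trace[idx] > REARM_LEVEL:
        t_armed = _down_crossing(res.times, res.trace, REARM_LEVEL, t_after)
        if t_armed is None:
            return False
        t_after = t_armed
    lat = _up_crossing(res.times, res.trace, ACTIVATION_LEVEL, t_after)
    return lat is not None and lat <= test_offset + window


def _scan_down(capture, start: float, res: float, scan_min: float):
    """Descend from `start` in steps of `res`; return (bracket, n_runs, status)."""
    n_runs = 0
    s = start
    prev_capturing = None
    while s >= scan_min - 1e-9:
        n_runs += 1
        if capture(s):
            prev_capturing = s
            s -= res
        else:
            if prev_capturing is None:
                return None, n_runs, "above_range"
            return (s, prev_capturing), n_runs, "ok"
    return None, n_runs, "below_range"


def _refine(capture, lo: float, hi: float, tol: float):
    """Bisection: lo fails, hi captures; shrink to width <= tol."""
    n_runs = 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        n_runs += 1
        if capture(mid):
            hi = mid
        else:
            lo = mid
    return lo, hi, n_runs


def erp_s1s2(
    p: TransformedEPParams,
    proto: PacingProtocol,
    cfg: Optional[CableConfig] = None,
    *,
    train: Optional[S1TrainState] = None,
) -> ErpResult:
    """Measure ERP under S1S2 pacing (scan the S2 coupling interval)."""
    if proto.kind != "S1S2":
        raise ValueError("protocol kind must be S1S2")
    cfg = cfg or CableConfig()
    state = train if train is not None else run_s1_train(p, cfg, proto)
    baseline = _baseline_crossings(state, [0.0], 2.0 * proto.s1_interval)
    # allow for conduction latency to the measurement site (large at low CV)
    latency = max(0.0, baseline[-1]) if baseline else 0.0

    def capture(s: float) -> bool:
        return _test_capture(
            state, [0.0, s], s, window=s + latency, baseline=baseline
        )

    bracket, n_runs, status = _scan_down(
        capture, proto.s1_interval, proto.scan_resolution, proto.scan_min
    )
    if status != "ok":
        return ErpResult(erp=None, bracket=None, status=status, n_runs=n_runs)
    lo, hi = bracket
    if proto.refine_tol is not None and hi - lo > proto.refine_tol:
        lo_r, hi_r, extra = _refine(capture, lo, hi, proto.refine_tol)
        n_runs += extra
        erp = 0.5 * (lo_r + hi_r)
    else:
        erp = 0.5 * (lo + hi)
    return ErpResult(erp=erp, bracket=bracket, status="ok", n_runs=n_runs)


def erp_s1s2s3(
    p: TransformedEPParams,
    proto: PacingProtocol,
    cfg: Optional[CableConfig] = None,
    *,
    train: Optional[S1TrainState] = None,
) -> ErpResult:
    """Measure ERP under S1S2S3 pacing: one fixed premature S2 beat, then scan S3.

    The S2 beat itself must capture; if it does not the protocol is invalid
    for these parameters (status 's2_no_capture')."""
    if proto.kind != "S1S2S3":
        raise ValueError("protocol kind must be S1S2S3")
    cfg = cfg or CableConfig()
    s1proto = PacingProtocol(kind="S1S2", s1_interval=proto.s1_interval, n_s1=proto.n_s1)
    state = train if train is not None else run_s1_train(p, cfg, s1proto)
    s2 = proto.s2_interval
    base_s1 = _baseline_crossings(state, [0.0], 2.0 * proto.s1_interval)
    latency = max(0.0, base_s1[-1]) if base_s1 else 0.0

    if not _test_capture(
        state, [0.0, s2], s2, window=s2 + latency, baseline=base_s1
    ):
        return ErpResult(erp=None, bracket=None, status="s2_no_capture", n_runs=1)

    base_s2 = _baseline_crossings(
        state, [0.0, s2], 2.0 * (s2 + proto.s2_interval) + latency
    )

    def capture(s: float) -> bool:
        return _test_capture(
            state, [0.0, s2, s2 + s], s2 + s, window=s + latency, baseline=base_s2
        )

    bracket, n_runs, status = _scan_down(
        capture, s2, proto.scan_resolution, proto.scan_min
    )
    n_runs += 1
    if status != "ok":
        return ErpResult(erp=None, bracket=None, status=status, n_runs=n_runs)
    lo, hi = bracket
    if proto.refine_tol is not None and hi - lo > proto.refine_tol:
        lo_r, hi_r, extra = _refine(capture, lo, hi, proto.refine_tol)
        n_runs += extra
        erp = 0.5 * (lo_r + hi_r)
    else:
        erp = 0.5 * (lo + hi)
    return ErpResult(erp=erp, bracket=bracket, status="ok", n_runs=n_runs)
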