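"""Numba kernels for the 1D monodomain mMS integrator.

Operator splitting: forward-Euler reaction sub-cycled at the ionic time
step inside each diffusion step, then a Crank-Nicolson diffusion solve
(Thomas algorithm, flux-form no-flux boundaries).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["mms_integrate"]


@njit(cache=True)
def _thomas_factor(a, b, c, n):
    """Precompute forward-elimination coefficients for a constant tridiagonal system."""
    cp = np.empty(n)
    bp = np.empty(n)
    bp[0] = b[0]
    cp[0] = c[0] / b[0]
    for i in range(1, n):
        bp[i] = b[i] - a[i] * cp[i - 1]
        cp[i] = c[i] / bp[i]
    return bp, cp


@njit(cache=True)
def mms_integrate(
    V,
    h,
    t0,
    n_steps,
    dt,
    n_sub,
    r,
    tau_in,
    tau_out,
    tau_open,
    tau_close,
    v_gate,
    stim_times,
    stim_dur,
    stim_amp,
    stim_n,
    rec,
    trace,
    full_V,
    full_h,
    store_full,
):
    """Advance (V, h) in place over n_steps diffusion steps of size dt.

    r = D*dt/dx^2.  trace receives V[rec] after every diffusion step.
    Returns -1 on success, else the step index at which the solution
    became non-finite or left a sane envelope.
    """
    n = V.shape[0]
    dt_i = dt / n_sub

    # Crank-Nicolson matrices: (I - r/2 L) V' = (I + r/2 L) V with
    # L the flux-form 1D Laplacian (no-flux ends).
    a = np.empty(n)
    b = np.empty(n)
    c = np.empty(n)
    half = 0.5 * r
    for i in range(n):
        a[i] = -half
        c[i] = -half
        b[i] = 1.0 + r
    b[0] = 1.0 + half
    b[n - 1] = 1.0 + half
    a[0] = 0.0
    c[n - 1] = 0.0
    bp, cp = _thomas_factor(a, b, c, n)

    rhs = np.empty(n)
    y = np.empty(n)

    for step in range(n_steps):
        t = t0 + step * dt
        # reaction substeps
        for sub in range(n_sub):
            ts = t + sub * dt_i
            amp = 0.0
            for j in range(stim_times.shape[0]):
                if stim_times[j] <= ts < stim_times[j] + stim_dur:
                    amp = stim_amp
                    break
            for i in range(n):
                v = V[i]
                g = h[i]
                dv = (
                    g * v * (v - v_gate) * (1.0 - v) / tau_in
                    - (1.0 - g) * v / tau_out
                )
                if amp != 0.0 and i < stim_n:
                    dv += amp
                if v <= v_gate:
                    dg = (1.0 - g) / tau_open
                else:
                    dg = -g / tau_close
                V[i] = v + dt_i * dv
                g = g + dt_i * dg
                if g < 0.0:
                    g = 0.0
                elif g > 1.0:
                    g = 1.0
                h[i] = g

        # CN diffusion
        rhs[0] = (1.0 - half) * V[0] + half * V[1]
        for i in range(1, n - 1):
            rhs[i] = half * V[i - 1] + (1.0 - r) * V[i] + half * V[i + 1]
        rhs[n - 1] = half * V[n - 2] + (1.0 - half) * V[n - 1]

        y[0] = rhs[0] / bp[0]
        for i in range(1, n):
            y[i] = (rhs[i] - a[i] * y[i - 1]) / bp[i]
        V[n - 1] = y[n - 1]
        for i in range(n - 2, -1, -1):
            V[i] = y[i] - cp[i] * V[i + 1]

        trace[step] = V[rec]
        if store_full:
            for i in range(n):
                full_V[step, i] = V[i]
                full_h[step, i] = h[i]

        if step % 200 == 0:
            bad = False
            for i in range(n):
                if not np.isfinite(V[i]) or V[i] > 10.0 or V[i] < -10.0:
                    bad = True
                    break
            if bad:
                return step
    for i in range(n):
        if not np.isfinite(V[i]) or V[i] > 10.0 or V[i] < -10.0:
            return n_steps - 1
    return -1
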