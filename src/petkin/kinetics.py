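"""Numerical core shared by the simulator and the compartment fitters.

The tissue response of a serial compartment model is a sum of exponentials
convolved with the arterial input.  With the input taken as piecewise linear
between grid samples, the convolution with ``exp(-a t)`` satisfies an exact
one-step recurrence, which we evaluate with a first-order IIR filter: no
quadrature error beyond the linear-interpolation assumption, and stable for
arbitrarily large ``a * t``.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import lfilter

from .data import InputFunction, TimeActivityCurve

__all__ = [
    "exp_conv",
    "tissue_frame_average",
    "irf_coefficients_1tc",
    "irf_coefficients_2tc",
    "tissue_curve_on_grid",
    "frame_average",
    "model_grid",
]

DEFAULT_GRID_STEP = 0.1  # minutes


def exp_conv(rate: float, dt: float, values: np.ndarray) -> np.ndarray:
    """Convolve ``values`` (piecewise linear, uniform step ``dt``) with exp(-rate t).

    Returns y(t_n) = int_0^{t_n} exp(-rate s) * f(t_n - s) ds for the linear
    interpolant f of ``values``; exact per segment:

        y_{n+1} = E y_n + c_{n+1},  E = exp(-rate dt),
        c_{n+1} = f_{n+1} (1-E)/a - b (1 - (1 + a dt) E)/a^2,

    with b the segment slope.  Evaluated via scipy.signal.lfilter.
    """
    a = float(rate)
    if a <= 0:
        raise ValueError("rate must be positive")
    values = np.asarray(values, dtype=float)
    n = len(values)
    if n == 0:
        return values.copy()
    E = np.exp(-a * dt)
    b = np.empty(n)
    b[0] = 0.0
    b[1:] = np.diff(values) / dt
    c = values * (1.0 - E) / a - b * (1.0 - (1.0 + a * dt) * E) / a**2
    c[0] = 0.0  # y(0) = 0
    return lfilter([1.0], [1.0, -E], c)


def irf_coefficients_1tc(K1: float, k2: float):
    """1TC impulse response K1 exp(-k2 t) as [(coef, rate)]."""
    return [(K1, k2)]


def irf_coefficients_2tc(K1: float, k2: float, k3: float, k4: float):
    """Serial 2TC impulse response as a sum of two exponentials.

    h(t) = K1/(a2-a1) [ (k3+k4-a1) e^{-a1 t} + (a2-k3-k4) e^{-a2 t} ]
    with a1,2 the roots of s^2 - (k2+k3+k4) s + k2 k4.
    """
    s = k2 + k3 + k4
    disc = s * s - 4.0 * k2 * k4
    d = np.sqrt(max(disc, 0.0))
    a1 = 0.5 * (s - d)
    a2 = 0.5 * (s + d)
    a1 = max(a1, 1e-12)
    d = max(a2 - a1, 1e-12)
    return [
        (K1 * (k3 + k4 - a1) / d, a1),
        (K1 * (a2 - k3 - k4) / d, a2),
    ]


def model_grid(end_time: float, grid_step: float = DEFAULT_GRID_STEP) -> np.ndarray:
    """Uniform evaluation grid from 0 to at least ``end_time`` minutes."""
    n = int(np.ceil(end_time / grid_step)) + 1
    return np.arange(n) * grid_step


def tissue_curve_on_grid(
    coefficients, grid: np.ndarray, aif_on_grid: np.ndarray
) -> np.ndarray:
    """Tissue concentration: sum_i coef_i * (aif conv exp(-rate_i t)) on the grid."""
    dt = grid[1] - grid[0]
    ct = np.zeros_like(aif_on_grid)
    for coef, rate in coefficients:
        if coef == 0.0:
            continue
        ct += coef * exp_conv(rate, dt, aif_on_grid)
    return ct


def tissue_frame_average(
    coefficients,
    grid: np.ndarray,
    aif_on_grid: np.ndarray,
    frame_start: np.ndarray,
    frame_end: np.ndarray,
) -> np.ndarray:
    """Exact frame averages of the compartmental tissue curve.

    Uses the identity  int_0^t (cp conv e^{-a s}) = (1/a) [int_0^t cp - y(t)]
    so the time integral inherits the exactness of :func:`exp_conv`; only the
    evaluation at off-grid frame edges interpolates (the integral is smooth).
    """
    from scipy.integrate import cumulative_trapezoid

    dt = grid[1] - grid[0]
    cum_cp = cumulative_trapezoid(aif_on_grid, grid, initial=0.0)
    Y = np.zeros_like(aif_on_grid)
    for coef, rate in coefficients:
        if coef == 0.0:
            continue
        Y += (coef / rate) * (cum_cp - exp_conv(rate, dt, aif_on_grid))
    lo = np.interp(frame_start, grid, Y)
    hi = np.interp(frame_end, grid, Y)
    return (hi - lo) / (frame_end - frame_start)


def frame_average(
    grid: np.ndarray, curve: np.ndarray, frame_start: np.ndarray, frame_end: np.ndarray
) -> np.ndarray:
    """Average a fine-grid curve over each [start, end) frame (trapezoid rule)."""
    from scipy.integrate import cumulative_trapezoid

    cum = cumulative_trapezoid(curve, grid, initial=0.0)
    lo = np.interp(frame_start, grid, cum)
    hi = np.interp(frame_end, grid, cum)
    return (hi - lo) / (frame_end - frame_start)


def check_aif_covers(aif: InputFunction, tac_or_end) -> float:
    """Raise if the AIF sampling does not span the frames; return the end time."""
    end = tac_or_end.end_time if isinstance(tac_or_end, TimeActivityCurve) else float(tac_or_end)
    if aif.end_time < end - 1e-9:
        raise ValueError(
            f"AIF sampled to {aif.end_time:g} min does not cover frames to {end:g} min"
        )
    return end
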