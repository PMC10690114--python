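"""Graphical and reference-tissue quantification: Logan plasma-input
analysis, its noninvasive reference-region variant, and the simplified
reference tissue model (SRTM).

Logan variants regress the normalised tissue integral on the normalised
input integral over frames whose midpoints lie at or beyond the
equilibration cutoff t* (default 30 min); the slope estimates V_T (plasma
input) or the distribution-volume ratio DVR (reference input), with
BP_ND = DVR - 1.  Tissue integrals use midpoint trapezoids with a leading
half-triangle from time zero; the plasma integral uses the AIF's own
sampling grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.optimize import minimize_scalar

from .data import InputFunction, TimeActivityCurve
from .kinetics import DEFAULT_GRID_STEP, exp_conv, model_grid

logger = logging.getLogger("petkin")

__all__ = [
    "LoganPlot",
    "NonInvasiveLogan",
    "SRTM",
    "GraphicalFitResult",
    "SRTMResult",
]

DEFAULT_T_STAR = 30.0  # minutes


@dataclass
class GraphicalFitResult:
    """OLS line through the linearised late-time plot."""

    method: str  # "logan" or "ni-logan"
    slope: float  # V_T (mL/cm3) or DVR (dimensionless)
    intercept: float  # minutes
    slope_se: float
    t_star: float
    n_points_used: int
    r_squared: float

    @property
    def vt(self) -> float:
        if self.method != "logan":
            raise AttributeError("V_T is defined for the plasma-input Logan plot only")
        return self.slope

    @property
    def dvr(self) -> float:
        if self.method != "ni-logan":
            raise AttributeError("DVR is defined for the reference-input plot only")
        return self.slope

    @property
    def bp_nd(self) -> float:
        return self.dvr - 1.0

    def summary(self) -> str:
        what = "V_T" if self.method == "logan" else "DVR"
        lines = [
            f"{self.method} graphical fit (t* = {self.t_star:g} min, "
            f"{self.n_points_used} frames, r^2 = {self.r_squared:.4f})",
            f"  {what} = {self.slope:.4f}  (SE {self.slope_se:.3g})",
            f"  intercept = {self.intercept:.3f} min",
        ]
        if self.method == "ni-logan":
            lines.append(f"  BP_ND = {self.bp_nd:.4f}")
        return "\n".join(lines)


def _tissue_cumulative_integral(tac: TimeActivityCurve) -> np.ndarray:
    """Integral of the tissue curve from 0 to each frame midpoint.

    Midpoint trapezoids with a leading half-triangle: the curve is taken as 0
    at injection and linear between successive midpoints.
    """
    t = np.concatenate([[0.0], tac.frame_mid])
    c = np.concatenate([[0.0], tac.activity])
    return cumulative_trapezoid(c, t)


def _ols_line(x: np.ndarray, y: np.ndarray):
    n = len(x)
    X = np.column_stack([x, np.ones(n)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    if n > 2:
        s2 = rss / (n - 2)
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = np.sqrt(s2 / sxx) if sxx > 0 else float("inf")
    else:
        slope_se = float("nan")
    return float(beta[0]), float(beta[1]), slope_se, r2


class LoganPlot:
    """Plasma-input Logan graphical analysis; the late slope estimates V_T."""

    def __init__(
        self,
        tac: TimeActivityCurve,
        aif: InputFunction,
        t_star: float = DEFAULT_T_STAR,
    ):
        self.tac = tac
        self.aif = aif
        self.t_star = float(t_star)

    def _points(self):
        mid = self.tac.frame_mid
        ct = self.tac.activity
        int_ct = _tissue_cumulative_integral(self.tac)
        int_cp = self.aif.cumulative_integral(mid)
        qualify = mid >= self.t_star - 1e-9
        nonzero = ct > 0
        dropped = qualify & ~nonzero
        if np.any(dropped):
            logger.warning(
                "Logan plot: dropping %d frame(s) with zero tissue activity",
                int(dropped.sum()),
            )
        use = qualify & nonzero
        if use.sum() < 3:
            raise ValueError(
                f"Logan regression needs >= 3 frames with midpoints past t* = {self.t_star:g} min"
            )
        x = int_cp[use] / ct[use]
        y = int_ct[use] / ct[use]
        return x, y, int(use.sum())

    def fit(self) -> GraphicalFitResult:
        x, y, n = self._points()
        slope, intercept, slope_se, r2 = _ols_line(x, y)
        return GraphicalFitResult(
            method="logan",
            slope=slope,
            intercept=intercept,
            slope_se=slope_se,
            t_star=self.t_star,
            n_points_used=n,
            r_squared=r2,
        )


class NonInvasiveLogan:
    """Reference-input Logan plot with a fixed reference efflux constant k2'.

    Regresses int C_T / C_T on [int C_ref + C_ref / k2'] / C_T past t*; the
    slope is the distribution-volume ratio DVR and BP_ND = DVR - 1.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        ref_tac: TimeActivityCurve,
        k2_prime: float,
        t_star: float = DEFAULT_T_STAR,
    ):
        if k2_prime <= 0:
            raise ValueError("k2_prime must be positive")
        if not np.allclose(tac.frame_mid, ref_tac.frame_mid):
            raise ValueError("target and reference curves must share a frame schedule")
        self.tac = tac
        self.ref_tac = ref_tac
        self.k2_prime = float(k2_prime)
        self.t_star = float(t_star)

    def fit(self) -> GraphicalFitResult:
        mid = self.tac.frame_mid
        ct = self.tac.activity
        cref = self.ref_tac.activity
        int_ct = _tissue_cumulative_integral(self.tac)
        int_cref = _tissue_cumulative_integral(self.ref_tac)
        qualify = (mid >= self.t_star - 1e-9) & (ct > 0)
        if qualify.sum() < 3:
            raise ValueError(
                f"reference Logan regression needs >= 3 frames past t* = {self.t_star:g} min"
            )
        x = (int_cref[qualify] + cref[qualify] / self.k2_prime) / ct[qualify]
        y = int_ct[qualify] / ct[qualify]
        slope, intercept, slope_se, r2 = _ols_line(x, y)
        return GraphicalFitResult(
            method="ni-logan",
            slope=slope,
            intercept=intercept,
            slope_se=slope_se,
            t_star=self.t_star,
            n_points_used=int(qualify.sum()),
            r_squared=r2,
        )


@dataclass
class SRTMResult:
    """Simplified reference tissue model estimates."""

    R1: float  # relative delivery K1/K1'
    k2: float  # target efflux, 1/min
    bp_nd: float
    rss: float
    converged: bool
    fitted_values: np.ndarray

    @property
    def k2_prime(self) -> float:
        """Reference-region efflux constant k2' = k2/R1 (feeds NI-Logan)."""
        return self.k2 / self.R1

    def summary(self) -> str:
        return (
            "SRTM fit\n"
            f"  R1 = {self.R1:.4f}   k2 = {self.k2:.5f} min-1\n"
            f"  BP_ND = {self.bp_nd:.4f}   k2' = {self.k2_prime:.5f} min-1\n"
            f"  RSS = {self.rss:.6g}   converged: {self.converged}"
        )


class SRTM:
    """Simplified reference tissue model, solved by basis-function expansion.

    C_T(t) = R1 C_ref(t) + [k2 - R1 k2a] (C_ref conv e^{-k2a t}) with
    k2a = k2 / (1 + BP_ND).  For each candidate k2a on a log grid the problem
    is linear in (R1, coefficient); the best grid point is then refined by
    bounded scalar minimisation — deterministic, with convex sub-problems.
    """

    def __init__(
        self,
        tac: TimeActivityCurve,
        ref_tac: TimeActivityCurve,
        theta_grid: np.ndarray | None = None,
        grid_step: float = DEFAULT_GRID_STEP,
    ):
        if not np.allclose(tac.frame_mid, ref_tac.frame_mid):
            raise ValueError("target and reference curves must share a frame schedule")
        self.tac = tac
        self.ref_tac = ref_tac
        self.theta_grid = (
            np.geomspace(1e-3, 1.0, 100) if theta_grid is None else np.asarray(theta_grid, float)
        )
        # fine grid for the convolution basis; the reference curve is taken
        # linear from (0, 0) through its frame midpoints
        self._grid = model_grid(tac.end_time, grid_step)
        self._cref_fine = np.interp(
            self._grid,
            np.concatenate([[0.0], ref_tac.frame_mid]),
            np.concatenate([[0.0], ref_tac.activity]),
        )

    def _basis(self, theta: float) -> np.ndarray:
        dt = self._grid[1] - self._grid[0]
        conv = exp_conv(theta, dt, self._cref_fine)
        return np.interp(self.tac.frame_mid, self._grid, conv)

    def _linear_subfit(self, theta: float):
        X = np.column_stack([self.ref_tac.activity, self._basis(theta)])
        beta, *_ = np.linalg.lstsq(X, self.tac.activity, rcond=None)
        resid = self.tac.activity - X @ beta
        return float(resid @ resid), beta, X @ beta

    def fit(self) -> SRTMResult:
        rss_grid = np.array([self._linear_subfit(th)[0] for th in self.theta_grid])
        i = int(np.argmin(rss_grid))
        lo = self.theta_grid[max(i - 1, 0)]
        hi = self.theta_grid[min(i + 1, len(self.theta_grid) - 1)]
        converged = True
        if lo < hi:
            res = minimize_scalar(
                lambda th: self._linear_subfit(th)[0],
                bounds=(lo, hi),
                method="bounded",
                options={"xatol": 1e-8},
            )
            theta = float(res.x)
            converged = bool(res.success)
        else:
            theta = float(self.theta_grid[i])
        rss, beta, fitted = self._linear_subfit(theta)
        R1, phi = float(beta[0]), float(beta[1])
        if R1 <= 0:
            return SRTMResult(R1=R1, k2=float("nan"), bp_nd=float("nan"),
                              rss=rss, converged=False, fitted_values=fitted)
        k2 = phi + R1 * theta
        bp = k2 / theta - 1.0
        return SRTMResult(R1=R1, k2=k2, bp_nd=bp, rss=rss,
                          converged=converged, fitted_values=fitted)
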