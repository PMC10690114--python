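"""Concentration-occupancy modeling: the effect-site (ke0) link and the
saturable sigmoidal Emax model.

Occupancy(%) = Emax * C^g / (EC50^g + C^g), with Emax fixed at 100% so that
C = EC50 yields exactly 50% occupancy.  ``C`` is either the measured plasma
concentration (gamma fixed at 1, assuming noncooperative binding) or the
effect-site concentration Ce obtained from dCe/dt = ke0 (Cp - Ce), which
absorbs the temporal lag (hysteresis) between plasma levels and brain
occupancy.  All times on this side of the package are hours post dose.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "effect_site_conc",
    "emax_occupancy",
    "EmaxModel",
    "EffectSiteEmaxModel",
    "EmaxFitResult",
]

KE0_BOUNDS = (1e-3, 1e2)  # 1/h


def effect_site_conc(time_h, cp, ke0: float) -> np.ndarray:
    """Solve dCe/dt = ke0 (Cp - Ce), Ce(0) = 0, for piecewise-linear Cp.

    Per sampling interval the update is exact: with Cp = a + b (t - t_i),

        Ce(t) = a + b (t - t_i) - b/ke0 + (Ce_i - a + b/ke0) e^{-ke0 (t - t_i)}.
    """
    if ke0 <= 0:
        raise ValueError("ke0 must be positive")
    t = np.asarray(time_h, dtype=float)
    cp = np.asarray(cp, dtype=float)
    if len(t) != len(cp):
        raise ValueError("time and concentration vectors must have equal length")
    if t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing from 0")
    ce = np.zeros_like(cp)
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        b = (cp[i + 1] - cp[i]) / dt
        E = np.exp(-ke0 * dt)
        ce[i + 1] = cp[i + 1] - b / ke0 + (ce[i] - cp[i] + b / ke0) * E
    return ce


def emax_occupancy(C, ec50: float, gamma: float = 1.0, emax: float = 100.0):
    """Sigmoidal occupancy (%) = emax * C^gamma / (ec50^gamma + C^gamma)."""
    if ec50 <= 0 or gamma <= 0:
        raise ValueError("ec50 and gamma must be positive")
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("concentrations must be non-negative")
    u = C**gamma
    out = emax * u / (ec50**gamma + u)
    return out if out.ndim else float(out)


@dataclass
class EmaxFitResult:
    """Estimates from a concentration-occupancy fit (Emax fixed at 100%)."""

    mode: str  # "plasma" or "effect_site"
    emax: float
    ec50: float
    gamma: float
    ke0: float | None
    relative_se: dict[str, float]  # percent, per free parameter
    rss: float
    converged: bool
    n_obs: int
    flags: list[str] = field(default_factory=list)

    def predict(self, C):
        return emax_occupancy(C, self.ec50, self.gamma, self.emax)

    def summary(self) -> str:
        lines = [
            f"Emax occupancy model ({self.mode} mode, Emax fixed at {self.emax:g}%)",
            f"  n = {self.n_obs}   RSS = {self.rss:.5g}   converged: {self.converged}",
            f"  EC50  = {self.ec50:.4g} ng/mL  (rel. SE {self.relative_se.get('ec50', float('nan')):.2f}%)",
        ]
        if "gamma" in self.relative_se:
            lines.append(
                f"  gamma = {self.gamma:.4g}  (rel. SE {self.relative_se['gamma']:.2f}%)"
            )
        else:
            lines.append(f"  gamma = {self.gamma:g} (fixed)")
        if self.ke0 is not None:
            lines.append(
                f"  ke0   = {self.ke0:.4g} /h  (rel. SE {self.relative_se.get('ke0', float('nan')):.2f}%)"
            )
        lines.extend(f"  note: {f}" for f in self.flags)
        return "\n".join(lines)

    def plot(self, concentrations=None, occupancies=None, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if concentrations is not None and occupancies is not None:
            ax.semilogx(concentrations, occupancies, "o", label="observed")
        top = self.ec50 * 100 if concentrations is None else max(np.max(concentrations), self.ec50 * 10)
        xs = np.geomspace(self.ec50 / 100, top, 200)
        ax.semilogx(xs, self.predict(xs), "-", label="fit")
        ax.set_xlabel("concentration (ng/mL)")
        ax.set_ylabel("occupancy (%)")
        ax.legend()
        return ax


def _relative_se(sol, names, values, n):
    """Percent SEs from the least-squares Jacobian (on the fitted scale)."""
    k = len(names)
    dof = max(n - k, 1)
    rss = 2.0 * sol.cost
    try:
        cov = np.linalg.pinv(sol.jac.T @ sol.jac) * (rss / dof)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except Exception:  # pragma: no cover
        ses = np.full(k, np.nan)
    out = {}
    for name, se, val in zip(names, ses, values):
        # parameters are fitted on log10 scale: d(log10 x) -> relative error
        out[name] = float(100.0 * se * np.log(10.0))
    return out


class EmaxModel:
    """Fit occupancy vs concentration with Emax fixed at 100%.

    In ``plasma`` mode gamma is fixed at 1 (only EC50 is free); in
    ``effect_site`` mode gamma is estimated as well.  Occupancies outside
    [0, 100]% are tolerated within [-10, 110] (noise) and retained.
    """

    def __init__(self, concentrations, occupancies, mode: str = "plasma", emax: float = 100.0):
        if mode not in ("plasma", "effect_site"):
            raise ValueError("mode must be 'plasma' or 'effect_site'")
        C = np.asarray(concentrations, dtype=float)
        occ = np.asarray(occupancies, dtype=float)
        if len(C) != len(occ):
            raise ValueError("concentration and occupancy vectors must match")
        if len(C) < 3:
            raise ValueError("need at least 3 observations")
        if np.any((occ < -10) | (occ > 110)):
            raise ValueError("occupancies outside the tolerated [-10, 110]% band")
        if np.all(np.abs(occ) < 1e-6):
            raise ValueError("all occupancies ~0: EC50 is unidentifiable")
        self.C = C
        self.occ = occ
        self.mode = mode
        self.emax = float(emax)

    def fit(self) -> EmaxFitResult:
        free_gamma = self.mode == "effect_site"

        def residuals(x):
            ec50 = 10.0 ** x[0]
            gamma = 10.0 ** x[1] if free_gamma else 1.0
            return emax_occupancy(self.C, ec50, gamma, self.emax) - self.occ

        # start EC50 at the concentration closest to half-maximal occupancy
        half_idx = int(np.argmin(np.abs(self.occ - 0.5 * self.emax)))
        c0 = self.C[half_idx] if self.C[half_idx] > 0 else np.median(self.C[self.C > 0])
        x0 = [np.log10(c0)] + ([0.0] if free_gamma else [])
        lo = [-6.0] + ([-1.0] if free_gamma else [])
        hi = [6.0] + ([1.0] if free_gamma else [])
        sol = least_squares(residuals, x0, bounds=(lo, hi), xtol=1e-12, ftol=1e-12)
        ec50 = float(10.0 ** sol.x[0])
        gamma = float(10.0 ** sol.x[1]) if free_gamma else 1.0
        names = ["ec50"] + (["gamma"] if free_gamma else [])
        rel_se = _relative_se(sol, names, sol.x, len(self.C))
        flags = []
        if not sol.success:
            flags.append("solver did not report convergence")
        if np.ptp(self.occ) < 1e-9:
            flags.append("degenerate data: a single occupancy level fits any EC50 at that C")
        return EmaxFitResult(
            mode=self.mode,
            emax=self.emax,
            ec50=ec50,
            gamma=gamma,
            ke0=None,
            relative_se=rel_se,
            rss=float(2 * sol.cost),
            converged=bool(sol.success),
            n_obs=len(self.C),
            flags=flags,
        )


class EffectSiteEmaxModel:
    """Joint (ke0, EC50, gamma) fit of timed occupancy observations.

    ``cp_series`` maps subject -> (time_h, Cp) plasma profiles starting at
    dosing; ``observations`` is a list of (subject, time_h, occupancy_%)
    tuples.  Model occupancy is the Emax curve evaluated at the effect-site
    concentration Ce(t_obs) implied by the subject's Cp and the shared ke0.
    """

    def __init__(self, cp_series: dict, observations, emax: float = 100.0):
        self.cp_series = {
            s: (np.asarray(t, float), np.asarray(c, float)) for s, (t, c) in cp_series.items()
        }
        obs = [(s, float(t), float(o)) for s, t, o in observations]
        if len(obs) < 3:
            raise ValueError("need at least 3 timed occupancy observations")
        for s, t_obs, _ in obs:
            if s not in self.cp_series:
                raise ValueError(f"no plasma series for subject {s!r}")
            if t_obs > self.cp_series[s][0][-1] + 1e-9:
                raise ValueError(f"plasma series for {s!r} does not cover t = {t_obs} h")
        self.observations = obs
        self.emax = float(emax)
        times = {round(t, 6) for _, t, _ in obs}
        self._single_time = len(times) < 2

    def _model_occ(self, ke0: float, ec50: float, gamma: float) -> np.ndarray:
        ce_cache = {}
        out = np.empty(len(self.observations))
        for i, (s, t_obs, _) in enumerate(self.observations):
            if s not in ce_cache:
                t, cp = self.cp_series[s]
                ce_cache[s] = (t, effect_site_conc(t, cp, ke0))
            t, ce = ce_cache[s]
            out[i] = emax_occupancy(np.interp(t_obs, t, ce), ec50, gamma, self.emax)
        return out

    def fit(self) -> EmaxFitResult:
        obs = np.array([o for _, _, o in self.observations])

        def residuals(x):
            return self._model_occ(10.0 ** x[0], 10.0 ** x[1], 10.0 ** x[2]) - obs

        lo = [np.log10(KE0_BOUNDS[0]), -6.0, -1.0]
        hi = [np.log10(KE0_BOUNDS[1]), 6.0, 1.0]
        # deterministic multistart over ke0; EC50 starts near the median
        # concentration with half-maximal occupancy, gamma at 1
        cs = np.concatenate([c for _, c in self.cp_series.values()])
        c0 = np.log10(max(np.median(cs[cs > 0]), 1e-3))
        best = None
        for ke0_start in np.geomspace(KE0_BOUNDS[0] * 10, KE0_BOUNDS[1] / 10, 7):
            sol = least_squares(
                residuals, [np.log10(ke0_start), c0, 0.0], bounds=(lo, hi),
                xtol=1e-12, ftol=1e-12,
            )
            if best is None or sol.cost < best.cost:
                best = sol
        ke0, ec50, gamma = (float(10.0 ** v) for v in best.x)
        rel_se = _relative_se(best, ["ke0", "ec50", "gamma"], best.x, len(obs))
        flags = []
        if self._single_time:
            flags.append(
                "all observations share one post-dose time: ke0 is unidentifiable"
            )
        if not best.success:
            flags.append("solver did not report convergence")
        return EmaxFitResult(
            mode="effect_site",
            emax=self.emax,
            ec50=ec50,
            gamma=gamma,
            ke0=ke0,
            relative_se=rel_se,
            rss=float(2 * best.cost),
            converged=bool(best.success),
            n_obs=len(obs),
            flags=flags,
        )
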