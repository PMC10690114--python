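"""Drug-occupancy estimation: surrogate AIF for the unsampled scan, the
Lassen occupancy plot, and BP_ND-based regional occupancies.

The Lassen plot regresses the baseline-minus-blocked V_T difference on
baseline V_T across regions; under a region-common nondisplaceable volume,

    V_T,baseline - V_T,blocked = occupancy * (V_T,baseline - V_ND),

so the slope is the global occupancy and the x-intercept is V_ND.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import InputFunction

__all__ = [
    "weighted_aif",
    "LassenPlot",
    "OccupancyResult",
    "direct_bpnd",
    "regional_occupancy",
]

SLOPE_EPS = 1e-6


def weighted_aif(
    aif_baseline: InputFunction,
    aif_blocking1: InputFunction,
    id_baseline: float,
    id_blocking1: float,
    id_blocking2: float,
) -> InputFunction:
    """Dose-weighted surrogate input for the second blocking scan.

    AIF_b2(t) = ID_b2 * (AIF_base(t)/ID_base + AIF_b1(t)/ID_b1) / 2.

    The first blocking AIF is resampled onto the baseline grid when the two
    grids differ; it must span the baseline grid for that to be admissible.
    """
    for name, dose in (
        ("id_baseline", id_baseline),
        ("id_blocking1", id_blocking1),
        ("id_blocking2", id_blocking2),
    ):
        if dose <= 0:
            raise ValueError(f"{name} must be positive")
    t = aif_baseline.sample_time
    if len(aif_blocking1.sample_time) == len(t) and np.allclose(aif_blocking1.sample_time, t):
        c1 = aif_blocking1.parent_plasma_conc
    else:
        if aif_blocking1.end_time < t[-1] - 1e-6:
            raise ValueError(
                "blocking-1 AIF does not span the baseline grid; grids not alignable"
            )
        c1 = aif_blocking1(t)
    conc = id_blocking2 * (
        aif_baseline.parent_plasma_conc / id_baseline + c1 / id_blocking1
    ) / 2.0
    return InputFunction(sample_time=t, parent_plasma_conc=conc, f_P=aif_baseline.f_P)


@dataclass
class OccupancyResult:
    """Lassen-plot estimates plus (optionally) per-region BP_ND occupancies."""

    occupancy: float  # fraction
    v_nd: float  # mL/cm3; nan when indeterminate
    slope_se: float
    intercept: float
    regions_used: tuple[str, ...]
    v_nd_indeterminate: bool = False
    per_region_bp_nd: dict[str, float] = field(default_factory=dict)
    per_region_occupancy: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)

    @property
    def occupancy_percent(self) -> float:
        return 100.0 * self.occupancy

    def summary(self) -> str:
        vnd = "indeterminate" if self.v_nd_indeterminate else f"{self.v_nd:.4f} mL/cm3"
        lines = [
            f"Lassen occupancy plot ({len(self.regions_used)} regions)",
            f"  occupancy = {self.occupancy_percent:.2f}%  (slope SE {self.slope_se:.3g})",
            f"  V_ND (x-intercept) = {vnd}",
        ]
        for region in sorted(self.per_region_occupancy):
            lines.append(
                f"  {region}: BP_ND(base) {self.per_region_bp_nd.get(region, float('nan')):.3f}"
                f" -> occupancy {self.per_region_occupancy[region]:.1f}%"
            )
        lines.extend(f"  note: {f}" for f in self.flags)
        return "\n".join(lines)

    def plot(self, v_t_baseline=None, v_t_blocking=None, ax=None):
        """Lassen plot: delta V_T vs baseline V_T with the fitted line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if v_t_baseline is not None and v_t_blocking is not None:
            base = np.array([v_t_baseline[r] for r in self.regions_used])
            diff = base - np.array([v_t_blocking[r] for r in self.regions_used])
            ax.plot(base, diff, "o")
            xs = np.linspace(0, base.max() * 1.05, 50)
            ax.plot(xs, self.occupancy * xs + self.intercept, "-")
        ax.set_xlabel("baseline $V_T$ (mL/cm$^3$)")
        ax.set_ylabel("$V_T$ baseline $-$ blocked (mL/cm$^3$)")
        ax.set_title(f"occupancy {self.occupancy_percent:.1f}%")
        return ax


class LassenPlot:
    """Occupancy plot over regions shared by a baseline and a blocked scan."""

    def __init__(self, v_t_baseline: dict[str, float], v_t_blocking: dict[str, float]):
        shared = sorted(set(v_t_baseline) & set(v_t_blocking))
        if len(shared) < 3:
            raise ValueError("Lassen plot needs at least 3 shared regions")
        base = np.array([v_t_baseline[r] for r in shared], dtype=float)
        if np.ptp(base) <= 0:
            raise ValueError("baseline V_T values must be distinct across regions")
        self.regions = tuple(shared)
        self._base = base
        self._block = np.array([v_t_blocking[r] for r in shared], dtype=float)
        self._v_t_baseline = dict(v_t_baseline)
        self._v_t_blocking = dict(v_t_blocking)

    def fit(self, compute_regional: bool = False) -> OccupancyResult:
        """OLS of (V_T,base - V_T,block) on V_T,base.

        With ``compute_regional`` the per-region BP_ND (from this plot's
        V_ND) and BP_ND-ratio occupancies are filled in as well.
        """
        x, y = self._base, self._base - self._block
        X = np.column_stack([x, np.ones_like(x)])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        slope, intercept = float(beta[0]), float(beta[1])
        resid = y - X @ beta
        n = len(x)
        s2 = float(resid @ resid) / max(n - 2, 1)
        sxx = float(np.sum((x - x.mean()) ** 2))
        slope_se = float(np.sqrt(s2 / sxx)) if sxx > 0 else float("inf")
        flags = []
        if abs(slope) < SLOPE_EPS:
            v_nd, indeterminate = float("nan"), True
            flags.append("slope ~ 0: occupancy is ~0 and V_ND is indeterminate")
        else:
            v_nd, indeterminate = -intercept / slope, False
        result = OccupancyResult(
            occupancy=slope,
            v_nd=v_nd,
            slope_se=slope_se,
            intercept=intercept,
            regions_used=self.regions,
            v_nd_indeterminate=indeterminate,
            flags=flags,
        )
        if compute_regional and not indeterminate:
            self.add_regional(result, v_nd)
        return result

    def add_regional(self, result: OccupancyResult, v_nd: float):
        """Fill per-region BP_ND and BP_ND-ratio occupancies using ``v_nd``.

        In the study design this v_nd comes from the subject's
        highest-occupancy (first blocking) scan's plot.
        """
        for region, base, block in zip(self.regions, self._base, self._block):
            bp_base = direct_bpnd(base, v_nd)
            result.per_region_bp_nd[region] = bp_base
            if bp_base > 0:
                bp_block = direct_bpnd(block, v_nd)
                occ = regional_occupancy(bp_base, bp_block)
                result.per_region_occupancy[region] = occ
                if not (0.0 <= occ <= 100.0):
                    result.flags.append(
                        f"{region}: occupancy {occ:.1f}% outside [0, 100] (noise); retained"
                    )
            else:
                result.flags.append(
                    f"{region}: baseline BP_ND <= 0, regional occupancy unavailable"
                )


def direct_bpnd(v_t: float, v_nd: float) -> float:
    """Direct binding potential BP_ND = V_T / V_ND - 1."""
    if v_nd <= 0:
        raise ValueError("V_ND must be positive")
    return v_t / v_nd - 1.0


def regional_occupancy(bpnd_baseline: float, bpnd_blocking: float) -> float:
    """Regional occupancy (%) = 100 (1 - BP_ND,blocking / BP_ND,baseline)."""
    if bpnd_baseline <= 0:
        raise ValueError("baseline BP_ND must be positive")
    return 100.0 * (1.0 - bpnd_blocking / bpnd_baseline)
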