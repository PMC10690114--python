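"""Synthetic study generator: AIFs, regional TACs with known kinetics,
test-retest cohorts, occupancy scenarios and oral-dose drug PK profiles.

Everything stochastic takes an explicit seed and is bit-for-bit reproducible.
The default ("study-like") ground truth is chosen to land on the printed
landmarks of the tracer's human kinetics: a common nondisplaceable volume
V_ND = K1/k2 = 1.5 mL/cm3 across regions, cerebellar V_T ~ 6.4 mL/cm3 with
an early (< 5 min) peak and fast washout, basal-ganglia-high V_T ordering,
and a putamen SUV peak of ~8 around 30 min post injection.  The rate
constants themselves are this package's choices, not measured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .data import (
    InputFunction,
    ParentFractionModel,
    StudyRecord,
    TimeActivityCurve,
)
from .kinetics import (
    DEFAULT_GRID_STEP,
    check_aif_covers,
    irf_coefficients_1tc,
    irf_coefficients_2tc,
    model_grid,
    tissue_frame_average,
)

__all__ = [
    "KineticGroundTruth",
    "OccupancyScenario",
    "PKScenario",
    "simulate_aif",
    "default_aif",
    "simulate_tac",
    "add_noise",
    "simulate_occupancy_study",
    "simulate_trt_study",
    "simulate_pk_profile",
    "default_frame_schedule",
    "occupancy_frame_schedule",
    "default_ground_truth",
    "blocked_truth",
    "DEFAULT_F_P",
    "DEFAULT_INJECTED_DOSE",
    "DEFAULT_BODY_WEIGHT",
]

DEFAULT_F_P = 0.48  # measured plasma free fraction of the parent tracer
DEFAULT_INJECTED_DOSE = 330.0  # MBq
DEFAULT_BODY_WEIGHT = 85.0  # kg
# AIF peak amplitude (kBq/mL) calibrated once so the default putamen curve
# peaks near SUV 8 with the default dose/weight; frozen thereafter.
DEFAULT_AIF_PEAK = 29.5


@dataclass(frozen=True)
class KineticGroundTruth:
    """True 2TC rate constants for one simulated region."""

    region_label: str
    K1: float  # mL cm-3 min-1
    k2: float  # min-1
    k3: float  # min-1
    k4: float  # min-1

    def __post_init__(self):
        for name in ("K1", "k2", "k3", "k4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("K1", "k2", "k4"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def vt(self) -> float:
        return (self.K1 / self.k2) * (1.0 + self.k3 / self.k4)

    @property
    def vnd(self) -> float:
        return self.K1 / self.k2


def default_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """Kinetic-study schedule: 6x0.5, 3x1, 2x2, 5x5, 9x10 min frames, a
    30-min scan break, then 9 more 10-min frames."""
    durations = [0.5] * 6 + [1.0] * 3 + [2.0] * 2 + [5.0] * 5 + [10.0] * 9
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    ends = starts + durations
    gap_start = ends[-1] + 30.0
    late = gap_start + 10.0 * np.arange(9)
    starts = np.concatenate([starts, late])
    ends = np.concatenate([ends, late + 10.0])
    return starts, ends


def occupancy_frame_schedule() -> tuple[np.ndarray, np.ndarray]:
    """120-min blocking-study schedule (no break): 6x0.5, 3x1, 2x2, 5x5, 8x10 min."""
    durations = [0.5] * 6 + [1.0] * 3 + [2.0] * 2 + [5.0] * 5 + [10.0] * 8
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    return starts, starts + np.asarray(durations)


# region -> (K1, k3); k2 = K1 / V_ND, k4 common.  Ordered high-to-low binding.
_DEFAULT_K4 = 0.024
_DEFAULT_VND = 1.5
_DEFAULT_REGIONS: dict[str, tuple[float, float]] = {
    "putamen": (0.50, 0.300),
    "caudate_nucleus": (0.48, 0.270),
    "nucleus_accumbens": (0.46, 0.250),
    "pallidum": (0.42, 0.200),
    "thalamus": (0.45, 0.180),
    "amygdala": (0.40, 0.175),
    "insula": (0.44, 0.165),
    "anterior_cingulate": (0.43, 0.160),
    "posterior_cingulate": (0.43, 0.150),
    "frontal_lobe": (0.42, 0.145),
    "temporal_lobe": (0.41, 0.140),
    "parietal_lobe": (0.41, 0.135),
    "occipital_lobe": (0.40, 0.130),
    "hippocampus": (0.38, 0.120),
    "brain_stem": (0.40, 0.096),
    "cerebellum": (0.55, 0.0784),
}


def default_ground_truth(v_nd: float = _DEFAULT_VND) -> dict[str, KineticGroundTruth]:
    """Study-like regional kinetics with a shared V_ND = K1/k2."""
    return {
        name: KineticGroundTruth(
            region_label=name, K1=K1, k2=K1 / v_nd, k3=k3, k4=_DEFAULT_K4
        )
        for name, (K1, k3) in _DEFAULT_REGIONS.items()
    }


def blocked_truth(truth: KineticGroundTruth, occupancy: float) -> KineticGroundTruth:
    """Apply drug occupancy by rescaling k3 (specific binding) only.

    With V_ND = K1/k2 untouched, blocked V_T = V_ND + (1 - occupancy) *
    (V_T - V_ND) — exactly the inverted Lassen relation — because V_T - V_ND
    = V_ND k3/k4 is proportional to k3.
    """
    if not (0.0 <= occupancy <= 1.0):
        raise ValueError("occupancy must lie in [0, 1]")
    return replace(truth, k3=truth.k3 * (1.0 - occupancy))


def simulate_aif(
    times,
    peak_time: float = 1.5,
    peak_value: float = DEFAULT_AIF_PEAK,
    decay_amplitudes=(0.75, 0.20, 0.05),
    decay_rates=(0.6, 0.08, 0.012),
    f_P: float = DEFAULT_F_P,
) -> InputFunction:
    """Bolus-like parent-plasma input: linear rise to a peak, tri-exponential
    decay after, continuous at the peak.

    ``decay_amplitudes`` are relative weights (normalised internally);
    ``decay_rates`` (1/min) must be positive and descending.
    """
    times = np.asarray(times, dtype=float)
    if peak_value <= 0:
        raise ValueError("peak_value must be positive")
    amps = np.asarray(decay_amplitudes, dtype=float)
    rates = np.asarray(decay_rates, dtype=float)
    if np.any(rates <= 0):
        raise ValueError("decay_rates must be positive")
    if np.any(np.diff(rates) >= 0):
        raise ValueError("decay_rates must be strictly descending")
    amps = amps / amps.sum()
    conc = np.where(
        times <= peak_time,
        peak_value * times / peak_time,
        peak_value
        * sum(a * np.exp(-r * np.maximum(times - peak_time, 0.0)) for a, r in zip(amps, rates)),
    )
    return InputFunction(sample_time=times, parent_plasma_conc=conc, f_P=f_P)


def aif_closed_form_integral(
    peak_time: float, peak_value: float, decay_amplitudes, decay_rates
) -> float:
    """Analytic integral over [0, inf): triangle + sum A_i/r_i (amplitudes normalised)."""
    amps = np.asarray(decay_amplitudes, dtype=float)
    amps = amps / amps.sum()
    rates = np.asarray(decay_rates, dtype=float)
    return 0.5 * peak_value * peak_time + peak_value * float(np.sum(amps / rates))


def default_aif(end_time: float = 245.0, sample_step: float = 0.25, **kwargs) -> InputFunction:
    times = np.arange(0.0, end_time + sample_step / 2, sample_step)
    return simulate_aif(times, **kwargs)


def simulate_tac(
    truth: KineticGroundTruth,
    aif: InputFunction,
    frames: tuple[np.ndarray, np.ndarray] | None = None,
    injected_dose: float = DEFAULT_INJECTED_DOSE,
    body_weight: float = DEFAULT_BODY_WEIGHT,
    grid_step: float = DEFAULT_GRID_STEP,
) -> TimeActivityCurve:
    """Noiseless frame-averaged tissue curve for 2TC kinetics (1TC when k3=0)."""
    if frames is None:
        frames = default_frame_schedule()
    frame_start, frame_end = (np.asarray(f, float) for f in frames)
    check_aif_covers(aif, float(frame_end[-1]))
    grid = model_grid(float(frame_end[-1]), grid_step)
    aif_grid = aif(grid)
    if truth.k3 == 0.0:
        coeffs = irf_coefficients_1tc(truth.K1, truth.k2)
    else:
        coeffs = irf_coefficients_2tc(truth.K1, truth.k2, truth.k3, truth.k4)
    activity = tissue_frame_average(coeffs, grid, aif_grid, frame_start, frame_end)
    return TimeActivityCurve(
        region_label=truth.region_label,
        frame_start=frame_start,
        frame_end=frame_end,
        activity=np.maximum(activity, 0.0),
        injected_dose=injected_dose,
        body_weight=body_weight,
    )


def add_noise(tac: TimeActivityCurve, noise_level: float, seed: int) -> TimeActivityCurve:
    """Frame-dependent Gaussian noise, sd = noise_level * activity / sqrt(duration),
    truncated at zero (a small positive-bias source at very high noise)."""
    if noise_level < 0:
        raise ValueError("noise_level must be non-negative")
    if noise_level == 0:
        return tac
    rng = np.random.default_rng(seed)
    sd = noise_level * tac.activity / np.sqrt(tac.frame_duration)
    noisy = np.maximum(tac.activity + rng.normal(0.0, 1.0, tac.n_frames) * sd, 0.0)
    return replace(tac, activity=noisy)


@dataclass(frozen=True)
class OccupancyScenario:
    """Blocking-study scenario: shared V_ND, per-condition true occupancy."""

    regions: dict[str, KineticGroundTruth] = field(default_factory=default_ground_truth)
    true_V_ND: float = _DEFAULT_VND
    true_occupancy: dict[str, float] = field(
        default_factory=lambda: {"blocking_1": 0.85, "blocking_2": 0.45}
    )
    noise_level: float = 0.0
    n_subjects: int = 1
    seed: int = 0
    drug_dose: float = 600.0  # mg
    scan_intervals: dict[str, float] = field(
        default_factory=lambda: {"blocking_1": 2.0, "blocking_2": 24.0}
    )  # hours post dose
    between_subject_cv: float = 0.0

    def __post_init__(self):
        for cond, occ in self.true_occupancy.items():
            if not (0.0 <= occ <= 1.0):
                raise ValueError(f"occupancy for {cond} outside [0, 1]: {occ}")
        if self.true_V_ND <= 0:
            raise ValueError("true_V_ND must be positive")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be at least 1")


def _normalise_vnd(truth: KineticGroundTruth, v_nd: float) -> KineticGroundTruth:
    """Force K1/k2 = v_nd (the Lassen model assumes a region-common V_ND)."""
    return replace(truth, k2=truth.K1 / v_nd)


def simulate_occupancy_study(scenario: OccupancyScenario) -> list[StudyRecord]:
    """Baseline + two blocking scans per subject with distinct injected doses.

    Blocked kinetics come from rescaling k3 by (1 - occupancy), which realises
    blocked V_T = V_ND + (1 - occupancy)(V_T_baseline - V_ND) exactly.  The
    AIF of each scan scales with its injected dose, so the dose-weighted
    surrogate-AIF construction can be exercised downstream.
    """
    rng = np.random.default_rng(scenario.seed)
    frames = occupancy_frame_schedule()
    end_time = float(frames[1][-1])
    records = []
    conditions = ["baseline"] + sorted(scenario.true_occupancy)
    for s in range(scenario.n_subjects):
        subject = f"S{s + 1:02d}"
        if scenario.between_subject_cv > 0:
            sigma = np.sqrt(np.log(1 + scenario.between_subject_cv**2))
            k1_mult = float(rng.lognormal(-0.5 * sigma**2, sigma))
            k3_mult = float(rng.lognormal(-0.5 * sigma**2, sigma))
        else:
            k1_mult = k3_mult = 1.0
        base_truth = {
            name: _normalise_vnd(
                replace(t, K1=t.K1 * k1_mult, k3=t.k3 * k3_mult), scenario.true_V_ND
            )
            for name, t in scenario.regions.items()
        }
        weight = DEFAULT_BODY_WEIGHT
        for condition in conditions:
            dose = float(rng.uniform(300.0, 360.0))
            occ = scenario.true_occupancy.get(condition, 0.0)
            aif = default_aif(end_time + 1.0, peak_value=DEFAULT_AIF_PEAK * dose / DEFAULT_INJECTED_DOSE)
            tacs = {}
            for name, truth in base_truth.items():
                tac = simulate_tac(
                    blocked_truth(truth, occ), aif, frames,
                    injected_dose=dose, body_weight=weight,
                )
                tac = add_noise(tac, scenario.noise_level, seed=int(rng.integers(2**31)))
                tacs[name] = tac
            records.append(
                StudyRecord(
                    subject_id=subject,
                    condition=condition,
                    tacs=tacs,
                    # the second blocking scan has no arterial sampling: its
                    # AIF must be reconstructed from the first two scans
                    input_function=None if condition == "blocking_2" else aif,
                    drug_dose=scenario.drug_dose if condition != "baseline" else None,
                    dose_to_scan_interval=scenario.scan_intervals.get(condition),
                )
            )
    return records


def simulate_trt_study(
    regions: dict[str, KineticGroundTruth] | None = None,
    n_subjects: int = 6,
    noise_level: float = 0.03,
    between_subject_cv: float = 0.15,
    seed: int = 0,
) -> list[StudyRecord]:
    """Test-retest cohort: between-subject log-normal variability on K1 and
    k3 (shared across the pair), within-subject variability via frame noise
    only — so the variance splits the way a high-ICC cohort does."""
    if regions is None:
        regions = default_ground_truth()
    rng = np.random.default_rng(seed)
    frames = default_frame_schedule()
    end_time = float(frames[1][-1])
    sigma = np.sqrt(np.log(1 + between_subject_cv**2)) if between_subject_cv > 0 else 0.0
    records = []
    for s in range(n_subjects):
        subject = f"S{s + 1:02d}"
        k1_mult = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma else 1.0
        k3_mult = float(rng.lognormal(-0.5 * sigma**2, sigma)) if sigma else 1.0
        subj_truth = {
            name: replace(t, K1=t.K1 * k1_mult, k2=t.k2 * k1_mult, k3=t.k3 * k3_mult)
            for name, t in regions.items()
        }
        for condition in ("test", "retest"):
            dose = float(rng.uniform(300.0, 360.0))
            aif = default_aif(end_time + 1.0, peak_value=DEFAULT_AIF_PEAK * dose / DEFAULT_INJECTED_DOSE)
            tacs = {
                name: add_noise(
                    simulate_tac(t, aif, frames, injected_dose=dose),
                    noise_level,
                    seed=int(rng.integers(2**31)),
                )
                for name, t in subj_truth.items()
            }
            records.append(
                StudyRecord(
                    subject_id=subject, condition=condition, tacs=tacs, input_function=aif
                )
            )
    return records


@dataclass(frozen=True)
class PKScenario:
    """One-compartment oral-absorption drug PK with an effect-site link."""

    dose: float = 300.0  # mg
    ka: float = 1.5  # 1/h
    ke: float = 0.15  # 1/h
    V_over_F: float = 2000.0  # L
    ke0: float = 0.35  # 1/h
    sample_times: np.ndarray = field(
        default_factory=lambda: np.arange(0.0, 30.001, 0.25)
    )  # hours

    def __post_init__(self):
        for name in ("dose", "ka", "ke", "V_over_F", "ke0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if abs(self.ka - self.ke) < 1e-9:
            raise ValueError("ka == ke degenerates the oral closed form")
        object.__setattr__(self, "sample_times", np.asarray(self.sample_times, float))


def simulate_pk_profile(scenario: PKScenario) -> pd.DataFrame:
    """Plasma and effect-site concentration (ng/mL) vs time (h).

    Cp(t) = dose ka / (V/F (ka - ke)) (e^{-ke t} - e^{-ka t}) (mg/L -> x1000
    ng/mL); Ce solves dCe/dt = ke0 (Cp - Ce) against this Cp on a fine grid.
    """
    from .pkpd import effect_site_conc

    t = scenario.sample_times
    A = 1000.0 * scenario.dose * scenario.ka / (scenario.V_over_F * (scenario.ka - scenario.ke))
    cp = A * (np.exp(-scenario.ke * t) - np.exp(-scenario.ka * t))
    fine = np.arange(0.0, t[-1] + 0.01, 0.01)
    cp_fine = A * (np.exp(-scenario.ke * fine) - np.exp(-scenario.ka * fine))
    ce_fine = effect_site_conc(fine, cp_fine, scenario.ke0)
    ce = np.interp(t, fine, ce_fine)
    return pd.DataFrame({"time_h": t, "plasma": cp, "effect_site": ce})
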