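"""Shared domain types and tabular IO for PET kinetic analysis.

All kinetic-side timestamps are minutes post-injection; the PK-PD side works
in hours.  Cross-module time conversion goes through :func:`minutes_to_hours`
/ :func:`hours_to_minutes` so the unit change is explicit at the call site.

Activity concentrations are kBq/mL, decay-corrected to injection time.
Injected doses are MBq, body weight kg; SUV therefore comes out dimensionless
(assuming tissue density 1 g/mL).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("petkin")

__all__ = [
    "TimeActivityCurve",
    "InputFunction",
    "ParentFractionModel",
    "StudyRecord",
    "CONDITIONS",
    "read_tac_table",
    "write_tac_table",
    "read_blood_table",
    "write_blood_table",
    "to_suv",
    "metabolite_correct",
    "minutes_to_hours",
    "hours_to_minutes",
]

CONDITIONS = ("baseline", "blocking_1", "blocking_2", "test", "retest")


def minutes_to_hours(t_min):
    """Explicit unit bridge from the kinetic modules (min) to PK-PD (h)."""
    return np.asarray(t_min, dtype=float) / 60.0


def hours_to_minutes(t_h):
    """Explicit unit bridge from PK-PD (h) to the kinetic modules (min)."""
    return np.asarray(t_h, dtype=float) * 60.0


def _as_array(x) -> np.ndarray:
    return np.atleast_1d(np.asarray(x, dtype=float))


@dataclass(frozen=True)
class TimeActivityCurve:
    """Framed activity concentrations for one brain region.

    Frames are ``[frame_start, frame_end)`` intervals in minutes post
    injection; gaps between frames (scan breaks) are allowed, overlaps are
    not.  ``activity`` is the frame-average concentration in kBq/mL
    (or dimensionless SUV after :meth:`to_suv`).
    """

    region_label: str
    frame_start: np.ndarray
    frame_end: np.ndarray
    activity: np.ndarray
    injected_dose: float | None = None  # MBq
    body_weight: float | None = None  # kg
    unit: str = "kBq/mL"

    def __post_init__(self):
        object.__setattr__(self, "frame_start", _as_array(self.frame_start))
        object.__setattr__(self, "frame_end", _as_array(self.frame_end))
        object.__setattr__(self, "activity", _as_array(self.activity))
        fs, fe, a = self.frame_start, self.frame_end, self.activity
        if not (len(fs) == len(fe) == len(a)):
            raise ValueError("frame_start, frame_end and activity must have equal length")
        if len(fs) == 0:
            raise ValueError("a TimeActivityCurve needs at least one frame")
        if np.any(np.diff(fs) <= 0):
            bad = int(np.flatnonzero(np.diff(fs) <= 0)[0]) + 1
            raise ValueError(f"frame_start must be strictly increasing (row {bad})")
        if np.any(fe <= fs):
            bad = int(np.flatnonzero(fe <= fs)[0])
            raise ValueError(f"frame_end must exceed frame_start (row {bad})")
        overlap = fs[1:] < fe[:-1] - 1e-9
        if np.any(overlap):
            bad = int(np.flatnonzero(overlap)[0]) + 1
            raise ValueError(f"frames overlap (row {bad} starts before row {bad - 1} ends)")
        if np.any(a < 0):
            bad = int(np.flatnonzero(a < 0)[0])
            raise ValueError(f"negative activity in frame {bad}")
        if self.injected_dose is not None and self.injected_dose <= 0:
            raise ValueError("injected_dose must be positive")
        if self.body_weight is not None and self.body_weight <= 0:
            raise ValueError("body_weight must be positive")

    # -- frame geometry -------------------------------------------------
    @property
    def frame_mid(self) -> np.ndarray:
        return 0.5 * (self.frame_start + self.frame_end)

    @property
    def frame_duration(self) -> np.ndarray:
        return self.frame_end - self.frame_start

    @property
    def n_frames(self) -> int:
        return len(self.frame_start)

    @property
    def end_time(self) -> float:
        return float(self.frame_end[-1])

    # -- transforms ------------------------------------------------------
    def to_suv(self) -> "TimeActivityCurve":
        """Scale activity to SUV: activity * body_weight / injected_dose.

        kBq/mL * kg / MBq = (kBq/MBq)*(kg/mL) -> dimensionless for tissue
        density 1 g/mL (kBq/MBq = 1e-3, kg/mL = 1e3 g/mL-normalised).
        """
        if self.injected_dose is None or self.body_weight is None:
            raise ValueError("to_suv requires injected_dose and body_weight")
        if self.unit == "SUV":
            raise ValueError("curve is already in SUV units")
        scale = self.body_weight / self.injected_dose
        return replace(self, activity=self.activity * scale, unit="SUV")

    def from_suv(self) -> "TimeActivityCurve":
        """Inverse of :meth:`to_suv`."""
        if self.unit != "SUV":
            raise ValueError("curve is not in SUV units")
        scale = self.injected_dose / self.body_weight
        return replace(self, activity=self.activity * scale, unit="kBq/mL")

    def truncated(self, end_time: float) -> "TimeActivityCurve":
        """Keep only frames ending at or before ``end_time`` minutes."""
        keep = self.frame_end <= end_time + 1e-9
        if not np.any(keep):
            raise ValueError(f"no frames end before {end_time} min")
        return replace(
            self,
            frame_start=self.frame_start[keep],
            frame_end=self.frame_end[keep],
            activity=self.activity[keep],
        )


@dataclass(frozen=True)
class InputFunction:
    """Metabolite-corrected arterial plasma parent concentration vs time.

    ``sample_time`` in minutes starting at 0; ``parent_plasma_conc`` in
    kBq/mL; optional raw ``parent_fraction`` samples; ``f_P`` is the plasma
    free fraction (defaults to 1.0 with a logged warning when unmeasured —
    none of the outcome measures here divide by it).
    """

    sample_time: np.ndarray
    parent_plasma_conc: np.ndarray
    parent_fraction: np.ndarray | None = None
    f_P: float | None = None

    def __post_init__(self):
        object.__setattr__(self, "sample_time", _as_array(self.sample_time))
        object.__setattr__(self, "parent_plasma_conc", _as_array(self.parent_plasma_conc))
        t, c = self.sample_time, self.parent_plasma_conc
        if len(t) != len(c):
            raise ValueError("sample_time and parent_plasma_conc must have equal length")
        if len(t) < 2:
            raise ValueError("an input function needs at least two samples")
        if t[0] != 0:
            raise ValueError("sample_time must start at 0 (injection)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("sample_time must be strictly increasing")
        if np.any(c < 0):
            raise ValueError("negative plasma concentration")
        if self.parent_fraction is not None:
            pf = _as_array(self.parent_fraction)
            if np.any((pf < 0) | (pf > 1)):
                raise ValueError("parent_fraction must lie in [0, 1]")
            object.__setattr__(self, "parent_fraction", pf)
        if self.f_P is None:
            logger.warning("plasma free fraction f_P not provided; defaulting to 1.0")
            object.__setattr__(self, "f_P", 1.0)
        if not (0 < self.f_P <= 1):
            raise ValueError("f_P must lie in (0, 1]")

    @property
    def end_time(self) -> float:
        return float(self.sample_time[-1])

    def __call__(self, t) -> np.ndarray:
        """Linear interpolation of the parent concentration at minutes ``t``."""
        return np.interp(np.asarray(t, dtype=float), self.sample_time, self.parent_plasma_conc)

    def cumulative_integral(self, t) -> np.ndarray:
        """Trapezoidal integral of the AIF from 0 to each time in ``t`` (min)."""
        from scipy.integrate import cumulative_trapezoid

        cum = cumulative_trapezoid(self.parent_plasma_conc, self.sample_time, initial=0.0)
        return np.interp(np.asarray(t, dtype=float), self.sample_time, cum)

    def scaled(self, factor: float) -> "InputFunction":
        return replace(self, parent_plasma_conc=self.parent_plasma_conc * factor)


@dataclass(frozen=True)
class ParentFractionModel:
    """Monotone parent-fraction curve pf(t) = plateau + (1-plateau) e^(-decay_rate t).

    pf(0) = 1 by construction and pf decreases toward ``plateau``.  The
    default is calibrated so pf(60 min) ~ 0.27 with a 0.25 plateau, the shape
    the tracer's measured metabolite profile shows.
    """

    plateau: float = 0.25
    decay_rate: float = 0.06040  # 1/min; solves pf(60) = 0.27 with plateau 0.25

    def __post_init__(self):
        if not (0 <= self.plateau <= 1):
            raise ValueError("plateau must lie in [0, 1]")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be non-negative")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.plateau + (1.0 - self.plateau) * np.exp(-self.decay_rate * t)


@dataclass
class StudyRecord:
    """One subject-condition scan: regional TACs plus blood and dosing metadata."""

    subject_id: str
    condition: str
    tacs: dict[str, TimeActivityCurve] = field(default_factory=dict)
    input_function: InputFunction | None = None
    drug_dose: float | None = None  # mg
    dose_to_scan_interval: float | None = None  # hours

    def __post_init__(self):
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}, got {self.condition!r}")
        if self.condition.startswith("blocking") and self.drug_dose is None:
            raise ValueError(f"{self.condition} record requires drug_dose")

    @property
    def injected_dose(self) -> float | None:
        for tac in self.tacs.values():
            return tac.injected_dose
        return None


# ---------------------------------------------------------------------------
# tabular IO (comma-separated, header row: frame_start, frame_end, regions...)
# ---------------------------------------------------------------------------

def read_tac_table(
    path,
    injected_dose: float | None = None,
    body_weight: float | None = None,
) -> dict[str, TimeActivityCurve]:
    """Read a regional TAC table into one curve per region column.

    The table is comma-separated with a header row; the first two columns are
    ``frame_start`` and ``frame_end`` in minutes, every further column is one
    region's frame-average activity in kBq/mL.
    """
    df = pd.read_csv(path)
    for col in ("frame_start", "frame_end"):
        if col not in df.columns:
            raise ValueError(f"TAC table {path} is missing required column {col!r}")
    regions = [c for c in df.columns if c not in ("frame_start", "frame_end")]
    if not regions:
        raise ValueError(f"TAC table {path} has no region columns")
    bad = df.index[df["frame_end"].to_numpy(float) <= df["frame_start"].to_numpy(float)]
    if len(bad):
        raise ValueError(f"frame_end <= frame_start in row {bad[0]} of {path}")
    # row order in the file is immaterial; frames are sorted by start time
    df = df.sort_values("frame_start").reset_index(drop=True)
    out = {}
    for region in regions:
        out[region] = TimeActivityCurve(
            region_label=region,
            frame_start=df["frame_start"].to_numpy(float),
            frame_end=df["frame_end"].to_numpy(float),
            activity=df[region].to_numpy(float),
            injected_dose=injected_dose,
            body_weight=body_weight,
        )
    return out


def write_tac_table(path, tacs: Iterable[TimeActivityCurve] | dict[str, TimeActivityCurve]):
    """Write regional curves (sharing one frame schedule) to a CSV table."""
    if isinstance(tacs, dict):
        tacs = list(tacs.values())
    else:
        tacs = list(tacs)
    if not tacs:
        raise ValueError("no curves to write")
    ref = tacs[0]
    for tac in tacs[1:]:
        if not (
            np.allclose(tac.frame_start, ref.frame_start)
            and np.allclose(tac.frame_end, ref.frame_end)
        ):
            raise ValueError("all curves in one table must share a frame schedule")
    df = pd.DataFrame({"frame_start": ref.frame_start, "frame_end": ref.frame_end})
    for tac in tacs:
        df[tac.region_label] = tac.activity
    df.to_csv(path, index=False)


def read_blood_table(path) -> pd.DataFrame:
    """Read a blood table (columns ``time``, ``conc``, optional ``parent_fraction``)."""
    df = pd.read_csv(path)
    for col in ("time", "conc"):
        if col not in df.columns:
            raise ValueError(f"blood table {path} is missing column {col!r}")
    return df


def write_blood_table(path, time, conc, parent_fraction=None):
    df = pd.DataFrame({"time": np.asarray(time, float), "conc": np.asarray(conc, float)})
    if parent_fraction is not None:
        df["parent_fraction"] = np.asarray(parent_fraction, float)
    df.to_csv(path, index=False)


def to_suv(tac: TimeActivityCurve) -> TimeActivityCurve:
    """Functional alias of :meth:`TimeActivityCurve.to_suv`."""
    return tac.to_suv()


def metabolite_correct(
    sample_time,
    total_plasma_conc,
    pf_model: ParentFractionModel,
    f_P: float | None = None,
) -> InputFunction:
    """Convert total plasma activity to the parent (metabolite-corrected) AIF.

    parent(t) = total(t) * pf(t), pointwise.
    """
    t = _as_array(sample_time)
    total = _as_array(total_plasma_conc)
    if np.any(total < 0):
        raise ValueError("negative total plasma concentration")
    pf = pf_model(t)
    return InputFunction(
        sample_time=t,
        parent_plasma_conc=total * pf,
        parent_fraction=pf,
        f_P=f_P,
    )
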