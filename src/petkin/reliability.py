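"""Test-retest variability, intraclass correlation, and time stability.

TRT(%) = 100 (test - retest) / [(test + retest)/2]; summaries report the
mean of |TRT| across subjects with its SD.  The ICC is the one-way
random-effects contrast (BMS - WMS)/(BMS + WMS) computed from paired
measurements.  Time stability refits a quantifier on truncated data and
reports the signed percent bias against the full-duration estimate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .data import InputFunction, TimeActivityCurve

__all__ = ["trt", "icc", "time_stability", "reliability_table"]


def trt(test: float, retest: float) -> float:
    """Signed test-retest difference as percent of the pair mean."""
    mean = 0.5 * (test + retest)
    if mean == 0:
        raise ValueError("TRT undefined when test + retest = 0")
    return 100.0 * (test - retest) / mean


def icc(pairs) -> float:
    """One-way intraclass correlation from (n_subjects, 2) paired measurements.

    ICC = (BMS - WMS) / (BMS + WMS) with BMS/WMS the between- and
    within-subject mean squares of the one-way ANOVA.
    """
    x = np.asarray(pairs, dtype=float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise ValueError("icc expects exactly 2 measurements per subject")
    n = x.shape[0]
    if n < 2:
        raise ValueError("icc needs at least 2 subjects")
    k = 2
    subject_means = x.mean(axis=1)
    grand = x.mean()
    bms = k * np.sum((subject_means - grand) ** 2) / (n - 1)
    wms = np.sum((x - subject_means[:, None]) ** 2) / (n * (k - 1))
    denom = bms + wms
    if denom == 0:
        raise ValueError("ICC undefined: no variance between or within subjects (0/0)")
    return float((bms - wms) / denom)


def _fit_vt(tac: TimeActivityCurve, aif: InputFunction, method: str) -> float:
    from .compartment import OneTissueModel, TwoTissueModel
    from .graphical import LoganPlot

    if method == "1tc":
        return OneTissueModel(tac, aif).fit().vt
    if method == "2tc":
        return TwoTissueModel(tac, aif).fit().vt
    if method == "logan":
        return LoganPlot(tac, aif).fit().vt
    raise ValueError(f"unknown quantification method {method!r}")


_MIN_DURATION = {"1tc": 10.0, "2tc": 20.0, "logan": 60.0}


def time_stability(
    tac: TimeActivityCurve,
    aif: InputFunction,
    end_times,
    method: str = "2tc",
) -> pd.DataFrame:
    """V_T from truncated acquisitions, as signed percent bias vs full data.

    Rows where the truncation leaves too few frames for the method are kept
    but marked unavailable.
    """
    full_vt = _fit_vt(tac, aif, method)
    rows = []
    for end in sorted(float(e) for e in end_times):
        row = {"end_time": end, "vt": np.nan, "bias_percent": np.nan, "available": False}
        try:
            if end < _MIN_DURATION.get(method, 0.0):
                raise ValueError("below method minimum duration")
            short = tac.truncated(end)
            vt = _fit_vt(short, aif, method)
            row.update(vt=vt, bias_percent=100.0 * (vt - full_vt) / full_vt, available=True)
        except ValueError:
            pass
        rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["full_vt"] = full_vt
    out.attrs["method"] = method
    return out


def reliability_table(test: pd.DataFrame, retest: pd.DataFrame) -> pd.DataFrame:
    """Aggregate paired outcome tables into per-region/method reliability rows.

    Inputs are tidy tables with columns ``subject``, ``region``, ``method``,
    ``value`` (one row per subject/region/method).  Output columns:
    ``region``, ``method``, ``mean_absolute_trt``, ``trt_sd``, ``icc``,
    ``n_subjects``.
    """
    for name, df in (("test", test), ("retest", retest)):
        missing = {"subject", "region", "method", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"{name} table missing columns {sorted(missing)}")
    merged = test.merge(
        retest, on=["subject", "region", "method"], suffixes=("_test", "_retest")
    )
    rows = []
    for (region, method), grp in merged.groupby(["region", "method"], sort=True):
        trts = np.array(
            [trt(a, b) for a, b in zip(grp["value_test"], grp["value_retest"])]
        )
        pairs = grp[["value_test", "value_retest"]].to_numpy()
        rows.append(
            {
                "region": region,
                "method": method,
                "mean_absolute_trt": float(np.mean(np.abs(trts))),
                "trt_sd": float(np.std(np.abs(trts), ddof=1)) if len(trts) > 1 else np.nan,
                "icc": icc(pairs) if len(pairs) >= 2 else np.nan,
                "n_subjects": len(grp),
            }
        )
    return pd.DataFrame(rows)
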