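"""End-to-end orchestration: simulate -> fit -> reliability / occupancy ->
PK-PD from a single YAML config, with seeding, logging and tidy outputs.

Every output filename embeds a short hash of the config so runs cannot be
silently mixed; a JSON run log records stage statuses and output manifests.
Stages communicate through tidy tables on disk, so each is independently
re-runnable from files (the CLI exposes them one by one).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic
from .compartment import OneTissueModel, TwoTissueModel
from .data import StudyRecord, write_blood_table, write_tac_table
from .graphical import LoganPlot
from .occupancy import LassenPlot, weighted_aif
from .pkpd import EffectSiteEmaxModel, EmaxModel
from .reliability import reliability_table

logger = logging.getLogger("petkin")

__all__ = ["RunConfig", "run_pipeline", "make_report", "config_hash"]

KNOWN_STAGES = ("simulate", "fit", "reliability", "occupancy", "pkpd", "report")


def config_hash(config: dict) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha1(canon.encode()).hexdigest()[:8]


class RunConfig:
    """Validated pipeline configuration (YAML mapping or path to one)."""

    def __init__(self, source):
        if isinstance(source, (str, Path)):
            with open(source) as fh:
                config = yaml.safe_load(fh)
        else:
            config = dict(source)
        if not isinstance(config, dict):
            raise ValueError("config must be a mapping")
        self.seed = int(config.get("seed", 0))
        self.output_dir = Path(config.get("output_dir", "petkin_out"))
        stages = config.get("stages")
        if not stages:
            raise ValueError("config must list at least one stage")
        self.stages: list[tuple[str, dict]] = []
        for entry in stages:
            if isinstance(entry, str):
                name, options = entry, {}
            elif isinstance(entry, dict) and len(entry) == 1:
                name, options = next(iter(entry.items()))
                options = options or {}
            else:
                raise ValueError(f"malformed stage entry: {entry!r}")
            if name not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {name!r}; expected one of {KNOWN_STAGES}")
            self.stages.append((name, dict(options)))
        self.raw = config
        self.hash = config_hash(config)


def _scenario_from_options(options: dict, seed: int):
    regions = synthetic.default_ground_truth()
    if "regions" in options:
        missing = [r for r in options["regions"] if r not in regions]
        if missing:
            raise ValueError(f"unknown region(s) in config: {missing}")
        regions = {r: regions[r] for r in options["regions"]}
    return regions


def _stage_simulate(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    kind = options.get("kind", "occupancy")
    seed = int(options.get("seed", cfg.seed))
    regions = _scenario_from_options(options, seed)
    if kind == "occupancy":
        scenario = synthetic.OccupancyScenario(
            regions=regions,
            true_V_ND=float(options.get("v_nd", 1.5)),
            true_occupancy={
                k: float(v)
                for k, v in options.get(
                    "occupancy", {"blocking_1": 0.85, "blocking_2": 0.45}
                ).items()
            },
            noise_level=float(options.get("noise_level", 0.0)),
            n_subjects=int(options.get("n_subjects", 1)),
            seed=seed,
            drug_dose=float(options.get("drug_dose", 600.0)),
        )
        records = synthetic.simulate_occupancy_study(scenario)
        truth_rows = [
            {"region": name, "true_vt": t.vt, "true_v_nd": scenario.true_V_ND}
            for name, t in regions.items()
        ]
        state["scenario"] = scenario
    elif kind == "trt":
        records = synthetic.simulate_trt_study(
            regions=regions,
            n_subjects=int(options.get("n_subjects", 6)),
            noise_level=float(options.get("noise_level", 0.03)),
            between_subject_cv=float(options.get("between_subject_cv", 0.15)),
            seed=seed,
        )
        truth_rows = [{"region": name, "true_vt": t.vt} for name, t in regions.items()]
    else:
        raise ValueError(f"unknown simulation kind {kind!r}")
    state["records"] = records
    outputs = []
    for rec in records:
        stem = f"{rec.subject_id}_{rec.condition}_{cfg.hash}"
        tac_path = cfg.output_dir / f"tacs_{stem}.csv"
        write_tac_table(tac_path, rec.tacs)
        outputs.append(str(tac_path))
        if rec.input_function is not None:
            blood_path = cfg.output_dir / f"blood_{stem}.csv"
            write_blood_table(
                blood_path, rec.input_function.sample_time, rec.input_function.parent_plasma_conc
            )
            outputs.append(str(blood_path))
    truth_path = cfg.output_dir / f"truth_{cfg.hash}.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    outputs.append(str(truth_path))
    return outputs


def _record_aif(rec: StudyRecord, records: list[StudyRecord]):
    """The record's own AIF, or the dose-weighted surrogate for an unsampled
    second blocking scan."""
    if rec.input_function is not None:
        return rec.input_function
    base = b1 = None
    for other in records:
        if other.subject_id != rec.subject_id:
            continue
        if other.condition == "baseline":
            base = other
        elif other.condition == "blocking_1":
            b1 = other
    if base is None or b1 is None or base.input_function is None or b1.input_function is None:
        raise ValueError(
            f"{rec.subject_id}/{rec.condition}: no AIF and no baseline+blocking_1 pair to build one"
        )
    return weighted_aif(
        base.input_function,
        b1.input_function,
        base.injected_dose,
        b1.injected_dose,
        rec.injected_dose,
    )


def _stage_fit(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    records = state.get("records")
    if records is None:
        raise ValueError("fit stage requires a prior simulate stage (or loaded records)")
    method = options.get("method", "logan")
    rows = []
    for rec in records:
        aif = _record_aif(rec, records)
        for region, tac in rec.tacs.items():
            if method == "logan":
                value = LoganPlot(tac, aif, t_star=float(options.get("t_star", 30.0))).fit().vt
            elif method == "1tc":
                value = OneTissueModel(tac, aif).fit().vt
            elif method == "2tc":
                value = TwoTissueModel(tac, aif).fit().vt
            else:
                raise ValueError(f"unknown fit method {method!r}")
            rows.append(
                {
                    "subject": rec.subject_id,
                    "condition": rec.condition,
                    "region": region,
                    "method": method,
                    "vt": value,
                }
            )
    vt = pd.DataFrame(rows)
    state["vt"] = vt
    path = cfg.output_dir / f"vt_{cfg.hash}.csv"
    vt.to_csv(path, index=False)
    return [str(path)]


def _stage_reliability(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    vt = state.get("vt")
    if vt is None:
        raise ValueError("reliability stage requires a prior fit stage")
    test = vt[vt.condition == "test"].rename(columns={"vt": "value"})
    retest = vt[vt.condition == "retest"].rename(columns={"vt": "value"})
    if test.empty or retest.empty:
        raise ValueError("reliability stage needs both test and retest conditions")
    table = reliability_table(
        test[["subject", "region", "method", "value"]],
        retest[["subject", "region", "method", "value"]],
    )
    state["reliability"] = table
    path = cfg.output_dir / f"reliability_{cfg.hash}.csv"
    table.to_csv(path, index=False)
    return [str(path)]


def _stage_occupancy(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    vt = state.get("vt")
    if vt is None:
        raise ValueError("occupancy stage requires a prior fit stage")
    blocking = sorted(c for c in vt.condition.unique() if c.startswith("blocking"))
    if not blocking:
        raise ValueError("occupancy stage needs blocking conditions in the V_T table")
    rows = []
    lassen_points = []
    warnings_ = []
    for subject, sub in vt.groupby("subject"):
        by_cond = {
            cond: dict(zip(grp.region, grp.vt)) for cond, grp in sub.groupby("condition")
        }
        if "baseline" not in by_cond:
            continue
        v_nd_first = None
        for cond in blocking:
            if cond not in by_cond:
                continue
            plot = LassenPlot(by_cond["baseline"], by_cond[cond])
            result = plot.fit()
            if cond == blocking[0] and not result.v_nd_indeterminate:
                v_nd_first = result.v_nd
            if v_nd_first is not None:
                plot.add_regional(result, v_nd_first)
            else:
                result.flags.append(
                    "V_ND from the first blocking scan unavailable; regional occupancies skipped"
                )
            warnings_.extend(f"{subject}/{cond}: {f}" for f in result.flags)
            rows.append(
                {
                    "subject": subject,
                    "condition": cond,
                    "occupancy_percent": result.occupancy_percent,
                    "v_nd": result.v_nd,
                    "slope_se": result.slope_se,
                    "n_regions": len(result.regions_used),
                    "mean_regional_occupancy": (
                        float(np.mean(list(result.per_region_occupancy.values())))
                        if result.per_region_occupancy
                        else np.nan
                    ),
                }
            )
            for region in result.regions_used:
                lassen_points.append(
                    {
                        "subject": subject,
                        "condition": cond,
                        "region": region,
                        "vt_baseline": by_cond["baseline"][region],
                        "vt_blocking": by_cond[cond][region],
                    }
                )
    occ = pd.DataFrame(rows)
    state["occupancy"] = occ
    state.setdefault("warnings", []).extend(warnings_)
    out1 = cfg.output_dir / f"occupancy_{cfg.hash}.csv"
    out2 = cfg.output_dir / f"lassen_points_{cfg.hash}.csv"
    occ.to_csv(out1, index=False)
    pd.DataFrame(lassen_points).to_csv(out2, index=False)
    return [str(out1), str(out2)]


def _stage_pkpd(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    occ = state.get("occupancy")
    if occ is None or occ.empty:
        raise ValueError("pkpd stage requires a prior occupancy stage")
    records = state.get("records", [])
    intervals = {}
    doses = {}
    for rec in records:
        if rec.dose_to_scan_interval is not None:
            intervals[(rec.subject_id, rec.condition)] = rec.dose_to_scan_interval
        if rec.drug_dose is not None:
            doses.setdefault(rec.subject_id, rec.drug_dose)
    pk_defaults = dict(
        ka=float(options.get("ka", 1.5)),
        ke=float(options.get("ke", 0.15)),
        V_over_F=float(options.get("v_over_f", 2000.0)),
        ke0=float(options.get("ke0", 0.35)),
    )
    cp_series = {}
    observations = []
    plasma_c = []
    plasma_occ = []
    for _, row in occ.iterrows():
        key = (row.subject, row.condition)
        t_obs = intervals.get(key)
        dose = doses.get(row.subject)
        if t_obs is None or dose is None:
            continue
        if row.subject not in cp_series:
            profile = synthetic.simulate_pk_profile(
                synthetic.PKScenario(
                    dose=dose, sample_times=np.arange(0.0, max(30.0, t_obs) + 0.25, 0.25),
                    **pk_defaults,
                )
            )
            cp_series[row.subject] = (
                profile.time_h.to_numpy(),
                profile.plasma.to_numpy(),
            )
        observations.append((row.subject, t_obs, row.occupancy_percent))
        t, cp = cp_series[row.subject]
        plasma_c.append(float(np.interp(t_obs, t, cp)))
        plasma_occ.append(row.occupancy_percent)
    if len(observations) < 3:
        raise ValueError("pkpd stage needs at least 3 timed occupancy observations")
    results = {}
    usable = [c > 0 for c in plasma_c]
    if sum(usable) >= 3:
        plasma_fit = EmaxModel(
            np.asarray(plasma_c)[usable], np.asarray(plasma_occ)[usable], mode="plasma"
        ).fit()
        results["plasma"] = plasma_fit
    es_fit = EffectSiteEmaxModel(cp_series, observations).fit()
    results["effect_site"] = es_fit
    state["pkpd"] = results
    rows = []
    for mode, fit in results.items():
        rows.append(
            {
                "mode": mode,
                "ec50": fit.ec50,
                "gamma": fit.gamma,
                "ke0": fit.ke0 if fit.ke0 is not None else np.nan,
                "rss": fit.rss,
                "converged": fit.converged,
                "n_obs": fit.n_obs,
            }
        )
    path = cfg.output_dir / f"pkpd_{cfg.hash}.csv"
    pd.DataFrame(rows).to_csv(path, index=False)
    return [str(path)]


def _stage_report(cfg: RunConfig, options: dict, state: dict) -> list[str]:
    text = make_report(state)
    path = cfg.output_dir / f"report_{cfg.hash}.md"
    path.write_text(text)
    return [str(path)]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "fit": _stage_fit,
    "reliability": _stage_reliability,
    "occupancy": _stage_occupancy,
    "pkpd": _stage_pkpd,
    "report": _stage_report,
}


def run_pipeline(config) -> dict:
    """Execute the configured stages in order; halt on the first failure.

    Returns a run summary: per-stage status and outputs, the config hash and
    the seed.  The same summary is written as ``run_log_<hash>.json``.
    """
    cfg = config if isinstance(config, RunConfig) else RunConfig(config)
    cfg.output_dir.mkdir(parents=True, exist_ok=True)
    state: dict = {"warnings": []}
    summary = {"config_hash": cfg.hash, "seed": cfg.seed, "stages": []}
    for name, options in cfg.stages:
        logger.info("stage %s: options=%s", name, options)
        entry = {"stage": name, "options": options}
        try:
            outputs = _STAGE_FUNCS[name](cfg, options, state)
        except Exception as exc:
            entry.update(status="failed", error=str(exc))
            summary["stages"].append(entry)
            summary["warnings"] = state.get("warnings", [])
            _write_log(cfg, summary)
            raise
        entry.update(status="ok", outputs=outputs)
        summary["stages"].append(entry)
    summary["warnings"] = state.get("warnings", [])
    _write_log(cfg, summary)
    return summary


def _write_log(cfg: RunConfig, summary: dict):
    log_path = cfg.output_dir / f"run_log_{cfg.hash}.json"
    log_path.write_text(json.dumps(summary, indent=2, sort_keys=True, default=str))


def make_report(state: dict) -> str:
    """Deterministic markdown report over whatever result tables are present."""
    lines = ["# petkin run report", ""]
    vt = state.get("vt")
    if vt is not None and not vt.empty:
        lines.append("## Regional V_T")
        lines.append("")
        pivot = vt.groupby(["condition", "method"]).vt.agg(["mean", "std", "count"])
        lines.append(pivot.round(4).to_markdown())
        lines.append("")
    rel = state.get("reliability")
    if rel is not None and not rel.empty:
        lines.append("## Test-retest reliability")
        lines.append("")
        lines.append(rel.round(4).to_markdown(index=False))
        lines.append("")
    occ = state.get("occupancy")
    lines.append("## Occupancy")
    lines.append("")
    if occ is not None and not occ.empty:
        lines.append(occ.round(4).to_markdown(index=False))
    else:
        lines.append("No blocking scans present; occupancy not estimated.")
    lines.append("")
    pkpd = state.get("pkpd")
    if pkpd:
        lines.append("## Concentration-occupancy (Emax) models")
        lines.append("")
        for mode, fit in sorted(pkpd.items()):
            lines.append("```")
            lines.append(fit.summary())
            lines.append("```")
            lines.append("")
    warnings_ = state.get("warnings") or []
    if warnings_:
        lines.append("## Warnings")
        lines.append("")
        lines.extend(f"- {w}" for w in warnings_)
        lines.append("")
    return "\n".join(lines)
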