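"""End-to-end run: simulate -> fit PET -> fit behavior -> report.

``run_pipeline`` executes every stage on data generated from a
:class:`~occmot.config.RunConfig` (or on user-supplied tables via the
stage functions directly) and assembles a :class:`RunReport` whose every
number traces to a stage output.  Identical config + seed gives an
identical report payload.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .behavior import (
    CostFamilyFit,
    RewardSizeFamilyFit,
    RtRelationFit,
    aggregate_refusal,
    fit_cost_family,
    fit_reward_size_family,
    fit_rt_relation_family,
)
from .config import RunConfig, config_hash
from .kinetics import (
    TimeActivityCurve,
    fit_decay,
    fit_hill,
    fit_srtm,
    lassen_occupancy,
    occupancy_from_bp,
)
from .simulate import (
    gen_occupancy_series,
    gen_pet_study,
    gen_reward_size_sessions,
    gen_work_delay_sessions,
)

__all__ = [
    "RunReport",
    "run_pipeline",
    "fit_pet_stage",
    "build_incentive_occupancy_table",
    "write_report",
]

REFERENCE_REGION = "cerebellum"


@dataclass
class RunReport:
    provenance: dict
    bp_table: pd.DataFrame  # region, condition, bp_nd
    occupancy_table: pd.DataFrame  # condition, method, occupancy_pct, se_pct
    hill: dict  # ed50, rss
    decay: dict  # occ_day0, decay_rate, rss
    reward_fit: RewardSizeFamilyFit
    cost_fit: CostFamilyFit
    rt_fit: RtRelationFit
    incentive_occupancy: pd.DataFrame  # condition, occupancy_pct, normalized_a

    def to_dict(self) -> dict:
        return {
            "provenance": self.provenance,
            "bp_table": _records(self.bp_table),
            "occupancy_table": _records(self.occupancy_table),
            "hill": self.hill,
            "decay": self.decay,
            "reward": {
                "selected_model": self.reward_fit.selected_id,
                "comparison": _records(self.reward_fit.comparison_table()),
                "parameters": self.reward_fit.selected.params,
                "normalized_a": self.reward_fit.normalized_a,
            },
            "cost": {
                "selected_variant": self.cost_fit.selected_id,
                "comparison": _records(self.cost_fit.comparison_table()),
                "parameters": _records(self.cost_fit.params),
            },
            "rt": {
                "selected_variant": self.rt_fit.selected_id,
                "structure": self.rt_fit.selected_structure,
                "comparison": _records(self.rt_fit.comparison_table()),
                "slope_ms": self.rt_fit.slope_ms,
                "intercept_ms": self.rt_fit.intercept_ms,
            },
            "incentive_occupancy": _records(self.incentive_occupancy),
        }


def _records(df: pd.DataFrame) -> list[dict]:
    out = df.copy()
    for col in out.columns:
        if out[col].dtype == object:
            out[col] = out[col].astype(str)
    clean = json.loads(out.to_json(orient="records"))
    return clean


def fit_pet_stage(tacs: pd.DataFrame, ref_region: str = REFERENCE_REGION) -> tuple[pd.DataFrame, pd.DataFrame]:
    """SRTM fits per region x condition and occupancy per treatment condition.

    Returns ``(bp_table, occupancy_table)``.  Occupancy is reported by the
    Lassen regression across regions and, for the region with the highest
    baseline binding (the striatal proxy), by the direct fractional
    BP_ND reduction.
    """
    conditions = list(pd.unique(tacs["condition"]))
    if "baseline" not in conditions:
        raise ValueError("TAC table must include a 'baseline' condition")
    regions = [r for r in pd.unique(tacs["region"]) if r != ref_region]

    bp_rows = []
    for cond in conditions:
        ref = TimeActivityCurve.from_frame(tacs, ref_region, cond)
        for region in regions:
            target = TimeActivityCurve.from_frame(tacs, region, cond)
            fit = fit_srtm(target, ref)
            bp_rows.append(
                {"region": region, "condition": cond, "bp_nd": fit.bp_nd,
                 "r1": fit.r1, "k2": fit.k2, "rss": fit.rss}
            )
    bp = pd.DataFrame(bp_rows)

    base = bp[bp["condition"] == "baseline"].set_index("region")["bp_nd"]
    striatal = base.idxmax()
    occ_rows = []
    for cond in conditions:
        if cond == "baseline":
            continue
        treat = bp[bp["condition"] == cond].set_index("region")["bp_nd"]
        paired = pd.DataFrame(
            {"region": base.index, "bp_baseline": base.values,
             "bp_treatment": treat.reindex(base.index).values}
        ).dropna()
        lassen = lassen_occupancy(paired)
        occ_rows.append(
            {"condition": cond, "method": "lassen_slope",
             "occupancy_pct": lassen.occupancy_pct, "se_pct": lassen.se_pct}
        )
        eq3 = occupancy_from_bp(base[striatal], treat[striatal])
        occ_rows.append(
            {"condition": cond, "method": "per_region_eq3",
             "occupancy_pct": eq3.occupancy_pct, "se_pct": np.nan}
        )
    return bp, pd.DataFrame(occ_rows)


def build_incentive_occupancy_table(
    occupancy_by_condition: dict[str, float],
    normalized_a: dict[str, float],
    control_condition: str = "CON",
) -> pd.DataFrame:
    """Join per-condition occupancy (%) with normalized incentive impact.

    The control condition maps to (0%, its normalized value, i.e. 1).
    Conditions present in only one input are excluded with a warning.
    No smoothing is applied; the raw pairs are the output.
    """
    occ = dict(occupancy_by_condition)
    if control_condition in normalized_a:
        occ.setdefault(control_condition, 0.0)
    shared = [c for c in normalized_a if c in occ]
    missing = sorted(set(normalized_a) ^ set(occ))
    if missing:
        warnings.warn(f"conditions excluded from incentive-occupancy join: {missing}", stacklevel=2)
    return pd.DataFrame(
        {
            "condition": shared,
            "occupancy_pct": [occ[c] for c in shared],
            "normalized_a": [normalized_a[c] for c in shared],
        }
    )


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages on synthetic data drawn from ``config``."""
    master = np.random.SeedSequence(config.seed)
    sub = [int(s) for s in (master.generate_state(6, np.uint32) >> np.uint32(1))]

    pet_cfg = config.pet.model_copy(update={"seed": sub[0]})
    tacs = gen_pet_study(pet_cfg)
    bp_table, occupancy_table = fit_pet_stage(tacs)

    dose_cfg = config.dose_series.model_copy(update={"seed": sub[1]})
    dose_obs = gen_occupancy_series(dose_cfg)
    hill = fit_hill(dose_obs["design_point"], dose_obs["occupancy_pct"])

    day_cfg = config.day_series.model_copy(update={"seed": sub[2]})
    day_obs = gen_occupancy_series(day_cfg)
    decay = fit_decay(day_obs["design_point"], day_obs["occupancy_pct"])

    reward_cfg = config.reward_behavior.model_copy(update={"seed": sub[3]})
    reward_trials = gen_reward_size_sessions(reward_cfg)
    reward_cells = aggregate_refusal(reward_trials)
    reward_fit = fit_reward_size_family(
        reward_cells,
        likelihood=config.likelihood,
        reference_condition=config.control_condition,
    )
    rt_fit = fit_rt_relation_family(reward_cells)

    cost_cfg = config.cost_behavior.model_copy(update={"seed": sub[4]})
    cost_trials = gen_work_delay_sessions(cost_cfg)
    cost_cells = aggregate_refusal(cost_trials)
    cost_fit = fit_cost_family(cost_cells)

    lassen = occupancy_table[occupancy_table["method"] == "lassen_slope"]
    occ_by_cond = dict(zip(lassen["condition"], lassen["occupancy_pct"]))
    # behavioral-only conditions fall back to their nominal occupancy band
    for cond, band in config.occupancy_bands.items():
        occ_by_cond.setdefault(cond, band)
    incentive = build_incentive_occupancy_table(
        occ_by_cond, reward_fit.normalized_a, config.control_condition
    )

    provenance = {
        "config_hash": config_hash(config),
        "seed": config.seed,
        "occmot_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    return RunReport(
        provenance=provenance,
        bp_table=bp_table,
        occupancy_table=occupancy_table,
        hill={"ed50": hill.ed50, "rss": hill.rss},
        decay={"occ_day0": decay.occ_day0, "decay_rate": decay.decay_rate, "rss": decay.rss},
        reward_fit=reward_fit,
        cost_fit=cost_fit,
        rt_fit=rt_fit,
        incentive_occupancy=incentive,
    )


#: files written by write_report and their contents
REPORT_FILES = {
    "report.json": "full report payload (RunReport.to_dict)",
    "bp_nd.csv": "SRTM binding potentials per region and condition",
    "occupancy.csv": "occupancy per condition and method",
    "model_comparison_reward.csv": "reward-size family BIC table (4 rows)",
    "model_comparison_cost.csv": "cost family BIC table (4 rows)",
    "model_comparison_rt.csv": "RT-relation family BIC table (4 rows)",
    "behavior_parameters.json": "selected-model parameters per condition",
    "incentive_occupancy.csv": "(occupancy %, normalized a) pairs",
}


def write_report(report: RunReport, out_dir: str | Path) -> list[Path]:
    """Write the report tables and JSON summary; returns the file list."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    payload = report.to_dict()
    written = []

    def _write_json(name: str, obj: dict) -> None:
        path = out / name
        path.write_text(json.dumps(obj, indent=2, sort_keys=True))
        written.append(path)

    def _write_csv(name: str, df: pd.DataFrame) -> None:
        path = out / name
        df.to_csv(path, index=False)
        written.append(path)

    _write_json("report.json", payload)
    _write_csv("bp_nd.csv", report.bp_table)
    _write_csv("occupancy.csv", report.occupancy_table)
    _write_csv("model_comparison_reward.csv", report.reward_fit.comparison_table())
    _write_csv("model_comparison_cost.csv", report.cost_fit.comparison_table())
    _write_csv("model_comparison_rt.csv", report.rt_fit.comparison_table())
    _write_json(
        "behavior_parameters.json",
        {
            "reward": report.reward_fit.selected.params,
            "normalized_a": report.reward_fit.normalized_a,
            "cost": _records(report.cost_fit.params),
        },
    )
    _write_csv("incentive_occupancy.csv", report.incentive_occupancy)
    return written
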