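"""Synthetic PET and operant-behavior data with known ground truth.

Every generator is deterministic under its config seed: substreams are
spawned from a single :class:`numpy.random.SeedSequence`, so identical
configs give byte-identical tables.

* :func:`gen_pet_study` — dynamic time-activity curves per region and
  condition from the SRTM forward model, with a fixed analytic reference
  curve and uniform fractional blockade applied to the baseline BP_ND.
* :func:`gen_occupancy_series` — occupancy observations following the Hill
  dose model or the exponential washout model plus Gaussian noise.
* :func:`gen_reward_size_sessions` — trial records with Bernoulli refusals
  at ``clip(1/(a R) + e, 0, 1)`` over reward sizes.
* :func:`gen_work_delay_sessions` — trial records with Bernoulli refusals
  at ``clip(k CU + E0, 0, 1)`` over remaining cost units, for work and
  delay trial types.

Reaction times on correct trials are linear in the cell's refusal
probability with Gaussian noise; refused trials carry a null RT.
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .config import BehaviorSimConfig, OccupancySeriesConfig, PetSimConfig
from .kinetics import (
    FINE_DT,
    TimeActivityCurve,
    decay_occupancy,
    hill_occupancy,
    reference_tac,
    srtm_forward,
)

__all__ = [
    "gen_pet_study",
    "gen_occupancy_series",
    "gen_reward_size_sessions",
    "gen_work_delay_sessions",
    "TRIALS_COLUMNS",
]

TRIALS_COLUMNS = [
    "monkey",
    "session",
    "condition",
    "task",
    "trial_type",
    "level",
    "remaining_cu",
    "reward_drops",
    "outcome",
    "release_ms",
    "rt_ms",
    "delay_s",
]

#: reward latency ranges (s) per delay cost-unit level
DELAY_RANGES_S = {0: (0.2, 0.4), 1: (3.0, 4.2), 2: (6.0, 8.4)}


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Deterministic substream for a (seed, key...) pair."""
    return np.random.default_rng(np.random.SeedSequence((seed, *key)))


def gen_pet_study(config: PetSimConfig) -> pd.DataFrame:
    """Simulate a baseline + treatment dynamic PET study.

    Returns a tidy table with columns ``region, condition,
    frame_start_min, frame_end_min, activity_kbq_ml`` containing the
    reference region (``cerebellum``, the SRTM reference, BP_ND = 0,
    R1 = 1 by construction) and each configured target region under the
    baseline and every treatment condition.

    Frame noise is Gaussian with SD ``noise_sd`` times the curve's peak.
    Noise substreams are keyed by (region, blockade fraction), so a
    treatment with zero occupancy reproduces the baseline scan exactly —
    a convenient identity for validating the occupancy estimators.
    """
    frames = np.asarray(config.frames, dtype=float)
    mids = frames.mean(axis=1)
    t_fine = np.arange(int(np.ceil(frames[-1, 1] / FINE_DT)) + 1) * FINE_DT
    ref_fine = reference_tac(t_fine)
    conditions = {"baseline": 0.0, **config.occupancy_truth}

    rows = []

    def frame_samples(curve_fine: np.ndarray, noise_key: tuple[int, ...]) -> np.ndarray:
        sampled = np.interp(mids, t_fine, curve_fine)
        if config.noise_sd > 0:
            rng = _rng_for(config.seed, *noise_key)
            sampled = sampled + rng.normal(0.0, config.noise_sd * curve_fine.max(), len(mids))
        return sampled

    for cond, occ in conditions.items():
        occ_key = int(round(occ * 1_000_000_000))
        # reference region is receptor-free: unaffected by the blocker
        ref_sampled = frame_samples(ref_fine, (0, 0))
        rows.append((cond, "cerebellum", ref_sampled))
        for i, region in enumerate(config.regions, start=1):
            bp = region.bp_nd * (1.0 - occ)
            curve = srtm_forward(t_fine, ref_fine, region.r1, region.k2, bp, FINE_DT)
            rows.append((cond, region.name, frame_samples(curve, (i, occ_key))))

    out = []
    for cond, name, activity in rows:
        out.append(
            pd.DataFrame(
                {
                    "region": name,
                    "condition": cond,
                    "frame_start_min": frames[:, 0],
                    "frame_end_min": frames[:, 1],
                    "activity_kbq_ml": activity,
                }
            )
        )
    return pd.concat(out, ignore_index=True)


def pet_study_tacs(df: pd.DataFrame) -> dict[tuple[str, str], TimeActivityCurve]:
    """Index a tidy TAC table as {(region, condition): TimeActivityCurve}."""
    out = {}
    for (region, cond), _ in df.groupby(["region", "condition"], sort=False):
        out[(region, cond)] = TimeActivityCurve.from_frame(df, region, cond)
    return out


def gen_occupancy_series(config: OccupancySeriesConfig) -> pd.DataFrame:
    """Occupancy observations (%) on a dose or day design, truncated to [0, 100].

    Returns columns ``mode, design_point, replicate, occupancy_pct``.
    """
    rng = _rng_for(config.seed, 1)
    pts = np.asarray(config.design_points, dtype=float)
    if config.mode == "dose":
        truth = hill_occupancy(pts, config.ed50)
    else:
        truth = decay_occupancy(pts, config.occ_day0, config.decay_rate)
    rows = []
    for rep in range(config.replicates):
        obs = truth + rng.normal(0.0, config.noise_sd, len(pts)) if config.noise_sd > 0 else truth.copy()
        obs = np.clip(obs, 0.0, 100.0)
        rows.append(
            pd.DataFrame(
                {
                    "mode": config.mode,
                    "design_point": pts,
                    "replicate": rep,
                    "occupancy_pct": obs,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def _clip_prob(p: float) -> float:
    return float(np.clip(p, 0.0, 1.0))


def _rt_for(config: BehaviorSimConfig, condition: str, p_cell: float, rng: np.random.Generator) -> float:
    offset = config.rt_condition_offset_ms.get(condition, 0.0)
    rt = (
        config.rt_intercept_ms
        + (config.rt_slope_ms + offset) * p_cell
        + rng.normal(0.0, config.rt_noise_sd_ms)
    )
    # a correct release lies in the (200, 1000] ms response window
    return float(np.clip(rt, 201.0, 1000.0))


def _emit_trial(
    config: BehaviorSimConfig,
    rng: np.random.Generator,
    base: dict,
    p: float,
    rows: list,
) -> bool:
    """Append one presentation; returns True if it was refused."""
    refused = rng.random() < p
    row = dict(base)
    if refused:
        early = rng.random() < 0.5
        row["outcome"] = "early" if early else "late"
        row["release_ms"] = float(rng.uniform(-300.0, 200.0)) if early else np.nan
        row["rt_ms"] = np.nan
    else:
        rt = _rt_for(config, base["condition"], p, rng)
        row["outcome"] = "correct"
        row["release_ms"] = rt
        row["rt_ms"] = rt
    rows.append(row)
    return refused


def _run_deck(
    config: BehaviorSimConfig,
    rng: np.random.Generator,
    deck: list[tuple[dict, float]],
    rows: list,
    max_repeats: int = 50,
) -> None:
    """Present a shuffled deck of (trial template, refusal probability).

    With ``repeat_refused_trials`` each refused presentation is repeated
    (as in the task, where a refused trial is re-offered after the
    intertrial interval) until success, each presentation its own row.
    """
    order = rng.permutation(len(deck))
    for idx in order:
        base, p = deck[idx]
        refused = _emit_trial(config, rng, base, p, rows)
        if config.repeat_refused_trials:
            n = 0
            while refused and n < max_repeats:
                refused = _emit_trial(config, rng, base, p, rows)
                n += 1


def gen_reward_size_sessions(config: BehaviorSimConfig) -> pd.DataFrame:
    """Trial records for the reward-size task.

    Per condition and session, each reward size in ``reward_sizes``
    contributes exactly ``trials_per_cell`` presentations, offered in
    random order (each size equally likely at any point in the session).
    Refusal probability per presentation is ``clip(1/(a R) + e, 0, 1)``.
    """
    if config.task != "reward_size":
        raise ValueError("config.task must be 'reward_size'")
    rows: list[dict] = []
    for ci, cond in enumerate(config.conditions):
        a = config.a[cond]
        e = config.e.get(cond, 0.0)
        for sess in range(config.sessions):
            rng = _rng_for(config.seed, 2, ci, sess)
            deck = []
            for r_size in config.reward_sizes:
                p = _clip_prob(1.0 / (a * r_size) + e)
                base = {
                    "monkey": config.monkey,
                    "session": f"{cond}-s{sess}",
                    "condition": cond,
                    "task": "reward_size",
                    "trial_type": "n/a",
                    "level": r_size,
                    "remaining_cu": np.nan,
                    "reward_drops": r_size,
                    "delay_s": np.nan,
                }
                deck.extend((base, p) for _ in range(config.trials_per_cell))
            _run_deck(config, rng, deck, rows)
    return pd.DataFrame(rows, columns=TRIALS_COLUMNS)


def gen_work_delay_sessions(config: BehaviorSimConfig) -> pd.DataFrame:
    """Trial records for the work/delay task.

    Per condition, session, trial type (work / delay) and remaining cost
    unit level, ``trials_per_cell`` presentations are offered in random
    order with refusal probability ``clip(k_type CU + E0, 0, 1)``.  Delay
    trials draw their reward latency uniformly from the level's range
    (0.2-0.4, 3.0-4.2, 6.0-8.4 s).
    """
    if config.task != "work_delay":
        raise ValueError("config.task must be 'work_delay'")
    rows: list[dict] = []
    for ci, cond in enumerate(config.conditions):
        e0 = config.e0[cond]
        if e0 < 0 and all(
            config.k_w[cond] * cu + e0 <= 0 and config.k_d[cond] * cu + e0 <= 0
            for cu in config.cost_units
        ):
            warnings.warn(
                f"condition {cond!r}: refusal probability clipped to 0 everywhere",
                stacklevel=2,
            )
        for sess in range(config.sessions):
            rng = _rng_for(config.seed, 3, ci, sess)
            deck = []
            for trial_type, k in (("work", config.k_w[cond]), ("delay", config.k_d[cond])):
                for cu in config.cost_units:
                    p = _clip_prob(k * cu + e0)
                    base = {
                        "monkey": config.monkey,
                        "session": f"{cond}-s{sess}",
                        "condition": cond,
                        "task": "work_delay",
                        "trial_type": trial_type,
                        "level": cu,
                        "remaining_cu": cu,
                        "reward_drops": np.nan,
                        "delay_s": np.nan,
                    }
                    deck.extend((base, p) for _ in range(config.trials_per_cell))
            _run_deck(config, rng, deck, rows)
    df = pd.DataFrame(rows, columns=TRIALS_COLUMNS)
    # reward latencies for delay trials, drawn per presentation
    is_delay = df["trial_type"] == "delay"
    rng = _rng_for(config.seed, 4)
    for cu, (lo, hi) in DELAY_RANGES_S.items():
        mask = is_delay & (df["level"] == cu)
        df.loc[mask, "delay_s"] = rng.uniform(lo, hi, int(mask.sum()))
    return df
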