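"""Validated configuration objects for simulation and pipeline runs.

All stochastic components take a single integer ``seed``; substreams are
derived deterministically with :class:`numpy.random.SeedSequence`, so a
config plus its seed fully determines every generated table.
"""
from __future__ import annotations

import hashlib
import json
from typing import Literal, Optional

from pydantic import BaseModel, Field, model_validator

__all__ = [
    "RegionSpec",
    "PetSimConfig",
    "BehaviorSimConfig",
    "OccupancySeriesConfig",
    "RunConfig",
    "config_hash",
]

#: default 60-minute dynamic scan: 4x1, 4x2, 4x4, 4x8 min frames
DEFAULT_FRAMES: list[tuple[float, float]] = [
    (0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0),
    (4.0, 6.0), (6.0, 8.0), (8.0, 10.0), (10.0, 12.0),
    (12.0, 16.0), (16.0, 20.0), (20.0, 24.0), (24.0, 28.0),
    (28.0, 36.0), (36.0, 44.0), (44.0, 52.0), (52.0, 60.0),
]

#: striatal/extrastriatal baseline binding potentials typical of a
#: D1/D2 radioligand study (high in striatum, low in cortex)
DEFAULT_REGIONS: list[dict] = [
    {"name": "caudate", "bp_nd": 2.5, "r1": 1.05, "k2": 0.17},
    {"name": "putamen", "bp_nd": 2.8, "r1": 1.10, "k2": 0.18},
    {"name": "nacc", "bp_nd": 2.2, "r1": 1.00, "k2": 0.16},
    {"name": "thalamus", "bp_nd": 0.9, "r1": 0.95, "k2": 0.14},
    {"name": "hippocampus", "bp_nd": 0.5, "r1": 0.85, "k2": 0.12},
    {"name": "amygdala", "bp_nd": 0.7, "r1": 0.90, "k2": 0.13},
    {"name": "parietal", "bp_nd": 0.4, "r1": 0.92, "k2": 0.12},
    {"name": "ps", "bp_nd": 0.55, "r1": 0.94, "k2": 0.13},
    {"name": "dlpfc", "bp_nd": 0.5, "r1": 0.93, "k2": 0.12},
    {"name": "vlpfc", "bp_nd": 0.45, "r1": 0.91, "k2": 0.12},
]


class RegionSpec(BaseModel):
    """One brain region's ground-truth kinetic parameters."""

    name: str
    bp_nd: float = Field(ge=0.0, description="baseline binding potential (unitless)")
    r1: float = Field(gt=0.0, default=1.0, description="delivery ratio target/reference")
    k2: float = Field(gt=0.0, default=0.15, description="tissue clearance rate (1/min)")


class PetSimConfig(BaseModel):
    """Ground truth for a simulated dynamic PET occupancy study."""

    regions: list[RegionSpec] = Field(
        default_factory=lambda: [RegionSpec(**r) for r in DEFAULT_REGIONS]
    )
    frames: list[tuple[float, float]] = Field(
        default_factory=lambda: list(DEFAULT_FRAMES),
        description="frame [start, end] in minutes",
    )
    occupancy_truth: dict[str, float] = Field(
        default_factory=lambda: {"MO": 0.5, "HO": 0.8},
        description="condition label -> uniform fractional blockade in [0, 1]",
    )
    noise_sd: float = Field(ge=0.0, default=0.0, description="Gaussian frame noise, fraction of curve peak")
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PetSimConfig":
        prev_end = -1e-12
        for start, end in self.frames:
            if not (end > start >= prev_end - 1e-12):
                raise ValueError("frames must be increasing and non-overlapping")
            prev_end = end
        if self.frames[0][0] < 0:
            raise ValueError("frames must start at time >= 0")
        for cond, occ in self.occupancy_truth.items():
            if not 0.0 <= occ <= 1.0:
                raise ValueError(f"occupancy_truth[{cond!r}] must lie in [0, 1]")
        return self


class BehaviorSimConfig(BaseModel):
    """Ground truth for simulated operant sessions.

    ``reward_size`` task: refusal probability ``clip(1/(a_c R) + e_c, 0, 1)``
    over reward sizes ``R``.  ``work_delay`` task: refusal probability
    ``clip(k_type CU + E0_c, 0, 1)`` over remaining cost units ``CU`` for
    work and delay trial types.  Reaction times on correct trials are linear
    in the cell's refusal probability.
    """

    task: Literal["reward_size", "work_delay"]
    conditions: list[str] = Field(default_factory=lambda: ["CON", "MO", "HO"])
    monkey: str = "SIM"

    reward_sizes: list[int] = Field(default_factory=lambda: [1, 2, 4, 8])
    cost_units: list[int] = Field(default_factory=lambda: [0, 1, 2])

    # reward-size truth (per condition)
    a: dict[str, float] = Field(default_factory=dict, description="incentive impact, 1/drop")
    e: dict[str, float] = Field(default_factory=dict, description="size-independent refusal intercept")
    # work/delay truth (per condition)
    k_w: dict[str, float] = Field(default_factory=dict, description="workload discounting per CU")
    k_d: dict[str, float] = Field(default_factory=dict, description="delay discounting per CU")
    e0: dict[str, float] = Field(default_factory=dict, description="shared intercept")

    sessions: int = Field(ge=1, default=5)
    trials_per_cell: int = Field(ge=0, default=100, description="presentations per level (x trial type) per session")

    rt_intercept_ms: float = 350.0
    rt_slope_ms: float = 250.0
    rt_condition_offset_ms: dict[str, float] = Field(default_factory=dict)
    rt_noise_sd_ms: float = Field(ge=0.0, default=40.0)

    repeat_refused_trials: bool = False
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "BehaviorSimConfig":
        if self.task == "reward_size":
            missing = [c for c in self.conditions if c not in self.a]
            if missing:
                raise ValueError(f"missing incentive parameter a for conditions {missing}")
            for c, val in self.a.items():
                if val <= 0:
                    raise ValueError(f"a[{c!r}] must be > 0")
        else:
            for name, d in (("k_w", self.k_w), ("k_d", self.k_d), ("e0", self.e0)):
                missing = [c for c in self.conditions if c not in d]
                if missing:
                    raise ValueError(f"missing {name} for conditions {missing}")
        return self


class OccupancySeriesConfig(BaseModel):
    """Design for a dose->occupancy (Hill) or day->occupancy (decay) series."""

    mode: Literal["dose", "day"]
    ed50: Optional[float] = Field(default=None, gt=0.0, description="dose of half-maximal occupancy (μg/kg)")
    occ_day0: Optional[float] = Field(default=None, ge=0.0, le=100.0, description="occupancy on injection day (%)")
    decay_rate: Optional[float] = Field(default=None, ge=0.0, description="occupancy washout rate λ (1/day)")
    design_points: list[float] = Field(min_length=1, description="doses (μg/kg) or days")
    noise_sd: float = Field(ge=0.0, default=0.0, description="Gaussian noise in percentage points")
    replicates: int = Field(ge=1, default=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "OccupancySeriesConfig":
        if self.mode == "dose":
            if self.ed50 is None:
                raise ValueError("dose mode requires ed50")
            if any(d < 0 for d in self.design_points):
                raise ValueError("doses must be non-negative")
        else:
            if self.occ_day0 is None or self.decay_rate is None:
                raise ValueError("day mode requires occ_day0 and decay_rate")
        return self


class RunConfig(BaseModel):
    """Everything one end-to-end pipeline run needs."""

    seed: int = 0
    control_condition: str = "CON"
    pet: PetSimConfig = Field(default_factory=PetSimConfig)
    reward_behavior: BehaviorSimConfig = Field(
        default_factory=lambda: BehaviorSimConfig(
            task="reward_size",
            a={"CON": 8.0, "MO": 5.4, "HO": 4.0},
            e={"CON": 0.0, "MO": 0.0, "HO": 0.0},
        )
    )
    cost_behavior: BehaviorSimConfig = Field(
        default_factory=lambda: BehaviorSimConfig(
            task="work_delay",
            k_w={"CON": 0.05, "MO": 0.12, "HO": 0.22},
            k_d={"CON": 0.08, "MO": 0.15, "HO": 0.28},
            e0={"CON": 0.03, "MO": 0.06, "HO": 0.10},
        )
    )
    dose_series: OccupancySeriesConfig = Field(
        default_factory=lambda: OccupancySeriesConfig(
            mode="dose", ed50=22.63, design_points=[10.0, 30.0, 50.0, 100.0],
            noise_sd=3.0, replicates=3,
        )
    )
    day_series: OccupancySeriesConfig = Field(
        default_factory=lambda: OccupancySeriesConfig(
            mode="day", occ_day0=78.0, decay_rate=0.4855,
            design_points=[0.0, 1.0, 2.0, 3.0, 7.0], noise_sd=3.0, replicates=3,
        )
    )
    #: condition -> nominal occupancy band (%), used for reporting only
    occupancy_bands: dict[str, float] = Field(
        default_factory=lambda: {"CON": 0.0, "MO": 50.0, "HO": 80.0}
    )
    likelihood: Literal["binomial", "gaussian"] = "binomial"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.reward_behavior.task != "reward_size":
            raise ValueError("reward_behavior must have task='reward_size'")
        if self.cost_behavior.task != "work_delay":
            raise ValueError("cost_behavior must have task='work_delay'")
        labels = set(self.reward_behavior.conditions) | set(self.cost_behavior.conditions)
        unknown = labels - set(self.occupancy_bands)
        if unknown:
            raise ValueError(f"occupancy_bands missing behavioral conditions {sorted(unknown)}")
        return self


def config_hash(config: BaseModel) -> str:
    """SHA-256 over the canonical JSON form; changes iff a semantic field changes."""
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()
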