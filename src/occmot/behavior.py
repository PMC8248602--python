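"""Refusal-rate aggregation and motivational model families.

The operant tasks measure motivation through the refusal rate ``E``: the
fraction of trial presentations on which the subject releases the bar too
early (at or before 200 ms after the go signal, or before it) or too late
(no release within 1 s).  Three bespoke model families relate ``E`` to the
offer and to response speed:

* reward-size family — ``E = clip(1/(a R) + e, 0, 1)`` over reward sizes
  ``R``; four nested parameter-sharing structures (condition-specific
  ``a`` and/or ``e``) compared by BIC,
* cost family — ``E = k_type * CU + E0`` over remaining cost units with a
  single intercept shared by work and delay trials; the nested structures
  differ in which grouping factors (condition, subject) get their own
  coefficients, with BIC summed over the per-group fits,
* refusal-RT relation — per-cell mean reaction time regressed on ``E``
  under the same kind of nested grouping structures.

"Random effects" over a handful of treatment conditions are implemented
as group-specific parameters estimated by maximum likelihood, each counted
as a parameter in the BIC penalty.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import minimize

__all__ = [
    "classify_trial_outcome",
    "aggregate_refusal",
    "fit_reward_size_family",
    "fit_cost_family",
    "fit_rt_relation_family",
    "sucrose_preference_index",
    "RewardSizeFamilyFit",
    "CostFamilyFit",
    "RtRelationFit",
]

_P_FLOOR = 1e-6  # probability floor/ceiling keeping log-likelihoods finite
_BIC_TIE_TOL = 1e-6  # ties broken toward the fewer-parameter model

CELL_KEY = ["monkey", "session", "condition", "task", "trial_type", "level"]


def classify_trial_outcome(release_ms_from_go: float | None, go_shown: bool = True) -> str:
    """Classify a bar release relative to the go signal.

    ``early``: release before the go signal or at/within 200 ms after it;
    ``late``: no release within 1,000 ms; ``correct``: release in the
    half-open window (200, 1000] ms.
    """
    if not go_shown:
        return "early"
    if release_ms_from_go is None or (
        isinstance(release_ms_from_go, float) and math.isnan(release_ms_from_go)
    ):
        return "late"
    if release_ms_from_go <= 200.0:
        return "early"
    if release_ms_from_go <= 1000.0:
        return "correct"
    return "late"


def aggregate_refusal(
    trials: pd.DataFrame,
    pool_early_late: bool = True,
    drop_before_first_success: bool = True,
) -> pd.DataFrame:
    """Per-cell refusal rates and correct-trial mean reaction times.

    Rows are grouped by (monkey, session, condition, task, trial type,
    level).  Within each session, presentations preceding the first
    correct trial are excluded (high-impatience session openings).  Early
    and late errors are pooled as refusals; with ``pool_early_late=False``
    the per-type counts are still reported for error-pattern description,
    but the refusal rate always uses their sum.

    Cells exist only where presentations exist — an empty cell is absent
    from the table, never a zero rate.
    """
    df = trials.copy()
    if drop_before_first_success:
        keep = np.zeros(len(df), dtype=bool)
        for _, idx in df.groupby(["monkey", "session"], sort=False).indices.items():
            outcomes = df["outcome"].to_numpy()[idx]
            correct_pos = np.flatnonzero(outcomes == "correct")
            if correct_pos.size:
                keep[idx[correct_pos[0]:]] = True
        df = df[keep]

    def _agg(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        n_early = int((g["outcome"] == "early").sum())
        n_late = int((g["outcome"] == "late").sum())
        n_ref = n_early + n_late
        correct_rt = g.loc[g["outcome"] == "correct", "rt_ms"]
        return pd.Series(
            {
                "n_presented": n,
                "n_refused": n_ref,
                "n_early": n_early,
                "n_late": n_late,
                "refusal_rate": n_ref / n,
                "mean_rt_ms": correct_rt.mean() if len(correct_rt) else np.nan,
            }
        )

    out = (
        df.groupby(CELL_KEY, sort=False, dropna=False)
        .apply(_agg, include_groups=False)
        .reset_index()
    )
    for col in ["n_presented", "n_refused", "n_early", "n_late"]:
        out[col] = out[col].astype(int)
    if pool_early_late:
        out = out.drop(columns=["n_early", "n_late"])
    return out


# ----------------------------------------------------------------------
# reward-size family
# ----------------------------------------------------------------------

REWARD_MODEL_STRUCTURES = {
    1: "a(cond)",
    2: "a(cond) + e",
    3: "a + e(cond)",
    4: "a(cond) + e(cond)",
}


@dataclass
class ModelFit:
    model_id: int
    structure: str
    params: dict
    loglik: float
    n_params: int
    n_obs: int
    bic: float
    converged: bool = True


@dataclass
class RewardSizeFamilyFit:
    fits: dict[int, ModelFit]
    selected_id: int
    conditions: list[str]
    reference_condition: str
    normalized_a: dict[str, float] = field(default_factory=dict)
    likelihood: str = "binomial"

    @property
    def selected(self) -> ModelFit:
        return self.fits[self.selected_id]

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": f.model_id,
                "structure": f.structure,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "bic": f.bic,
            }
            for f in self.fits.values()
        ]
        df = pd.DataFrame(rows).sort_values("model_id").reset_index(drop=True)
        df["delta_bic"] = df["bic"] - df["bic"].min()
        return df


def _inverse_reward_p(a: np.ndarray, e: np.ndarray, r: np.ndarray) -> np.ndarray:
    return np.clip(1.0 / (a * r) + e, _P_FLOOR, 1.0 - _P_FLOOR)


def _reward_unpack(x: np.ndarray, model_id: int, n_cond: int):
    if model_id == 1:
        return x[:n_cond], np.zeros(n_cond)
    if model_id == 2:
        return x[:n_cond], np.full(n_cond, x[n_cond])
    if model_id == 3:
        return np.full(n_cond, x[0]), x[1 : 1 + n_cond]
    return x[:n_cond], x[n_cond : 2 * n_cond]


def _reward_pack_bounds(model_id: int, n_cond: int):
    a_b, e_b = (1e-2, 1e3), (0.0, 1.0 - 1e-4)
    if model_id == 1:
        return [a_b] * n_cond
    if model_id == 2:
        return [a_b] * n_cond + [e_b]
    if model_id == 3:
        return [a_b] + [e_b] * n_cond
    return [a_b] * n_cond + [e_b] * n_cond


def fit_reward_size_family(
    refusals: pd.DataFrame,
    likelihood: Literal["binomial", "gaussian"] = "binomial",
    reference_condition: str = "CON",
) -> RewardSizeFamilyFit:
    """Fit and compare the four inverse reward-size model structures.

    ``refusals`` is an :func:`aggregate_refusal` table restricted to the
    reward-size task (``level`` = reward drops).  The binomial likelihood
    operates on pooled per-(condition, size) refusal counts and uses the
    total presentation count as the BIC sample size; the gaussian
    likelihood operates on the table's cell rates and uses the number of
    cells (one extra parameter counts the residual variance).

    The per-condition incentive impact ``a`` of the selected model is
    normalized by the reference condition's value when present.
    """
    conditions = list(pd.unique(refusals["condition"]))
    n_cond = len(conditions)
    sizes = np.sort(pd.unique(refusals["level"]))
    if len(sizes) < 2:
        raise ValueError("need >= 2 reward levels")
    if n_cond < 2:
        warnings.warn(
            "single condition: family comparison is uninformative (structures coincide)",
            stacklevel=2,
        )

    cond_codes = pd.Categorical(refusals["condition"], categories=conditions).codes
    if likelihood == "binomial":
        cells = (
            pd.DataFrame(
                {
                    "cond": cond_codes,
                    "r": refusals["level"].to_numpy(dtype=float),
                    "k": refusals["n_refused"].to_numpy(dtype=float),
                    "n": refusals["n_presented"].to_numpy(dtype=float),
                }
            )
            .groupby(["cond", "r"], as_index=False)
            .sum()
        )
        cond_idx = cells["cond"].to_numpy()
        r = cells["r"].to_numpy()
        k = cells["k"].to_numpy()
        n = cells["n"].to_numpy()
        n_obs = int(n.sum())

        def negloglik(x: np.ndarray, model_id: int) -> float:
            a, e = _reward_unpack(x, model_id, n_cond)
            p = _inverse_reward_p(a[cond_idx], e[cond_idx], r)
            return -float(np.sum(k * np.log(p) + (n - k) * np.log1p(-p)))

    else:
        cond_idx = cond_codes
        r = refusals["level"].to_numpy(dtype=float)
        y = refusals["refusal_rate"].to_numpy(dtype=float)
        n_obs = len(y)

        def negloglik(x: np.ndarray, model_id: int) -> float:
            a, e = _reward_unpack(x, model_id, n_cond)
            p = _inverse_reward_p(a[cond_idx], e[cond_idx], r)
            rss = float(np.sum((y - p) ** 2))
            sigma2 = max(rss / n_obs, 1e-12)
            return 0.5 * n_obs * (np.log(2 * np.pi * sigma2) + 1.0)

    def starts_for(model_id: int, nested_solutions: list[tuple[np.ndarray, np.ndarray]]):
        base = []
        for a0 in (0.5, 2.0, 8.0):
            a_vec, e_vec = np.full(n_cond, a0), np.full(n_cond, 0.05)
            base.append((a_vec, e_vec))
        if model_id == 4:
            base.extend(nested_solutions)
        packed = []
        for a_vec, e_vec in base:
            if model_id == 1:
                packed.append(a_vec)
            elif model_id == 2:
                packed.append(np.concatenate([a_vec, [float(np.mean(e_vec))]]))
            elif model_id == 3:
                packed.append(np.concatenate([[float(np.mean(a_vec))], e_vec]))
            else:
                packed.append(np.concatenate([a_vec, e_vec]))
        return packed

    fits: dict[int, ModelFit] = {}
    nested_solutions: list[tuple[np.ndarray, np.ndarray]] = []
    for model_id in (1, 2, 3, 4):
        bounds = _reward_pack_bounds(model_id, n_cond)
        best = None
        converged = False
        for x0 in starts_for(model_id, nested_solutions):
            res = minimize(
                negloglik,
                np.clip(x0, [b[0] for b in bounds], [b[1] for b in bounds]),
                args=(model_id,),
                method="L-BFGS-B",
                bounds=bounds,
            )
            if best is None or res.fun < best.fun:
                best = res
            converged = converged or bool(res.success)
        a_hat, e_hat = _reward_unpack(best.x, model_id, n_cond)
        if model_id in (1, 2, 3):
            nested_solutions.append((a_hat.copy(), e_hat.copy()))
        n_params = len(bounds) + (1 if likelihood == "gaussian" else 0)
        loglik = -float(best.fun)
        bic = n_params * np.log(n_obs) - 2.0 * loglik
        params = {
            "a": {c: float(a_hat[i]) for i, c in enumerate(conditions)},
            "e": {c: float(e_hat[i]) for i, c in enumerate(conditions)},
        }
        if not converged:
            warnings.warn(f"reward-size model #{model_id} did not converge", stacklevel=2)
        fits[model_id] = ModelFit(
            model_id=model_id,
            structure=REWARD_MODEL_STRUCTURES[model_id],
            params=params,
            loglik=loglik,
            n_params=n_params,
            n_obs=n_obs,
            bic=float(bic),
            converged=converged,
        )

    selected_id = _select_by_bic({m: (f.bic, f.n_params) for m, f in fits.items() if f.converged})
    ref = reference_condition if reference_condition in conditions else conditions[0]
    a_sel = fits[selected_id].params["a"]
    normalized = {c: a_sel[c] / a_sel[ref] for c in conditions}
    return RewardSizeFamilyFit(
        fits=fits,
        selected_id=selected_id,
        conditions=conditions,
        reference_condition=ref,
        normalized_a=normalized,
        likelihood=likelihood,
    )


def _select_by_bic(candidates: dict[int, tuple[float, int]]) -> int:
    """Arg-min BIC; ties within tolerance go to the fewer-parameter model."""
    if not candidates:
        raise ValueError("no converged fits to select from")
    best_bic = min(b for b, _ in candidates.values())
    tied = [m for m, (b, _) in candidates.items() if b - best_bic < _BIC_TIE_TOL]
    return min(tied, key=lambda m: (candidates[m][1], m))


# ----------------------------------------------------------------------
# cost (work/delay) family
# ----------------------------------------------------------------------

COST_VARIANT_STRUCTURES = {
    1: "E ~ type:CU + E0 | cond x monkey",
    2: "E ~ type:CU + E0 | monkey",
    3: "E ~ type:CU + E0 | cond",
    4: "E ~ type:CU + E0",
}
_COST_FACETS = {1: ["monkey", "condition"], 2: ["monkey"], 3: ["condition"], 4: []}


def _gaussian_ll(rss: float, n: int) -> float:
    sigma2 = max(rss / n, 1e-12)
    return -0.5 * n * (np.log(2 * np.pi * sigma2) + 1.0)


def _cost_ols(cells: pd.DataFrame) -> tuple[float, float, float, float]:
    """(k_w, k_d, E0, rss) for E = k_type*CU + E0 with shared intercept."""
    cu = cells["level"].to_numpy(dtype=float)
    y = cells["refusal_rate"].to_numpy(dtype=float)
    is_work = (cells["trial_type"] == "work").to_numpy()
    X = np.column_stack([cu * is_work, cu * ~is_work, np.ones_like(cu)])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return float(beta[0]), float(beta[1]), float(beta[2]), rss


@dataclass
class CostFamilyFit:
    variants: dict[int, ModelFit]
    selected_id: int
    params: pd.DataFrame  # per (monkey, condition): k_w, k_d, e0 from the full facet fit
    flagged_cells: int = 0

    @property
    def selected(self) -> ModelFit:
        return self.variants[self.selected_id]

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": f.model_id,
                "structure": f.structure,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "bic": f.bic,
            }
            for f in self.variants.values()
        ]
        df = pd.DataFrame(rows).sort_values("model_id").reset_index(drop=True)
        df["delta_bic"] = df["bic"] - df["bic"].min()
        return df


def fit_cost_family(refusals: pd.DataFrame) -> CostFamilyFit:
    """Fit and compare the nested linear cost-discounting structures.

    Each variant fits ``E = k_w CU`` (work trials) / ``k_d CU`` (delay
    trials) plus a single intercept ``E0`` shared by both trial types, by
    least squares on cell rates, separately within each unit of its
    grouping structure (condition x subject, subject, condition, or
    pooled); the variant's BIC is the sum over its unit fits.  The
    reported parameter table always comes from the fully faceted
    (condition x subject) fits, one shared ``E0`` per unit.

    Cells whose fitted rate falls outside [0, 1] at an observed CU are
    counted in ``flagged_cells``; the linear fit is retained.
    """
    types = set(refusals["trial_type"])
    if not {"work", "delay"}.issubset(types):
        raise ValueError("both work and delay trial types are required")
    if refusals["level"].nunique() < 2:
        raise ValueError("need >= 2 cost-unit levels")

    variants: dict[int, ModelFit] = {}
    for vid, facet_cols in _COST_FACETS.items():
        groups = (
            [(None, refusals)]
            if not facet_cols
            else list(refusals.groupby(facet_cols, sort=False))
        )
        loglik = 0.0
        bic = 0.0
        n_params = 0
        n_obs = 0
        for _, g in groups:
            _, _, _, rss = _cost_ols(g)
            n = len(g)
            ll = _gaussian_ll(rss, n)
            p = 4  # k_w, k_d, E0, sigma
            loglik += ll
            bic += p * np.log(n) - 2.0 * ll
            n_params += p
            n_obs += n
        variants[vid] = ModelFit(
            model_id=vid,
            structure=COST_VARIANT_STRUCTURES[vid],
            params={},
            loglik=loglik,
            n_params=n_params,
            n_obs=n_obs,
            bic=float(bic),
        )

    selected = _select_by_bic({m: (f.bic, f.n_params) for m, f in variants.items()})

    rows = []
    flagged = 0
    for (monkey, cond), g in refusals.groupby(["monkey", "condition"], sort=False):
        k_w, k_d, e0, rss = _cost_ols(g)
        cu = g["level"].to_numpy(dtype=float)
        k_vec = np.where(g["trial_type"] == "work", k_w, k_d)
        fitted = k_vec * cu + e0
        flagged += int(np.sum((fitted < 0) | (fitted > 1)))
        rows.append(
            {"monkey": monkey, "condition": cond, "k_w": k_w, "k_d": k_d, "e0": e0, "rss": rss}
        )
    return CostFamilyFit(
        variants=variants,
        selected_id=selected,
        params=pd.DataFrame(rows),
        flagged_cells=flagged,
    )


# ----------------------------------------------------------------------
# refusal-rate vs reaction-time relation
# ----------------------------------------------------------------------

RT_VARIANT_STRUCTURES = {1: "none", 2: "subject", 3: "condition", 4: "both"}
_RT_FACETS = {1: [], 2: ["monkey"], 3: ["condition"], 4: ["monkey", "condition"]}


@dataclass
class RtRelationFit:
    variants: dict[int, ModelFit]
    selected_id: int
    slope_ms: float
    intercept_ms: float
    group_coefficients: pd.DataFrame | None = None

    @property
    def selected_structure(self) -> str:
        return RT_VARIANT_STRUCTURES[self.selected_id]

    @property
    def selected(self) -> ModelFit:
        return self.variants[self.selected_id]

    def comparison_table(self) -> pd.DataFrame:
        rows = [
            {
                "model_id": f.model_id,
                "structure": f.structure,
                "n_params": f.n_params,
                "loglik": f.loglik,
                "bic": f.bic,
            }
            for f in self.variants.values()
        ]
        df = pd.DataFrame(rows).sort_values("model_id").reset_index(drop=True)
        df["delta_bic"] = df["bic"] - df["bic"].min()
        return df


def _rt_ols(cells: pd.DataFrame) -> tuple[float, float, float]:
    x = cells["refusal_rate"].to_numpy(dtype=float)
    y = cells["mean_rt_ms"].to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return float(beta[1]), float(beta[0]), rss


def fit_rt_relation_family(refusals: pd.DataFrame) -> RtRelationFit:
    """Regress per-cell mean RT on refusal rate under nested groupings.

    The four structures give every group of (nothing, subject, condition,
    subject x condition) its own slope and intercept; BIC (summed over
    group fits, gaussian likelihood, 3 parameters per group including the
    residual SD) selects the structure.  When a grouped structure wins,
    the per-group coefficients are reported and the headline slope and
    intercept are the pooled fit's.
    """
    cells = refusals.dropna(subset=["refusal_rate", "mean_rt_ms"])
    if len(cells) < 3:
        raise ValueError("need >= 3 cells with both refusal rate and mean RT")

    variants: dict[int, ModelFit] = {}
    coefs: dict[int, pd.DataFrame] = {}
    for vid, facet_cols in _RT_FACETS.items():
        groups = (
            [(None, cells)] if not facet_cols else list(cells.groupby(facet_cols, sort=False))
        )
        loglik = 0.0
        bic = 0.0
        n_params = 0
        rows = []
        for key, g in groups:
            if len(g) < 3:  # cannot estimate slope, intercept and spread
                continue
            slope, intercept, rss = _rt_ols(g)
            n = len(g)
            ll = _gaussian_ll(rss, n)
            p = 3
            loglik += ll
            bic += p * np.log(n) - 2.0 * ll
            n_params += p
            rows.append({"group": key, "slope_ms": slope, "intercept_ms": intercept, "n": n})
        variants[vid] = ModelFit(
            model_id=vid,
            structure=RT_VARIANT_STRUCTURES[vid],
            params={},
            loglik=loglik,
            n_params=n_params,
            n_obs=len(cells),
            bic=float(bic),
        )
        coefs[vid] = pd.DataFrame(rows)

    selected = _select_by_bic({m: (f.bic, f.n_params) for m, f in variants.items()})
    slope, intercept, _ = _rt_ols(cells)
    return RtRelationFit(
        variants=variants,
        selected_id=selected,
        slope_ms=slope,
        intercept_ms=intercept,
        group_coefficients=coefs[selected] if selected != 1 else None,
    )


def sucrose_preference_index(sucrose_ml: float, water_ml: float) -> float:
    """Sucrose preference SP = (SW - TW) / (SW + TW), in [-1, 1]."""
    if sucrose_ml < 0 or water_ml < 0:
        raise ValueError("intake volumes must be non-negative")
    total = sucrose_ml + water_ml
    if total <= 0:
        raise ValueError("SP undefined for zero total intake")
    return (sucrose_ml - water_ml) / total
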