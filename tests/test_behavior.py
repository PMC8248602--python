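"""Trial classification, refusal aggregation, and the behavioral model families."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occmot.behavior import (
    aggregate_refusal,
    classify_trial_outcome,
    fit_cost_family,
    fit_reward_size_family,
    fit_rt_relation_family,
    sucrose_preference_index,
)
from occmot.config import BehaviorSimConfig
from occmot.simulate import gen_reward_size_sessions

from conftest import make_refusal_cells


# ------------------------------------------------------------- classification


@pytest.mark.parametrize(
    "release_ms, go_shown, expected",
    [
        (500.0, True, "correct"),
        (-50.0, True, "early"),
        (1200.0, True, "late"),
        (200.0, True, "early"),  # boundary: within 200 ms is an error
        (200.001, True, "correct"),
        (1000.0, True, "correct"),  # boundary: 1,000 ms still in window
        (np.nan, True, "late"),
        (None, True, "late"),
        (350.0, False, "early"),  # released before the go signal appeared
    ],
)
def test_release_classification_window(release_ms, go_shown, expected):
    assert classify_trial_outcome(release_ms, go_shown) == expected


@settings(derandomize=True, max_examples=100)
@given(release=st.floats(-2000, 5000, allow_nan=False))
def test_classification_is_total_and_consistent(release):
    outcome = classify_trial_outcome(release)
    assert outcome in {"early", "correct", "late"}
    assert (outcome == "correct") == (200.0 < release <= 1000.0)


# --------------------------------------------------------------- aggregation


def trials_frame(outcomes, level=1, session="s0", condition="CON"):
    return pd.DataFrame(
        {
            "monkey": "M1",
            "session": session,
            "condition": condition,
            "task": "reward_size",
            "trial_type": "n/a",
            "level": level,
            "remaining_cu": np.nan,
            "reward_drops": level,
            "outcome": outcomes,
            "release_ms": [500.0 if o == "correct" else np.nan for o in outcomes],
            "rt_ms": [500.0 if o == "correct" else np.nan for o in outcomes],
            "delay_s": np.nan,
        }
    )


def test_session_opening_refusals_excluded_until_first_success():
    df = trials_frame(["early", "late", "correct", "early", "correct"])
    cells = aggregate_refusal(df)
    assert cells["n_presented"].sum() == 3
    assert cells["n_refused"].sum() == 1
    without = aggregate_refusal(df, drop_before_first_success=False)
    assert without["n_presented"].sum() == 5


def test_all_correct_input_gives_zero_rates():
    cells = aggregate_refusal(trials_frame(["correct"] * 10))
    assert (cells["refusal_rate"] == 0.0).all()
    assert cells["mean_rt_ms"].notna().all()


def test_refusal_rate_is_count_ratio():
    outcomes = ["correct"] + ["early"] * 2 + ["late"] + ["correct"] * 6
    cells = aggregate_refusal(trials_frame(outcomes))
    assert cells.loc[0, "n_presented"] == 10
    assert cells.loc[0, "refusal_rate"] == pytest.approx(0.3)


def test_aggregation_conserves_counts():
    cfg = BehaviorSimConfig(
        task="reward_size", conditions=["CON", "MO"],
        a={"CON": 8.0, "MO": 4.0}, e={"CON": 0.0, "MO": 0.05},
        sessions=3, trials_per_cell=50, seed=21,
    )
    trials = gen_reward_size_sessions(cfg)
    cells = aggregate_refusal(trials, pool_early_late=False)
    assert (cells["n_early"] + cells["n_late"] == cells["n_refused"]).all()
    corrects = cells["n_presented"] - cells["n_refused"]
    assert (corrects >= 0).all()
    assert cells["n_presented"].sum() <= len(trials)


def test_unseen_cells_are_absent_not_zero():
    cells = aggregate_refusal(trials_frame(["correct"] * 4, level=8))
    assert set(cells["level"]) == {8}


# ------------------------------------------------------- reward-size family


def exact_inverse_cells(a_by_cond, e_by_cond=None, n=10_000):
    e_by_cond = e_by_cond or {c: 0.0 for c in a_by_cond}
    rows = []
    for cond, a in a_by_cond.items():
        for r in (1, 2, 4, 8):
            rate = min(1.0, 1.0 / (a * r) + e_by_cond[cond])
            rows.append((cond, "n/a", r, rate, n))
    return make_refusal_cells(rows)


def test_noiseless_inverse_rates_recover_a_exactly():
    cells = exact_inverse_cells({"CON": 5.0})
    with pytest.warns(UserWarning, match="single condition"):
        fit = fit_reward_size_family(cells)
    assert fit.fits[1].params["a"]["CON"] == pytest.approx(5.0, abs=1e-3)


def test_mle_recovers_generating_incentive_impact():
    cfg = BehaviorSimConfig(
        task="reward_size", conditions=["RAC"], a={"RAC": 5.2}, e={"RAC": 0.0},
        sessions=1, trials_per_cell=2000, seed=12345,
    )
    cells = aggregate_refusal(gen_reward_size_sessions(cfg), drop_before_first_success=False)
    with pytest.warns(UserWarning, match="single condition"):
        fit = fit_reward_size_family(cells, reference_condition="RAC")
    assert fit.fits[1].params["a"]["RAC"] == pytest.approx(5.2, abs=0.2)


def test_mle_error_shrinks_with_sample_size():
    errors = {}
    for n in (200, 2000, 20000):
        errs = []
        for seed in range(5):
            cfg = BehaviorSimConfig(
                task="reward_size", conditions=["C"], a={"C": 5.2}, e={"C": 0.0},
                sessions=1, trials_per_cell=n, seed=100 + seed,
            )
            cells = aggregate_refusal(
                gen_reward_size_sessions(cfg), drop_before_first_success=False
            )
            with pytest.warns(UserWarning, match="single condition"):
                fit = fit_reward_size_family(cells, reference_condition="C")
            errs.append(abs(fit.fits[1].params["a"]["C"] - 5.2))
        errors[n] = np.mean(errs)
    assert errors[20000] < errors[2000] < errors[200]


def test_family_structures_and_normalization():
    cells = exact_inverse_cells({"CON": 8.0, "MO": 5.0, "HO": 4.0})
    fit = fit_reward_size_family(cells)
    assert set(fit.fits) == {1, 2, 3, 4}
    assert fit.normalized_a["CON"] == pytest.approx(1.0)
    table = fit.comparison_table()
    assert len(table) == 4
    assert table["delta_bic"].min() == 0.0
    # fitted refusal rate strictly decreasing in reward size for a > 0, e >= 0
    a = fit.selected.params["a"]["MO"]
    e = fit.selected.params["e"]["MO"]
    r = np.array([1.0, 2.0, 4.0, 8.0])
    assert np.all(np.diff(1.0 / (a * r) + e) < 0)


def test_nested_loglik_never_exceeds_full_model():
    rng = np.random.default_rng(77)
    for _ in range(5):
        rows = []
        for cond, a, e in (("CON", 8.0, 0.02), ("MO", 5.0, 0.1), ("HO", 3.5, 0.2)):
            for r in (1, 2, 4, 8):
                p = min(1.0, 1.0 / (a * r) + e)
                k = rng.binomial(500, p)
                rows.append((cond, "n/a", r, k / 500, 500))
        fit = fit_reward_size_family(make_refusal_cells(rows))
        for mid in (1, 2, 3):
            assert fit.fits[4].loglik >= fit.fits[mid].loglik - 1e-8


def test_gaussian_likelihood_counts_cells_not_presentations():
    cells = exact_inverse_cells({"CON": 8.0, "HO": 4.0})
    fit = fit_reward_size_family(cells, likelihood="gaussian")
    assert fit.fits[1].n_obs == len(cells)
    assert fit.fits[1].n_params == 2 + 1  # a per condition + residual SD


# --------------------------------------------------------------- cost family


def linear_cost_cells(k_w, k_d, e0, conds=("CON",), monkeys=("M1",), noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for m in monkeys:
        for c in conds:
            for trial_type, k in (("work", k_w[c]), ("delay", k_d[c])):
                for cu in (0, 1, 2):
                    rate = k * cu + e0[c] + (rng.normal(0, noise) if noise else 0.0)
                    rows.append(
                        {
                            "monkey": m, "session": f"{c}-s0", "condition": c,
                            "task": "work_delay", "trial_type": trial_type,
                            "level": cu, "n_presented": 500,
                            "n_refused": int(round(max(rate, 0) * 500)),
                            "refusal_rate": rate, "mean_rt_ms": np.nan,
                        }
                    )
    return pd.DataFrame(rows)


def test_cost_family_exact_recovery_from_noiseless_rates():
    cells = linear_cost_cells({"CON": 0.15}, {"CON": 0.10}, {"CON": 0.05})
    fit = fit_cost_family(cells)
    row = fit.params.iloc[0]
    assert row["k_w"] == pytest.approx(0.15, abs=1e-12)
    assert row["k_d"] == pytest.approx(0.10, abs=1e-12)
    assert row["e0"] == pytest.approx(0.05, abs=1e-12)


def test_cost_family_zero_slope_returns_mean_rate():
    cells = linear_cost_cells({"CON": 0.0}, {"CON": 0.0}, {"CON": 0.12})
    fit = fit_cost_family(cells)
    row = fit.params.iloc[0]
    assert row["k_w"] == pytest.approx(0.0, abs=1e-12)
    assert row["k_d"] == pytest.approx(0.0, abs=1e-12)
    assert row["e0"] == pytest.approx(0.12, abs=1e-12)


def test_cost_family_exposes_single_intercept_per_condition():
    """One E0 spans both trial types within each (monkey, condition) unit."""
    cells = linear_cost_cells(
        {"CON": 0.1, "HO": 0.3}, {"CON": 0.1, "HO": 0.2}, {"CON": 0.05, "HO": 0.1},
        conds=("CON", "HO"), noise=0.02, seed=4,
    )
    fit = fit_cost_family(cells)
    assert list(fit.params.columns[:5]) == ["monkey", "condition", "k_w", "k_d", "e0"]
    assert len(fit.params) == 2  # one row (one E0) per monkey x condition
    assert len(fit.comparison_table()) == 4


def test_cost_family_requires_both_trial_types():
    cells = linear_cost_cells({"CON": 0.1}, {"CON": 0.1}, {"CON": 0.05})
    with pytest.raises(ValueError, match="work and delay"):
        fit_cost_family(cells[cells["trial_type"] == "work"])


# ------------------------------------------------------------ RT relation


def rt_cells(slopes_by_cond, intercept=350.0, noise=0.0, monkeys=("M1", "M2"), seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for m in monkeys:
        for cond, slope in slopes_by_cond.items():
            for s in range(6):
                for r in (1, 2, 4, 8):
                    e_rate = float(rng.uniform(0.02, 0.6))
                    rt = intercept + slope * e_rate + (rng.normal(0, noise) if noise else 0.0)
                    rows.append((cond, "n/a", r, e_rate, 200, rt))
    cells = make_refusal_cells(rows)
    cells["monkey"] = np.repeat([m for m in monkeys for _ in slopes_by_cond for _ in range(24)], 1)
    return cells


def test_collinear_rt_data_recovers_line_and_simplest_structure():
    cells = rt_cells({"CON": 300.0, "MO": 300.0})
    fit = fit_rt_relation_family(cells)
    assert fit.selected_structure == "none"
    assert fit.slope_ms == pytest.approx(300.0, abs=1e-8)
    assert fit.intercept_ms == pytest.approx(350.0, abs=1e-8)
    assert fit.group_coefficients is None


def test_rt_coefficients_match_normal_equations_oracle():
    cells = rt_cells({"CON": 280.0}, noise=25.0, seed=9)
    fit = fit_rt_relation_family(cells)
    x = cells["refusal_rate"].to_numpy()
    y = cells["mean_rt_ms"].to_numpy()
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    assert fit.intercept_ms == pytest.approx(beta[0], abs=1e-8)
    assert fit.slope_ms == pytest.approx(beta[1], abs=1e-8)


def test_rt_relation_rejects_tiny_inputs():
    cells = rt_cells({"CON": 300.0}).head(2)
    with pytest.raises(ValueError, match=">= 3 cells"):
        fit_rt_relation_family(cells)


# ---------------------------------------------------------------- sucrose


@pytest.mark.parametrize(
    "sw, tw, expected", [(150.0, 150.0, 0.0), (300.0, 0.0, 1.0), (300.0, 100.0, 0.5)]
)
def test_sucrose_preference_values(sw, tw, expected):
    assert sucrose_preference_index(sw, tw) == pytest.approx(expected)


def test_sucrose_preference_undefined_for_zero_intake():
    with pytest.raises(ValueError):
        sucrose_preference_index(0.0, 0.0)


@settings(derandomize=True, max_examples=100)
@given(sw=st.floats(0, 1e4), tw=st.floats(0, 1e4))
def test_sucrose_preference_bounded(sw, tw):
    if sw + tw <= 0:
        return
    assert -1.0 <= sucrose_preference_index(sw, tw) <= 1.0
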