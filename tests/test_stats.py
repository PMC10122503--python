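"""Odds ratios, logistic fits vs likelihood oracles, importance measures."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from smokesurg.stats import (
    ContingencyTable2x2,
    Covariate,
    LogisticModelFit,
    ModelSpec,
    collapse_sparse_levels,
    default_model_spec,
    fit_logistic,
    odds_ratio_2x2,
    pseudo_r2,
    shapley_importance,
    unadjusted_or_table,
    wald_partial_chisq,
)

# ---------------------------------------------------------------------------
# 2x2 odds ratios


def test_equal_case_fractions_give_unit_odds_ratio():
    res = odds_ratio_2x2(ContingencyTable2x2(30, 70, 60, 140))
    assert res.odds_ratio == pytest.approx(1.0)


def test_zero_cell_raises_with_guidance():
    with pytest.raises(ValueError, match="zero cell"):
        odds_ratio_2x2(ContingencyTable2x2(0, 10, 5, 5))


def test_swapping_groups_inverts_or_and_ci():
    t = ContingencyTable2x2(17, 83, 9, 191)
    fwd = odds_ratio_2x2(t)
    rev = odds_ratio_2x2(ContingencyTable2x2(9, 191, 17, 83))
    assert rev.odds_ratio == pytest.approx(1 / fwd.odds_ratio, rel=1e-12)
    assert rev.ci_low == pytest.approx(1 / fwd.ci_high, rel=1e-12)
    assert rev.ci_high == pytest.approx(1 / fwd.ci_low, rel=1e-12)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        ContingencyTable2x2(-1, 5, 5, 5)


# ---------------------------------------------------------------------------
# logistic fits


def _rows_from_2x2(table):
    rows = (
        [("ex", 1)] * table.cases_exposed
        + [("ex", 0)] * table.noncases_exposed
        + [("never", 1)] * table.cases_ref
        + [("never", 0)] * table.noncases_ref
    )
    frame = pd.DataFrame(rows, columns=["smoking_status", "y"])
    return frame, frame["y"].to_numpy()


def test_saturated_logistic_equals_2x2_odds_ratio_exactly():
    table = ContingencyTable2x2(30, 70, 20, 80)
    frame, y = _rows_from_2x2(table)
    fit = fit_logistic(frame, y, default_model_spec(adjusted=False))
    direct = odds_ratio_2x2(table)
    ors = fit.odds_ratios().loc["smoking_status[ex]"]
    assert ors["odds_ratio"] == pytest.approx(direct.odds_ratio, abs=1e-10)
    assert ors["ci_low"] == pytest.approx(direct.ci_low, abs=1e-10)
    assert ors["ci_high"] == pytest.approx(direct.ci_high, abs=1e-10)


def _toy_frame():
    return pd.DataFrame(
        {
            "age_at_surgery": [20, 30, 40, 50, 60, 70, 45, 55],
            "sex": ["male", "female"] * 4,
        }
    ), np.array([0, 0, 1, 1, 0, 0, 1, 1])


def _toy_spec():
    return ModelSpec(
        outcome="y",
        covariates=(
            Covariate("age_at_surgery", "continuous"),
            Covariate("sex", "categorical", "female"),
        ),
    )


def _nll(beta, X, y):
    eta = X @ beta
    return -np.sum(y * eta - np.log1p(np.exp(eta)))


def test_irls_matches_direct_likelihood_maximization():
    frame, y = _toy_frame()
    fit = fit_logistic(frame, y, _toy_spec())
    X = fit.design.to_numpy()
    oracle = minimize(
        _nll, np.zeros(X.shape[1]), args=(X, y), method="BFGS",
        options={"gtol": 1e-10},
    )
    assert np.allclose(fit.params.to_numpy(), oracle.x, atol=1e-4)
    assert fit.llf == pytest.approx(-_nll(oracle.x, X, y), abs=1e-6)


def test_missing_covariates_dropped_and_counted():
    frame, y = _toy_frame()
    frame.loc[0, "age_at_surgery"] = np.nan
    fit = fit_logistic(frame, y, _toy_spec())
    assert fit.n == 7
    assert fit.n_dropped_missing == 1


def test_perfect_separation_detected():
    frame = pd.DataFrame(
        {"age_at_surgery": [1, 2, 3, 4, 10, 11, 12, 13], "sex": ["male"] * 8}
    )
    y = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    spec = ModelSpec(
        outcome="y", covariates=(Covariate("age_at_surgery", "continuous"),)
    )
    from smokesurg.stats import SeparationError

    with pytest.raises((SeparationError, RuntimeError)):
        fit_logistic(frame, y, spec)


# ---------------------------------------------------------------------------
# Wald partial chi-squared


def _manual_fit(params, cov, groups):
    names = list(params)
    return LogisticModelFit(
        params=pd.Series(params),
        cov=pd.DataFrame(cov, index=names, columns=names),
        llf=-10.0, llnull=-20.0, n=100, converged=True,
        groups=groups, spec=None,
    )


def test_single_df_wald_is_squared_z():
    fit = _manual_fit(
        {"const": 0.1, "x": 0.8}, [[0.01, 0.0], [0.0, 0.04]], {"x": ["x"]}
    )
    table = wald_partial_chisq(fit)
    assert table.loc["x", "chisq"] == pytest.approx((0.8 / 0.2) ** 2)
    assert table.loc["x", "share_pct"] == pytest.approx(100.0)


def test_zero_coefficient_zero_statistic():
    fit = _manual_fit(
        {"const": 0.1, "x": 0.0, "z": 1.0},
        np.diag([0.01, 0.04, 0.25]),
        {"x": ["x"], "z": ["z"]},
    )
    table = wald_partial_chisq(fit)
    assert table.loc["x", "chisq"] == 0.0


def test_two_df_block_matches_hand_computed_quadratic_form():
    # b = [1, 2], Vb = [[4, 1], [1, 2]]  =>  b' Vb^-1 b = 2.0
    fit = _manual_fit(
        {"const": 0.0, "a1": 1.0, "a2": 2.0},
        [[1.0, 0, 0], [0, 4.0, 1.0], [0, 1.0, 2.0]],
        {"a": ["a1", "a2"]},
    )
    table = wald_partial_chisq(fit)
    assert table.loc["a", "chisq"] == pytest.approx(2.0)
    assert table.loc["a", "df"] == 2


def test_wald_shares_invariant_to_covariate_order():
    frame, y = _toy_frame()
    spec_a = _toy_spec()
    spec_b = ModelSpec(outcome="y", covariates=tuple(reversed(spec_a.covariates)))
    shares_a = wald_partial_chisq(fit_logistic(frame, y, spec_a))["share_pct"]
    shares_b = wald_partial_chisq(fit_logistic(frame, y, spec_b))["share_pct"]
    assert shares_a.sort_index().round(9).equals(shares_b.sort_index().round(9))
    assert shares_a.sum() == pytest.approx(100.0, abs=0.1)


# ---------------------------------------------------------------------------
# Shapley importance


def test_shapley_efficiency_row_by_row():
    frame, y = _toy_frame()
    fit = fit_logistic(frame, y, _toy_spec())
    from smokesurg.stats import shapley_rowwise

    G, variables = shapley_rowwise(fit)
    eta = fit.design.to_numpy() @ fit.params.to_numpy()
    assert np.allclose(G.sum(axis=1), eta - eta.mean(), atol=1e-9)


def test_single_balanced_binary_covariate_mean_abs_half():
    X = pd.DataFrame({"const": 1.0, "x": [0.0] * 50 + [1.0] * 50})
    fit = _manual_fit(
        {"const": 0.0, "x": 1.0}, np.eye(2) * 0.01, {"x": ["x"]}
    )
    fit.design = X
    shap = shapley_importance(fit)
    assert shap["x"] == pytest.approx(0.5)


def _three_var_fit():
    rng = np.random.default_rng(4)
    X = pd.DataFrame(
        {
            "const": 1.0,
            "x1": rng.normal(size=40),
            "x2": rng.normal(size=40),
            "x3": rng.integers(0, 2, size=40).astype(float),
        }
    )
    fit = _manual_fit(
        {"const": 0.2, "x1": 0.5, "x2": -1.2, "x3": 0.7},
        np.eye(4) * 0.01,
        {"x1": ["x1"], "x2": ["x2"], "x3": ["x3"]},
    )
    fit.design = X
    return fit


def test_exact_linear_equals_permutation_enumeration():
    fit = _three_var_fit()
    X = fit.design
    variables = ["x1", "x2", "x3"]
    centered = {
        v: (X[v] - X[v].mean()).to_numpy() * fit.params[v] for v in variables
    }
    # brute force over all 3! orderings of additive coalition values
    acc = {v: np.zeros(len(X)) for v in variables}
    for order in itertools.permutations(variables):
        running = np.zeros(len(X))
        for v in order:
            with_v = running + centered[v]
            acc[v] += with_v - running
            running = with_v
    brute = pd.Series(
        {v: np.abs(acc[v] / 6.0).mean() for v in variables}
    )
    exact = shapley_importance(fit, mode="exact_linear")
    assert np.allclose(exact[variables], brute[variables], atol=1e-12)


def test_montecarlo_sampler_converges_to_exact():
    fit = _three_var_fit()
    exact = shapley_importance(fit, mode="exact_linear")
    mc = shapley_importance(fit, mode="montecarlo", n_permutations=60, seed=1)
    assert np.allclose(mc, exact, atol=1e-9)  # additive model: no sampling error
    with pytest.raises(ValueError, match="10 permutations"):
        shapley_importance(fit, mode="montecarlo", n_permutations=5)


# ---------------------------------------------------------------------------
# pseudo-R2


def test_null_model_has_zero_pseudo_r2():
    frame = pd.DataFrame(index=range(10))
    y = np.array([0, 1] * 5)
    spec = ModelSpec(outcome="y", covariates=())  # intercept-only
    fit = fit_logistic(frame, y, spec)
    r2 = pseudo_r2(fit)
    assert r2.mcfadden == pytest.approx(0.0, abs=1e-10)
    assert r2.nagelkerke == pytest.approx(0.0, abs=1e-10)


def test_pseudo_r2_matches_direct_formula_on_toy_fit():
    frame, y = _toy_frame()
    fit = fit_logistic(frame, y, _toy_spec())
    X = fit.design.to_numpy()
    ll = -_nll(fit.params.to_numpy(), X, y)
    p0 = y.mean()
    ll0 = len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
    r2 = pseudo_r2(fit)
    assert r2.mcfadden == pytest.approx(1 - ll / ll0, abs=1e-8)
    cs = 1 - np.exp(2 * (ll0 - ll) / len(y))
    assert r2.nagelkerke == pytest.approx(cs / (1 - np.exp(2 * ll0 / len(y))),
                                          abs=1e-8)
    assert r2.nagelkerke >= r2.cox_snell


def test_strong_predictor_approaches_one():
    rng = np.random.default_rng(6)
    x = rng.normal(size=400)
    y = (expit(8 * x) > rng.random(400)).astype(float)
    frame = pd.DataFrame({"x": x})
    spec = ModelSpec(outcome="y", covariates=(Covariate("x", "continuous"),))
    fit = fit_logistic(frame, y, spec)
    r2 = pseudo_r2(fit)
    assert r2.mcfadden > 0.5
    assert r2.nagelkerke >= r2.cox_snell


# ---------------------------------------------------------------------------
# level collapsing and adjustment behaviour


def test_collapse_sparse_levels_merges_thin_top_bands():
    values = ["0"] * 200 + ["1"] * 100 + ["2"] * 40 + ["3"] * 4 + [">=5"] * 2
    y = [True, False] * 173
    merged = collapse_sparse_levels(
        values, y, ["0", "1", "2", "3", "4", ">=5"], min_count=20, min_events=5
    )
    # the thin 3 / >=5 bands fold downward into band 2
    assert set(merged) == {"0", "1", ">=2"}
    assert (merged[:200] == "0").all()  # reference untouched


def test_adjustment_recovers_conditional_effect_better_than_crude():
    from smokesurg.cohort import CohortConfig, generate_cohort
    from smokesurg.outcomes import default_definitions, flag_outcomes

    truth = np.log(1.09)
    crude_err, adj_err = [], []
    for seed in (31, 32, 33):
        tables = generate_cohort(CohortConfig(n_patients=10_000, seed=seed))
        overall_def, _ = default_definitions()
        flags = flag_outcomes(
            tables.surgeries, tables.diagnosis_events, tables.care_events,
            overall_def,
        )
        surg = tables.surgeries.merge(
            tables.patients[["patient_id", "sex", "true_status"]], on="patient_id"
        ).set_index("surgery_id")
        df = surg.assign(
            smoking_status=surg["true_status"],
            cci_band=surg["cci_band"].astype(str),
            asa_class=surg["asa_class"].astype(str),
            y=flags,
        ).reset_index()
        crude = unadjusted_or_table(df, df["y"].to_numpy()).loc["ex", "odds_ratio"]
        fit = fit_logistic(df, df["y"].to_numpy(), default_model_spec())
        adj = fit.params["smoking_status[ex]"]
        crude_err.append(abs(np.log(crude) - truth))
        adj_err.append(abs(adj - truth))
    assert all(a < c for a, c in zip(adj_err, crude_err))
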