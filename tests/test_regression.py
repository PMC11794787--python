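import numpy as np
import pandas as pd
import pytest

from faerspv.regression import (
    build_design,
    fit_logistic,
    multivariate_fit,
    results_frame,
    select_significant,
    two_stage,
    univariate_screen,
)
from faerspv.simulate import simulate_logistic


def test_irls_matches_statsmodels_on_random_designs():
    """Independent reference: statsmodels GLM/Binomial on 20 random fits."""
    import statsmodels.api as sm

    rng = np.random.default_rng(0)
    for rep in range(20):
        n = 200
        p = rng.integers(1, 4)
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p))])
        beta_true = rng.normal(scale=0.8, size=p + 1)
        y = (rng.random(n) < 1 / (1 + np.exp(-X @ beta_true))).astype(float)
        if y.sum() in (0, n):
            continue
        fit = fit_logistic(X, y)
        ref = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        assert np.max(np.abs(fit.beta - ref.params)) < 1e-6
        assert np.max(np.abs(fit.se - ref.bse)) < 1e-5


def test_fitted_probabilities_sum_to_outcome_count():
    X, y = simulate_logistic(1000, [0.7, -0.3], seed=5)
    fit = fit_logistic(X, y)
    mu = 1 / (1 + np.exp(-(X @ fit.beta)))
    assert mu.sum() == pytest.approx(y.sum(), rel=1e-8)


def test_separation_is_flagged_not_raised():
    x = np.array([0.0, 0, 0, 1, 1, 1])
    y = np.array([0.0, 0, 0, 1, 1, 1])
    X = np.column_stack([np.ones(6), x])
    fit = fit_logistic(X, y)
    assert fit.separation
    assert np.isfinite(fit.beta).all()


def test_build_design_fatal_restricts_and_drops_cv_class(fixture_analysis):
    cohort = fixture_analysis["cohort"].reports
    design_cvae, y_cvae = build_design(cohort, outcome="cvae")
    design_fatal, y_fatal = build_design(cohort, outcome="fatal_within_cvae")
    assert len(y_fatal) < len(y_cvae)
    assert "Cardiovascular system medications" not in design_fatal.columns
    assert y_fatal.sum() <= cohort["is_fatal"].sum()


def test_build_design_listwise_missing(fixture_analysis):
    cohort = fixture_analysis["cohort"].reports
    design, y = build_design(cohort, outcome="cvae")
    n_complete = int((cohort["sex"].isin(["M", "F"]) & cohort["age_years"].notna()).sum())
    assert len(design) == len(y) == n_complete


def test_constant_outcome_refused():
    df = pd.DataFrame(
        {
            "age_years": [5.0, 10.0],
            "sex": ["M", "F"],
            "is_cvae": [True, True],
            "is_fatal": [False, False],
            "atc_N": [True, False],
        }
    )
    with pytest.raises(ValueError):
        build_design(df, outcome="cvae")


def test_constant_covariate_skipped():
    rng = np.random.default_rng(1)
    design = pd.DataFrame({"flat": np.ones(50), "x": rng.random(50)})
    y = (rng.random(50) < 0.4).astype(float)
    results = univariate_screen(design, y)
    assert [r.variable for r in results] == ["x"]


def test_strong_effect_screens_in_at_cohort_scale():
    """An OR of 4.6 at n=568 passes the univariate p<0.05 screen."""
    X, y = simulate_logistic(568, [np.log(4.6)], seed=3, prevalence=0.25)
    design = pd.DataFrame({"drug": X[:, 1]})
    results = univariate_screen(design, y)
    assert select_significant(results) == ["drug"]


def test_or_and_ci_internally_consistent(fixture_analysis):
    cohort = fixture_analysis["cohort"].reports
    design, y = build_design(cohort, outcome="cvae")
    uni, multi = two_stage(design, y)
    for r in uni + multi:
        assert r.or_ == pytest.approx(np.exp(r.beta))
        assert r.ci_low == pytest.approx(np.exp(r.beta - 1.96 * r.se))
        assert r.ci_high == pytest.approx(np.exp(r.beta + 1.96 * r.se))
        if np.isfinite(r.wald_chi2):
            assert r.wald_chi2 == pytest.approx((r.beta / r.se) ** 2)


def test_age_t_statistic_reported_for_fatal_analysis(fixture_analysis):
    cohort = fixture_analysis["cohort"].reports
    design, y = build_design(cohort, outcome="fatal_within_cvae")
    uni = univariate_screen(design, y, age_t_test=True)
    age_row = next(r for r in uni if r.variable == "age")
    assert np.isfinite(age_row.t_stat) and np.isfinite(age_row.t_p)


def test_multivariate_requires_selection():
    with pytest.raises(ValueError):
        multivariate_fit(pd.DataFrame({"x": [0.0, 1.0]}), np.array([0.0, 1.0]), [])


def test_null_generator_ors_center_on_one():
    ors = []
    for seed in range(40):
        X, y = simulate_logistic(2000, [0.0], seed=seed)
        fit = fit_logistic(X, y)
        ors.append(np.exp(fit.beta[1]))
    assert np.median(ors) == pytest.approx(1.0, abs=0.1)
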