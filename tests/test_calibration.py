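"""Pearson screening, OLS fitting, and end-to-end recalibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from haigisl import (
    DegenerateSeriesError,
    PEModel,
    correlate_predictors,
    default_params_training,
    fit_pe_regression,
    generate_cohort,
    pearson,
    prediction_errors,
    recalibrate,
    run_recovery,
)


def normal_equations_fit(x, y):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    X = np.column_stack([np.asarray(x, float), np.ones(len(x))])
    slope, intercept = np.linalg.solve(X.T @ X, X.T @ np.asarray(y, float))
    return slope, intercept


def test_pearson_perfect_correlations():
    x = [1.0, 2.0, 5.0, 7.0]
    assert pearson(x, x)[0] == pytest.approx(1.0)
    assert pearson(x, [-v for v in x])[0] == pytest.approx(-1.0)


def test_pearson_worked_value():
    r, p = pearson([1, 2, 3, 4], [2, 2, 4, 4])
    assert r == pytest.approx(0.89443, abs=1e-5)
    assert 0 < p < 1


def test_pearson_degenerate_inputs():
    with pytest.raises(DegenerateSeriesError):
        pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    with pytest.raises(DegenerateSeriesError):
        pearson([1.0, 2.0], [1.0, 2.0])


def test_fit_exact_line():
    sa = np.array([1.0, 2.0, 3.5, 5.0])
    fit = fit_pe_regression(sa, 2.0 * sa - 1.0)
    assert fit.slope == pytest.approx(2.0, abs=1e-12)
    assert fit.intercept == pytest.approx(-1.0, abs=1e-12)
    assert fit.pearson_r == pytest.approx(1.0)


def test_fit_worked_value():
    fit = fit_pe_regression([1, 2, 3, 4], [2, 2, 4, 4])
    assert fit.slope == pytest.approx(0.8, abs=1e-12)
    assert fit.intercept == pytest.approx(1.0, abs=1e-12)
    assert fit.n == 4


@settings(max_examples=200, deadline=None)
@given(
    arrays(np.float64, st.integers(3, 10), elements=st.floats(-50, 50)),
    st.data(),
)
def test_fit_matches_normal_equations_oracle(x, data):
    if np.ptp(x) < 1e-6:
        x = x + np.linspace(0, 1, len(x))  # ensure a usable predictor
    y = np.asarray(
        data.draw(arrays(np.float64, len(x), elements=st.floats(-50, 50)))
    )
    fit = fit_pe_regression(x, y)
    slope, intercept = normal_equations_fit(x, y)
    assert abs(fit.slope - slope) < 1e-9
    assert abs(fit.intercept - intercept) < 1e-9
    # fitted line passes through the mean point
    assert fit.slope * np.mean(x) + fit.intercept == pytest.approx(
        np.mean(y), abs=1e-9
    )


def test_fit_affine_equivariance():
    rng = np.random.default_rng(7)
    sa = rng.normal(3.7, 0.9, 40)
    pe = 0.6 * sa - 2.0 + rng.normal(0, 0.4, 40)
    base = fit_pe_regression(sa, pe)
    scaled = fit_pe_regression(sa, 2.5 * pe + 1.0)
    assert scaled.slope == pytest.approx(2.5 * base.slope)
    assert scaled.intercept == pytest.approx(2.5 * base.intercept + 1.0)
    assert scaled.pearson_r == pytest.approx(base.pearson_r)


def test_correlate_predictors_ranks_duplicated_pe_first(default_cohort):
    pe = prediction_errors(default_cohort, "haigis-l")
    table = correlate_predictors(default_cohort, pe)
    assert set(table.columns) >= {"predictor", "r", "p", "degenerate"}
    assert table.iloc[0]["predictor"] == "SA8"  # PE was built from SA8
    assert table.iloc[0]["r"] > 0.5


def test_correlate_predictors_flags_degenerate_not_fatal(default_cohort):
    import dataclasses

    flat = [
        dataclasses.replace(c, biometry=dataclasses.replace(c.biometry, q6=1.0))
        for c in default_cohort
    ]
    pe = prediction_errors(flat, "haigis-l")
    table = correlate_predictors(flat, pe, predictors=["SA8", "Q6"])
    sa8_row = table[table.predictor == "SA8"].iloc[0]
    q6_row = table[table.predictor == "Q6"].iloc[0]
    assert not sa8_row.degenerate
    assert q6_row.degenerate and np.isnan(q6_row.r)
    assert table.iloc[-1]["predictor"] == "Q6"  # degenerate rows sort last


def test_recalibrate_noiseless_recovery():
    import dataclasses

    truth = PEModel(slope=0.9, intercept=-3.1)
    params = dataclasses.replace(
        default_params_training(n=40, seed=5), pe_model=truth, residual_sd=0.0
    )
    model, fit = recalibrate(generate_cohort(params))
    assert model.slope == pytest.approx(truth.slope, abs=1e-9)
    assert model.intercept == pytest.approx(truth.intercept, abs=1e-9)
    assert fit.pearson_r == pytest.approx(1.0, abs=1e-9)


def test_recalibrate_rejects_tiny_cohort():
    cases = generate_cohort(default_params_training(n=2, seed=3))
    with pytest.raises(DegenerateSeriesError):
        recalibrate(cases)


def test_parameter_recovery_over_replicates():
    """Mean recovered coefficients over 200 seeded n=80 cohorts stay close
    to the generative truth."""
    res = run_recovery(n_replicates=200, n=80, seed=2024)
    assert abs(res["slope"].mean() - 0.583) < 0.02
    assert abs(res["intercept"].mean() - (-2.3488)) < 0.08
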