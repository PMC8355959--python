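"""Evaluation battery: fit statistics, deviations, Williams plot, relevancy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teacelm.datasets import Dataset, GeneratorConfig, generate_dataset
from teacelm.diagnostics import (fit_metrics, relative_deviation,
                                 relevancy_factors, williams)


def test_perfect_fit_metrics():
    y = np.array([10.0, 20.0, 30.0])
    m = fit_metrics(y, y, "train")
    assert m.r2 == 1.0 and m.mse == 0.0 and m.rmse == 0.0
    assert m.mre_percent == 0.0 and m.std == 0.0 and m.n == 3


def test_mean_predictor_has_zero_r2():
    y = np.array([1.0, 2.0, 3.0, 4.0])
    m = fit_metrics(y, np.full(4, y.mean()))
    assert m.r2 == pytest.approx(0.0)


def test_hand_computed_metrics():
    y = np.array([10.0, 20.0, 30.0])
    yhat = np.array([11.0, 19.0, 33.0])
    m = fit_metrics(y, yhat)
    assert m.mse == pytest.approx(11.0 / 3.0)
    assert m.rmse == pytest.approx(np.sqrt(11.0 / 3.0))
    assert m.mre_percent == pytest.approx(100.0 * (0.1 + 0.05 + 0.1) / 3.0)
    # std of absolute errors (1, 1, 3), ddof=1
    assert m.std == pytest.approx(np.std([1.0, 1.0, 3.0], ddof=1))


def test_r2_agrees_with_sklearn_cross_check(rng):
    from sklearn.metrics import mean_squared_error, r2_score
    y = rng.uniform(10, 90, 50)
    yhat = y + rng.normal(0, 5, 50)
    m = fit_metrics(y, yhat)
    assert m.r2 == pytest.approx(r2_score(y, yhat), abs=1e-12)
    assert m.mse == pytest.approx(mean_squared_error(y, yhat), abs=1e-12)


def test_rmse_squared_equals_mse_always(rng):
    for _ in range(20):
        y = rng.uniform(1, 100, 30)
        m = fit_metrics(y, y + rng.normal(0, 3, 30))
        assert m.rmse**2 == pytest.approx(m.mse, abs=1e-12)
        assert m.std < m.rmse  # std(|e|)^2 = rmse^2 - mae^2


def test_metrics_reject_degenerate_inputs():
    with pytest.raises(ValueError, match="zero"):
        fit_metrics(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
    with pytest.raises(ValueError, match="constant"):
        fit_metrics(np.array([2.0, 2.0]), np.array([1.0, 3.0]))
    with pytest.raises(ValueError, match="equal-length"):
        fit_metrics(np.array([1.0]), np.array([1.0, 2.0]))


def test_relative_deviation_values_and_identity_with_mre(rng):
    assert relative_deviation(np.array([100.0]), np.array([95.0]))[0] == 5.0
    y = rng.uniform(10, 90, 40)
    yhat = y + rng.normal(0, 4, 40)
    devs = relative_deviation(y, yhat)
    assert devs.mean() == pytest.approx(fit_metrics(y, yhat).mre_percent)
    np.testing.assert_array_equal(devs >= 0, True)


def test_williams_warning_leverage_formula_and_trace(default_dataset):
    """h* = 3(p+1)/n and the leverages of a full-rank design sum to p+1."""
    from teacelm.preprocessing import fit_normalizer, normalize
    norm = normalize(default_dataset, fit_normalizer(default_dataset))
    residuals = np.zeros(172) + 0.1
    ad = williams(norm.features, norm.features, residuals, rmse=1.0)
    assert ad.warning_leverage == pytest.approx(3 * 7 / 172)
    assert ad.leverages.sum() == pytest.approx(7.0)
    assert (ad.leverages >= 0).all() and (ad.leverages <= 1).all()


def test_williams_flags_follow_thresholds(rng):
    X = rng.uniform(-1, 1, size=(40, 2))
    X_all = np.vstack([X, [[50.0, 50.0]]])  # far outside: huge leverage
    residuals = np.zeros(41)
    residuals[0] = 10.0  # standardized residual 10 with rmse 1
    ad = williams(X, X_all, residuals, rmse=1.0)
    assert ad.flags[0] == "residual_outlier"
    assert ad.flags[40] == "high_leverage"
    assert ad.counts()["in_domain"] == 39
    assert ad.suspicious_rows() == [0, 40]


def test_duplicated_rows_share_leverage(rng):
    X = rng.uniform(-1, 1, size=(20, 3))
    X[5] = X[11]
    ad = williams(X, X, np.zeros(20), rmse=1.0)
    assert ad.leverages[5] == pytest.approx(ad.leverages[11], abs=1e-12)


def test_rank_deficient_design_is_an_error(rng):
    X = rng.uniform(-1, 1, size=(15, 3))
    X[:, 2] = 2 * X[:, 0] - X[:, 1]  # exact collinearity
    with pytest.raises(np.linalg.LinAlgError, match="rank"):
        williams(X, X, np.zeros(15), rmse=1.0)


def test_leverage_invariant_under_affine_feature_rescaling(rng):
    """Min-max rescaling of a column does not move hat values once an
    intercept is in the design."""
    X = rng.uniform(-1, 1, size=(25, 4))
    X2 = X.copy()
    X2[:, 1] = 3.0 * X2[:, 1] + 10.0
    a = williams(X, X, np.zeros(25), rmse=1.0)
    b = williams(X2, X2, np.zeros(25), rmse=1.0)
    np.testing.assert_allclose(a.leverages, b.leverages, atol=1e-10)


def test_relevancy_trivial_extremes():
    y = np.linspace(1, 9, 9)
    data = Dataset(np.column_stack([y, -y]), y, feature_names=("a", "b"))
    sens = relevancy_factors(data)
    assert sens.relevancy["a"] == pytest.approx(1.0)
    assert sens.relevancy["b"] == pytest.approx(-1.0)
    assert sens.ranking_by_signed_effect() == ["a", "b"]


def test_relevancy_matches_textbook_pearson_oracle():
    x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
    y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
    expected = (np.mean(x * y) - x.mean() * y.mean()) / (np.std(x) * np.std(y))
    data = Dataset(x[:, None], y, feature_names=("x",))
    assert relevancy_factors(data).relevancy["x"] == pytest.approx(
        expected, abs=1e-12)


def test_relevancy_rejects_constant_columns():
    data = Dataset(np.ones((5, 1)), np.arange(5.0), feature_names=("c",))
    with pytest.raises(ValueError, match="c"):
        relevancy_factors(data)


def test_published_relevancy_factors_recovered_at_large_n(large_dataset):
    sens = relevancy_factors(large_dataset)
    assert sens.relevancy["GLS"] == pytest.approx(-0.85, abs=0.01)
    assert sens.relevancy["TTOT"] == pytest.approx(0.26, abs=0.01)
    assert sens.ranking_by_magnitude()[0] == "GLS"


@settings(deadline=None, derandomize=True, max_examples=20)
@given(seed=st.integers(0, 10_000),
       rho_gls=st.floats(-0.9, -0.2), rho_ttot=st.floats(0.2, 0.9))
def test_recovered_sign_matches_configured_sign(seed, rho_gls, rho_ttot):
    """At n = 1,000 the sign of every |rho| >= 0.2 correlation is recovered."""
    cfg = GeneratorConfig(
        n_samples=1_000, seed=seed,
        target_correlations={"TP": -0.4, "IP6": -0.3, "GLS": rho_gls,
                             "PROT": -0.35, "AA": -0.25, "TTOT": rho_ttot})
    sens = relevancy_factors(generate_dataset(cfg))
    for name, rho in cfg.target_correlations.items():
        assert np.sign(sens.relevancy[name]) == np.sign(rho)
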