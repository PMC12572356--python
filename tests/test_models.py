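"""Cartesian-coordinate phase regressors: SIMPLS, selection, elastic net."""

import numpy as np
import pandas as pd
import pytest

from circaphase import circular as c
from circaphase.exceptions import (
    AlignmentError,
    ConfigError,
    DegenerateDirectionError,
)
from circaphase.models import (
    ElasticNetPhaseRegressor,
    FixedPanelPhaseRegressor,
    PlsrPhaseRegressor,
    cartesian_predict,
    en_cv_lambda,
    model_from_dict,
    phase_to_targets,
    plsr_select,
    simpls,
)
from conftest import sinusoid_matrix


# ------------------------------------------------------------------ SIMPLS
def test_simpls_full_rank_reproduces_ols(rng):
    """With as many latent factors as the design rank, PLS regression
    coefficients coincide with ordinary least squares (independent oracle:
    lstsq on the augmented design)."""
    X = rng.normal(size=(40, 6))
    Y = rng.normal(size=(40, 2))
    res = simpls(X, Y, 6)
    B = np.linalg.lstsq(np.column_stack([np.ones(40), X]), Y, rcond=None)[0]
    assert np.allclose(res["coef"], B[1:], atol=1e-8)
    assert np.allclose(res["intercept"], B[0], atol=1e-8)


def test_simpls_one_component_weight_is_leading_singular_vector(rng):
    """The first SIMPLS weight maximizes covariance with the targets: it is
    the leading left singular vector of X0'Y0 (dense SVD oracle)."""
    X = rng.normal(size=(30, 8))
    Y = rng.normal(size=(30, 2))
    res = simpls(X, Y, 1)
    X0 = X - X.mean(0)
    Y0 = Y - Y.mean(0)
    u = np.linalg.svd(X0.T @ Y0)[0][:, 0]
    w = res["weights"][:, 0]
    w = w / np.linalg.norm(w)
    assert min(np.abs(w - u).max(), np.abs(w + u).max()) < 1e-8


def test_simpls_informative_feature_dominates_weights(rng):
    """The covariance-maximizing first weight vector loads most on the one
    feature correlated with the targets (nulls at comparable variance, as
    after z-scoring)."""
    theta = rng.uniform(0, 2 * np.pi, 50)
    X = np.column_stack([np.sqrt(2) * np.cos(theta),
                         rng.normal(0, 1.0, (50, 9))])
    res = simpls(X, phase_to_targets(theta), 1)
    rowsums = np.abs(res["weights"]).sum(axis=1)
    assert np.argmax(rowsums) == 0


def test_simpls_caps_components_with_warning(rng):
    X = rng.normal(size=(4, 10))
    Y = rng.normal(size=(4, 2))
    with pytest.warns(UserWarning, match="capped"):
        res = simpls(X, Y, 9)
    assert res["n_components"] <= 3
    capped = simpls(X, Y, res["n_components"])
    assert np.allclose(res["coef"], capped["coef"])


# --------------------------------------------------------------- selection
def test_plsr_select_ranking_ties_and_identity():
    W = np.array([[3.0], [1.0], [2.0]])
    assert plsr_select(W, ["a", "b", "c"], 2) == ["a", "c"]
    W_tied = np.array([[1.0], [1.0], [0.5]])
    assert plsr_select(W_tied, ["zed", "abc", "mid"], 1) == ["abc"]
    assert plsr_select(W, ["a", "b", "c"], 3) == ["a", "b", "c"]
    with pytest.raises(ConfigError):
        plsr_select(W, ["a", "b", "c"], 4)


# -------------------------------------------------------------------- PLSR
def test_plsr_noiseless_recovery_selects_signal(rng):
    X, theta = sinusoid_matrix(rng, n_samples=100, n_signal=10, n_null=40)
    m = PlsrPhaseRegressor(n_latent=5, n_predictors=10).fit(
        X.iloc[:70], theta[:70]
    )
    assert set(m.selected_features_) == {f"sig{i:03d}" for i in range(10)}
    pred = m.predict(X.iloc[70:])
    assert c.mae(pred, theta[70:]) * 15 < 1.0  # < 1 degree


def test_plsr_grid_size_selection(rng):
    X, theta = sinusoid_matrix(rng, n_samples=60, n_signal=30, n_null=170,
                               noise_sd=0.2)
    m = PlsrPhaseRegressor(n_latent=5, n_predictors=150).fit(X, theta)
    assert len(m.selected_features_) == 150


def test_plsr_refit_and_norefit_differ_on_collinear_design(rng):
    theta = rng.uniform(0, 2 * np.pi, 40)
    base = np.cos(theta)
    X = pd.DataFrame(
        np.column_stack(
            [base, base + rng.normal(0, 0.01, 40), np.sin(theta),
             rng.normal(size=(40, 2))]
        ),
        columns=list("abcde"),
    )
    refit = PlsrPhaseRegressor(n_latent=2, n_predictors=3, refit=True).fit(
        X, theta
    )
    sliced = PlsrPhaseRegressor(n_latent=2, n_predictors=3, refit=False).fit(
        X, theta
    )
    assert refit.selected_features_ == sliced.selected_features_
    assert not np.allclose(refit.coef_cos_, sliced.coef_cos_)


def test_plsr_rotation_equivariance(rng):
    X, theta = sinusoid_matrix(rng, n_samples=80, n_signal=8, n_null=0)
    phi = 1.2345
    m0 = PlsrPhaseRegressor(n_latent=4, n_predictors=8).fit(X, theta)
    m1 = PlsrPhaseRegressor(n_latent=4, n_predictors=8).fit(
        X, c.canonical(theta + phi)
    )
    d = c.signed_diff(m1.predict(X), m0.predict(X))
    assert np.allclose(c.signed_diff(d, phi), 0, atol=1e-6)


def test_prediction_invariant_to_feature_order(rng):
    X, theta = sinusoid_matrix(rng, n_samples=60, n_signal=6, n_null=10)
    m = PlsrPhaseRegressor(n_latent=3, n_predictors=6).fit(X, theta)
    shuffled = X[list(reversed(X.columns))]
    assert np.allclose(m.predict(X), m.predict(shuffled))


# ------------------------------------------------------------- elastic net
def test_en_full_shrinkage_predicts_training_resultant(rng):
    X, theta = sinusoid_matrix(rng, n_samples=50, n_signal=5, n_null=5)
    m = ElasticNetPhaseRegressor(lam=1e6).fit(X, theta)
    assert len(m.selected_features_) == 0
    expected = c.circular_mean(theta)
    pred = m.predict(X.iloc[:3])
    assert np.allclose(c.signed_diff(pred, expected), 0, atol=1e-9)


def test_en_small_lambda_recovers_least_squares(rng):
    X, theta = sinusoid_matrix(rng, n_samples=80, n_signal=10, n_null=5)
    m = ElasticNetPhaseRegressor(lam=1e-6).fit(X.iloc[:60], theta[:60])
    assert c.mae(m.predict(X.iloc[60:]), theta[60:]) < 1e-3 * 12 / np.pi


def test_en_false_selection_rate_on_nulls(rng):
    """alpha=0.5 with a moderate penalty rarely selects pure-noise features."""
    theta = rng.uniform(0, 2 * np.pi, 140)
    psi = rng.uniform(0, 2 * np.pi, 10)
    signal = 0.8 * np.cos(theta[:, None] - psi[None, :])
    nulls = rng.normal(size=(140, 990))
    X = pd.DataFrame(
        np.column_stack([signal + rng.normal(0, 0.3, signal.shape), nulls]),
        columns=[f"sig{i:03d}" for i in range(10)]
        + [f"nul{i:03d}" for i in range(990)],
    )
    m = ElasticNetPhaseRegressor(alpha=0.5, lam=0.1).fit(X, theta)
    true_sel = sum(f.startswith("sig") for f in m.selected_features_)
    false_sel = sum(f.startswith("nul") for f in m.selected_features_)
    assert true_sel == 10
    assert false_sel / 990 < 0.05


def test_en_l1_is_sparser_than_l2_at_matched_lambda(rng):
    X, theta = sinusoid_matrix(rng, n_samples=60, n_signal=8, n_null=40,
                               noise_sd=0.3)
    lasso = ElasticNetPhaseRegressor(alpha=1.0, lam=0.05).fit(X, theta)
    ridge = ElasticNetPhaseRegressor(alpha=0.0, lam=0.05).fit(X, theta)
    assert len(lasso.selected_features_) <= len(ridge.selected_features_)


def test_en_rejects_nonpositive_lambda(rng):
    X, theta = sinusoid_matrix(rng, n_samples=10, n_signal=2, n_null=2)
    with pytest.raises(ConfigError):
        ElasticNetPhaseRegressor(lam=0.0).fit(X, theta)


def test_en_cv_lambda_signal_vs_noise(rng):
    theta = rng.uniform(0, 2 * np.pi, 60)
    psi = rng.uniform(0, 2 * np.pi, 10)
    X_sig = np.column_stack(
        [np.cos(theta[:, None] - psi[None, :]), rng.normal(size=(60, 20))]
    )
    lam_sig = en_cv_lambda(X_sig, theta, random_state=0)
    X_noise = rng.normal(size=(60, 30))
    lam_noise = en_cv_lambda(X_noise, theta, random_state=0)
    assert lam_noise > lam_sig
    # strong noiseless signal drives lambda into the bottom decade
    path_top = np.max(np.abs(
        (X_sig - X_sig.mean(0)).T @ (phase_to_targets(theta)
                                     - phase_to_targets(theta).mean(0))
    )) / (60 * 0.5)
    assert lam_sig < path_top * 1e-3


def test_en_cv_lambda_path_of_length_one(rng):
    X, theta = sinusoid_matrix(rng, n_samples=30, n_signal=4, n_null=4)
    lam = en_cv_lambda(X.to_numpy(), theta, n_lambdas=1, random_state=0)
    assert lam > 0


def test_en_cv_mode_runs_inside_estimator(rng):
    X, theta = sinusoid_matrix(rng, n_samples=40, n_signal=5, n_null=10,
                               noise_sd=0.2)
    m = ElasticNetPhaseRegressor(
        lambda_mode="cv", cv_folds=4, n_lambdas=20, random_state=1
    ).fit(X, theta)
    assert m.lambda_ > 0
    assert c.mae(m.predict(X), theta) < 2.0


# ------------------------------------------------------------- fixed panel
def test_fixed_panel_noiseless_recovery(rng):
    X, theta = sinusoid_matrix(rng, n_samples=90, n_signal=4, n_null=20)
    m = FixedPanelPhaseRegressor(panel=["sig000", "sig001"], n_latent=2).fit(
        X.iloc[:60], theta[:60]
    )
    assert c.mae(m.predict(X.iloc[60:]), theta[60:]) < 1e-6 * 12 / np.pi


def test_fixed_panel_constant_features_varying_coefficients(rng):
    X, theta = sinusoid_matrix(rng, n_samples=80, n_signal=4, n_null=20,
                               noise_sd=0.3)
    panel = ["sig000", "sig001", "sig002"]
    m1 = FixedPanelPhaseRegressor(panel=panel, n_latent=2).fit(
        X.iloc[:40], theta[:40]
    )
    m2 = FixedPanelPhaseRegressor(panel=panel, n_latent=2).fit(
        X.iloc[40:], theta[40:]
    )
    assert m1.selected_features_ == m2.selected_features_ == panel
    assert not np.allclose(m1.coef_cos_, m2.coef_cos_)


def test_fixed_panel_missing_id_is_named(rng):
    X, theta = sinusoid_matrix(rng, n_samples=20, n_signal=2, n_null=2)
    with pytest.raises(AlignmentError, match="nope"):
        FixedPanelPhaseRegressor(panel=["sig000", "nope"]).fit(X, theta)
    with pytest.raises(ConfigError):
        FixedPanelPhaseRegressor(panel=[]).fit(X, theta)


# -------------------------------------------------------------- prediction
def test_cartesian_predict_intercept_only_cases(rng):
    X, theta = sinusoid_matrix(rng, n_samples=30, n_signal=2, n_null=2)
    m = ElasticNetPhaseRegressor(lam=1e6).fit(X, theta)
    m.intercept_cos_, m.intercept_sin_ = 1.0, 0.0
    assert cartesian_predict(m, X.iloc[0])[0] == pytest.approx(0.0)
    m.intercept_cos_, m.intercept_sin_ = 0.0, 1.0
    assert cartesian_predict(m, X.iloc[0])[0] == pytest.approx(np.pi / 2)
    m.intercept_cos_, m.intercept_sin_ = 0.0, 0.0
    with pytest.raises(DegenerateDirectionError):
        cartesian_predict(m, X.iloc[0])


def test_model_json_roundtrip_bit_identical_predictions(rng, tmp_path):
    from circaphase import io as cio

    X, theta = sinusoid_matrix(rng, n_samples=50, n_signal=6, n_null=20,
                               noise_sd=0.1)
    for est in (
        PlsrPhaseRegressor(n_latent=3, n_predictors=10),
        ElasticNetPhaseRegressor(lam=0.02),
        FixedPanelPhaseRegressor(panel=["sig000", "sig001"], n_latent=2),
    ):
        est.fit(X, theta)
        path = tmp_path / f"{est.method}.json"
        cio.save_model(est, path)
        back = cio.load_model(path)
        assert np.array_equal(est.predict(X), back.predict(X))


def test_model_from_dict_rejects_unknown_method():
    with pytest.raises(ConfigError):
        model_from_dict({"method": "mystery"})
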