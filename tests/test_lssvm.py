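import numpy as np
import pytest

from spadspec import (
    DataError,
    SMAConfig,
    evaluate,
    lssvm_predict,
    lssvm_train,
    sma_lssvm_fit,
)


def _rbf(A, B, s2):
    d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(-1)
    return np.exp(-d2 / s2)


def test_constant_target_carried_by_bias(rng):
    X = rng.normal(size=(15, 4))
    m = lssvm_train(X, np.full(15, 3.5), gamma=1.0, sigma2=1.0)
    np.testing.assert_allclose(lssvm_predict(m, X), 3.5, atol=1e-8)


def test_interpolation_limit_at_large_gamma(rng):
    X = rng.normal(size=(12, 2))
    y = np.sin(X[:, 0]) + X[:, 1] ** 2
    m = lssvm_train(X, y, gamma=1e8, sigma2=2.0)
    assert np.max(np.abs(lssvm_predict(m, X) - y)) < 1e-4


def test_matches_dense_inversion_oracle(rng):
    """5-point 1-D instance against an explicit inverse of the KKT system."""
    X = rng.normal(size=(5, 1))
    y = rng.normal(size=5)
    gamma, s2 = 7.0, 1.3
    m = lssvm_train(X, y, gamma, s2)
    Xs = m.scaler.transform(X)
    K = _rbf(Xs, Xs, s2)
    A = np.zeros((6, 6))
    A[0, 1:] = 1.0
    A[1:, 0] = 1.0
    A[1:, 1:] = K + np.eye(5) / gamma
    sol = np.linalg.inv(A) @ np.concatenate([[0.0], y])
    np.testing.assert_allclose(m.bias, sol[0], atol=1e-9)
    np.testing.assert_allclose(m.dual_coefficients, sol[1:], atol=1e-9)
    np.testing.assert_allclose(
        lssvm_predict(m, X), K @ sol[1:] + sol[0], atol=1e-9
    )


def test_far_point_predicts_bias(rng):
    X = rng.normal(size=(10, 2))
    y = rng.normal(size=10)
    m = lssvm_train(X, y, gamma=10.0, sigma2=0.5)
    far = np.full((1, 2), 1e3)
    assert lssvm_predict(m, far)[0] == pytest.approx(m.bias, abs=1e-8)


def test_feature_count_mismatch(rng):
    m = lssvm_train(rng.normal(size=(8, 3)), rng.normal(size=8), 1.0, 1.0)
    with pytest.raises(DataError, match="feature-count"):
        lssvm_predict(m, rng.normal(size=(2, 4)))


def test_equals_kernel_ridge_with_intercept(rng):
    """Closed-form equivalence: eliminating the bias from the KKT system gives
    centred kernel ridge, so predictions must agree."""
    X = rng.normal(size=(20, 3))
    y = rng.normal(size=20)
    gamma, s2 = 5.0, 2.0
    m = lssvm_train(X, y, gamma, s2)
    Xs = m.scaler.transform(X)
    K = _rbf(Xs, Xs, s2)
    R = K + np.eye(20) / gamma
    Rinv = np.linalg.inv(R)
    one = np.ones(20)
    b = (one @ Rinv @ y) / (one @ Rinv @ one)
    alpha = Rinv @ (y - b * one)
    np.testing.assert_allclose(lssvm_predict(m, X), K @ alpha + b, atol=1e-9)


def test_affine_rescaling_of_raw_features_is_invariant(rng):
    X = rng.normal(size=(25, 3))
    y = rng.normal(size=25)
    X2 = X * np.array([10.0, 0.2, 3.0]) + np.array([-5.0, 7.0, 0.1])
    m1 = lssvm_train(X, y, 50.0, 1.5)
    m2 = lssvm_train(X2, y, 50.0, 1.5)
    Xt = rng.normal(size=(6, 3))
    Xt2 = Xt * np.array([10.0, 0.2, 3.0]) + np.array([-5.0, 7.0, 0.1])
    np.testing.assert_allclose(
        lssvm_predict(m1, Xt), lssvm_predict(m2, Xt2), atol=1e-8
    )


def test_invalid_hyperparameters(rng):
    X, y = rng.normal(size=(5, 1)), rng.normal(size=5)
    with pytest.raises(ValueError):
        lssvm_train(X, y, -1.0, 1.0)
    with pytest.raises(ValueError):
        lssvm_train(X, y, 1.0, 0.0)


def test_evaluate_contracts(rng):
    y = rng.normal(2.0, 1.0, size=30)
    perfect = evaluate(y, y)
    assert perfect["rmse"] == 0.0
    assert perfect["r2_standard"] == 1.0 and perfect["r2_uncentered"] == 1.0
    at_mean = evaluate(y, np.full(30, y.mean()))
    assert at_mean["r2_standard"] == pytest.approx(0.0, abs=1e-12)


def test_evaluate_matches_hand_computed_oracle(rng):
    yt = rng.normal(3.0, 2.0, size=25)
    yp = yt + rng.normal(0, 0.5, size=25)
    got = evaluate(yt, yp)
    sse = np.sum((yt - yp) ** 2)
    assert got["rmse"] == pytest.approx(np.sqrt(sse / 25), abs=1e-12)
    assert got["r2_uncentered"] == pytest.approx(1 - sse / np.sum(yt**2), abs=1e-12)
    assert got["r2_standard"] == pytest.approx(
        1 - sse / np.sum((yt - yt.mean()) ** 2), abs=1e-12
    )


def test_uncentered_r2_never_below_standard(rng):
    for _ in range(20):
        yt = rng.normal(5.0, 2.0, size=15)  # nonzero mean
        yp = yt + rng.normal(0, 1.0, size=15)
        got = evaluate(yt, yp)
        assert got["r2_uncentered"] >= got["r2_standard"] - 1e-12


def test_sma_tuning_beats_fixed_default_majority(rng):
    """The default (gamma=100, sigma2=1) lies inside the search box, so the
    tuned model should win on most seeds (stochastic search, majority of 5)."""
    X = rng.normal(size=(60, 3))
    y = X[:, 0] - 2 * X[:, 1] ** 2 + rng.normal(0, 0.3, 60)
    tr, te = np.arange(45), np.arange(45, 60)
    m0 = lssvm_train(X[tr], y[tr], 100.0, 1.0)
    rmse0 = evaluate(y[te], lssvm_predict(m0, X[te]))["rmse"]
    wins = 0
    for s in range(5):
        cfg = SMAConfig(lb=[-2, -3], ub=[6, 4], pop_size=10, max_iter=15, seed=s)
        _, rep = sma_lssvm_fit(X[tr], y[tr], X[te], y[te], sma_cfg=cfg)
        wins += rep.rmse_val <= rmse0 + 1e-9
    assert wins >= 3


def test_degenerate_constant_target_report(rng):
    X = rng.normal(size=(20, 2))
    y = np.full(20, 4.0)
    cfg = SMAConfig(lb=[-2, -3], ub=[6, 4], pop_size=6, max_iter=5, seed=0)
    _, rep = sma_lssvm_fit(X[:15], y[:15], X[15:], y[15:], sma_cfg=cfg)
    assert rep.rmse_val == pytest.approx(0.0, abs=1e-6)
    assert rep.r2_uncentered_val == pytest.approx(1.0, abs=1e-9)
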