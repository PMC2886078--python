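"""NIPALS PLS1: oracle equivalence, covariance property, invariants."""

import warnings

import numpy as np
import pytest

from chylopls import (
    SimulationConfig,
    crop,
    fit_pls,
    fitted_values,
    load_model_json,
    mean_center,
    predict,
    regression_coefficient_profile,
    save_model_json,
    simulate_dataset,
)
from oracles import ols_coefficients, pls1_reference_predict


def test_single_column_equal_to_y_is_fit_exactly():
    y = np.array([0.1, 0.9, 0.4, 1.7, 1.2])
    X = y[:, None].copy()
    model = fit_pls(X, y, 1)
    np.testing.assert_allclose(fitted_values(model), y, atol=1e-12)
    # slope on the original scale is 1
    np.testing.assert_allclose(predict(model, X), y, atol=1e-12)
    assert model.b[0] == pytest.approx(1.0, abs=1e-12)


def test_full_rank_pls_matches_least_squares(rng):
    """At A = rank(Xc) the PLS regression vector is the least-squares one."""
    X = rng.standard_normal((20, 10))
    y = X @ rng.standard_normal(10) + 0.05 * rng.standard_normal(20)
    model = fit_pls(X, y, 10)
    np.testing.assert_allclose(model.b, ols_coefficients(X, y), atol=1e-8)


def test_first_weight_is_proportional_to_covariance(rng):
    """w₁ ∝ Xc'yc — the covariance-guided projection property."""
    X = rng.standard_normal((30, 12))
    y = rng.standard_normal(30)
    model = fit_pls(X, y, 3)
    Xc, yc, _ = mean_center(X, y)
    v = Xc.T @ yc
    cosine = (model.W[:, 0] @ v) / np.linalg.norm(v)
    assert abs(abs(cosine) - 1.0) < 1e-12


def test_predictions_match_score_space_reference(rng):
    """Predicting via b + intercept equals the score-space deflation path."""
    X = rng.standard_normal((25, 40))
    y = X[:, 3] - 0.5 * X[:, 10] + 0.1 * rng.standard_normal(25)
    X_new = rng.standard_normal((7, 40))
    for A in (1, 2, 4):
        model = fit_pls(X, y, A)
        expected = pls1_reference_predict(X, y, X_new, A)
        np.testing.assert_allclose(predict(model, X_new), expected, atol=1e-10)


def test_matches_sklearn_pls_predictions(rng):
    """Cross-check against an independently developed PLS implementation."""
    sklearn = pytest.importorskip("sklearn.cross_decomposition")
    X = rng.standard_normal((30, 15))
    y = X @ rng.standard_normal(15) + rng.standard_normal(30)
    X_new = rng.standard_normal((5, 15))
    for A in (1, 3):
        ours = predict(fit_pls(X, y, A), X_new)
        ref = sklearn.PLSRegression(n_components=A, scale=False).fit(X, y[:, None])
        np.testing.assert_allclose(ours, ref.predict(X_new).ravel(), atol=1e-8)


def test_scores_are_orthogonal(rng):
    X = rng.standard_normal((40, 25))
    y = rng.standard_normal(40)
    model = fit_pls(X, y, 6)
    G = model.T.T @ model.T
    off = G - np.diag(np.diag(G))
    assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()


def test_b_reproduces_training_fit(rng):
    X = rng.standard_normal((20, 30))
    y = rng.standard_normal(20)
    model = fit_pls(X, y, 4)
    np.testing.assert_allclose(predict(model, X), fitted_values(model), atol=1e-10)


def test_column_permutation_permutes_b(rng):
    X = rng.standard_normal((15, 8))
    y = rng.standard_normal(15)
    perm = rng.permutation(8)
    b_ref = fit_pls(X, y, 3).b
    b_perm = fit_pls(X[:, perm], y, 3).b
    np.testing.assert_allclose(b_perm, b_ref[perm], atol=1e-12)


def test_training_r2_nondecreasing_in_components(rng):
    X = rng.standard_normal((25, 12))
    y = X @ rng.standard_normal(12) + rng.standard_normal(25)
    sst = np.sum((y - y.mean()) ** 2)
    r2s = []
    for A in range(1, 8):
        resid = y - predict(fit_pls(X, y, A), X)
        r2s.append(1 - np.sum(resid**2) / sst)
    assert np.all(np.diff(r2s) >= -1e-12)


def test_prediction_equivariance_under_y_shift(rng):
    X = rng.standard_normal((18, 9))
    y = rng.standard_normal(18)
    X_new = rng.standard_normal((4, 9))
    base = predict(fit_pls(X, y, 3), X_new)
    shifted = predict(fit_pls(X, y + 2.5, 3), X_new)
    np.testing.assert_allclose(shifted, base + 2.5, atol=1e-10)


def test_predicting_the_training_mean_row_returns_mean_y(rng):
    X = rng.standard_normal((12, 6))
    y = rng.standard_normal(12)
    model = fit_pls(X, y, 2)
    got = predict(model, X.mean(axis=0)[None, :])[0]
    assert got == pytest.approx(y.mean(), abs=1e-12)


# ---------------------------------------------------------------------------
# validation of inputs and degenerate cases
# ---------------------------------------------------------------------------

def test_rejects_zero_variance_y():
    with pytest.raises(ValueError, match="variance"):
        fit_pls(np.eye(4), np.ones(4), 1)


def test_rejects_too_many_components():
    with pytest.raises(ValueError, match="exceeds"):
        fit_pls(np.random.default_rng(0).standard_normal((5, 3)), np.arange(5.0), 4)


def test_rejects_nonpositive_components():
    with pytest.raises(ValueError, match=">= 1"):
        fit_pls(np.eye(4), np.arange(4.0), 0)


def test_rank_deficient_x_stops_early_with_warning(rng):
    col = rng.standard_normal(10)
    X = np.column_stack([col, 2 * col, -col])  # rank 1 after centering
    y = col + 0.01 * rng.standard_normal(10)
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = fit_pls(X, y, 3)
    assert model.n_components < 3
    assert any("stopping early" in str(w.message) for w in caught)


# ---------------------------------------------------------------------------
# coefficient profile and serialization
# ---------------------------------------------------------------------------

def test_coefficient_profile_matches_region_length(small_sim_dataset):
    sub = crop(small_sim_dataset, 1.05, 1.4)
    model = fit_pls(sub.X, sub.y, 3, ppm=sub.ppm)
    ppm, b = regression_coefficient_profile(model)
    assert ppm.shape == b.shape == (sub.n_points,)
    assert model.region == (pytest.approx(1.05, abs=0.002), pytest.approx(1.4, abs=0.002))


def test_largest_coefficient_sits_left_of_methylene_center():
    """With the TG-dependent shift towards higher ppm, the most informative
    variables lie on the high-ppm (left) flank of the 1.28 ppm peak."""
    cfg = SimulationConfig(seed=42, noise_sd=0.005, reference_jitter_sd=0.0)
    ds = simulate_dataset(60, cfg)
    sub = crop(ds, 1.05, 1.4)
    model = fit_pls(sub.X, sub.y, 3, ppm=sub.ppm)
    ppm, b = regression_coefficient_profile(model)
    assert ppm[np.argmax(np.abs(b))] > 1.28


def test_model_json_round_trip(tmp_path, rng):
    X = rng.standard_normal((12, 6))
    y = rng.uniform(0, 2, 12)
    ppm = np.linspace(2.0, 1.0, 6)
    model = fit_pls(X, y, 2, ppm=ppm)
    path = tmp_path / "model.json"
    save_model_json(model, path, provenance={"note": "round-trip"})
    back = load_model_json(path)
    np.testing.assert_allclose(back.b, model.b, rtol=1e-15)
    assert back.intercept == model.intercept
    assert back.region == model.region
    X_new = rng.standard_normal((3, 6))
    np.testing.assert_allclose(predict(back, X_new), predict(model, X_new), rtol=1e-15)
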