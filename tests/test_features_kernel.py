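import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from softsensor.errors import DataError
from softsensor.features_kernel import (
    approx_gram,
    exact_rbf_gram,
    fit_feature_layer,
    apply_feature_layer,
    fit_kernel_ae,
    median_heuristic_sigma,
    rff_transform,
    sample_rff_basis,
)


# ------------------------------------------------------------ feature layer
def test_layer_shape_contract():
    X = np.random.default_rng(0).normal(size=(5, 4))
    layer, Z = fit_feature_layer(X, n_groups=2, nodes_per_group=3, seed=0)
    assert Z.shape == (5, 6)
    assert layer.n_total == 6


def test_layer_zero_input_identity_gives_bias_rows():
    X = np.zeros((4, 3))
    layer, Z = fit_feature_layer(X, 2, 5, activation="identity", seed=1)
    expected = np.hstack([np.tile(b, (4, 1)) for b in layer.biases])
    np.testing.assert_allclose(Z, expected)


def test_layer_determinism():
    X = np.random.default_rng(3).normal(size=(10, 4))
    _, Z1 = fit_feature_layer(X, 3, 4, seed=42)
    _, Z2 = fit_feature_layer(X, 3, 4, seed=42)
    _, Z3 = fit_feature_layer(X, 3, 4, seed=43)
    np.testing.assert_array_equal(Z1, Z2)
    assert not np.array_equal(Z1, Z3)


def test_apply_layer_consistency_and_rows():
    X = np.random.default_rng(5).normal(size=(8, 3))
    layer, Z = fit_feature_layer(X, 2, 4, seed=0)
    np.testing.assert_array_equal(apply_feature_layer(layer, X), Z)
    assert apply_feature_layer(layer, X[:1]).shape == (1, 8)
    assert (np.abs(apply_feature_layer(layer, X)) < 1.0).all()  # tanh range
    with pytest.raises(DataError, match="columns"):
        apply_feature_layer(layer, X[:, :2])


def test_layer_rejects_nonfinite():
    with pytest.raises(DataError):
        fit_feature_layer(np.array([[np.inf, 0.0]]), 1, 1)


# --------------------------------------------------------------- RFF basis
def test_rff_frequency_moments():
    basis = sample_rff_basis(dim=1, m=100_000, sigma=1.0, seed=0)
    assert 0.99 <= basis.frequencies.std() <= 1.01
    halved = sample_rff_basis(dim=1, m=100_000, sigma=2.0, seed=0)
    np.testing.assert_allclose(halved.frequencies, basis.frequencies / 2.0)


def test_rff_minimal_basis():
    basis = sample_rff_basis(dim=3, m=1, sigma=1.0, seed=0)
    H = rff_transform(basis, np.zeros((2, 3)))
    assert H.shape == (2, 2)


def test_rff_sigma_validation():
    with pytest.raises(DataError):
        sample_rff_basis(2, 10, 0.0)


def test_rff_zero_vector_row():
    m = 7
    basis = sample_rff_basis(dim=4, m=m, sigma=1.0, seed=0)
    row = rff_transform(basis, np.zeros((1, 4)))[0]
    np.testing.assert_allclose(row[:m], 1.0 / np.sqrt(m), atol=1e-15)
    np.testing.assert_allclose(row[m:], 0.0, atol=1e-15)


def test_rff_unit_norm_rows():
    rng = np.random.default_rng(1)
    basis = sample_rff_basis(dim=6, m=50, sigma=0.7, seed=2)
    H = rff_transform(basis, rng.normal(size=(20, 6)))
    np.testing.assert_allclose((H**2).sum(axis=1), 1.0, atol=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.integers(0, 2**31 - 1))
def test_rff_unit_norm_property(seed):
    rng = np.random.default_rng(seed)
    basis = sample_rff_basis(dim=3, m=11, sigma=1.3, seed=seed)
    H = rff_transform(basis, rng.normal(scale=3.0, size=(5, 3)))
    np.testing.assert_allclose((H**2).sum(axis=1), 1.0, atol=1e-12)


def test_rff_inner_product_trig_identity():
    # H_a . H_b == (1/m) sum_j cos(w_j . (z_a - z_b)), the
    # product-to-difference identity
    rng = np.random.default_rng(4)
    Z = rng.normal(size=(6, 5))
    basis = sample_rff_basis(dim=5, m=40, sigma=1.0, seed=9)
    H = rff_transform(basis, Z)
    for a in range(6):
        for b in range(6):
            expected = np.mean(np.cos(basis.frequencies @ (Z[a] - Z[b])))
            assert H[a] @ H[b] == pytest.approx(expected, abs=1e-12)


# -------------------------------------------------------------- Gram blocks
def test_approx_gram_symmetry_and_diag():
    rng = np.random.default_rng(0)
    H = rff_transform(sample_rff_basis(4, 30, 1.0, 0), rng.normal(size=(10, 4)))
    omega = approx_gram(H, H)
    np.testing.assert_allclose(omega, omega.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(omega), 1.0, atol=1e-12)


def test_approx_gram_single_rows():
    H = rff_transform(sample_rff_basis(2, 5, 1.0, 0), np.ones((1, 2)))
    np.testing.assert_allclose(approx_gram(H, H), [[1.0]], atol=1e-12)


def test_approx_gram_monte_carlo_bound():
    # m = 10^4: uniform error against the exact kernel below 0.05
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(50, 8))
    sigma = 2.0
    K = exact_rbf_gram(Z, Z, sigma)
    H = rff_transform(sample_rff_basis(8, 10_000, sigma, seed=1), Z)
    assert np.abs(approx_gram(H, H) - K).max() <= 0.05


def test_approx_gram_error_monotone_in_m():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(40, 6))
    sigma = 1.5
    K = exact_rbf_gram(Z, Z, sigma)
    maes = []
    for m in (10, 100, 1000, 10_000):
        per_seed = [
            np.abs(
                approx_gram(h, h) - K
            ).mean()
            for h in (
                rff_transform(sample_rff_basis(6, m, sigma, seed=s), Z)
                for s in range(3)
            )
        ]
        maes.append(np.mean(per_seed))
    assert all(a > b for a, b in zip(maes, maes[1:]))


def test_approx_gram_unbiased():
    # averaged over 50 bases at m=100, entries match the exact kernel
    # within 3 standard errors (a handful of 2500 entries may poke out)
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(15, 4))
    sigma = 1.0
    K = exact_rbf_gram(Z, Z, sigma)
    samples = np.stack(
        [
            approx_gram(h, h)
            for h in (
                rff_transform(sample_rff_basis(4, 100, sigma, seed=s), Z)
                for s in range(50)
            )
        ]
    )
    se = samples.std(axis=0, ddof=1) / np.sqrt(50)
    dev = np.abs(samples.mean(axis=0) - K)
    off_diag = ~np.eye(15, dtype=bool)
    frac_ok = np.mean(dev[off_diag] <= 3 * se[off_diag])
    assert frac_ok >= 0.98


def test_exact_rbf_gram_values():
    sigma = 0.8
    z = np.zeros((1, 3))
    w = np.full((1, 3), sigma * np.sqrt(2.0 / 3.0))  # distance sigma*sqrt(2)
    assert exact_rbf_gram(z, z, sigma)[0, 0] == pytest.approx(1.0)
    assert exact_rbf_gram(z, w, sigma)[0, 0] == pytest.approx(np.exp(-1.0), rel=1e-12)
    # strictly decreasing with distance
    ds = np.linspace(0.1, 3.0, 7)
    vals = [exact_rbf_gram(z, np.full((1, 3), d / np.sqrt(3)), sigma)[0, 0] for d in ds]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    with pytest.raises(DataError):
        exact_rbf_gram(z, z, -1.0)


# ------------------------------------------------------------- kernel AE
def test_kernel_ae_push_through_identity():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(20, 7))
    omega = rng.normal(size=(20, 20))
    C = 0.1
    W = fit_kernel_ae(Z, omega, C)
    oracle = np.linalg.solve(C * np.eye(7) + Z.T @ Z, Z.T @ omega)
    np.testing.assert_allclose(W, oracle, rtol=1e-8, atol=1e-10)


def test_kernel_ae_self_reconstruction_limit():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(10, 15))  # wide: Z Z^T full rank
    omega = Z @ Z.T
    prev = np.inf
    for C in (1e-2, 1e-6, 1e-10):
        err = np.abs(Z @ fit_kernel_ae(Z, omega, C) - omega).max() / np.abs(omega).max()
        assert err < prev
        prev = err
    assert prev < 1e-8


def test_kernel_ae_large_C_shrinks_to_zero():
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(10, 4))
    omega = rng.normal(size=(10, 10))
    assert np.abs(fit_kernel_ae(Z, omega, 1e12)).max() < 1e-9


def test_kernel_ae_validation():
    with pytest.raises(DataError):
        fit_kernel_ae(np.ones((3, 2)), np.ones((3, 3)), 0.0)
    with pytest.raises(DataError):
        fit_kernel_ae(np.ones((3, 2)), np.ones((4, 4)), 1.0)


def test_median_heuristic_positive():
    rng = np.random.default_rng(0)
    assert median_heuristic_sigma(rng.normal(size=(30, 3))) > 0
    assert median_heuristic_sigma(np.zeros((5, 2))) == 1.0
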