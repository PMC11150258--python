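"""Shared fixtures and the literal dense-algebra reference pipeline.

The reference implementation below recomputes every model mode with
plain ``np.linalg.inv`` and no shortcuts, sharing only the random draws
(feature-layer weights, Fourier frequencies, enhancement weights) with
the fitted model under test.  It is the independent oracle for the
"matches a literal transcription" equivalence checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from softsensor import features_kernel as fk
from softsensor.dataset import ProcessDataset
from softsensor.fermsim import BatchSimConfig, simulate_batch, simulate_campaign
from softsensor.models import ModelConfig, SoftSensorModel, fit_model


@pytest.fixture(scope="session")
def short_batch() -> ProcessDataset:
    """One 80 h batch, reused by cheap tests."""
    return simulate_batch(BatchSimConfig(duration=80.0))


@pytest.fixture(scope="session")
def small_campaign() -> ProcessDataset:
    """Four short batches with default batch-to-batch variation."""
    return simulate_campaign(4, BatchSimConfig(duration=80.0), seed=3)


def make_toy_regression(n: int = 50, m: int = 5, seed: int = 0, noise: float = 0.0):
    """Smooth nonlinear toy problem y = sin(3 x0) + x1^2 (+ 0.5 x2)."""
    rng = np.random.default_rng(seed)
    X = rng.uniform(-1.0, 1.0, size=(n, m))
    y = np.sin(3.0 * X[:, 0]) + X[:, 1] ** 2
    if m >= 3:
        y = y + 0.5 * X[:, 2]
    if noise:
        y = y + rng.normal(0.0, noise, size=n)
    return X, y


@pytest.fixture
def toy_xy():
    return make_toy_regression()


# ---------------------------------------------------------------- oracle
def literal_reference_predict(
    model: SoftSensorModel, X_train, y_train, X_test
) -> np.ndarray:
    """Dense-inverse transcription of the training/prediction algebra.

    Reuses the fitted model's random draws only; every matrix product,
    Gram, ridge solve and scaling step is recomputed from scratch with
    explicit inverses.
    """
    cfg = model.config
    X_train = np.asarray(X_train, float)
    y_train = np.asarray(y_train, float)
    X_test = np.atleast_2d(np.asarray(X_test, float))

    mean, sd = X_train.mean(axis=0), X_train.std(axis=0)
    sd = np.where(sd <= 1e-12, 1.0, sd)
    y_mean, y_sd = y_train.mean(), y_train.std()
    y_scale = y_sd if (cfg.scale_target and y_sd > 1e-12) else 1.0
    Xs, Xs_t = (X_train - mean) / sd, (X_test - mean) / sd
    ys = (y_train - y_mean) / y_scale

    phi = fk.ACTIVATIONS[cfg.activation]
    Z = np.hstack(
        [phi(Xs @ W + b) for W, b in zip(model.layer.weights, model.layer.biases)]
    )
    Z_t = np.hstack(
        [phi(Xs_t @ W + b) for W, b in zip(model.layer.weights, model.layer.biases)]
    )

    if cfg.mode == "bls":
        xi = fk.ACTIVATIONS[cfg.enhance_activation]
        enh = model.enhancement
        block = xi(Z @ enh.weights + enh.biases)
        block_t = xi(Z_t @ enh.weights + enh.biases)
    else:
        sigma = model.kernel.sigma
        if cfg.mode == "akbls":
            F = model.kernel.basis.frequencies
            sc = 1.0 / np.sqrt(F.shape[0])

            def rff(A):
                P = A @ F.T
                return np.hstack([np.cos(P), np.sin(P)]) * sc

            H, H_t = rff(Z), rff(Z_t)
            omega = H @ H.T
            cross = H_t @ H.T
        else:
            def gram(A, B):
                d2 = ((A[:, None, :] - B[None, :, :]) ** 2).sum(axis=2)
                return np.exp(-d2 / (2 * sigma**2))

            omega = gram(Z, Z)
            cross = gram(Z_t, Z)
        block = omega
        if cfg.test_kernel == "ae":
            W_omega = Z.T @ np.linalg.inv(cfg.C * np.eye(len(Z)) + Z @ Z.T) @ omega
            block_t = Z_t @ W_omega
        else:
            block_t = cross

    A = np.hstack([Z, block])
    A_t = np.hstack([Z_t, block_t])
    W = A.T @ np.linalg.inv(cfg.gamma * np.eye(A.shape[0]) + A @ A.T) @ ys
    return (A_t @ W) * y_scale + y_mean
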