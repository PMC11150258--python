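"""Random feature layers and (approximate) kernel blocks.

This module owns the random building blocks of the broad-learning
regressors: the grouped random feature layer, the random Fourier feature
map whose inner products approximate an RBF kernel, the exact RBF Gram
matrix, and the ridge "autoencoder" weights that map feature nodes onto
the kernel block for out-of-sample use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.spatial.distance import cdist, pdist

from .errors import DataError, NumericalError

__all__ = [
    "ACTIVATIONS",
    "FeatureLayer",
    "RFFBasis",
    "KernelBlock",
    "fit_feature_layer",
    "apply_feature_layer",
    "sample_rff_basis",
    "rff_transform",
    "approx_gram",
    "exact_rbf_gram",
    "fit_kernel_ae",
    "median_heuristic_sigma",
]

ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    "sigmoid": lambda a: 1.0 / (1.0 + np.exp(-a)),
    "relu": lambda a: np.maximum(a, 0.0),
    "identity": lambda a: a,
}


@dataclass
class FeatureLayer:
    """n_groups random maps of the input, each ``X @ W + b`` through an
    activation; columns of all groups are concatenated."""

    weights: list[np.ndarray]  # each (M, nodes_per_group)
    biases: list[np.ndarray]   # each (nodes_per_group,)
    activation: str
    seed: int

    @property
    def n_groups(self) -> int:
        return len(self.weights)

    @property
    def nodes_per_group(self) -> int:
        return self.weights[0].shape[1]

    @property
    def n_inputs(self) -> int:
        return self.weights[0].shape[0]

    @property
    def n_total(self) -> int:
        return self.n_groups * self.nodes_per_group


@dataclass
class RFFBasis:
    """m Fourier components of an RBF kernel of bandwidth ``sigma``.

    Frequencies are i.i.d. Normal(0, sigma^-2 I); the induced map z(x)
    is 2m-dimensional and has unit squared norm for every x.
    """

    frequencies: np.ndarray  # (m, dim)
    sigma: float
    seed: int

    @property
    def m(self) -> int:
        return self.frequencies.shape[0]

    @property
    def dim(self) -> int:
        return self.frequencies.shape[1]


@dataclass
class KernelBlock:
    """The trained kernel part of a KBLS/AKBLS model."""

    mode: str                      # "approximate" | "exact"
    sigma: float
    C: float
    W_omega: Optional[np.ndarray] = None  # (n_F, N_train), 'ae' route only
    basis: Optional[RFFBasis] = None
    H_train: Optional[np.ndarray] = None  # (N, 2m), approximate mode
    Z_train: Optional[np.ndarray] = None  # (N, n_F), exact mode


def fit_feature_layer(
    X_scaled: np.ndarray,
    n_groups: int,
    nodes_per_group: int,
    activation: str = "tanh",
    seed: int = 0,
) -> tuple[FeatureLayer, np.ndarray]:
    """Draw the grouped random-feature layer and apply it to ``X_scaled``.

    Weights and biases are uniform on [-1, 1], the convention of the
    original broad-learning reference implementation.
    """
    X_scaled = np.asarray(X_scaled, dtype=float)
    if not np.isfinite(X_scaled).all():
        raise DataError("non-finite values in scaled input")
    if n_groups < 1 or nodes_per_group < 1:
        raise DataError("n_groups and nodes_per_group must be >= 1")
    if activation not in ACTIVATIONS:
        raise DataError(f"unknown activation {activation!r}")
    rng = np.random.default_rng(seed)
    M = X_scaled.shape[1]
    weights = [
        rng.uniform(-1.0, 1.0, size=(M, nodes_per_group)) for _ in range(n_groups)
    ]
    biases = [rng.uniform(-1.0, 1.0, size=nodes_per_group) for _ in range(n_groups)]
    layer = FeatureLayer(weights=weights, biases=biases, activation=activation, seed=seed)
    return layer, apply_feature_layer(layer, X_scaled)


def apply_feature_layer(layer: FeatureLayer, X_scaled: np.ndarray) -> np.ndarray:
    """Stateless application of a fitted layer; output is N x n_total."""
    X_scaled = np.atleast_2d(np.asarray(X_scaled, dtype=float))
    if X_scaled.shape[1] != layer.n_inputs:
        raise DataError(
            f"input has {X_scaled.shape[1]} columns, layer expects {layer.n_inputs}"
        )
    phi = ACTIVATIONS[layer.activation]
    blocks = [phi(X_scaled @ W + b) for W, b in zip(layer.weights, layer.biases)]
    return np.hstack(blocks)


def sample_rff_basis(dim: int, m: int, sigma: float, seed: int = 0) -> RFFBasis:
    """Sample ``m`` frequency vectors from Normal(0, sigma^-2 I_dim)."""
    if sigma <= 0:
        raise DataError("sigma must be > 0")
    if m < 1 or dim < 1:
        raise DataError("m and dim must be >= 1")
    rng = np.random.default_rng(seed)
    freqs = rng.standard_normal((m, dim)) / sigma
    return RFFBasis(frequencies=freqs, sigma=float(sigma), seed=seed)


def rff_transform(basis: RFFBasis, Z: np.ndarray) -> np.ndarray:
    """Map rows of ``Z`` to (1/sqrt(m)) [cos(w_j.z), sin(w_j.z)]_{j=1..m}."""
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    if Z.shape[1] != basis.dim:
        raise DataError(f"input has {Z.shape[1]} columns, basis expects {basis.dim}")
    proj = Z @ basis.frequencies.T
    scale = 1.0 / np.sqrt(basis.m)
    return np.hstack([np.cos(proj), np.sin(proj)]) * scale


def approx_gram(H_a: np.ndarray, H_b: np.ndarray) -> np.ndarray:
    """Sample-by-sample Gram of two random-Fourier maps: H_a @ H_b.T."""
    H_a = np.atleast_2d(np.asarray(H_a, dtype=float))
    H_b = np.atleast_2d(np.asarray(H_b, dtype=float))
    if H_a.shape[1] != H_b.shape[1]:
        raise DataError("feature maps have differing widths")
    return H_a @ H_b.T


def exact_rbf_gram(Z_a: np.ndarray, Z_b: np.ndarray, sigma: float) -> np.ndarray:
    """K[i, j] = exp(-||z_i - z_j||^2 / (2 sigma^2))."""
    if sigma <= 0:
        raise DataError("sigma must be > 0")
    Z_a = np.atleast_2d(np.asarray(Z_a, dtype=float))
    Z_b = np.atleast_2d(np.asarray(Z_b, dtype=float))
    if Z_a.shape[1] != Z_b.shape[1]:
        raise DataError("inputs have differing dimensions")
    d2 = cdist(Z_a, Z_b, metric="sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


def fit_kernel_ae(Z: np.ndarray, omega: np.ndarray, C: float) -> np.ndarray:
    """Ridge reconstruction weights W = Z^T (C I + Z Z^T)^-1 Omega.

    Solved through a Cholesky factorization of the symmetric
    positive-definite N x N system; no explicit inverse is formed.
    """
    if C <= 0:
        raise DataError("ridge constant C must be > 0")
    Z = np.asarray(Z, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if Z.shape[0] != omega.shape[0]:
        raise DataError("Z and Omega row counts differ")
    G = Z @ Z.T
    G[np.diag_indices_from(G)] += C
    try:
        factor = cho_factor(G, lower=True, check_finite=False)
        W = Z.T @ cho_solve(factor, omega, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise NumericalError(f"kernel-autoencoder solve failed: {exc}") from exc
    if not np.isfinite(W).all():
        raise NumericalError("kernel-autoencoder weights are non-finite")
    return W


def median_heuristic_sigma(
    Z: np.ndarray, max_rows: int = 500, seed: int = 0
) -> float:
    """Median pairwise distance of (a subsample of) the rows of ``Z``."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[0] > max_rows:
        rng = np.random.default_rng(seed)
        Z = Z[rng.choice(Z.shape[0], size=max_rows, replace=False)]
    if Z.shape[0] < 2:
        return 1.0
    med = float(np.median(pdist(Z)))
    return med if med > 0 else 1.0
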