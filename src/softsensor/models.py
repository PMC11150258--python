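"""The three broad-learning soft-sensor estimators.

``bls``    random feature nodes + random enhancement nodes;
``kbls``   feature nodes + exact RBF Gram block;
``akbls``  feature nodes + random-Fourier approximate Gram block.

All three share the pipeline: standardize -> random feature layer ->
hidden block -> concatenated hidden matrix A -> closed-form ridge /
pseudo-inverse output weights.  At test time the kernel block is mapped
out-of-sample either through the direct cross-Gram (default) or through
the ridge autoencoder weights (``test_kernel='ae'``).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from . import features_kernel as fk
from .dataset import ProcessDataset
from .errors import DataError, NumericalError

__all__ = [
    "ModelConfig",
    "Scaler",
    "EnhancementLayer",
    "SoftSensorModel",
    "solve_ridge_output",
    "fit_model",
    "predict",
    "load_model",
]

log = logging.getLogger(__name__)

MODES = ("bls", "kbls", "akbls")
_FORMAT_TAG = "softsensor-model-1"


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of one soft-sensor model."""

    mode: str = "akbls"
    n_groups: int = 10
    nodes_per_group: int = 10
    activation: str = "tanh"
    m_fourier: int = 500
    sigma: Optional[float] = None  # None -> median heuristic on training Z
    sigma_scale: float = 0.5       # multiplier on the median-heuristic bandwidth
    C: float = 1e-6                # kernel-autoencoder ridge constant
    gamma: float = 1e-6            # output-layer ridge constant
    n_enhance: int = 100           # bls only
    enhance_activation: str = "tanh"
    test_kernel: str = "direct"    # "direct" | "ae"
    scale_target: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.mode not in MODES:
            raise DataError(f"unknown mode {self.mode!r}; choose from {MODES}")
        if self.n_groups < 1 or self.nodes_per_group < 1:
            raise DataError("n_groups and nodes_per_group must be >= 1")
        if self.mode == "akbls" and self.m_fourier < 1:
            raise DataError("m_fourier must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise DataError("sigma must be > 0")
        if self.sigma_scale <= 0:
            raise DataError("sigma_scale must be > 0")
        if self.C <= 0:
            raise DataError("C must be > 0")
        if self.gamma < 0:
            raise DataError("gamma must be >= 0")
        if self.test_kernel not in ("ae", "direct"):
            raise DataError("test_kernel must be 'ae' or 'direct'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        return cls(**d)


@dataclass
class Scaler:
    """Column-wise standardization; constant columns pass through centered."""

    mean_: np.ndarray
    scale_: np.ndarray
    constant_mask: np.ndarray
    y_mean: float
    y_scale: float
    scale_target: bool

    @classmethod
    def fit(cls, X: np.ndarray, y: np.ndarray, scale_target: bool = True) -> "Scaler":
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        constant = sd <= 1e-12
        scale = np.where(constant, 1.0, sd)
        y_mean = float(y.mean())
        y_sd = float(y.std())
        y_scale = y_sd if (scale_target and y_sd > 1e-12) else 1.0
        return cls(mean, scale, constant, y_mean, y_scale, scale_target)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.mean_) / self.scale_

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (y - self.y_mean) / self.y_scale

    def inverse_transform_y(self, y_scaled: np.ndarray) -> np.ndarray:
        return y_scaled * self.y_scale + self.y_mean


@dataclass
class EnhancementLayer:
    """Single random enhancement group used by the plain bls mode."""

    weights: np.ndarray  # (n_F, n_enhance)
    biases: np.ndarray   # (n_enhance,)
    activation: str

    def transform(self, Z: np.ndarray) -> np.ndarray:
        return fk.ACTIVATIONS[self.activation](Z @ self.weights + self.biases)


def solve_ridge_output(A: np.ndarray, Y: np.ndarray, gamma: float) -> np.ndarray:
    """Closed-form ridge output weights W = A^T (gamma I + A A^T)^-1 Y.

    The dual (right-sided) and primal (normal-equations) forms coincide
    by the push-through identity; whichever side is smaller is solved via
    Cholesky.  ``gamma == 0`` falls back to the minimum-norm pseudo-inverse
    solution.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if A.ndim != 2 or A.shape[0] != Y.shape[0]:
        raise DataError("A and Y have incompatible shapes")
    if gamma < 0:
        raise DataError("gamma must be >= 0")
    squeeze = Y.ndim == 1
    Yc = Y[:, None] if squeeze else Y
    n, p = A.shape
    if gamma == 0.0:
        W, *_ = np.linalg.lstsq(A, Yc, rcond=None)
        log.debug("gamma=0: minimum-norm least-squares solution used")
    else:
        try:
            if n <= p:
                G = A @ A.T
                G[np.diag_indices_from(G)] += gamma
                W = A.T @ cho_solve(
                    cho_factor(G, lower=True, check_finite=False), Yc, check_finite=False
                )
            else:
                G = A.T @ A
                G[np.diag_indices_from(G)] += gamma
                W = cho_solve(
                    cho_factor(G, lower=True, check_finite=False),
                    A.T @ Yc,
                    check_finite=False,
                )
        except np.linalg.LinAlgError:
            log.warning("ridge system singular; falling back to lstsq")
            AtA = A.T @ A + gamma * np.eye(p)
            W, *_ = np.linalg.lstsq(AtA, A.T @ Yc, rcond=None)
    if not np.isfinite(W).all():
        raise NumericalError("output-weight solve produced non-finite values")
    return W[:, 0] if squeeze else W


@dataclass
class SoftSensorModel:
    """One trained bls/kbls/akbls estimator."""

    config: ModelConfig
    scaler: Scaler
    layer: fk.FeatureLayer
    W: np.ndarray
    n_train: int
    variable_names: Optional[list[str]] = None
    kernel: Optional[fk.KernelBlock] = None
    enhancement: Optional[EnhancementLayer] = None

    # -------------------------------------------------------------- predict
    def _hidden(self, X_scaled: np.ndarray) -> np.ndarray:
        Z = fk.apply_feature_layer(self.layer, X_scaled)
        cfg = self.config
        if cfg.mode == "bls":
            assert self.enhancement is not None
            block = self.enhancement.transform(Z)
        else:
            assert self.kernel is not None
            if cfg.test_kernel == "ae":
                if self.kernel.W_omega is None:
                    raise DataError(
                        "model was fit with test_kernel='direct'; refit with 'ae' "
                        "to use the autoencoder route"
                    )
                block = Z @ self.kernel.W_omega
            elif cfg.mode == "akbls":
                H = fk.rff_transform(self.kernel.basis, Z)
                block = fk.approx_gram(H, self.kernel.H_train)
            else:
                block = fk.exact_rbf_gram(Z, self.kernel.Z_train, self.kernel.sigma)
        return np.hstack([Z, block])

    def predict(self, X: Union[np.ndarray, ProcessDataset]) -> np.ndarray:
        X = _resolve_inputs(X, self.variable_names)
        A = self._hidden(self.scaler.transform(X))
        return self.scaler.inverse_transform_y(A @ self.W)

    # ------------------------------------------------------------- persist
    def save(self, path) -> None:
        arrays = {
            "W": self.W,
            "scaler_mean": self.scaler.mean_,
            "scaler_scale": self.scaler.scale_,
            "scaler_constant": self.scaler.constant_mask,
            "scaler_y": np.array([self.scaler.y_mean, self.scaler.y_scale]),
            "layer_weights": np.stack(self.layer.weights),
            "layer_biases": np.stack(self.layer.biases),
        }
        if self.kernel is not None:
            if self.kernel.W_omega is not None:
                arrays["W_omega"] = self.kernel.W_omega
            if self.kernel.basis is not None:
                arrays["rff_frequencies"] = self.kernel.basis.frequencies
            if self.kernel.H_train is not None:
                arrays["H_train"] = self.kernel.H_train
            if self.kernel.Z_train is not None:
                arrays["Z_train"] = self.kernel.Z_train
            arrays["kernel_sigma"] = np.array([self.kernel.sigma, self.kernel.C])
        if self.enhancement is not None:
            arrays["enh_weights"] = self.enhancement.weights
            arrays["enh_biases"] = self.enhancement.biases
        meta = {
            "format": _FORMAT_TAG,
            "config": self.config.to_dict(),
            "n_train": self.n_train,
            "variable_names": self.variable_names,
            "scale_target": self.scaler.scale_target,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "SoftSensorModel":
        with np.load(path, allow_pickle=False) as arc:
            meta = json.loads(str(arc["meta"]))
            if meta.get("format") != _FORMAT_TAG:
                raise DataError(f"unrecognized model archive format: {meta.get('format')!r}")
            config = ModelConfig.from_dict(meta["config"])
            scaler = Scaler(
                mean_=arc["scaler_mean"],
                scale_=arc["scaler_scale"],
                constant_mask=arc["scaler_constant"],
                y_mean=float(arc["scaler_y"][0]),
                y_scale=float(arc["scaler_y"][1]),
                scale_target=meta["scale_target"],
            )
            layer = fk.FeatureLayer(
                weights=list(arc["layer_weights"]),
                biases=list(arc["layer_biases"]),
                activation=config.activation,
                seed=config.seed,
            )
            kernel = None
            enhancement = None
            if "kernel_sigma" in arc:
                sigma, C = arc["kernel_sigma"]
                basis = None
                if "rff_frequencies" in arc:
                    basis = fk.RFFBasis(
                        frequencies=arc["rff_frequencies"], sigma=float(sigma), seed=config.seed
                    )
                kernel = fk.KernelBlock(
                    mode="approximate" if config.mode == "akbls" else "exact",
                    sigma=float(sigma),
                    C=float(C),
                    W_omega=arc["W_omega"] if "W_omega" in arc else None,
                    basis=basis,
                    H_train=arc["H_train"] if "H_train" in arc else None,
                    Z_train=arc["Z_train"] if "Z_train" in arc else None,
                )
            if "enh_weights" in arc:
                enhancement = EnhancementLayer(
                    weights=arc["enh_weights"],
                    biases=arc["enh_biases"],
                    activation=config.enhance_activation,
                )
            return cls(
                config=config,
                scaler=scaler,
                layer=layer,
                W=arc["W"],
                n_train=int(meta["n_train"]),
                variable_names=meta["variable_names"],
                kernel=kernel,
                enhancement=enhancement,
            )


def load_model(path) -> SoftSensorModel:
    return SoftSensorModel.load(path)


def _resolve_inputs(
    X: Union[np.ndarray, ProcessDataset], expected_names: Optional[list[str]]
) -> np.ndarray:
    if isinstance(X, ProcessDataset):
        if expected_names is not None and X.variable_names != expected_names:
            missing = sorted(set(expected_names) - set(X.variable_names))
            extra = sorted(set(X.variable_names) - set(expected_names))
            raise DataError(
                f"column mismatch: missing {missing or 'none'}, extra {extra or 'none'}"
            )
        return X.X
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return X


def fit_model(
    data: Union[ProcessDataset, tuple],
    config: Optional[ModelConfig] = None,
    **overrides,
) -> SoftSensorModel:
    """Train one soft-sensor model.

    ``data`` may be a :class:`ProcessDataset` or an ``(X, y)`` pair.
    Keyword overrides are applied on top of ``config``.
    """
    config = replace(config or ModelConfig(), **overrides)
    config.validate()
    if isinstance(data, ProcessDataset):
        X, y, names = data.X, data.y, data.variable_names
    else:
        X, y = data
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        names = None
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise DataError("X and y have incompatible shapes")
    if X.shape[0] < 2:
        raise DataError("at least two training samples are required")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("non-finite values in training data")

    scaler = Scaler.fit(X, y, scale_target=config.scale_target)
    Xs = scaler.transform(X)
    ys = scaler.transform_y(y)

    layer, Z = fk.fit_feature_layer(
        Xs, config.n_groups, config.nodes_per_group, config.activation, seed=config.seed
    )

    kernel = None
    enhancement = None
    if config.mode == "bls":
        rng = np.random.default_rng(config.seed + 1)
        enhancement = EnhancementLayer(
            weights=rng.uniform(-1.0, 1.0, size=(layer.n_total, config.n_enhance)),
            biases=rng.uniform(-1.0, 1.0, size=config.n_enhance),
            activation=config.enhance_activation,
        )
        block = enhancement.transform(Z)
    else:
        sigma = config.sigma or config.sigma_scale * fk.median_heuristic_sigma(
            Z, seed=config.seed
        )
        # the autoencoder weights are only needed for the 'ae' test route;
        # skip the N x N solve otherwise
        if config.mode == "akbls":
            basis = fk.sample_rff_basis(
                layer.n_total, config.m_fourier, sigma, seed=config.seed + 1
            )
            H = fk.rff_transform(basis, Z)
            omega = fk.approx_gram(H, H)
            kernel = fk.KernelBlock(
                mode="approximate",
                sigma=sigma,
                C=config.C,
                W_omega=(
                    fk.fit_kernel_ae(Z, omega, config.C)
                    if config.test_kernel == "ae"
                    else None
                ),
                basis=basis,
                H_train=H,
            )
        else:  # kbls
            omega = fk.exact_rbf_gram(Z, Z, sigma)
            kernel = fk.KernelBlock(
                mode="exact",
                sigma=sigma,
                C=config.C,
                W_omega=(
                    fk.fit_kernel_ae(Z, omega, config.C)
                    if config.test_kernel == "ae"
                    else None
                ),
                Z_train=Z,
            )
        block = omega

    A = np.hstack([Z, block])
    W = solve_ridge_output(A, ys, config.gamma)
    return SoftSensorModel(
        config=config,
        scaler=scaler,
        layer=layer,
        W=W,
        n_train=X.shape[0],
        variable_names=names,
        kernel=kernel,
        enhancement=enhancement,
    )


def predict(model: SoftSensorModel, X_new) -> np.ndarray:
    """Functional alias for :meth:`SoftSensorModel.predict`."""
    return model.predict(X_new)
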