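"""Multivariate prediction pipelines for brain-wide association analyses.

Two model families are provided, mirroring the two pipelines commonly
compared for connectome-based prediction of continuous phenotypes:

``pca_svr``
    Standardize features, project onto principal components retaining a
    target fraction of variance (fitted on training data only), then linear
    support-vector regression on the component scores.

``ridge``
    Standardize features, then ridge regression with a fixed shrinkage
    parameter (default 1, the conventional default for partial-correlation
    connectivity features).

All preprocessing (standardization, PCA basis) is learned strictly from the
training partition; :func:`cross_validated_predictions` refits the whole
pipeline inside every fold so out-of-fold predictions are leakage-free.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .errors import ConfigError, DataError, FitError, NumericalError, SizeError

__all__ = [
    "ModelSpec",
    "FittedModel",
    "fit",
    "predict",
    "cross_validated_predictions",
    "partial_correlation_matrix",
    "vectorize_edges",
]

ModelFamily = Literal["ridge", "pca_svr"]


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a prediction pipeline.

    Hyperparameters not consulted by the chosen family are ignored but kept,
    so a spec round-trips through configuration files unchanged.
    """

    family: ModelFamily = "ridge"
    ridge_shrinkage: float = 1.0
    pca_variance_kept: float = 0.95
    pca_max_components: int = 250
    svr_c: float = 1.0
    svr_epsilon: float = 0.1
    svr_tol: float = 0.1
    standardize_features: bool = True

    def validate(self) -> None:
        if self.family not in ("ridge", "pca_svr"):
            raise ConfigError(f"family must be 'ridge' or 'pca_svr', got {self.family!r}")
        if self.ridge_shrinkage <= 0:
            raise ConfigError(f"ridge_shrinkage must be positive, got {self.ridge_shrinkage}")
        if not (0.0 < self.pca_variance_kept <= 1.0):
            raise ConfigError(
                f"pca_variance_kept must lie in (0, 1], got {self.pca_variance_kept}"
            )
        if self.pca_max_components < 1:
            raise ConfigError(
                f"pca_max_components must be positive, got {self.pca_max_components}"
            )
        if self.svr_c <= 0 or self.svr_epsilon < 0:
            raise ConfigError("svr_c must be positive and svr_epsilon nonnegative")
        if self.svr_tol <= 0:
            raise ConfigError(f"svr_tol must be positive, got {self.svr_tol}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelSpec fields: {sorted(unknown)}")
        spec = cls(**d)
        spec.validate()
        return spec


class _VarianceCappedPCA(BaseEstimator, TransformerMixin):
    """PCA keeping the fewest components reaching a variance target.

    The component count is additionally capped at ``max_components`` and at
    n_train - 1; the cap binds when the variance target is unreachable.
    """

    def __init__(self, variance_kept: float = 0.95, max_components: int = 250):
        self.variance_kept = variance_kept
        self.max_components = max_components

    def fit(self, X, y=None):
        n, p = X.shape
        limit = max(1, min(n - 1, p, self.max_components))
        self.pca_ = PCA(n_components=limit)
        self.pca_.fit(X)
        cum = np.cumsum(self.pca_.explained_variance_ratio_)
        reached = np.nonzero(cum >= self.variance_kept)[0]
        self.n_components_ = int(reached[0]) + 1 if reached.size else limit
        return self

    def transform(self, X):
        return self.pca_.transform(X)[:, : self.n_components_]


@dataclass
class FittedModel:
    """A trained pipeline; prediction is a pure function of its stored state."""

    spec: ModelSpec
    pipeline: Pipeline = field(repr=False)
    n_train: int
    p_train: int
    feature_names: np.ndarray | None = field(default=None, repr=False)

    @property
    def n_components(self) -> int | None:
        """Number of principal components retained (pca_svr only)."""
        if self.spec.family != "pca_svr":
            return None
        return self.pipeline.named_steps["pca"].n_components_

    def metadata(self) -> dict:
        md = self.spec.to_dict() | {"n_train": self.n_train, "p_train": self.p_train}
        if self.spec.family == "pca_svr":
            md["n_components"] = self.n_components
        return md

    def weight_table(self) -> pd.DataFrame:
        """Linear readout weights mapped back to the original feature space."""
        if self.spec.family == "ridge":
            beta = self.pipeline.named_steps["model"].coef_.ravel()
        else:
            pca = self.pipeline.named_steps["pca"]
            svr = self.pipeline.named_steps["model"]
            comp = pca.pca_.components_[: pca.n_components_]
            beta = (svr.coef_.ravel() @ comp).ravel()
        if self.spec.standardize_features:
            beta = beta / self.pipeline.named_steps["scale"].scale_
        names = (
            self.feature_names
            if self.feature_names is not None
            else [f"f{j}" for j in range(len(beta))]
        )
        return pd.DataFrame({"feature": names, "weight": beta})


def _build_pipeline(spec: ModelSpec) -> Pipeline:
    steps: list[tuple] = []
    if spec.standardize_features:
        steps.append(("scale", StandardScaler()))
    if spec.family == "ridge":
        steps.append(("model", Ridge(alpha=spec.ridge_shrinkage)))
    else:
        steps.append(
            ("pca", _VarianceCappedPCA(spec.pca_variance_kept, spec.pca_max_components))
        )
        # tol is looser than the library default: in noise-dominated fits the
        # SMO solver otherwise spends seconds polishing KKT conditions that
        # change the prediction-outcome correlation by < 0.01
        steps.append(
            (
                "model",
                SVR(
                    kernel="linear",
                    C=spec.svr_c,
                    epsilon=spec.svr_epsilon,
                    tol=spec.svr_tol,
                ),
            )
        )
    return Pipeline(steps)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise DataError("X must be a 2-D samples x features matrix")
    if y.shape[0] != X.shape[0]:
        raise DataError(f"y length {y.shape[0]} does not match {X.shape[0]} samples")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise DataError("training data contain missing or non-finite values")
    if X.shape[0] < 4:
        raise SizeError(f"at least 4 training samples required, got {X.shape[0]}")
    if np.ptp(y) == 0.0:
        raise FitError("outcome is constant; prediction-outcome correlation undefined")
    return X, y


def fit(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: np.ndarray | None = None,
) -> FittedModel:
    """Train the pipeline described by ``spec`` on (X, y)."""
    spec.validate()
    X, y = _check_xy(X, y)
    pipe = _build_pipeline(spec)
    pipe.fit(X, y)
    return FittedModel(
        spec=spec,
        pipeline=pipe,
        n_train=X.shape[0],
        p_train=X.shape[1],
        feature_names=feature_names,
    )


def predict(model: FittedModel, X: np.ndarray) -> np.ndarray:
    """Apply a fitted pipeline; deterministic given the stored state."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    if X.shape[1] != model.p_train:
        raise DataError(
            f"feature count {X.shape[1]} does not match training count {model.p_train}"
        )
    return np.asarray(model.pipeline.predict(X), dtype=float)


def cross_validated_predictions(
    spec: ModelSpec,
    X: np.ndarray,
    y: np.ndarray,
    k_folds: int = 10,
    seed: int = 0,
    n_repeats: int = 1,
) -> np.ndarray:
    """Out-of-fold predictions from seeded k-fold cross-validation.

    The entire pipeline (standardization, PCA, regressor) is refit on each
    fold's complement, so every prediction comes from a model that never saw
    that sample.  With ``n_repeats > 1`` the fold partition is reshuffled and
    out-of-fold predictions are averaged across repetitions.
    """
    spec.validate()
    X, y = _check_xy(X, y)
    n = X.shape[0]
    if not (2 <= k_folds <= n):
        raise SizeError(f"k_folds must lie in [2, n={n}], got {k_folds}")
    preds = np.zeros(n)
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        kf = KFold(n_splits=k_folds, shuffle=True, random_state=int(rng.integers(2**31)))
        for train_idx, test_idx in kf.split(X):
            pipe = _build_pipeline(spec)  # fresh pipeline per fold
            pipe.fit(X[train_idx], y[train_idx])
            preds[test_idx] += pipe.predict(X[test_idx])
    return preds / n_repeats


# ---------------------------------------------------------------------------
# Partial-correlation features from node timeseries


def partial_correlation_matrix(
    samples: np.ndarray, regularization: float = 0.1
) -> np.ndarray:
    """Partial correlations between nodes from a timepoints-by-nodes matrix.

    The sample covariance is (optionally) ridge-regularized by adding
    ``regularization * mean(diag(cov))`` to the diagonal before inversion;
    entry (i, j) of the result is ``-omega_ij / sqrt(omega_ii * omega_jj)``
    where omega is the (regularized) precision matrix.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 3:
        raise SizeError("samples must be a 2-D matrix with at least 3 timepoints")
    if regularization < 0:
        raise ConfigError(f"regularization must be nonnegative, got {regularization}")
    cov = np.cov(samples, rowvar=False)
    if regularization > 0:
        cov = cov + regularization * np.mean(np.diag(cov)) * np.eye(cov.shape[0])
    try:
        omega = np.linalg.inv(cov)
    except np.linalg.LinAlgError as exc:
        raise NumericalError(
            "covariance matrix is singular; pass a positive regularization"
        ) from exc
    if regularization == 0.0 and np.linalg.cond(cov) > 1e12:
        raise NumericalError(
            "covariance matrix is near-singular; pass a positive regularization"
        )
    d = np.sqrt(np.diag(omega))
    pc = -omega / np.outer(d, d)
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(pc, 1.0)
    return pc


def vectorize_edges(matrix: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major.

    This is the standard vectorization of a network matrix into a feature
    vector of length d(d-1)/2, in the stable order
    (0,1), (0,2), ..., (0,d-1), (1,2), ...
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise DataError("input must be a square matrix")
    if np.max(np.abs(matrix - matrix.T)) > tol:
        raise DataError(f"matrix is asymmetric beyond tolerance {tol}")
    iu = np.triu_indices(matrix.shape[0], k=1)
    return matrix[iu]
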