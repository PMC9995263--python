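"""Effect-size estimation and inference for prediction-outcome correlations.

The effect size of a multivariate brain-wide association model is the Pearson
correlation r between its predictions and the observed outcome.  Two
estimation methods are distinguished throughout:

``in_sample``
    r computed on the very samples used to train the model.  For flexible
    models this is inflated by overfitting and is not a valid effect-size
    estimate.

``cv``
    r between pooled out-of-fold predictions and outcomes within the same
    sample.  This is unbiased (slightly pessimistic at small n, because each
    fold model trains on fewer samples).

Significance uses the exact t transform of r; confidence intervals use the
Fisher z approximation.  :func:`permutation_null` quantifies the estimator
bias directly by predicting permuted outcomes: the in-sample estimator stays
far from zero while the cross-validated estimator is centred on zero.

Sign conventions: p-values default to two-sided.  Where an analysis needs a
directional "positive result" (a significant *positive* correlation), the
one-sided option tests r > 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ConstantInputError, SizeError
from .models import ModelSpec, cross_validated_predictions, fit, predict
from .synthetic import LabeledDataset

__all__ = [
    "EffectEstimate",
    "NullDistributionSummary",
    "prediction_outcome_r",
    "r_p_value",
    "critical_r",
    "fisher_ci",
    "effect_estimate",
    "permutation_null",
]

Sidedness = Literal["one_sided", "two_sided"]
EstimatorMethod = Literal["in_sample", "cv"]


@dataclass(frozen=True)
class EffectEstimate:
    """A prediction-outcome correlation with its inferential context."""

    r: float
    n: int
    method: EstimatorMethod
    p_value: float
    sidedness: Sidedness
    ci_low: float
    ci_high: float
    k_folds: int | None = None


@dataclass
class NullDistributionSummary:
    """Permuted-outcome null distribution of an estimator across sample sizes.

    ``table`` has one row per sample size: (estimator, n, mean_r, lo, hi,
    n_perm) where lo/hi are the 2.5/97.5 permutation percentiles.  ``draws``
    keeps the raw per-permutation correlations for downstream tests.
    """

    method: EstimatorMethod
    table: pd.DataFrame
    draws: dict[int, np.ndarray] = field(default_factory=dict, repr=False)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def prediction_outcome_r(predictions: np.ndarray, outcomes: np.ndarray) -> float:
    """Pearson correlation between predictions and observed outcomes."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    outcomes = np.asarray(outcomes, dtype=float).ravel()
    if predictions.shape != outcomes.shape:
        raise SizeError("predictions and outcomes must have equal length")
    if predictions.size < 3:
        raise SizeError(f"need at least 3 pairs, got {predictions.size}")
    if np.ptp(predictions) == 0.0 or np.ptp(outcomes) == 0.0:
        raise ConstantInputError(
            "correlation undefined: predictions or outcomes are constant"
        )
    r = float(np.corrcoef(predictions, outcomes)[0, 1])
    return float(np.clip(r, -1.0, 1.0))


def r_p_value(r: float, n: int, sidedness: Sidedness = "two_sided") -> float:
    """p-value for a Pearson correlation via t = r sqrt((n-2)/(1-r^2)).

    The one-sided version tests r > 0.  At |r| = 1 the statistic is on the
    boundary and p = 0 is returned with a warning.
    """
    _check_rn(r, n, sidedness)
    if abs(r) == 1.0:
        warnings.warn("|r| = 1 is on the boundary; p-value is exactly 0", stacklevel=2)
        return 0.0 if sidedness == "two_sided" or r > 0 else 1.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    if sidedness == "two_sided":
        return float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return float(stats.t.sf(t, df=n - 2))


def critical_r(n: int, alpha: float = 0.05, sidedness: Sidedness = "two_sided") -> float:
    """Smallest nonnegative r significant at level alpha for sample size n.

    Exact inversion of the t transform; monotone decreasing in n.
    """
    if not (0.0 < alpha < 1.0):
        raise ConfigError(f"alpha must lie in (0, 1), got {alpha}")
    _check_rn(0.0, n, sidedness)
    q = alpha / 2.0 if sidedness == "two_sided" else alpha
    t = stats.t.isf(q, df=n - 2)
    return float(t / np.sqrt(n - 2 + t * t))


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval tanh(atanh(r) +/- z / sqrt(n-3))."""
    if not (0.0 < level < 1.0):
        raise ConfigError(f"level must lie in (0, 1), got {level}")
    if n < 4:
        raise SizeError(f"n must be at least 4, got {n}")
    if abs(r) >= 1.0:
        raise ConstantInputError("|r| = 1 gives a degenerate Fisher-z interval")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z / np.sqrt(n - 3)
    zr = np.arctanh(r)
    return float(np.tanh(zr - half)), float(np.tanh(zr + half))


def effect_estimate(
    predictions: np.ndarray,
    outcomes: np.ndarray,
    method: EstimatorMethod,
    sidedness: Sidedness = "two_sided",
    level: float = 0.95,
    k_folds: int | None = None,
) -> EffectEstimate:
    """Bundle r, its p-value and Fisher-z interval into an EffectEstimate."""
    r = prediction_outcome_r(predictions, outcomes)
    n = len(np.asarray(outcomes).ravel())
    lo, hi = fisher_ci(r, n, level) if abs(r) < 1.0 else (r, r)
    return EffectEstimate(
        r=r,
        n=n,
        method=method,
        p_value=r_p_value(r, n, sidedness),
        sidedness=sidedness,
        ci_low=lo,
        ci_high=hi,
        k_folds=k_folds,
    )


def permutation_null(
    spec: ModelSpec,
    ds: LabeledDataset,
    estimator: EstimatorMethod,
    n_grid: list[int],
    n_permutations: int = 100,
    seed: int = 0,
    k_folds: int = 10,
) -> NullDistributionSummary:
    """Null distribution of an effect-size estimator under permuted outcomes.

    For each sample size in ``n_grid``: draw a subsample without replacement,
    permute its outcomes (severing any feature-outcome link), compute the
    estimator's r, and repeat ``n_permutations`` times.  The summary reports
    the mean null r with 2.5/97.5 percentile bounds.

    A systematically positive mean exposes estimator bias; the cross-validated
    estimator must be statistically indistinguishable from zero.
    """
    if estimator not in ("in_sample", "cv"):
        raise ConfigError(f"estimator must be 'in_sample' or 'cv', got {estimator!r}")
    if n_permutations < 20:
        raise ConfigError(f"n_permutations must be at least 20, got {n_permutations}")
    spec.validate()
    rows = []
    draws: dict[int, np.ndarray] = {}
    for n in n_grid:
        if n > ds.n_samples:
            raise SizeError(f"grid size {n} exceeds dataset size {ds.n_samples}")
        rs = np.empty(n_permutations)
        for j in range(n_permutations):
            ss = np.random.SeedSequence([seed, n, j])
            rng = np.random.default_rng(ss)
            idx = rng.choice(ds.n_samples, size=n, replace=False)
            X = ds.features[idx]
            y_perm = rng.permutation(ds.outcome[idx])
            if estimator == "in_sample":
                model = fit(spec, X, y_perm)
                preds = predict(model, X)
            else:
                preds = cross_validated_predictions(
                    spec, X, y_perm, k_folds=k_folds, seed=int(rng.integers(2**31))
                )
            rs[j] = prediction_outcome_r(preds, y_perm)
        draws[n] = rs
        lo, hi = np.percentile(rs, [2.5, 97.5])
        rows.append(
            {
                "estimator": estimator,
                "n": n,
                "mean_r": float(np.mean(rs)),
                "lo": float(lo),
                "hi": float(hi),
                "n_perm": n_permutations,
            }
        )
    return NullDistributionSummary(
        method=estimator, table=pd.DataFrame(rows), draws=draws
    )


def _check_rn(r: float, n: int, sidedness: Sidedness) -> None:
    if not -1.0 <= r <= 1.0:
        raise ConfigError(f"r must lie in [-1, 1], got {r}")
    if n < 4:
        raise SizeError(f"n must be at least 4, got {n}")
    if sidedness not in ("one_sided", "two_sided"):
        raise ConfigError(f"sidedness must be 'one_sided' or 'two_sided', got {sidedness!r}")
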