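"""Discovery/replication bootstrap benchmark.

The central experiment: at each sample size n, repeatedly draw two *disjoint*
subsamples — a discovery sample on which the model is trained (with both an
in-sample and a cross-validated effect-size estimate) and a replication
sample on which the frozen discovery-trained model is evaluated once.  From
the resulting replicate records the benchmark derives, per sample size:

- mean effect-size inflation, r_discovery - r_replication, separately for the
  in-sample (non-CV) and cross-validated discovery estimates;
- in-sample power: the fraction of replicates whose cross-validated discovery
  effect is a positive result;
- P_rep, the out-of-sample replication probability: among discovery-positive
  replicates, the fraction whose frozen model is also a positive result in
  the replication sample;
- conditional inflation: mean CV inflation restricted to a significance
  condition, emulating the winner's curse / publication-bias selection.

A "positive result" is directional — a significant positive prediction-
outcome correlation.  By default significance is assessed with a one-sided
test of r > 0 at level alpha, which makes the discovery-positive rate equal
alpha under the null; a two-sided test combined with the r > 0 requirement
(rate alpha/2 under a symmetric null) is available via ``sidedness``.

Two p-value constructions are available for the cross-validated discovery
effect.  The parametric t transform treats the out-of-fold predictions as
fixed, which they are not: every prediction depends on the other folds'
outcomes, so prediction errors are correlated within folds and the pooled
CV r is overdispersed relative to the t null — the parametric test is
anti-conservative for flexible models.  The default therefore calibrates the
test by permutation: a permuted-outcome null distribution of the CV r is
computed once per sample size and the replicate's p-value is its rank in
that null.  Replication p-values are always parametric, which is exact
there: the frozen discovery model is independent of the replication sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .errors import ConfigError, FitError, SizeError
from .inference import (
    EffectEstimate,
    Sidedness,
    effect_estimate,
    prediction_outcome_r,
    r_p_value,
)
from .models import ModelSpec, cross_validated_predictions, fit, predict
from .synthetic import LabeledDataset

__all__ = [
    "BenchmarkConfig",
    "ReplicateRecord",
    "BenchmarkTable",
    "draw_pair",
    "run_replicate",
    "run_benchmark",
    "aggregate",
    "min_n",
    "full_sample_effect",
    "records_to_frame",
    "permutation_p_value",
]

logger = logging.getLogger(__name__)

Conditioning = Literal["none", "discovery_significant", "replication_significant", "both"]

METRICS = (
    "mean_inflation_insample",
    "mean_inflation_cv",
    "power",
    "p_rep",
    "conditional_inflation",
)


@dataclass(frozen=True)
class BenchmarkConfig:
    """Configuration of a full benchmark run."""

    n_grid: tuple[int, ...] = (25, 50, 75, 100, 150, 200, 300, 400, 500)
    n_bootstrap: int = 100
    alpha: float = 0.05
    model: ModelSpec = field(default_factory=ModelSpec)
    k_folds: int = 10
    conditioning: Conditioning = "discovery_significant"
    sidedness: Sidedness = "one_sided"
    cv_p_method: Literal["permutation", "parametric"] = "permutation"
    n_null_permutations: int = 200
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "n_grid", tuple(int(n) for n in self.n_grid))

    def validate(self, ds: LabeledDataset | None = None) -> None:
        if len(self.n_grid) == 0 or list(self.n_grid) != sorted(set(self.n_grid)):
            raise ConfigError("n_grid must be a nonempty increasing sequence of integers")
        if min(self.n_grid) < 8:
            raise ConfigError(f"n_grid entries must be at least 8, got {min(self.n_grid)}")
        if self.n_bootstrap < 1:
            raise ConfigError(f"n_bootstrap must be positive, got {self.n_bootstrap}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.k_folds < 2:
            raise ConfigError(f"k_folds must be at least 2, got {self.k_folds}")
        if self.conditioning not in (
            "none",
            "discovery_significant",
            "replication_significant",
            "both",
        ):
            raise ConfigError(f"unknown conditioning mode {self.conditioning!r}")
        if self.sidedness not in ("one_sided", "two_sided"):
            raise ConfigError(f"unknown sidedness {self.sidedness!r}")
        if self.cv_p_method not in ("permutation", "parametric"):
            raise ConfigError(f"unknown cv_p_method {self.cv_p_method!r}")
        if self.cv_p_method == "permutation" and self.n_null_permutations < 20:
            raise ConfigError(
                f"n_null_permutations must be at least 20, got {self.n_null_permutations}"
            )
        self.model.validate()
        if ds is not None and 2 * max(self.n_grid) > ds.n_samples:
            raise SizeError(
                f"disjoint discovery/replication pairs of size {max(self.n_grid)} "
                f"need at least {2 * max(self.n_grid)} samples, dataset has {ds.n_samples}"
            )


@dataclass(frozen=True)
class ReplicateRecord:
    """One bootstrap replicate at one sample size."""

    n: int
    replicate_index: int
    r_disc_insample: float
    r_disc_cv: float
    p_disc_cv: float
    r_rep: float
    p_rep_value: float
    seed_used: int


def records_to_frame(records: Iterable[ReplicateRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


class BenchmarkTable:
    """Per-sample-size aggregate metrics with percentile intervals.

    Stored as a tidy frame with columns (n, metric, value, lo, hi, subset_n);
    ``subset_n`` is the number of replicates the metric was computed over
    (the conditioning subset for conditional metrics).  Undefined conditional
    metrics are NaN with subset_n 0, never a silent zero.
    """

    def __init__(self, frame: pd.DataFrame, conditioning: Conditioning):
        self.frame = frame.reset_index(drop=True)
        self.conditioning = conditioning

    @property
    def n_grid(self) -> list[int]:
        return sorted(self.frame["n"].unique())

    def value(self, n: int, metric: str) -> float:
        sel = self.frame[(self.frame["n"] == n) & (self.frame["metric"] == metric)]
        if sel.empty:
            raise KeyError(f"no entry for n={n}, metric={metric!r}")
        return float(sel["value"].iloc[0])

    def metric_series(self, metric: str) -> pd.Series:
        sel = self.frame[self.frame["metric"] == metric].set_index("n")["value"]
        return sel.sort_index()

    def to_csv(self, path: str | Path) -> None:
        self.frame.to_csv(path, index=False)


def draw_pair(
    ds: LabeledDataset, n: int, seed: int | np.random.SeedSequence
) -> tuple[LabeledDataset, LabeledDataset]:
    """Draw disjoint discovery and replication subsamples of size n each.

    Sampling is without replacement within the replicate, so the replication
    sample is fully independent of discovery; across replicates the same
    individuals may recur (bootstrap over subsamples).
    """
    if 2 * n > ds.n_samples:
        raise SizeError(
            f"cannot draw two disjoint subsamples of size {n} from {ds.n_samples} "
            f"samples (limit {ds.n_samples // 2})"
        )
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n_samples)
    return ds.subset(perm[:n]), ds.subset(perm[n : 2 * n])


def _replicate_seed_sequence(seed: int, n: int, replicate_index: int) -> np.random.SeedSequence:
    # deterministic per (config seed, n, replicate); independent of B and of
    # execution order, which makes replicates parallelizable and extendable;
    # the leading 0 separates this stream family from the null-draw family
    return np.random.SeedSequence([seed, 0, n, replicate_index])


def _null_seed(seed: int) -> int:
    # a distinct deterministic stream family for the shared permutation nulls
    return int(np.random.SeedSequence([seed, 1]).generate_state(1)[0])


def permutation_p_value(
    r: float, null_draws: np.ndarray, sidedness: Sidedness = "one_sided"
) -> float:
    """Rank-based p-value of r in a permutation null distribution.

    Uses the add-one estimator (1 + #{null at least as extreme}) / (1 + N);
    one-sided tests r > 0.
    """
    null_draws = np.asarray(null_draws, dtype=float)
    if sidedness == "one_sided":
        extreme = np.sum(null_draws >= r)
    else:
        extreme = np.sum(np.abs(null_draws) >= abs(r))
    return float((1 + extreme) / (1 + null_draws.size))


def run_replicate(
    ds: LabeledDataset,
    n: int,
    model: ModelSpec,
    k_folds: int = 10,
    alpha: float = 0.05,
    seed: int | np.random.SeedSequence = 0,
    sidedness: Sidedness = "one_sided",
    replicate_index: int = 0,
    cv_null_draws: np.ndarray | None = None,
) -> ReplicateRecord:
    """One discovery/replication draw.

    Trains on the discovery subsample and records (i) the in-sample (non-CV)
    effect size, (ii) the cross-validated effect size from out-of-fold
    predictions, and (iii) the replication effect size of the single model
    refit on the whole discovery subsample and applied unchanged to the
    replication subsample.

    When ``cv_null_draws`` (a permuted-outcome null sample of the CV r at
    this n) is provided, the discovery p-value is its permutation rank;
    otherwise the parametric t transform is used.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seed_used = int(ss.generate_state(1)[0])
    ss_pair, ss_cv = ss.spawn(2)
    disc, rep = draw_pair(ds, n, ss_pair)
    try:
        model_full = fit(model, disc.features, disc.outcome)
        r_insample = prediction_outcome_r(
            predict(model_full, disc.features), disc.outcome
        )
        cv_preds = cross_validated_predictions(
            model,
            disc.features,
            disc.outcome,
            k_folds=min(k_folds, n),
            seed=int(np.random.default_rng(ss_cv).integers(2**31)),
        )
        r_cv = prediction_outcome_r(cv_preds, disc.outcome)
        rep_preds = predict(model_full, rep.features)
        r_rep = prediction_outcome_r(rep_preds, rep.outcome)
    except FitError as exc:
        raise FitError(f"replicate (n={n}, index={replicate_index}) invalid: {exc}") from exc
    if cv_null_draws is not None:
        p_disc = permutation_p_value(r_cv, cv_null_draws, sidedness)
    else:
        p_disc = r_p_value(r_cv, n, sidedness)
    return ReplicateRecord(
        n=n,
        replicate_index=replicate_index,
        r_disc_insample=r_insample,
        r_disc_cv=r_cv,
        p_disc_cv=p_disc,
        r_rep=r_rep,
        p_rep_value=r_p_value(r_rep, n, sidedness),
        seed_used=seed_used,
    )


def run_benchmark(
    ds: LabeledDataset, cfg: BenchmarkConfig, n_jobs: int = 1
) -> list[ReplicateRecord]:
    """Run the full grid of bootstrap replicates.

    Replicate seeds derive deterministically from (cfg.seed, n, index), so the
    output is identical regardless of execution order or job count, and the
    first B records of a larger run coincide with a smaller run.  Invalid
    replicates (degenerate subsamples) are excluded and logged; the run aborts
    if more than 10% of replicates are invalid.
    """
    cfg.validate(ds)

    nulls: dict[int, np.ndarray] = {}
    if cfg.cv_p_method == "permutation":
        # one shared permuted-outcome null of the CV r per grid n; computed
        # before the replicates so every replicate's p-value is a rank in it
        from .inference import permutation_null

        summary = permutation_null(
            cfg.model,
            ds,
            "cv",
            n_grid=list(cfg.n_grid),
            n_permutations=cfg.n_null_permutations,
            seed=_null_seed(cfg.seed),
            k_folds=cfg.k_folds,
        )
        nulls = summary.draws

    def one(n: int, b: int) -> ReplicateRecord | None:
        try:
            return run_replicate(
                ds,
                n,
                cfg.model,
                k_folds=cfg.k_folds,
                alpha=cfg.alpha,
                seed=_replicate_seed_sequence(cfg.seed, n, b),
                sidedness=cfg.sidedness,
                replicate_index=b,
                cv_null_draws=nulls.get(n),
            )
        except FitError as exc:
            logger.warning("excluding invalid replicate: %s", exc)
            return None

    tasks = [(n, b) for n in cfg.n_grid for b in range(cfg.n_bootstrap)]
    if n_jobs == 1:
        results = [one(n, b) for n, b in tasks]
    else:
        results = Parallel(n_jobs=n_jobs)(delayed(one)(n, b) for n, b in tasks)
    records = [r for r in results if r is not None]
    n_invalid = len(results) - len(records)
    if n_invalid > 0.1 * len(results):
        raise FitError(
            f"{n_invalid}/{len(results)} replicates invalid; aborting benchmark"
        )
    if n_invalid:
        logger.warning("excluded %d invalid replicates", n_invalid)
    return sorted(records, key=lambda r: (r.n, r.replicate_index))


def _positive(r: np.ndarray, p: np.ndarray, alpha: float) -> np.ndarray:
    return (p <= alpha) & (r > 0)


def _condition_mask(df: pd.DataFrame, conditioning: Conditioning, alpha: float) -> np.ndarray:
    disc = _positive(df["r_disc_cv"].to_numpy(), df["p_disc_cv"].to_numpy(), alpha)
    rep = _positive(df["r_rep"].to_numpy(), df["p_rep_value"].to_numpy(), alpha)
    if conditioning == "none":
        return np.ones(len(df), dtype=bool)
    if conditioning == "discovery_significant":
        return disc
    if conditioning == "replication_significant":
        return rep
    return disc & rep


def _percentile_ci(
    values: np.ndarray,
    stat,
    rng: np.random.Generator,
    n_boot: int = 1000,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile bootstrap interval for a statistic of the replicate values."""
    if len(values) == 0:
        return (float("nan"), float("nan"))
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot = np.array([stat(values[row]) for row in idx])
    boot = boot[np.isfinite(boot)]
    if boot.size == 0:
        return (float("nan"), float("nan"))
    q = 100 * (1 - level) / 2
    lo, hi = np.percentile(boot, [q, 100 - q])
    return float(lo), float(hi)


def aggregate(
    records: Iterable[ReplicateRecord], cfg: BenchmarkConfig, n_boot: int = 1000
) -> BenchmarkTable:
    """Aggregate replicate records into the per-sample-size metric table.

    Intervals are 95% percentile bootstrap over replicates, seeded from
    ``cfg.seed`` so aggregation is deterministic.
    """
    df = records_to_frame(list(records))
    if df.empty:
        raise ConfigError("no replicate records to aggregate")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2**20]))
    rows = []
    for n, grp in df.groupby("n", sort=True):
        disc_pos = _positive(
            grp["r_disc_cv"].to_numpy(), grp["p_disc_cv"].to_numpy(), cfg.alpha
        )
        rep_pos = _positive(
            grp["r_rep"].to_numpy(), grp["p_rep_value"].to_numpy(), cfg.alpha
        )
        infl_ins = (grp["r_disc_insample"] - grp["r_rep"]).to_numpy()
        infl_cv = (grp["r_disc_cv"] - grp["r_rep"]).to_numpy()
        cond = _condition_mask(grp, cfg.conditioning, cfg.alpha)

        def add(metric: str, values: np.ndarray, stat, subset_n: int) -> None:
            value = stat(values) if subset_n else float("nan")
            lo, hi = _percentile_ci(values, stat, rng, n_boot=n_boot)
            rows.append(
                {
                    "n": int(n),
                    "metric": metric,
                    "value": float(value),
                    "lo": lo,
                    "hi": hi,
                    "subset_n": int(subset_n),
                }
            )

        add("mean_inflation_insample", infl_ins, np.mean, len(grp))
        add("mean_inflation_cv", infl_cv, np.mean, len(grp))
        add("power", disc_pos.astype(float), np.mean, len(grp))
        # P_rep conditions on discovery positivity: bootstrap resamples the
        # (disc_pos, rep_pos) pairs and recomputes the conditional fraction
        if disc_pos.any():
            value = float(rep_pos[disc_pos].mean())
            idx = rng.integers(0, len(grp), size=(n_boot, len(grp)))
            with np.errstate(invalid="ignore"):
                boot = np.where(
                    disc_pos[idx].any(axis=1),
                    (disc_pos[idx] & rep_pos[idx]).sum(axis=1)
                    / np.maximum(disc_pos[idx].sum(axis=1), 1),
                    np.nan,
                )
            boot = boot[np.isfinite(boot)]
            lo, hi = (
                (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
                if boot.size
                else (float("nan"), float("nan"))
            )
        else:
            value, lo, hi = float("nan"), float("nan"), float("nan")
        rows.append(
            {
                "n": int(n),
                "metric": "p_rep",
                "value": value,
                "lo": lo,
                "hi": hi,
                "subset_n": int(disc_pos.sum()),
            }
        )
        add(
            "conditional_inflation",
            infl_cv[cond],
            np.mean,
            int(cond.sum()),
        )
    return BenchmarkTable(pd.DataFrame(rows), conditioning=cfg.conditioning)


def min_n(
    table: BenchmarkTable, metric: Literal["power", "p_rep"], threshold: float
) -> int | str:
    """Smallest grid sample size reaching the threshold, or a '>max' sentinel.

    No interpolation between grid points: the first grid n whose metric value
    meets the threshold is returned.  When no grid point qualifies the
    sentinel string ``">MAX"`` is returned, mirroring above-grid arrow bars in
    sample-size charts.  A non-monotone metric profile is logged but the
    first-crossing rule still applies.
    """
    if metric not in ("power", "p_rep"):
        raise ConfigError(f"metric must be 'power' or 'p_rep', got {metric!r}")
    series = table.metric_series(metric)
    if len(series) < 2:
        raise ConfigError("table must cover at least 2 grid sample sizes")
    values = series.to_numpy()
    finite = values[np.isfinite(values)]
    if len(finite) >= 2 and np.any(np.diff(finite) < 0):
        logger.warning("metric %s is non-monotone across the grid", metric)
    for n, v in series.items():
        if np.isfinite(v) and v >= threshold:
            return int(n)
    return f">{int(series.index.max())}"


def full_sample_effect(
    ds: LabeledDataset,
    model: ModelSpec,
    k_folds: int = 10,
    seed: int = 0,
    sidedness: Sidedness = "two_sided",
) -> EffectEstimate:
    """Cross-validated effect estimate on the entire dataset."""
    preds = cross_validated_predictions(
        model, ds.features, ds.outcome, k_folds=k_folds, seed=seed
    )
    return effect_estimate(
        preds, ds.outcome, method="cv", sidedness=sidedness, k_folds=k_folds
    )
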