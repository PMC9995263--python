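"""End-to-end experiment driver: data, benchmark, nulls, tables, log.

One call of :func:`run_experiment` produces a self-describing output
directory whose numeric contents are bit-for-bit reproducible from the
configuration alone:

- ``records.csv``      one row per bootstrap replicate
- ``metrics.csv``      tidy per-sample-size metric table with intervals
- ``min_n_summary.csv``  smallest grid n reaching the power / P_rep threshold
- ``null_distribution.csv``  permuted-outcome nulls (when requested)
- ``metadata.yaml``    config echo, effective seeds, library versions
- ``run.log``          human-readable narrative of the run

A failed run leaves an ``INCOMPLETE`` marker in the directory so partial
output can never be mistaken for a finished experiment.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path

import pandas as pd
import yaml

from .bench import aggregate, min_n, records_to_frame, run_benchmark
from .config import ExperimentConfig
from .inference import permutation_null

__all__ = ["run_experiment"]

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.17g"


def run_experiment(
    config: ExperimentConfig, n_jobs: int = 1, out_dir: Path | None = None
) -> dict[str, Path]:
    """Run the configured experiment and write all artifacts.

    Returns a mapping from artifact name to written path.  Validation happens
    before any computation, so an infeasible configuration fails fast.
    """
    out = Path(out_dir) if out_dir is not None else Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "INCOMPLETE"
    marker.write_text("experiment started and not yet finished\n")
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    try:
        t0 = time.perf_counter()
        ds = config.load_data()
        cfg = config.benchmark
        cfg.validate(ds)  # fail fast before any model fitting
        log(f"dataset: {ds.n_samples} samples x {ds.n_features} features")
        log(f"benchmark config: {cfg}")

        artifacts: dict[str, Path] = {}
        records = run_benchmark(ds, cfg, n_jobs=n_jobs)
        rec_df = records_to_frame(records)
        artifacts["records"] = out / "records.csv"
        rec_df.to_csv(artifacts["records"], index=False, float_format=FLOAT_FORMAT)
        log(f"benchmark: {len(records)} replicate records across grid {cfg.n_grid}")

        table = aggregate(records, cfg)
        artifacts["metrics"] = out / "metrics.csv"
        table.frame.to_csv(artifacts["metrics"], index=False, float_format=FLOAT_FORMAT)

        rows = []
        for metric in ("power", "p_rep"):
            result = min_n(table, metric, config.min_n_threshold)
            rows.append(
                {
                    "metric": metric,
                    "threshold": config.min_n_threshold,
                    "min_n": result,
                }
            )
            log(f"min n for {metric} >= {config.min_n_threshold}: {result}")
        artifacts["min_n_summary"] = out / "min_n_summary.csv"
        pd.DataFrame(rows).to_csv(artifacts["min_n_summary"], index=False)

        if config.permutation is not None:
            perm = config.permutation
            tables = []
            for estimator in perm.estimators:
                summary = permutation_null(
                    cfg.model,
                    ds,
                    estimator,  # type: ignore[arg-type]
                    n_grid=list(perm.n_grid),
                    n_permutations=perm.n_permutations,
                    seed=cfg.seed,
                    k_folds=cfg.k_folds,
                )
                tables.append(summary.table)
                log(
                    f"permutation null ({estimator}): mean r per n = "
                    + ", ".join(
                        f"{r.n}: {r.mean_r:+.4f}" for r in summary.table.itertuples()
                    )
                )
            artifacts["null_distribution"] = out / "null_distribution.csv"
            pd.concat(tables, ignore_index=True).to_csv(
                artifacts["null_distribution"], index=False, float_format=FLOAT_FORMAT
            )

        meta = {
            "config": config.to_dict(),
            "environment": config.environment_metadata(),
            "n_jobs": n_jobs,
            "elapsed_seconds": round(time.perf_counter() - t0, 3),
        }
        artifacts["metadata"] = out / "metadata.yaml"
        with open(artifacts["metadata"], "w") as fh:
            yaml.safe_dump(meta, fh, sort_keys=False)
        artifacts["log"] = out / "run.log"
        artifacts["log"].write_text("\n".join(log_lines) + "\n")
    except BaseException:
        marker.write_text("experiment FAILED; directory contents are incomplete\n")
        raise
    marker.unlink()
    return artifacts
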