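"""Experiment configuration: one YAML file describes a full run.

A configuration names exactly one data source (the synthetic generator or a
pair of delimited text files), a benchmark block, and optionally a
permutation-null block.  :func:`validate_config` reports *all* violations, not
just the first, so a config can be repaired in one pass.
"""

from __future__ import annotations

import dataclasses
import platform
import sys
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .bench import BenchmarkConfig
from .errors import ConfigError
from .models import ModelSpec
from .synthetic import GroundTruthConfig, LabeledDataset, generate_dataset, load_dataset

__all__ = [
    "ExperimentConfig",
    "PermutationBlock",
    "load_config",
    "validate_config",
]


@dataclass(frozen=True)
class PermutationBlock:
    """Optional permuted-outcome null analysis attached to an experiment."""

    estimators: tuple[str, ...] = ("in_sample", "cv")
    n_permutations: int = 100
    n_grid: tuple[int, ...] = (50, 100, 200)


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one experiment end to end."""

    benchmark: BenchmarkConfig
    synthetic: GroundTruthConfig | None = None
    data_files: dict | None = None
    permutation: PermutationBlock | None = None
    output_dir: Path = Path("results/experiment")
    min_n_threshold: float = 0.8

    def load_data(self) -> LabeledDataset:
        if self.synthetic is not None:
            return generate_dataset(self.synthetic)
        files = self.data_files or {}
        return load_dataset(
            files["features"],
            files["phenotype"],
            sep=files.get("sep", "\t"),
            outcome_column=files.get("outcome_column", "outcome"),
        )

    def to_dict(self) -> dict:
        d: dict = {
            "benchmark": {
                **dataclasses.asdict(self.benchmark),
                "model": self.benchmark.model.to_dict(),
                "n_grid": list(self.benchmark.n_grid),
            },
            "output_dir": str(self.output_dir),
            "min_n_threshold": self.min_n_threshold,
        }
        if self.synthetic is not None:
            d["data"] = {"synthetic": dataclasses.asdict(self.synthetic)}
        if self.data_files is not None:
            d["data"] = {"files": dict(self.data_files)}
        if self.permutation is not None:
            d["permutation"] = {
                "estimators": list(self.permutation.estimators),
                "n_permutations": self.permutation.n_permutations,
                "n_grid": list(self.permutation.n_grid),
            }
        return d

    def environment_metadata(self) -> dict:
        import numpy, pandas, scipy, sklearn  # noqa: PLC0415

        return {
            "bwasrep_version": __version__,
            "python": sys.version.split()[0],
            "platform": platform.platform(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "scikit_learn": sklearn.__version__,
        }


def _build(raw: dict, violations: list[str]) -> ExperimentConfig | None:
    if not isinstance(raw, dict):
        violations.append("top level must be a mapping")
        return None

    data = raw.get("data")
    synthetic = None
    data_files = None
    if not isinstance(data, dict) or ("synthetic" in data) == ("files" in data):
        violations.append(
            "data must contain exactly one source: 'synthetic' or 'files'"
        )
    elif "synthetic" in data:
        try:
            synthetic = GroundTruthConfig(**data["synthetic"])
            synthetic.validate()
        except (TypeError, ConfigError) as exc:
            violations.append(f"data.synthetic: {exc}")
    else:
        files = data["files"]
        if not isinstance(files, dict) or not {"features", "phenotype"} <= set(files):
            violations.append("data.files must name 'features' and 'phenotype' paths")
        else:
            data_files = files

    bench_raw = dict(raw.get("benchmark") or {})
    model_raw = bench_raw.pop("model", None)
    benchmark = None
    try:
        model = ModelSpec.from_dict(model_raw) if model_raw else ModelSpec()
        benchmark = BenchmarkConfig(model=model, **bench_raw)
        benchmark.validate()
    except (TypeError, ConfigError) as exc:
        violations.append(f"benchmark: {exc}")

    permutation = None
    if "permutation" in raw and raw["permutation"] is not None:
        perm_raw = dict(raw["permutation"])
        try:
            permutation = PermutationBlock(
                estimators=tuple(perm_raw.get("estimators", ("in_sample", "cv"))),
                n_permutations=int(perm_raw.get("n_permutations", 100)),
                n_grid=tuple(perm_raw.get("n_grid", (50, 100, 200))),
            )
            bad = set(permutation.estimators) - {"in_sample", "cv"}
            if bad:
                violations.append(f"permutation.estimators: unknown {sorted(bad)}")
            if permutation.n_permutations < 20:
                violations.append("permutation.n_permutations must be at least 20")
        except (TypeError, ValueError) as exc:
            violations.append(f"permutation: {exc}")

    threshold = raw.get("min_n_threshold", 0.8)
    if not (0.0 < float(threshold) <= 1.0):
        violations.append(f"min_n_threshold must lie in (0, 1], got {threshold}")

    if violations or benchmark is None:
        return None
    return ExperimentConfig(
        benchmark=benchmark,
        synthetic=synthetic,
        data_files=data_files,
        permutation=permutation,
        output_dir=Path(raw.get("output_dir", "results/experiment")),
        min_n_threshold=float(threshold),
    )


def load_config(path: str | Path) -> ExperimentConfig:
    """Parse and validate a YAML experiment config; raise on any violation."""
    cfg, violations = _parse(path)
    if violations:
        raise ConfigError("invalid experiment config:\n- " + "\n- ".join(violations))
    assert cfg is not None
    return cfg


def validate_config(path: str | Path) -> list[str]:
    """Return the full list of violations for a config file (empty if valid)."""
    return _parse(path)[1]


def _parse(path: str | Path) -> tuple[ExperimentConfig | None, list[str]]:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        return None, [f"unparseable YAML: {exc}"]
    except OSError as exc:
        return None, [f"cannot read config file: {exc}"]
    violations: list[str] = []
    cfg = _build(raw, violations)
    return cfg, violations
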