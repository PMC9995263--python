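"""Shared fixtures.

The expensive discovery/replication benchmarks are session-scoped and shared
between the property tests and the acceptance suite, so the full run stays
within a desk-scale compute budget.
"""

from __future__ import annotations

import numpy as np
import pytest

import bwasrep as b


@pytest.fixture(scope="session")
def ds_signal():
    """Reference dataset: rho_true=0.3 at the generator's default shape."""
    return b.generate_dataset(b.GroundTruthConfig(rho_true=0.3, seed=5))


@pytest.fixture(scope="session")
def ds_null():
    """Null dataset: outcome independent of all features."""
    return b.generate_dataset(b.GroundTruthConfig(rho_true=0.0, seed=7))


@pytest.fixture(scope="session")
def ds_wide():
    """Feature count an order of magnitude above sample size (p >> n)."""
    return b.generate_dataset(
        b.GroundTruthConfig(n_samples=400, n_features=2000, rho_true=0.3, seed=9)
    )


@pytest.fixture(scope="session")
def bench_signal(ds_signal):
    """Ridge benchmark on the rho=0.3 dataset across the sample-size grid."""
    cfg = b.BenchmarkConfig(
        n_grid=(50, 100, 200, 400), n_bootstrap=100, model=b.ModelSpec(), seed=42
    )
    records = b.run_benchmark(ds_signal, cfg)
    return cfg, records, b.aggregate(records, cfg)


@pytest.fixture(scope="session")
def bench_null(ds_null):
    """Ridge benchmark under the global null (type-I calibration)."""
    cfg = b.BenchmarkConfig(
        n_grid=(100,), n_bootstrap=200, model=b.ModelSpec(), seed=11
    )
    records = b.run_benchmark(ds_null, cfg)
    return cfg, records, b.aggregate(records, cfg)
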