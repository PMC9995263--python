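"""Discovery/replication benchmark: sampling design, records, aggregation."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import bwasrep as b
from bwasrep.bench import permutation_p_value, records_to_frame
from bwasrep.errors import ConfigError, SizeError


class TestDrawPair:
    def test_disjoint_and_exhaustive(self, ds_null):
        disc, rep = b.draw_pair(ds_null, ds_null.n_samples // 2, seed=0)
        assert set(disc.sample_ids).isdisjoint(rep.sample_ids)
        assert len(set(disc.sample_ids) | set(rep.sample_ids)) == ds_null.n_samples

    def test_deterministic_and_distinct_across_seeds(self, ds_null):
        a1 = b.draw_pair(ds_null, 100, seed=3)[0]
        a2 = b.draw_pair(ds_null, 100, seed=3)[0]
        np.testing.assert_array_equal(a1.sample_ids, a2.sample_ids)
        b1 = b.draw_pair(ds_null, 100, seed=4)[0]
        assert not np.array_equal(a1.sample_ids, b1.sample_ids)

    def test_overlap_frequency_matches_hypergeometric(self, ds_null):
        """Discovery sets from independent seeds overlap as without-replacement
        sampling predicts: E[overlap] = n^2 / N."""
        n, N = 100, ds_null.n_samples
        draws = [set(b.draw_pair(ds_null, n, seed=s)[0].sample_ids) for s in range(40)]
        overlaps = [
            len(draws[i] & draws[j]) for i in range(40) for j in range(i + 1, 40)
        ]
        expected = n * n / N  # hypergeometric mean
        sd = np.sqrt(expected * (1 - n / N))  # close to binomial spread
        assert np.mean(overlaps) == pytest.approx(expected, abs=3 * sd / np.sqrt(len(overlaps)))

    def test_infeasible_size_names_limit(self, ds_null):
        with pytest.raises(SizeError, match=str(ds_null.n_samples // 2)):
            b.draw_pair(ds_null, ds_null.n_samples, seed=0)


class TestRunReplicate:
    def test_strong_signal_survives_cv_and_replication(self):
        """At rho_true=0.9 the CV estimate and the frozen-model replication
        agree and stay high; shrinkage-1 ridge at n = p attenuates both
        (simulation oracle: cv ~0.74, rep ~0.72, never below ~0.66)."""
        ds = b.generate_dataset(b.GroundTruthConfig(n_samples=600, rho_true=0.9, seed=3))
        recs = [
            b.run_replicate(ds, 200, b.ModelSpec(), seed=np.random.SeedSequence([9, i]))
            for i in range(5)
        ]
        for r in recs:
            assert r.r_disc_cv > 0.6 and r.r_rep > 0.6
            assert abs(r.r_disc_cv - r.r_rep) < 0.15
        assert np.mean([r.r_disc_insample for r in recs]) > np.mean(
            [r.r_disc_cv for r in recs]
        )

    def test_permuted_outcome_insample_inflated_replication_null(self, ds_null):
        rec = b.run_replicate(ds_null, 200, b.ModelSpec(), seed=1)
        assert rec.r_disc_insample > 0.5  # overfitting
        assert abs(rec.r_rep) < 0.25  # frozen model cannot replicate noise

    def test_identical_seed_identical_record(self, ds_null):
        r1 = b.run_replicate(ds_null, 80, b.ModelSpec(), seed=12)
        r2 = b.run_replicate(ds_null, 80, b.ModelSpec(), seed=12)
        assert r1 == r2


class TestRunBenchmark:
    def test_record_count_and_grid(self, ds_null):
        cfg = b.BenchmarkConfig(n_grid=(50, 100), n_bootstrap=10, seed=2)
        recs = b.run_benchmark(ds_null, cfg)
        assert len(recs) == 20
        assert {r.n for r in recs} == {50, 100}

    def test_extending_bootstrap_preserves_prefix(self, ds_null):
        small = b.BenchmarkConfig(n_grid=(60,), n_bootstrap=4, seed=3)
        large = b.BenchmarkConfig(n_grid=(60,), n_bootstrap=8, seed=3)
        r_small = b.run_benchmark(ds_null, small)
        r_large = b.run_benchmark(ds_null, large)
        assert r_large[:4] == r_small

    def test_parallel_execution_identical(self, ds_null):
        cfg = b.BenchmarkConfig(n_grid=(50,), n_bootstrap=6, seed=4)
        assert b.run_benchmark(ds_null, cfg, n_jobs=2) == b.run_benchmark(ds_null, cfg)

    def test_infeasible_grid_fails_fast(self, ds_null):
        cfg = b.BenchmarkConfig(n_grid=(700,), n_bootstrap=2, seed=0)
        with pytest.raises(SizeError, match="disjoint"):
            b.run_benchmark(ds_null, cfg)


class TestAggregate:
    @staticmethod
    def _constructed_records(n=100, n_pos=80, n_rep_pos=60):
        """n records: the first n_pos are discovery-positive, and of those the
        first n_rep_pos are also replication-positive."""
        recs = []
        for i in range(n):
            disc_pos = i < n_pos
            rep_pos = i < n_rep_pos
            recs.append(
                b.ReplicateRecord(
                    n=100,
                    replicate_index=i,
                    r_disc_insample=0.8,
                    r_disc_cv=0.3 if disc_pos else 0.1,
                    p_disc_cv=0.01 if disc_pos else 0.5,
                    r_rep=0.25 if rep_pos else 0.05,
                    p_rep_value=0.01 if rep_pos else 0.5,
                    seed_used=i,
                )
            )
        return recs

    def test_power_and_p_rep_arithmetic(self):
        cfg = b.BenchmarkConfig(n_grid=(100,), n_bootstrap=100, seed=0)
        table = b.aggregate(self._constructed_records(), cfg)
        assert table.value(100, "power") == pytest.approx(0.80)
        assert table.value(100, "p_rep") == pytest.approx(0.75)

    def test_all_positive_collapses_conditional_to_unconditional(self):
        cfg = b.BenchmarkConfig(n_grid=(100,), n_bootstrap=100, seed=0)
        table = b.aggregate(self._constructed_records(n_pos=100, n_rep_pos=100), cfg)
        assert table.value(100, "power") == 1.0
        assert table.value(100, "p_rep") == 1.0
        assert table.value(100, "conditional_inflation") == pytest.approx(
            table.value(100, "mean_inflation_cv")
        )

    def test_no_discovery_positive_gives_sentinel(self):
        cfg = b.BenchmarkConfig(n_grid=(100,), n_bootstrap=100, seed=0)
        table = b.aggregate(self._constructed_records(n_pos=0, n_rep_pos=0), cfg)
        assert table.value(100, "power") == 0.0
        assert np.isnan(table.value(100, "p_rep"))
        row = table.frame.query("metric == 'p_rep'").iloc[0]
        assert row.subset_n == 0

    def test_conditioning_modes(self):
        recs = self._constructed_records()
        for mode, expected_subset in [
            ("none", 100),
            ("discovery_significant", 80),
            ("replication_significant", 60),
            ("both", 60),
        ]:
            cfg = b.BenchmarkConfig(
                n_grid=(100,), n_bootstrap=100, conditioning=mode, seed=0
            )
            row = b.aggregate(recs, cfg).frame.query(
                "metric == 'conditional_inflation'"
            ).iloc[0]
            assert row.subset_n == expected_subset

    def test_interval_bounds_bracket_value(self, bench_signal):
        _, _, table = bench_signal
        f = table.frame.dropna(subset=["value"])
        ok = (f.lo <= f.value + 1e-12) & (f.value <= f.hi + 1e-12)
        assert ok.all()


class TestMinN:
    @staticmethod
    def _table(values: dict[int, float]) -> b.BenchmarkTable:
        frame = pd.DataFrame(
            [
                {"n": n, "metric": "power", "value": v, "lo": v, "hi": v, "subset_n": 100}
                for n, v in values.items()
            ]
        )
        return b.BenchmarkTable(frame, conditioning="none")

    def test_first_crossing(self):
        t = self._table({75: 0.4, 150: 0.7, 300: 0.85, 500: 0.95})
        assert b.min_n(t, "power", 0.8) == 300

    def test_above_grid_sentinel(self):
        t = self._table({75: 0.3, 150: 0.5, 500: 0.7})
        assert b.min_n(t, "power", 0.8) == ">500"

    def test_non_monotone_first_crossing_rule(self):
        t = self._table({75: 0.85, 150: 0.7, 300: 0.9})
        assert b.min_n(t, "power", 0.8) == 75

    def test_unknown_metric_rejected(self):
        with pytest.raises(ConfigError):
            b.min_n(self._table({50: 0.1, 100: 0.2}), "accuracy", 0.8)


class TestBenchmarkStatisticalProperties:
    def test_cv_pessimistic_then_unbiased_never_inflated(self, bench_signal):
        """Mean CV discovery r grows with n and never exceeds rho_true + 0.03."""
        _, records, _ = bench_signal
        df = records_to_frame(records)
        means = df.groupby("n")["r_disc_cv"].mean()
        assert means[50] <= means[400]
        assert (means <= 0.3 + 0.03).all()

    def test_effect_estimate_variability_shrinks_with_n(self, bench_signal):
        _, records, _ = bench_signal
        sds = records_to_frame(records).groupby("n")["r_disc_cv"].std()
        assert sds.is_monotonic_decreasing

    def test_power_and_p_rep_trend_upward(self, bench_signal):
        _, _, table = bench_signal
        power = table.metric_series("power")
        assert power.iloc[-1] > power.iloc[0]
        # non-decreasing up to Monte-Carlo error on B = 100 replicates
        assert (np.diff(power.to_numpy()) > -0.1).all()
        p_rep = table.metric_series("p_rep").dropna()
        assert p_rep.iloc[-1] > p_rep.iloc[0]

    def test_full_sample_effect_positive_but_attenuated(self, ds_signal):
        """Whole-sample CV estimate is clearly positive and significant but
        below rho_true: shrinkage-1 ridge fits noise in 200 dimensions
        (simulation oracle: r ~0.18 +/- 0.02 at n=1200)."""
        est = b.full_sample_effect(ds_signal, b.ModelSpec(), seed=5)
        assert est.method == "cv"
        assert 0.10 < est.r < 0.30
        assert est.p_value < 0.001
        assert est.ci_low <= est.r <= est.ci_high

    def test_full_sample_effect_null_within_critical_band(self, ds_null):
        est = b.full_sample_effect(ds_null, b.ModelSpec(), seed=6)
        assert abs(est.r) < b.critical_r(ds_null.n_samples, 0.2)


class TestPermutationPValue:
    def test_rank_p_value_add_one(self):
        null = np.array([0.5, 0.1, -0.2, 0.3])
        assert permutation_p_value(0.4, null) == pytest.approx(2 / 5)
        assert permutation_p_value(0.6, null) == pytest.approx(1 / 5)
        assert permutation_p_value(-1.0, null, "one_sided") == pytest.approx(1.0)
        assert permutation_p_value(-1.0, null, "two_sided") == pytest.approx(1 / 5)
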