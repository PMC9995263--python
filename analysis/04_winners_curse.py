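"""Winner's curse: conditioning on significance inflates published effects.

Re-aggregates the replicate records written by 02_effect_size_inflation.py
under publication-bias conditioning: effect-size inflation
(r_discovery - r_replication, cross-validated) computed only over replicates
whose discovery effect was a positive result.  At underpowered sample sizes
the significant subset systematically overestimates the replication effect
even though the CV estimator itself is unbiased.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from bwasrep import BenchmarkConfig, ModelSpec, ReplicateRecord, aggregate


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument(
        "--records", type=Path, default=Path("results/inflation/records.csv"),
        help="records.csv from 02_effect_size_inflation.py",
    )
    ap.add_argument("--out", type=Path, default=Path("results/winners_curse"))
    args = ap.parse_args()

    df = pd.read_csv(args.records)
    records = [ReplicateRecord(**row) for row in df.to_dict("records")]
    rows = []
    for mode in ("discovery_significant", "replication_significant"):
        cfg = BenchmarkConfig(
            n_grid=tuple(sorted(df.n.unique())), n_bootstrap=df.replicate_index.max() + 1,
            model=ModelSpec(), conditioning=mode, seed=0,
        )
        table = aggregate(records, cfg)
        sub = table.frame.query("metric in ('conditional_inflation', 'mean_inflation_cv', 'power')")
        sub = sub.assign(conditioning=mode)
        rows.append(sub)

    out = pd.concat(rows, ignore_index=True)
    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "conditional_inflation.csv"
    out.to_csv(path, index=False, float_format="%.17g")

    disc = out.query("conditioning == 'discovery_significant'")
    wide = disc.pivot(index="n", columns="metric", values="value")
    print("discovery-significant conditioning (CV estimates):")
    print(wide[["power", "mean_inflation_cv", "conditional_inflation"]].round(3).to_string())
    print("\nreading: at sample sizes with low power, inflation conditional on a")
    print("significant discovery greatly exceeds the (near-zero) unconditional")
    print("inflation; the gap closes as power approaches 1.")
    print(f"\nwritten: {path}")


if __name__ == "__main__":
    main()
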