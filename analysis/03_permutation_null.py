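"""Permuted-outcome analysis: estimator bias when there is nothing to find.

Outcomes are permuted so no feature carries signal, in a p >> n regime
(2,000 features, subsamples of 200).  The in-sample (non-CV) effect-size
estimate stays far above zero for both flexible pipelines — pure
overfitting — while the cross-validated estimate is centred on zero.
Writes the per-estimator null summaries to null_distribution.csv.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from bwasrep import GroundTruthConfig, ModelSpec, generate_dataset, permutation_null


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=31)
    ap.add_argument("--out", type=Path, default=Path("results/permutation_null"))
    ap.add_argument("--n-permutations", type=int, default=100)
    args = ap.parse_args()

    ds = generate_dataset(
        GroundTruthConfig(n_samples=400, n_features=2000, rho_true=0.3, seed=9)
    )
    tables = []
    for family in ("pca_svr", "ridge"):
        summary = permutation_null(
            ModelSpec(family=family), ds, "in_sample",
            n_grid=[200], n_permutations=args.n_permutations, seed=args.seed,
        )
        summary.table.insert(0, "model", family)
        tables.append(summary.table)
        row = summary.table.iloc[0]
        print(f"{family:8s} in-sample null r: mean {row.mean_r:+.3f} [{row.lo:+.3f}, {row.hi:+.3f}]")

    cv = permutation_null(
        ModelSpec(), ds, "cv", n_grid=[200],
        n_permutations=args.n_permutations, seed=args.seed + 1,
    )
    cv.table.insert(0, "model", "ridge")
    tables.append(cv.table)
    row = cv.table.iloc[0]
    print(f"ridge    CV null r:        mean {row.mean_r:+.3f} [{row.lo:+.3f}, {row.hi:+.3f}]")
    print("\nreading: without cross-validation the in-sample estimate reports a")
    print("large 'effect' on pure noise; cross-validation removes that bias.")

    args.out.mkdir(parents=True, exist_ok=True)
    path = args.out / "null_distribution.csv"
    pd.concat(tables, ignore_index=True).to_csv(path, index=False, float_format="%.17g")
    print(f"\nwritten: {path}")


if __name__ == "__main__":
    main()
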