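"""Reproduce the benchmark cross-validation on an externally supplied dataset.

The curated benchmark (448 proteins, 780 sumoylated / 21,353 non-sumoylated
lysines, CPLM-derived) is not bundled; given its feature matrix as a CSV in
this package's format (columns protein_id, position, label, f_000..f_123 —
see hsesite.structio.write_feature_matrix), this script applies NearMiss-1
balancing and runs 6-, 8- and 10-fold cross-validation of the decision tree,
printing sensitivity, specificity, accuracy, MCC and mean AUC per scheme.

Usage: python scripts/reproduce_published.py --features matrix.csv [--seed 0]
"""

from __future__ import annotations

import argparse
from pathlib import Path

from hsesite import CvConfig, NearMissConfig, TreeParams, kfold_cv, nearmiss_undersample, round_metric
from hsesite.structio import read_feature_matrix


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--features", type=Path, required=True)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--skip-balance", action="store_true",
                        help="Dataset is already balanced.")
    args = parser.parse_args()

    dataset = read_feature_matrix(args.features)
    if not args.skip_balance:
        dataset = nearmiss_undersample(dataset, NearMissConfig(n_neighbors=3))
    print(f"dataset: {len(dataset)} sites after balancing")

    header = f"{'k':>3} {'sens':>6} {'spec':>6} {'acc':>6} {'mcc':>6} {'auc':>6}"
    print(header)
    for k in (6, 8, 10):
        result = kfold_cv(dataset, TreeParams(), CvConfig(k=k, seed=args.seed))
        row = [result.mean[name] for name in ("sens", "spec", "accuracy", "mcc", "auc")]
        print(f"{k:>3} " + " ".join(f"{round_metric(v):6.3f}" for v in row))


if __name__ == "__main__":
    main()
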