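#!/usr/bin/env python
"""Evaluate the six classifiers on the selected principal components.

Reads results/scores.csv and runs the full grid: four group comparisons
x six models x two decision thresholds under repeated 10-fold CV with
training-set upsampling.  Writes the two metrics tables (thresholds 50%
and 95%), the Bonferroni-corrected pairwise model comparisons, and
prints the headline numbers.

Expected pattern on the default cohort: near-ceiling accuracy for
control vs bulbar, intermediate for the comparisons involving the
non-bulbar group, a clear drop for bulbar vs non-bulbar, and a
sensitivity collapse at the restrictive 95% threshold.
"""

import argparse
from pathlib import Path

import pandas as pd

from bulbarvoice import models as mdl

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--scores", type=Path, default=ROOT / "results" / "scores.csv")
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--subject-grouped", action="store_true",
                        help="Leakage-free folds (subjects never split across folds).")
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    scores = pd.read_csv(args.scores)
    scheme = mdl.CVScheme(seed=args.seed, subject_grouped=args.subject_grouped)
    grid = mdl.evaluate_grid(scores, scheme=scheme)
    tables = mdl.results_report(grid, seed=args.seed, n_pcs=8, config_hash=None)
    args.out.mkdir(parents=True, exist_ok=True)
    suffix = "_grouped" if args.subject_grouped else ""
    for thr, tbl in tables.items():
        tbl.to_csv(args.out / f"metrics_threshold_{int(thr * 100)}{suffix}.csv",
                   index=False)
    pvals = []
    for cname in mdl.COMPARISON_NAMES:
        for thr in mdl.THRESHOLDS:
            acc = {m: grid[(cname, m, thr)].fold_accuracy for m in mdl.MODEL_NAMES}
            t = mdl.compare_models(acc)
            t.insert(0, "comparison", cname)
            t.insert(1, "threshold", thr)
            pvals.append(t)
    pd.concat(pvals, ignore_index=True).to_csv(
        args.out / f"model_comparisons{suffix}.csv", index=False)

    print(mdl.report_text(tables, args.seed, 8, None))
    best50 = max(((grid[("C_vs_B", m, 0.5)].accuracy_pct, m) for m in mdl.MODEL_NAMES))
    best95 = max(((grid[("C_vs_B", m, 0.95)].accuracy_pct, m) for m in mdl.MODEL_NAMES))
    print(f"best C vs B at 50%: {best50[1]} ({best50[0]:.1f}%)")
    print(f"best C vs B at 95%: {best95[1]} ({best95[0]:.1f}%)")


if __name__ == "__main__":
    main()
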