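#!/usr/bin/env python
"""Impute, age-correct, standardize and PCA-decompose the feature table.

Reads results/features.csv, applies the fixed preprocessing order
(shimmer(apq11) imputation -> aging correction fitted on controls ->
zero-mean/unit-SD scaling -> SVD), writes the 8-PC score table, the
serialized PCA model and the biplot export (PC1/PC2 scores by group plus
feature loadings), and prints the explained-variance profile.
"""

import argparse
from pathlib import Path

import pandas as pd

from bulbarvoice.preprocess import biplot_export, preprocess_pipeline, save_pca_model

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--features", type=Path, default=ROOT / "results" / "features.csv")
    parser.add_argument("--n-pcs", type=int, default=8)
    parser.add_argument("--out", type=Path, default=ROOT / "results")
    args = parser.parse_args()

    table = pd.read_csv(args.features)
    result = preprocess_pipeline(table, n_pcs=args.n_pcs)
    args.out.mkdir(parents=True, exist_ok=True)
    result.selected.to_csv(args.out / "scores.csv", index=False)
    save_pca_model(result.pca, result.params, result.age_model,
                   args.out / "pca_model.json")
    export = biplot_export(result.pca)
    export["scores"].to_csv(args.out / "biplot_scores.csv", index=False)
    export["loadings"].to_csv(args.out / "biplot_loadings.csv", index=False)

    print("explained variance (%):",
          [round(float(100 * v), 1) for v in result.pca.explained_variance_ratio[:8]])
    print("cumulative at k=%d: %.2f%%" % (
        args.n_pcs, 100 * result.pca.cumulative_variance[args.n_pcs - 1]))
    print("biplot Dim1+Dim2 share: %.1f%%" % (
        100 * result.pca.explained_variance_ratio[:2].sum()))
    centroids = export["scores"].groupby("group")[["Dim1", "Dim2"]].mean().round(2)
    print("group centroids in the biplot plane:")
    print(centroids.to_string())


if __name__ == "__main__":
    main()
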