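"""Cohort preprocessing: imputation, aging correction, scaling and PCA.

The pipeline order is fixed: impute shimmer(apq11) -> remove age effects
(slopes fitted on controls only, correction applied to every row) ->
standardize each feature to zero mean / unit SD -> singular value
decomposition -> keep the leading principal components as classifier
inputs.

The SVD is taken of the standardized matrix divided by sqrt(n-1), so each
singular value is the standard deviation of its component and the sum of
squared singular values equals the total feature variance (variance
bookkeeping is exact).  Loading signs are fixed by making the
largest-magnitude entry of each loading vector positive, which removes
the inherent sign ambiguity of the SVD from all exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .features import FEATURE_COLUMNS, META_COLUMNS

logger = logging.getLogger(__name__)


def build_table(feature_rows: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Join per-utterance feature rows with the subject metadata table.

    Row granularity is one utterance (subject x vowel).  Metadata columns
    (sex, age, group) override/complete whatever the feature rows carry.
    """
    orphans = sorted(set(feature_rows["subject_id"]) - set(metadata["subject_id"]))
    if orphans:
        raise ValueError(f"feature rows reference unknown subjects: {orphans}")
    dup = feature_rows.duplicated(subset=["subject_id", "vowel"])
    if dup.any():
        pairs = feature_rows.loc[dup, ["subject_id", "vowel"]].values.tolist()
        raise ValueError(f"duplicated (subject, vowel) rows: {pairs}")
    meta_cols = ["subject_id", "group", "sex", "age"]
    merged = feature_rows.drop(columns=[c for c in ("sex", "age_years", "group")
                                        if c in feature_rows.columns])
    merged = merged.merge(metadata[meta_cols], on="subject_id", how="left")
    merged = merged.rename(columns={"age": "age_years"})
    n_expected = metadata.shape[0] * feature_rows["vowel"].nunique()
    if merged.shape[0] < n_expected:
        logger.warning("table has %d rows, expected %d (missing vowels)",
                       merged.shape[0], n_expected)
    return merged[META_COLUMNS + FEATURE_COLUMNS]


def impute_apq11(table: pd.DataFrame) -> pd.DataFrame:
    """Replace undefined shimmer(apq11) cells by the subject's mean over
    the other vowels.  No other feature is ever imputed."""
    out = table.copy()
    col = "shimmer_apq11_pct"
    missing = out[col].isna()
    if not missing.any():
        return out
    for idx in out.index[missing]:
        subject = out.at[idx, "subject_id"]
        others = out[(out["subject_id"] == subject) & (out.index != idx)][col].dropna()
        if others.empty:
            raise ValueError(
                f"subject {subject!r}: shimmer(apq11) undefined for every vowel; "
                "no imputation rule applies")
        out.at[idx, col] = float(others.mean())
        logger.info("imputed shimmer(apq11) for %s from %d other vowels",
                    subject, others.size)
    return out


@dataclass
class AgeCorrectionModel:
    """Per-feature linear aging slopes, fitted on control rows only."""

    slopes: pd.Series  # feature-units per year

    def to_dict(self) -> dict[str, float]:
        return self.slopes.to_dict()


def fit_age_correction(table: pd.DataFrame,
                       feature_columns: list[str] | None = None) -> AgeCorrectionModel:
    """OLS slope of each feature against age, on group-C rows only."""
    cols = feature_columns or FEATURE_COLUMNS
    controls = table[table["group"] == "C"]
    ages = controls["age_years"].to_numpy(dtype=float)
    if np.unique(ages).size < 2:
        raise ValueError("control ages are degenerate (all equal); cannot fit aging")
    if controls.shape[0] < 3:
        raise ValueError("need at least 3 control rows to fit aging")
    a = np.column_stack([ages, np.ones_like(ages)])
    slopes = {}
    for col in cols:
        y = controls[col].to_numpy(dtype=float)
        keep = ~np.isnan(y)
        coef, *_ = np.linalg.lstsq(a[keep], y[keep], rcond=None)
        slopes[col] = float(coef[0])
    return AgeCorrectionModel(slopes=pd.Series(slopes))


def remove_age_effects(table: pd.DataFrame, model: AgeCorrectionModel) -> pd.DataFrame:
    """Subtract slope x age (the "normal aging") from every row's features."""
    out = table.copy()
    ages = out["age_years"].to_numpy(dtype=float)
    for col, slope in model.slopes.items():
        out[col] = out[col] - slope * ages
    return out


@dataclass
class StandardizationParams:
    means: pd.Series
    sds: pd.Series  # n-1 denominator


def standardize(table: pd.DataFrame,
                feature_columns: list[str] | None = None
                ) -> tuple[pd.DataFrame, StandardizationParams]:
    """(x - mean) / sd per feature column; errors on zero-variance columns."""
    cols = feature_columns or FEATURE_COLUMNS
    out = table.copy()
    means, sds = {}, {}
    for col in cols:
        x = out[col].to_numpy(dtype=float)
        mu = float(np.nanmean(x))
        sd = float(np.nanstd(x, ddof=1))
        if not sd > 0:
            raise ValueError(f"feature {col!r} has zero variance; cannot standardize")
        out[col] = (x - mu) / sd
        means[col], sds[col] = mu, sd
    return out, StandardizationParams(pd.Series(means), pd.Series(sds))


@dataclass
class PCAModel:
    """Thin SVD of the standardized feature matrix scaled by 1/sqrt(n-1)."""

    u: np.ndarray                 # left singular vectors (n x p)
    s: np.ndarray                 # singular values = component SDs
    v: np.ndarray                 # loading directions, columns orthonormal
    feature_names: list[str]
    scores: pd.DataFrame          # metadata + PC1..PCp (scores = X V)
    explained_variance_ratio: np.ndarray
    cumulative_variance: np.ndarray


def pca_svd(table: pd.DataFrame,
            feature_columns: list[str] | None = None) -> PCAModel:
    """PCA of a standardized table via singular value decomposition."""
    cols = feature_columns or FEATURE_COLUMNS
    sub = table.dropna(subset=cols)
    dropped = table.shape[0] - sub.shape[0]
    if dropped:
        logger.warning("dropping %d rows with undefined features before PCA", dropped)
    x = sub[cols].to_numpy(dtype=float)
    n = x.shape[0]
    if n < 2:
        raise ValueError("need at least 2 complete rows for PCA")
    u, s, vt = np.linalg.svd(x / np.sqrt(n - 1), full_matrices=False)
    v = vt.T
    # Sign convention: largest-magnitude entry of each loading positive.
    for j in range(v.shape[1]):
        if v[np.argmax(np.abs(v[:, j])), j] < 0:
            v[:, j] = -v[:, j]
            u[:, j] = -u[:, j]
    var = s ** 2
    ratio = var / var.sum()
    scores = x @ v
    meta = sub[[c for c in META_COLUMNS if c in sub.columns]].reset_index(drop=True)
    score_df = pd.concat(
        [meta, pd.DataFrame(scores, columns=[f"PC{j + 1}" for j in range(v.shape[1])])],
        axis=1)
    return PCAModel(u=u, s=s, v=v, feature_names=list(cols), scores=score_df,
                    explained_variance_ratio=ratio,
                    cumulative_variance=np.cumsum(ratio))


def select_pcs(model: PCAModel, k: int = 8) -> pd.DataFrame:
    """First k score columns (with row metadata carried through)."""
    p = model.s.size
    if not 1 <= k <= p:
        raise ValueError(f"k must be in [1, {p}], got {k}")
    meta_cols = [c for c in model.scores.columns if not c.startswith("PC")]
    logger.info("keeping %d PCs; cumulative explained variance %.2f%%",
                k, 100.0 * model.cumulative_variance[k - 1])
    return model.scores[meta_cols + [f"PC{j + 1}" for j in range(k)]].copy()


def biplot_export(model: PCAModel) -> dict[str, pd.DataFrame]:
    """Numeric data behind a PC1/PC2 biplot: per-row scores by group,
    per-feature loading vectors, and the two variance shares."""
    meta_cols = [c for c in model.scores.columns if not c.startswith("PC")]
    scores = model.scores[meta_cols + ["PC1", "PC2"]].rename(
        columns={"PC1": "Dim1", "PC2": "Dim2"})
    loadings = pd.DataFrame(
        {"feature": model.feature_names,
         "Dim1": model.v[:, 0], "Dim2": model.v[:, 1]})
    variance = pd.DataFrame(
        {"dimension": ["Dim1", "Dim2"],
         "variance_share": model.explained_variance_ratio[:2]})
    return {"scores": scores, "loadings": loadings, "variance": variance}


def save_pca_model(model: PCAModel, params: StandardizationParams,
                   age_model: AgeCorrectionModel, path: str | Path) -> None:
    payload = {
        "feature_names": model.feature_names,
        "standardization": {"means": params.means.to_dict(), "sds": params.sds.to_dict()},
        "age_slopes": age_model.to_dict(),
        "singular_values": model.s.tolist(),
        "loadings": model.v.tolist(),
        "explained_variance_ratio": model.explained_variance_ratio.tolist(),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


@dataclass
class PreprocessResult:
    table: pd.DataFrame           # imputed, age-corrected, standardized
    age_model: AgeCorrectionModel
    params: StandardizationParams
    pca: PCAModel
    selected: pd.DataFrame        # metadata + leading PC scores


def preprocess_pipeline(table: pd.DataFrame, n_pcs: int = 8,
                        subject_level: bool = False) -> PreprocessResult:
    """Full preprocessing in the mandated order.

    ``subject_level=True`` averages each subject's defined feature values
    over vowels first (per-subject granularity instead of per-utterance).
    """
    work = table
    if subject_level:
        agg = {c: "mean" for c in FEATURE_COLUMNS}
        agg.update({"sex": "first", "age_years": "first", "group": "first"})
        work = work.groupby("subject_id", as_index=False).agg(agg)
        work["vowel"] = "all"
        work = work[META_COLUMNS + FEATURE_COLUMNS]
    work = impute_apq11(work)
    age_model = fit_age_correction(work)
    work = remove_age_effects(work, age_model)
    work, params = standardize(work)
    pca = pca_svd(work)
    selected = select_pcs(pca, n_pcs)
    return PreprocessResult(table=work, age_model=age_model, params=params,
                            pca=pca, selected=selected)
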