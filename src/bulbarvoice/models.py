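"""Supervised classifier suite and repeated cross-validated evaluation.

Six binary classifiers — random forest (500 trees, OOB-tuned mtry),
Gaussian naive Bayes, logistic regression (binomial, logit link, no
penalty), linear discriminant analysis, a one-hidden-layer neural network
(3 tanh units, backpropagation with adaptive learning rate) and a
linear-kernel C-SVM (C tuned over a fixed grid by inner cross-validation)
— are evaluated on the leading principal components for four group
comparisons (C vs B, C vs NB, B vs NB, C vs ALS).

Evaluation follows repeated k-fold cross-validation: each trial permutes
the rows with a seeded RNG and splits them into k contiguous chunks; each
chunk in turn is the test set while training happens on the remainder
after upsampling the minority class with replacement to equal counts.
Every model sees the identical folds and the identical resampled training
sets, so per-fold metrics are paired across models.  Class probabilities
are thresholded at 50% and at the more restrictive 95% (positive iff
p >= threshold); accuracy, sensitivity and specificity are averaged over
the trials x k fold evaluations.  Pairwise model differences are assessed
with paired t tests on the fold accuracies, Bonferroni-corrected for the
number of model pairs.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

logger = logging.getLogger(__name__)

MODEL_NAMES = ("RF", "NaB", "LR", "LDA", "NN", "SVM")
COMPARISON_NAMES = ("C_vs_B", "C_vs_NB", "B_vs_NB", "C_vs_ALS")
THRESHOLDS = (0.50, 0.95)

SVM_C_GRID = (0.0001, 0.0005, 0.001, 0.01, 0.1, 1.0)
RF_N_TREES = 500
RF_MTRY_GRID = (2, 5, 8)
_INNER_CV_FOLDS = 3


@dataclass(frozen=True)
class Comparison:
    """A two-class problem: which groups enter, and who is positive."""

    name: str
    negative_groups: tuple[str, ...]
    positive_groups: tuple[str, ...]
    positive_label: str


COMPARISONS: dict[str, Comparison] = {
    "C_vs_B": Comparison("C_vs_B", ("C",), ("B",), "B"),
    "C_vs_NB": Comparison("C_vs_NB", ("C",), ("NB",), "NB"),
    "B_vs_NB": Comparison("B_vs_NB", ("NB",), ("B",), "B"),
    "C_vs_ALS": Comparison("C_vs_ALS", ("C",), ("B", "NB"), "ALS"),
}


@dataclass
class CVScheme:
    k: int = 10
    trials: int = 10
    seed: int = 0
    upsampling: bool = True
    # Split folds by subject rather than by utterance.  Off by default for
    # fidelity to the published procedure, but note that with five
    # utterances per subject, utterance-level folds place the same voice in
    # both training and test sets, which inflates accuracy through speaker
    # memorization.
    subject_grouped: bool = False

    def __post_init__(self) -> None:
        if self.k < 2 or self.trials < 1:
            raise ValueError("need k >= 2 folds and trials >= 1")


class ConfusionCounts(NamedTuple):
    tp: int
    fn: int
    tn: int
    fp: int

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


class FoldMetrics(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


@dataclass
class EvaluationResult:
    comparison: str
    model: str
    threshold: float
    fold_counts: list[ConfusionCounts]
    fold_accuracy: np.ndarray
    fold_sensitivity: np.ndarray   # NaN where the fold had no positives
    fold_specificity: np.ndarray
    accuracy_pct: float = field(init=False)
    sensitivity_pct: float = field(init=False)
    specificity_pct: float = field(init=False)

    def __post_init__(self) -> None:
        self.accuracy_pct = float(np.mean(self.fold_accuracy))
        n_undef = int(np.isnan(self.fold_sensitivity).sum())
        if n_undef:
            logger.info("%s/%s@%.2f: %d folds with undefined sensitivity excluded",
                        self.comparison, self.model, self.threshold, n_undef)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            self.sensitivity_pct = float(np.nanmean(self.fold_sensitivity))
            self.specificity_pct = float(np.nanmean(self.fold_specificity))


# ---------------------------------------------------------------------------
# Dataset assembly and resampling


def make_binary_dataset(scores: pd.DataFrame, comparison: Comparison | str
                        ) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Restrict score rows to the comparison's two classes.

    Returns (X, y, meta) with y=1 for the positive class.  C_vs_ALS keeps
    every row, relabelling both patient groups as positive.
    """
    if isinstance(comparison, str):
        comparison = COMPARISONS[comparison]
    groups = scores["group"]
    keep = groups.isin(comparison.negative_groups + comparison.positive_groups)
    sub = scores[keep]
    y = sub["group"].isin(comparison.positive_groups).to_numpy(dtype=int)
    if y.sum() == 0 or y.sum() == y.size:
        raise ValueError(f"{comparison.name}: a class has zero rows")
    pc_cols = [c for c in sub.columns if c.startswith("PC")]
    x = sub[pc_cols].to_numpy(dtype=float)
    return x, y, sub.drop(columns=pc_cols).reset_index(drop=True)


def upsample(x: np.ndarray, y: np.ndarray, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Resample the minority class with replacement to equal class counts."""
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("upsampling requires two classes in the training rows")
    rng = np.random.default_rng(seed)
    target = counts.max()
    idx_parts = []
    for cls, count in zip(classes, counts):
        members = np.nonzero(y == cls)[0]
        idx_parts.append(members)
        if count < target:
            idx_parts.append(rng.choice(members, size=target - count, replace=True))
    idx = np.concatenate(idx_parts)
    return x[idx], y[idx]


# ---------------------------------------------------------------------------
# Model fitting


def _inner_folds(n: int, seed: int) -> list[np.ndarray]:
    rng = np.random.default_rng(seed)
    return np.array_split(rng.permutation(n), _INNER_CV_FOLDS)


def _tune_by_inner_cv(x: np.ndarray, y: np.ndarray, seed: int,
                      make: Callable[[float], object],
                      grid: Sequence[float]) -> float:
    """Pick the grid value with the best mean inner-CV accuracy."""
    chunks = _inner_folds(y.size, seed)
    best_val, best_acc = grid[0], -1.0
    for val in grid:
        accs = []
        for i, test in enumerate(chunks):
            train = np.concatenate([c for j, c in enumerate(chunks) if j != i])
            if np.unique(y[train]).size < 2 or test.size == 0:
                continue
            clf = make(val)
            clf.fit(x[train], y[train])
            accs.append(float(np.mean(clf.predict(x[test]) == y[test])))
        acc = float(np.mean(accs)) if accs else -1.0
        if acc > best_acc:
            best_val, best_acc = val, acc
    return best_val


class _PlattSVM:
    """Linear-kernel C-SVM scored through a logistic calibration of its
    decision values, fitted on the training fold."""

    def __init__(self, c: float, seed: int):
        self.svc = SVC(kernel="linear", C=c, random_state=seed)
        self.platt = LogisticRegression(max_iter=1000)

    def fit(self, x: np.ndarray, y: np.ndarray) -> "_PlattSVM":
        self.svc.fit(x, y)
        d = self.svc.decision_function(x).reshape(-1, 1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.platt.fit(d, y)
        return self

    def predict_proba_positive(self, x: np.ndarray) -> np.ndarray:
        d = self.svc.decision_function(x).reshape(-1, 1)
        return self.platt.predict_proba(d)[:, 1]


class _SklearnScorer:
    def __init__(self, clf):
        self.clf = clf

    def fit(self, x, y):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            self.clf.fit(x, y)
        return self

    def predict_proba_positive(self, x: np.ndarray) -> np.ndarray:
        proba = self.clf.predict_proba(x)
        pos_col = int(np.nonzero(self.clf.classes_ == 1)[0][0])
        return proba[:, pos_col]


def select_rf_mtry(x: np.ndarray, y: np.ndarray, seed: int) -> int:
    """Tune the forest's mtry once per classification problem: the grid
    value with the best out-of-bag accuracy on the (upsampled) data wins."""
    xb, yb = upsample(x, y, seed)
    best_mtry, best_oob = RF_MTRY_GRID[0], -1.0
    for i, mtry in enumerate(RF_MTRY_GRID):
        clf = RandomForestClassifier(
            n_estimators=RF_N_TREES, max_features=min(mtry, x.shape[1]),
            oob_score=True, random_state=seed + i, n_jobs=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            clf.fit(xb, yb)
        if clf.oob_score_ > best_oob:
            best_mtry, best_oob = mtry, clf.oob_score_
    logger.debug("RF mtry tuning selected %d (oob %.3f)", best_mtry, best_oob)
    return best_mtry


def fit_model(name: str, x: np.ndarray, y: np.ndarray, seed: int,
              rf_mtry: int | None = None):
    """Fit one named model on (already upsampled) training rows; returns a
    scorer exposing ``predict_proba_positive``.

    ``rf_mtry`` carries the per-problem tuned forest mtry; when absent it
    is selected on the spot from the training rows by OOB accuracy.
    """
    if np.unique(y).size < 2:
        raise ValueError(f"{name}: training rows contain a single class")
    if name == "RF":
        if rf_mtry is None:
            rf_mtry = select_rf_mtry(x, y, seed)
        clf = RandomForestClassifier(
            n_estimators=RF_N_TREES, max_features=min(rf_mtry, x.shape[1]),
            random_state=seed, n_jobs=1)
        return _SklearnScorer(clf).fit(x, y)
    if name == "NaB":
        return _SklearnScorer(GaussianNB()).fit(x, y)
    if name == "LR":
        # Binomial GLM with logit link: unpenalized logistic regression.
        return _SklearnScorer(
            LogisticRegression(C=np.inf, max_iter=1000)).fit(x, y)
    if name == "LDA":
        return _SklearnScorer(LinearDiscriminantAnalysis()).fit(x, y)
    if name == "NN":
        return _SklearnScorer(MLPClassifier(
            hidden_layer_sizes=(3,), activation="tanh", solver="sgd",
            learning_rate="adaptive", learning_rate_init=0.1,
            max_iter=500, n_iter_no_change=20, tol=1e-5,
            random_state=seed)).fit(x, y)
    if name == "SVM":
        best_c = _tune_by_inner_cv(
            x, y, seed, lambda c: SVC(kernel="linear", C=c), SVM_C_GRID)
        logger.debug("SVM inner tuning selected C=%g", best_c)
        return _PlattSVM(best_c, seed).fit(x, y)
    raise ValueError(f"unknown model {name!r}")


# ---------------------------------------------------------------------------
# Thresholding and metrics


def apply_threshold(probabilities: np.ndarray, threshold: float) -> np.ndarray:
    """Positive iff p >= threshold (the boundary counts as positive)."""
    p = np.asarray(probabilities, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= threshold).astype(int)


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
    )


def confusion_metrics(counts: ConfusionCounts) -> FoldMetrics:
    """Accuracy / sensitivity / specificity in %, NaN where a class is empty."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    acc = 100.0 * (counts.tp + counts.tn) / counts.total
    sens = (100.0 * counts.tp / (counts.tp + counts.fn)
            if counts.tp + counts.fn > 0 else float("nan"))
    spec = (100.0 * counts.tn / (counts.tn + counts.fp)
            if counts.tn + counts.fp > 0 else float("nan"))
    return FoldMetrics(acc, sens, spec)


# ---------------------------------------------------------------------------
# Repeated k-fold evaluation


def _fold_indices(n: int, scheme: CVScheme,
                  groups: np.ndarray | None = None
                  ) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """(trial, train_idx, test_idx) for every trial x fold, from contiguous
    chunks of a seeded permutation.

    With ``scheme.subject_grouped`` and ``groups`` given, the permutation
    and chunking act on unique group ids (subjects) and every row follows
    its subject, so no voice appears on both sides of a fold.
    """
    out = []
    ss = np.random.SeedSequence([scheme.seed, 0x5EED])
    grouped = scheme.subject_grouped and groups is not None
    if grouped:
        uniq = np.unique(np.asarray(groups))
    for trial, child in enumerate(ss.spawn(scheme.trials)):
        rng = np.random.default_rng(child)
        if grouped:
            perm = rng.permutation(uniq)
            chunks = np.array_split(perm, scheme.k)
            for i, test_subjects in enumerate(chunks):
                test = np.nonzero(np.isin(groups, test_subjects))[0]
                train = np.nonzero(~np.isin(groups, test_subjects))[0]
                out.append((trial, train, test))
        else:
            perm = rng.permutation(n)
            chunks = np.array_split(perm, scheme.k)
            for i, test in enumerate(chunks):
                train = np.concatenate([c for j, c in enumerate(chunks) if j != i])
                out.append((trial, train, test))
    return out


def evaluate_models(x: np.ndarray, y: np.ndarray,
                    model_names: Sequence[str] = MODEL_NAMES,
                    scheme: CVScheme | None = None,
                    thresholds: Sequence[float] = THRESHOLDS,
                    comparison_name: str = "",
                    groups: np.ndarray | None = None
                    ) -> dict[tuple[str, float], EvaluationResult]:
    """Evaluate all models on identical folds and resamples.

    Returns one :class:`EvaluationResult` per (model, threshold); the fold
    partitions, the upsampled training rows and the probability vectors are
    shared across thresholds, so the two operating points are two cuts of
    the same scorer, and metrics are paired across models.
    """
    scheme = scheme or CVScheme()
    folds = _fold_indices(y.size, scheme, groups)
    counts: dict[tuple[str, float], list[ConfusionCounts]] = {
        (m, t): [] for m in model_names for t in thresholds}
    ss = np.random.SeedSequence([scheme.seed, 0xF01D])
    fold_seeds = ss.generate_state(2 * len(folds)) % (2**31)
    rf_mtry = (select_rf_mtry(x, y, scheme.seed) if "RF" in model_names else None)
    for f, (trial, train, test) in enumerate(folds):
        if np.unique(y[train]).size < 2:
            raise ValueError(
                f"trial {trial}: training rows of a fold contain a single class")
        if scheme.upsampling:
            xtr, ytr = upsample(x[train], y[train], int(fold_seeds[2 * f]))
        else:
            xtr, ytr = x[train], y[train]
        model_seed = int(fold_seeds[2 * f + 1])
        for name in model_names:
            scorer = fit_model(name, xtr, ytr, model_seed, rf_mtry=rf_mtry)
            proba = scorer.predict_proba_positive(x[test])
            for thr in thresholds:
                pred = apply_threshold(proba, thr)
                counts[(name, thr)].append(confusion_counts(y[test], pred))
    results = {}
    for (name, thr), clist in counts.items():
        metrics = [confusion_metrics(c) for c in clist]
        results[(name, thr)] = EvaluationResult(
            comparison=comparison_name, model=name, threshold=thr,
            fold_counts=clist,
            fold_accuracy=np.array([m.accuracy for m in metrics]),
            fold_sensitivity=np.array([m.sensitivity for m in metrics]),
            fold_specificity=np.array([m.specificity for m in metrics]),
        )
    return results


def repeated_kfold_evaluate(x: np.ndarray, y: np.ndarray, model_name: str,
                            scheme: CVScheme, threshold: float,
                            comparison_name: str = "") -> EvaluationResult:
    """Single-model, single-threshold convenience wrapper; folds depend only
    on the scheme seed, so results pair with any other model's."""
    out = evaluate_models(x, y, [model_name], scheme, [threshold], comparison_name)
    return out[(model_name, threshold)]


def evaluate_grid(scores: pd.DataFrame,
                  model_names: Sequence[str] = MODEL_NAMES,
                  comparison_names: Sequence[str] = COMPARISON_NAMES,
                  scheme: CVScheme | None = None,
                  thresholds: Sequence[float] = THRESHOLDS
                  ) -> dict[tuple[str, str, float], EvaluationResult]:
    """The full comparisons x models x thresholds grid on one score table."""
    scheme = scheme or CVScheme()
    grid = {}
    for cname in comparison_names:
        x, y, meta = make_binary_dataset(scores, cname)
        groups = (meta["subject_id"].to_numpy()
                  if scheme.subject_grouped and "subject_id" in meta else None)
        for key, res in evaluate_models(x, y, model_names, scheme, thresholds,
                                        cname, groups).items():
            grid[(cname,) + key] = res
    return grid


# ---------------------------------------------------------------------------
# Model comparison and reporting


def compare_models(fold_accuracies: dict[str, np.ndarray],
                   alpha: float = 0.05) -> pd.DataFrame:
    """Paired t tests on fold accuracies for every model pair, with
    Bonferroni correction over the number of pairs."""
    names = list(fold_accuracies)
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            diff = fold_accuracies[a] - fold_accuracies[b]
            degenerate = bool(np.allclose(diff, diff[0]) and np.allclose(diff[0], 0.0)
                              or np.std(diff) == 0)
            if degenerate:
                p_raw = 1.0
            else:
                p_raw = float(stats.ttest_rel(fold_accuracies[a], fold_accuracies[b]).pvalue)
            p_corr = min(p_raw * n_pairs, 1.0)
            rows.append({"model_a": a, "model_b": b,
                         "mean_diff_pct": float(np.mean(diff)),
                         "p_raw": p_raw, "p_bonferroni": p_corr,
                         "significant": bool(p_corr < alpha),
                         "degenerate": degenerate})
    return pd.DataFrame(rows)


def results_report(grid: dict[tuple[str, str, float], EvaluationResult],
                   seed: int | None = None, n_pcs: int | None = None,
                   config_hash: str | None = None,
                   model_names: Sequence[str] = MODEL_NAMES,
                   comparison_names: Sequence[str] = COMPARISON_NAMES,
                   thresholds: Sequence[float] = THRESHOLDS
                   ) -> dict[float, pd.DataFrame]:
    """One wide metrics table per threshold (models x metrics by comparison),
    values formatted from the 100-fold means."""
    missing = [(c, m, t) for c in comparison_names for m in model_names
               for t in thresholds if (c, m, t) not in grid]
    if missing:
        raise ValueError(f"missing grid cells: {missing}")
    tables = {}
    for thr in thresholds:
        rows = []
        for m in model_names:
            for metric in ("accuracy", "sensitivity", "specificity"):
                row = {"model": m, "metric": metric}
                for c in comparison_names:
                    row[c] = round(getattr(grid[(c, m, thr)], f"{metric}_pct"), 1)
                rows.append(row)
        tables[thr] = pd.DataFrame(rows)
    return tables


def report_text(tables: dict[float, pd.DataFrame], seed, n_pcs, config_hash) -> str:
    lines = [f"seed={seed} n_pcs={n_pcs} config_hash={config_hash}", ""]
    for thr, table in sorted(tables.items()):
        lines.append(f"Classification performance (%) at threshold {int(thr * 100)}%")
        lines.append(table.to_string(index=False))
        lines.append("")
    return "\n".join(lines)


def config_digest(payload: dict) -> str:
    return hashlib.sha256(repr(sorted(payload.items())).encode()).hexdigest()[:12]
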