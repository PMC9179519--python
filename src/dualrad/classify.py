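"""Random-forest diagnosis with leave-one-out cross-validation.

Benign-vs-malignant classification from conventional (12-d embedded), deep
(4-d latent), or combined (16-d) radiomic feature sets.  Every case is
predicted by a forest trained on all other cases; accuracy is summarized as
the median and interquartile range of case-resampled bootstrap replicates,
agreement as Cohen's kappa, ranking quality as average precision, and
between-setting contrasts as a two-sample t-test on the bootstrap accuracy
samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, cohen_kappa_score
from sklearn.model_selection import StratifiedKFold


class ClassifyError(ValueError):
    """Raised for degenerate label vectors or misaligned inputs."""


@dataclass(frozen=True)
class RFHyperparams:
    """One random-forest setting.  random_state doubles as a grid dimension
    and as the forest's RNG seed — intentionally so, mirroring grids that
    treat it as a tunable."""

    n_estimators: int
    max_depth: int
    random_state: int

    def __post_init__(self) -> None:
        if self.n_estimators < 1 or self.max_depth < 1:
            raise ClassifyError("n_estimators and max_depth must be >= 1")


#: the six settings of the default hyperparameter grid
DEFAULT_GRID: Tuple[RFHyperparams, ...] = (
    RFHyperparams(10, 2, 10),
    RFHyperparams(25, 3, 30),
    RFHyperparams(15, 4, 65),
    RFHyperparams(22, 5, 80),
    RFHyperparams(22, 6, 80),
    RFHyperparams(22, 6, 90),
)


@dataclass
class CVResult:
    """Per-case LOOCV predictions with summary statistics."""

    feature_set: str
    hyperparams: RFHyperparams
    predictions: np.ndarray          # predicted labels, one per case
    scores: np.ndarray               # forest vote fraction for class 1
    labels: np.ndarray
    accuracy_median: float
    accuracy_iqr_low: float
    accuracy_iqr_high: float
    kappa_mean: float
    kappa_std: float
    average_precision: float
    bootstrap_accuracies: np.ndarray = field(repr=False, default=None)


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ClassifyError("labels contain a single class")
    if not np.all(np.isin(classes, [0, 1])):
        raise ClassifyError("labels must be 0 (benign) / 1 (malignant)")
    return y


def cohen_kappa(pred: Sequence[int], y: Sequence[int]) -> float:
    """Chance-corrected agreement; 0 (with a warning) if chance agreement
    is already perfect (degenerate marginals)."""
    pred = np.asarray(pred)
    y = np.asarray(y)
    if pred.shape != y.shape:
        raise ClassifyError("pred and y must be aligned")
    classes = np.union1d(pred, y)
    if len(classes) == 1:
        warnings.warn("degenerate marginals: chance agreement is 1; kappa := 0",
                      stacklevel=2)
        return 0.0
    return float(cohen_kappa_score(y, pred, labels=classes))


def accuracy_summary(pred: Sequence[int], y: Sequence[int], n_boot: int = 1000,
                     seed: int = 0) -> Tuple[float, Tuple[float, float], np.ndarray]:
    """Median and IQR of accuracy over case-resampled bootstrap replicates.

    A single LOOCV pass yields one accuracy number; resampling the
    (prediction, label) pairs gives it a sampling distribution without
    re-running any training.  Returns (median, (q25, q75), samples).
    """
    pred = np.asarray(pred)
    y = np.asarray(y)
    if pred.shape != y.shape:
        raise ClassifyError("pred and y must be aligned")
    if n_boot < 100:
        raise ClassifyError("n_boot must be >= 100")
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    acc = (pred[idx] == y[idx]).mean(axis=1)
    q25, q50, q75 = np.percentile(acc, [25, 50, 75])
    return float(q50), (float(q25), float(q75)), acc


def paired_accuracy_ttest(boot_a: np.ndarray, boot_b: np.ndarray
                          ) -> Tuple[float, float]:
    """Two-sample two-tailed t-test between two bootstrap accuracy samples."""
    a = np.asarray(boot_a, dtype=float)
    b = np.asarray(boot_b, dtype=float)
    if a.std() == 0.0 and b.std() == 0.0:
        # degenerate samples (e.g. every replicate at accuracy 1.0)
        return (0.0, 1.0) if a.mean() == b.mean() else (np.inf, 0.0)
    t, p = stats.ttest_ind(a, b)
    return float(t), float(p)


def pr_curve_ap(scores: Sequence[float], y: Sequence[int]
                ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Precision-recall points and step-interpolated average precision."""
    y = _check_binary(np.asarray(y))
    scores = np.asarray(scores, dtype=float)
    from sklearn.metrics import precision_recall_curve

    precision, recall, _ = precision_recall_curve(y, scores)
    ap = float(average_precision_score(y, scores))
    return precision, recall, ap


def per_feature_wilcoxon(X: np.ndarray, y: Sequence[int],
                         bh_correct: bool = False) -> pd.DataFrame:
    """Two-sided rank-sum (Mann-Whitney) test per feature column.

    Exact null when both groups have <= 10 cases and the column has no ties;
    otherwise the tie-corrected normal approximation.  Constant columns get
    p = 1 with a warning.  Raw p-values by default; ``bh_correct`` adds a
    Benjamini-Hochberg column.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = _check_binary(np.asarray(y))
    a = X[y == 0]
    b = X[y == 1]
    if len(a) < 2 or len(b) < 2:
        raise ClassifyError("need >= 2 cases per class")
    stats_out, pvals = [], []
    exact_ok = min(len(a), len(b)) <= 10
    for j in range(X.shape[1]):
        col = X[:, j]
        if np.all(col == col[0]):
            warnings.warn(f"feature column {j} is constant; p := 1", stacklevel=2)
            stats_out.append(len(a) * len(b) / 2.0)
            pvals.append(1.0)
            continue
        has_ties = len(np.unique(col)) < len(col)
        method = "exact" if (exact_ok and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(a[:, j], b[:, j], alternative="two-sided",
                                 method=method)
        stats_out.append(float(res.statistic))
        pvals.append(float(res.pvalue))
    out = pd.DataFrame({"statistic": stats_out, "p_value": pvals})
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        out["p_bh"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# LOOCV
# ---------------------------------------------------------------------------

FoldTransform = Callable[[np.ndarray, np.ndarray], Tuple[np.ndarray, np.ndarray]]


def loocv_predictions(X: np.ndarray, y: np.ndarray, hp: RFHyperparams,
                      fold_transform: Optional[FoldTransform] = None,
                      ) -> Tuple[np.ndarray, np.ndarray]:
    """Leave-one-out predictions and class-1 scores.

    ``fold_transform(X_train, X_test)`` is applied per fold before fitting —
    e.g. an inductive spectral embedding — so the left-out case never
    influences any fitted stage.
    """
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    if len(X) != len(y):
        raise ClassifyError("X and y are misaligned")
    n = len(y)
    preds = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    for i in range(n):
        tr = np.arange(n) != i
        Xtr, Xte = X[tr], X[i:i + 1]
        if fold_transform is not None:
            Xtr, Xte = fold_transform(Xtr, Xte)
        clf = RandomForestClassifier(n_estimators=hp.n_estimators,
                                     max_depth=hp.max_depth,
                                     random_state=hp.random_state)
        clf.fit(Xtr, y[tr])
        prob = clf.predict_proba(Xte)[0]
        score = prob[list(clf.classes_).index(1)] if 1 in clf.classes_ else 0.0
        scores[i] = score
        preds[i] = int(score >= 0.5)
    return preds, scores


def loocv_rf(X: np.ndarray, y: np.ndarray, hp: RFHyperparams,
             feature_set: str = "conv",
             fold_transform: Optional[FoldTransform] = None,
             n_boot: int = 1000, boot_seed: int = 0) -> CVResult:
    """Full LOOCV evaluation of one feature set under one hyperparameter
    setting, with bootstrap accuracy/kappa summaries and average precision."""
    preds, scores = loocv_predictions(X, y, hp, fold_transform)
    y = _check_binary(y)
    return summarize_cv(preds, scores, y, hp, feature_set, n_boot, boot_seed)


def summarize_cv(preds: np.ndarray, scores: np.ndarray, y: np.ndarray,
                 hp: RFHyperparams, feature_set: str,
                 n_boot: int = 1000, boot_seed: int = 0) -> CVResult:
    med, (lo, hi), acc_boot = accuracy_summary(preds, y, n_boot, boot_seed)
    rng = np.random.default_rng(boot_seed)
    n = len(y)
    idx = rng.integers(0, n, size=(n_boot, n))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappas = np.array([cohen_kappa(preds[ix], y[ix]) for ix in idx])
    _, _, ap = pr_curve_ap(scores, y)
    return CVResult(
        feature_set=feature_set, hyperparams=hp,
        predictions=preds, scores=scores, labels=y,
        accuracy_median=med, accuracy_iqr_low=lo, accuracy_iqr_high=hi,
        kappa_mean=float(kappas.mean()), kappa_std=float(kappas.std()),
        average_precision=ap, bootstrap_accuracies=acc_boot,
    )


def grid_evaluate(X_conv: np.ndarray, X_deep: np.ndarray, y: np.ndarray,
                  grid: Sequence[RFHyperparams] = DEFAULT_GRID,
                  conv_fold_transform: Optional[FoldTransform] = None,
                  n_boot: int = 1000, boot_seed: int = 0) -> pd.DataFrame:
    """Evaluate every grid setting on conv, deep, and concatenated features.

    Returns a table with one row per (setting, feature set) — 18 rows under
    the default six-setting grid — including a t-test of each row's
    bootstrap accuracy sample against the best row's.
    """
    X_conv = np.asarray(X_conv, dtype=float)
    X_deep = np.asarray(X_deep, dtype=float)
    y = _check_binary(y)
    if len(X_conv) != len(y) or len(X_deep) != len(y):
        raise ClassifyError("feature matrices and labels are misaligned")
    ncol = X_conv.shape[1]
    combined_ft: Optional[FoldTransform] = None
    if conv_fold_transform is not None:
        def combined_ft(Xtr, Xte):  # reduce the conv part, pass deep through
            ctr, cte = conv_fold_transform(Xtr[:, :ncol], Xte[:, :ncol])
            return (np.hstack([ctr, Xtr[:, ncol:]]),
                    np.hstack([cte, Xte[:, ncol:]]))
    feature_sets = {
        "conv": (X_conv, conv_fold_transform),
        "deep": (X_deep, None),
        "conv+deep": (np.hstack([X_conv, X_deep]), combined_ft),
    }
    results: List[CVResult] = []
    for hp in grid:
        for name, (Xf, ft) in feature_sets.items():
            results.append(loocv_rf(Xf, y, hp, feature_set=name,
                                    fold_transform=ft,
                                    n_boot=n_boot, boot_seed=boot_seed))
    best = max(results, key=lambda r: r.accuracy_median)
    rows = []
    for r in results:
        if r is best:
            t = p = np.nan
        else:
            t, p = paired_accuracy_ttest(best.bootstrap_accuracies,
                                         r.bootstrap_accuracies)
        rows.append({
            "n_estimators": r.hyperparams.n_estimators,
            "max_depth": r.hyperparams.max_depth,
            "random_state": r.hyperparams.random_state,
            "feature_set": r.feature_set,
            "accuracy_median": r.accuracy_median,
            "accuracy_iqr_low": r.accuracy_iqr_low,
            "accuracy_iqr_high": r.accuracy_iqr_high,
            "kappa_mean": r.kappa_mean,
            "kappa_std": r.kappa_std,
            "t_vs_best": t,
            "p_vs_best": p,
            "average_precision": r.average_precision,
        })
    return pd.DataFrame(rows)


def kfold_grid_search(X: np.ndarray, y: np.ndarray,
                      grid: Sequence[RFHyperparams] = DEFAULT_GRID,
                      k: int = 5, seed: int = 0) -> RFHyperparams:
    """Best setting by mean k-fold accuracy; ties prefer fewer trees, then
    shallower depth."""
    X = np.asarray(X, dtype=float)
    y = _check_binary(y)
    if k > len(y):
        raise ClassifyError(f"k={k} exceeds n={len(y)}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    scored = []
    for hp in grid:
        accs = []
        for tr, te in folds:
            clf = RandomForestClassifier(n_estimators=hp.n_estimators,
                                         max_depth=hp.max_depth,
                                         random_state=hp.random_state)
            clf.fit(X[tr], y[tr])
            accs.append(float((clf.predict(X[te]) == y[te]).mean()))
        scored.append((float(np.mean(accs)), hp))
    scored.sort(key=lambda item: (-item[0], item[1].n_estimators,
                                  item[1].max_depth))
    return scored[0][1]
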