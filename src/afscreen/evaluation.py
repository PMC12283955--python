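"""Model selection and evaluation protocol.

Hyperparameters (sigma, gamma, and the class-cost ratio) are chosen by
stratified 5-fold cross-validation grid search maximizing the mean held-out
AUROC.  The reported operating point is the raw SVM decision boundary
(score 0); ROC curves use the continuous scores.  The module also provides
the cross-source evaluation table, confusion counts by original rhythm label,
and the data-efficiency resampling study (repeated stratified subsampling of
the training pool at increasing sizes against a frozen test set).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold

from .kernel import KernelParams, SelfTermCache, pairwise_sq_dist, second_level_kernel
from .svm import DistributionalSVC, _solve_dual

#: Default tuning grids.  Normalized RRi values live near 1, so informative
#: base bandwidths are sub-unit; cost ratios favor sensitivity when > 1.
DEFAULT_SIGMAS = (0.01, 0.05, 0.1, 0.5, 1.0)
DEFAULT_GAMMAS = (0.25, 0.5, 1.0, 2.0)
DEFAULT_COST_RATIOS = (1.0, 2.0, 4.0, 8.0, 16.0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Confusion counts and the derived screening metrics.

    accuracy = (TP+TN)/N, F1 = 2TP/(2TP+FP+FN), sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); AUROC by trapezoidal integration of the ROC.
    Metrics with a zero denominator (and AUROC when only one class is
    present) are NaN, i.e. flagged undefined rather than silently 0.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float
    auroc: float
    roc_points: np.ndarray = field(default_factory=lambda: np.empty((0, 3)))

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "accuracy": self.accuracy, "f1": self.f1,
                "sensitivity": self.sensitivity, "specificity": self.specificity,
                "auroc": self.auroc}


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else float("nan")


def compute_metrics(y_true, y_pred, scores=None) -> MetricsReport:
    """Confusion counts and the metric panel from true/predicted labels in {-1, +1}.

    ``scores`` (continuous decision values, higher = more AF-like) feed the
    ROC; without them AUROC is undefined.
    """
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal lengths")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == -1) & (y_pred == -1)))
    fp = int(np.sum((y_true == -1) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == -1)))

    auroc, roc_points = float("nan"), np.empty((0, 3))
    if scores is not None:
        scores = np.asarray(scores, dtype=float)
        if scores.shape != y_true.shape:
            raise ValueError("scores must align with y_true")
        if np.unique(y_true).size == 2:
            fpr, tpr, thr = roc_curve(y_true, scores, pos_label=1)
            auroc = float(auc(fpr, tpr))
            roc_points = np.column_stack([fpr, tpr, thr])
    return MetricsReport(
        tp=tp, tn=tn, fp=fp, fn=fn,
        accuracy=_safe_div(tp + tn, tp + tn + fp + fn),
        f1=_safe_div(2 * tp, 2 * tp + fp + fn),
        sensitivity=_safe_div(tp, tp + fn),
        specificity=_safe_div(tn, tn + fp),
        auroc=auroc, roc_points=roc_points)


@dataclass
class ConfusionByLabel:
    """Predicted AF/noAF counts per original rhythm label (the corpus vocabulary)."""

    counts: pd.DataFrame  # index: raw_label; columns: pred_AF, pred_noAF

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)


def confusion_by_label(raw_labels, y_pred) -> ConfusionByLabel:
    y_pred = np.asarray(y_pred, dtype=int)
    df = pd.DataFrame({"raw": list(raw_labels), "pred": y_pred})
    tab = (df.assign(col=np.where(df["pred"] == 1, "pred_AF", "pred_noAF"))
             .pivot_table(index="raw", columns="col", aggfunc="size", fill_value=0))
    for c in ("pred_AF", "pred_noAF"):
        if c not in tab:
            tab[c] = 0
    return ConfusionByLabel(counts=tab[["pred_AF", "pred_noAF"]].sort_index())


# ---------------------------------------------------------------------------
# Cross-validated grid search
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Finite search grids over sigma, gamma and the cost ratio."""

    sigmas: tuple = DEFAULT_SIGMAS
    gammas: tuple = DEFAULT_GAMMAS
    cost_ratios: tuple = DEFAULT_COST_RATIOS
    n_folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sigmas", "gammas", "cost_ratios"):
            vals = tuple(getattr(self, name))
            object.__setattr__(self, name, vals)
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if len(set(vals)) != len(vals):
                raise ValueError(f"{name} contains duplicates: {vals}")
            if any(not v > 0 for v in vals):
                raise ValueError(f"{name} must be positive: {vals}")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def _labels_of(vectors) -> np.ndarray:
    y = np.array([v.binary_label for v in vectors])
    if any(lab not in (-1, 1) for lab in y):
        raise ValueError("every vector needs a binary_label of +1 or -1")
    return y.astype(int)


def cv_grid_search(train_val, grid: GridSpec):
    """Stratified k-fold grid search maximizing mean held-out AUROC.

    For every (sigma, gamma, cost_ratio) cell the SVM is trained on k-1 folds
    and scored on the held-out fold; the cell maximizing the mean AUROC wins,
    with ties resolved toward the cell earlier in (sigma, gamma, cost_ratio)
    grid order.  Squared-distance matrices are computed once per sigma and
    shared across gammas, folds and cost ratios via the self-term cache.

    Returns ``(best_params, best_cost_ratio, table)`` where ``table`` has one
    row per grid cell with per-fold AUROCs, their mean, and (both labeled)
    their variance and standard deviation.
    """
    vectors = list(train_val)
    y = _labels_of(vectors)
    counts = {c: int(np.sum(y == c)) for c in (-1, 1)}
    if min(counts.values()) < grid.n_folds:
        small = min(counts, key=counts.get)
        raise ValueError(f"class {small:+d} has {counts[small]} members, fewer "
                         f"than n_folds={grid.n_folds}")
    skf = StratifiedKFold(n_splits=grid.n_folds, shuffle=True, random_state=grid.seed)
    folds = list(skf.split(np.zeros(len(y)), y))

    cache = SelfTermCache()
    rows = []
    best = None  # (mean_auroc, params, w)
    for sigma in grid.sigmas:
        D = pairwise_sq_dist(vectors, vectors, sigma, cache)
        for gamma in grid.gammas:
            K = second_level_kernel(D, gamma)
            for w in grid.cost_ratios:
                fold_aurocs = []
                for tr, te in folds:
                    svc = _solve_dual(K[np.ix_(tr, tr)], y[tr], C=1.0,
                                      cost_ratio=w, tol=1e-6, max_iter=1_000_000)
                    scores = svc.decision_function(K[np.ix_(te, tr)])
                    fpr, tpr, _ = roc_curve(y[te], scores, pos_label=1)
                    fold_aurocs.append(float(auc(fpr, tpr)))
                mean_auroc = float(np.mean(fold_aurocs))
                rows.append({"sigma": sigma, "gamma": gamma, "cost_ratio": w,
                             **{f"fold{i}_auroc": a for i, a in enumerate(fold_aurocs)},
                             "mean_auroc": mean_auroc,
                             "var_auroc": float(np.var(fold_aurocs)),
                             "sd_auroc": float(np.std(fold_aurocs))})
                if best is None or mean_auroc > best[0]:
                    best = (mean_auroc, KernelParams(sigma, gamma), w)
    table = pd.DataFrame(rows)
    return best[1], best[2], table


# ---------------------------------------------------------------------------
# Evaluation harnesses
# ---------------------------------------------------------------------------

def evaluate_model(model: DistributionalSVC, vectors) -> tuple:
    """Score a vector set; returns (MetricsReport, ConfusionByLabel)."""
    vectors = list(vectors)
    y = _labels_of(vectors)
    scores = model.decision_function(vectors)
    pred = np.where(scores >= 0.0, 1, -1)
    report = compute_metrics(y, pred, scores)
    return report, confusion_by_label([v.raw_label for v in vectors], pred)


def evaluate_cross(models: dict, testsets: dict) -> pd.DataFrame:
    """Full train-source x test-source metric table (one row per pair)."""
    rows = []
    for train_name, model in models.items():
        for test_name, vectors in testsets.items():
            report, _ = evaluate_model(model, vectors)
            rows.append({"train_source": train_name, "test_source": test_name,
                         **report.as_dict()})
    return pd.DataFrame(rows)


def _stratified_draw(rng: np.random.Generator, y: np.ndarray, size: int) -> np.ndarray:
    """Indices of a stratified subsample of ``size`` preserving class proportions
    (largest remainder; at least one member per class)."""
    classes = np.unique(y)
    exact = {c: size * np.mean(y == c) for c in classes}
    take = {c: int(np.floor(v)) for c, v in exact.items()}
    order = sorted(classes, key=lambda c: (-(exact[c] - take[c]), c))
    for c in order[: size - sum(take.values())]:
        take[c] += 1
    if any(take[c] == 0 for c in classes):
        raise ValueError(f"size {size} cannot contain both classes at pool prevalence")
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        idx.append(rng.choice(members, size=take[c], replace=False))
    return np.concatenate(idx)


def data_efficiency_study(pool, sizes, n_resamples: int, seed: int,
                          params: KernelParams, cost_ratio: float,
                          test_set) -> pd.DataFrame:
    """Learning-curve study: repeated stratified subsampling of the training pool.

    For each requested size, ``n_resamples`` independent stratified draws are
    each trained with the fixed hyperparameters and evaluated on the frozen
    ``test_set``.  Returns one row per (size, resample) with the metric panel;
    summarize with :func:`summarize_data_efficiency` for box-plot quantiles.
    """
    pool = list(pool)
    test_set = list(test_set)
    y = _labels_of(pool)
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > len(pool):
            raise ValueError(f"size {size} exceeds pool size {len(pool)}")
        for r in range(n_resamples):
            idx = _stratified_draw(rng, y, size)
            model = DistributionalSVC(sigma=params.sigma, gamma=params.gamma,
                                      cost_ratio=cost_ratio)
            model.fit([pool[i] for i in idx], y[idx])
            report, _ = evaluate_model(model, test_set)
            rows.append({"size": size, "resample": r, **report.as_dict()})
    return pd.DataFrame(rows)


def summarize_data_efficiency(table: pd.DataFrame,
                              quantiles=(0.05, 0.25, 0.5, 0.75, 0.95)) -> pd.DataFrame:
    """Per-size metric quantiles (the box-plot analogue of the resampling study)."""
    metrics = ["accuracy", "f1", "sensitivity", "specificity", "auroc"]
    out = table.groupby("size")[metrics].quantile(list(quantiles))
    out.index.names = ["size", "quantile"]
    return out.reset_index()
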