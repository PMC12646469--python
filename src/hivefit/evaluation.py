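"""Leakage-safe evaluation harness.

Stratified k-fold cross-validation with minority oversampling (SMOTE)
applied strictly inside training folds, the confusion-count metric suite
(accuracy, sensitivity/recall, precision, F1), probabilistic metrics
(Brier score, reliability curve, ROC-AUC, PR-AUC), a paired-fold t test
for model comparison, and the stage-by-base comparison report.

Headline metrics are reported both fold-averaged (the cross-validation
convention) and pooled over the out-of-fold confusion counts; the two can
differ and both are first-class outputs. Undefined ratios (zero
denominators) are reported as NaN with a reason code, never silently 0,
and are excluded from fold averages with an exclusion count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neighbors import NearestNeighbors

from .cohort import CohortTable
from .models import HybridClassifier, ModelSpec, build_model


class StratificationError(ValueError):
    pass


class ResamplingError(ValueError):
    pass


@dataclass(frozen=True)
class CVConfig:
    """Cross-validation protocol parameters (defaults: stratified 5-fold
    with SMOTE inside training folds)."""

    k: int = 5
    stratified: bool = True
    resampling: str = "smote_within_fold"  # or "none"
    smote_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.smote_neighbors < 1:
            raise ValueError("smote_neighbors must be >= 1")
        if self.resampling not in ("none", "smote_within_fold"):
            raise ValueError(f"unknown resampling {self.resampling!r}")


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true, dtype=int)
        y_pred = np.asarray(y_pred, dtype=int)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )


@dataclass
class MetricValues:
    accuracy: float
    sensitivity: float
    precision: float
    f1: float
    reasons: dict[str, str] = field(default_factory=dict)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "precision": self.precision,
            "f1": self.f1,
        }


def metrics_from_counts(c: ConfusionCounts) -> MetricValues:
    """Accuracy, sensitivity (recall), precision and F1 from confusion counts.

    accuracy = (TP+TN)/(TP+FP+FN+TN); sensitivity = TP/(TP+FN);
    precision = TP/(TP+FP); F1 = 2*sens*prec/(sens+prec). A zero denominator
    yields NaN with a reason code.
    """
    if c.total == 0:
        raise ValueError("no evaluated instances")
    reasons: dict[str, str] = {}
    accuracy = (c.tp + c.tn) / c.total

    if c.tp + c.fn == 0:
        sensitivity = float("nan")
        reasons["sensitivity"] = "no positive instances"
    else:
        sensitivity = c.tp / (c.tp + c.fn)

    if c.tp + c.fp == 0:
        precision = float("nan")
        reasons["precision"] = "no positive predictions"
    else:
        precision = c.tp / (c.tp + c.fp)

    if np.isnan(sensitivity) or np.isnan(precision):
        f1 = float("nan")
        reasons["f1"] = "undefined component"
    elif sensitivity + precision == 0:
        f1 = float("nan")
        reasons["f1"] = "sensitivity + precision = 0"
    else:
        f1 = 2 * sensitivity * precision / (sensitivity + precision)
    return MetricValues(accuracy, sensitivity, precision, f1, reasons)


# ----------------------------------------------------------------------
# Folds and resampling
# ----------------------------------------------------------------------

def stratified_folds(y, k: int, seed: int = 0) -> list[np.ndarray]:
    """k disjoint test-index sets partitioning all indices, with per-fold
    class counts within 1 of proportionality."""
    y = np.asarray(y, dtype=int)
    if k == len(y):  # boundary: k = n is a leave-one-out partition
        return [np.array([i]) for i in range(k)]
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise StratificationError(
            f"smallest class has {counts.min()} members, fewer than k={k}"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros_like(y), y)]


def holdout_split(y, test_fraction: float = 33 / 162, seed: int = 0):
    """Optional stratified holdout (train_idx, test_idx); cross-validation
    remains the primary protocol."""
    idx = np.arange(len(y))
    tr, te = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return np.sort(tr), np.sort(te)


def smote_oversample(X, y, k_neighbors: int = 5, seed: int = 0):
    """Classic SMOTE: balance classes by interpolating synthetic minority rows.

    Each synthetic row is s = x_i + u * (x_j - x_i) with u ~ Uniform[0, 1],
    x_i a minority row and x_j one of its k minority-class nearest neighbors.
    Original rows are returned unchanged (first), synthetic rows appended.
    Already-balanced input is returned as-is. ``k_neighbors`` is shrunk to
    minority_count - 1 with a warning when necessary.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ResamplingError("smote_oversample requires exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min < 2:
        raise ResamplingError("minority class has a single member")
    k = k_neighbors
    if k > n_min - 1:
        warnings.warn(
            f"k_neighbors={k_neighbors} exceeds minority size - 1; using {n_min - 1}",
            stacklevel=2,
        )
        k = n_min - 1

    X_min = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, neighbors = nn.kneighbors(X_min)  # col 0 is the point itself

    rng = np.random.default_rng(seed)
    need = n_maj - n_min
    base = rng.integers(n_min, size=need)
    pick = rng.integers(1, k + 1, size=need)
    u = rng.random((need, 1))
    xi = X_min[base]
    xj = X_min[neighbors[base, pick]]
    synthetic = xi + u * (xj - xi)

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(need, minority)])
    return X_out, y_out


# ----------------------------------------------------------------------
# Probability metrics
# ----------------------------------------------------------------------

@dataclass
class CalibrationCurve:
    bin_edges: np.ndarray
    mean_predicted: np.ndarray
    observed_frequency: np.ndarray
    counts: np.ndarray

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo": self.bin_edges[:-1],
                "bin_hi": self.bin_edges[1:],
                "mean_predicted": self.mean_predicted,
                "observed_frequency": self.observed_frequency,
                "count": self.counts,
            }
        )


@dataclass
class ProbabilityMetrics:
    brier: float
    roc_auc: float
    pr_auc: float
    calibration: CalibrationCurve
    reasons: dict[str, str] = field(default_factory=dict)


def calibration_curve(probs, y, n_bins: int = 10) -> CalibrationCurve:
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    # right-closed last bin so probability 1.0 is counted
    idx = np.clip(np.digitize(probs, edges[1:-1]), 0, n_bins - 1)
    mean_pred = np.full(n_bins, np.nan)
    obs = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            mean_pred[b] = probs[sel].mean()
            obs[b] = y[sel].mean()
    return CalibrationCurve(edges, mean_pred, obs, counts)


def probability_metrics(probs, y, n_bins: int = 10) -> ProbabilityMetrics:
    """Brier score, reliability curve, ROC-AUC (trapezoidal over the full
    threshold sweep) and PR-AUC (step interpolation)."""
    probs = np.asarray(probs, dtype=float)
    y = np.asarray(y, dtype=int)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    brier = float(np.mean((probs - y) ** 2))
    curve = calibration_curve(probs, y, n_bins)
    reasons: dict[str, str] = {}
    if len(np.unique(y)) < 2:
        roc = pr = float("nan")
        reasons["roc_auc"] = reasons["pr_auc"] = "single-class outcome"
    else:
        roc = float(roc_auc_score(y, probs))
        pr = float(average_precision_score(y, probs))
    return ProbabilityMetrics(brier, roc, pr, curve, reasons)


# ----------------------------------------------------------------------
# Cross-validation
# ----------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Per-model evaluation report: fold-averaged and pooled-count metrics,
    per-fold score vectors, pooled confusion counts and probability metrics."""

    model_name: str
    fold_scores: dict[str, np.ndarray]
    fold_counts: list[ConfusionCounts]
    pooled_counts: ConfusionCounts
    pooled_metrics: MetricValues
    probability: ProbabilityMetrics
    n: int
    excluded: dict[str, int] = field(default_factory=dict)

    def mean_fold(self, metric: str) -> float:
        vals = self.fold_scores[metric]
        finite = vals[np.isfinite(vals)]
        return float(finite.mean()) if len(finite) else float("nan")

    def as_dict(self) -> dict:
        out = {
            "model": self.model_name,
            "n": self.n,
            "pooled": self.pooled_metrics.as_dict(),
            "fold_mean": {m: self.mean_fold(m) for m in self.fold_scores},
            "brier": self.probability.brier,
            "roc_auc": self.probability.roc_auc,
            "pr_auc": self.probability.pr_auc,
            "confusion": {
                "tp": self.pooled_counts.tp,
                "tn": self.pooled_counts.tn,
                "fp": self.pooled_counts.fp,
                "fn": self.pooled_counts.fn,
            },
        }
        return out


def cross_validate(
    spec: ModelSpec, cohort: CohortTable, cv: CVConfig | None = None
) -> MetricsReport:
    """Stratified k-fold evaluation of one model spec.

    Per fold: the full pipeline (any L1 selection or ABC mask search
    included) is fit on the training portion only, with oversampling — when
    enabled — applied to that training portion alone; the untouched test
    fold is then predicted. Test folds never contain synthetic rows: rows
    are referenced by original index and resampling happens after the split,
    which is asserted on every call.
    """
    cv = cv or CVConfig()
    X, y = cohort.X, cohort.y
    folds = stratified_folds(y, cv.k, seed=cv.seed)
    n = len(y)
    all_test = np.concatenate(folds)
    assert len(all_test) == n and len(np.unique(all_test)) == n, (
        "folds must partition the original rows"
    )

    resample = "smote" if cv.resampling == "smote_within_fold" else None
    fold_scores: dict[str, list[float]] = {
        m: [] for m in ("accuracy", "sensitivity", "precision", "f1")
    }
    fold_counts: list[ConfusionCounts] = []
    pooled_probs = np.empty(n)
    pooled_pred = np.empty(n, dtype=int)
    excluded: dict[str, int] = {}

    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), test_idx)
        y_tr, y_te = y[train_idx], y[test_idx]
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            raise StratificationError(f"fold {f} has a single class after split")
        model = build_model(spec_with_seed(spec, spec.seed * 100 + f))
        model.fit(X[train_idx], y_tr, resample=resample)
        probs = model.predict_proba(X[test_idx])
        pred = (probs >= 0.5).astype(int)
        pooled_probs[test_idx] = probs
        pooled_pred[test_idx] = pred

        counts = ConfusionCounts.from_predictions(y_te, pred)
        fold_counts.append(counts)
        vals = metrics_from_counts(counts)
        for m, v in vals.as_dict().items():
            fold_scores[m].append(v)
            if np.isnan(v):
                excluded[m] = excluded.get(m, 0) + 1

    pooled = ConfusionCounts.from_predictions(y, pooled_pred)
    assert pooled.total == n, "pooled confusion counts must sum to n"
    report = MetricsReport(
        model_name=spec.name,
        fold_scores={m: np.array(v) for m, v in fold_scores.items()},
        fold_counts=fold_counts,
        pooled_counts=pooled,
        pooled_metrics=metrics_from_counts(pooled),
        probability=probability_metrics(pooled_probs, y),
        n=n,
        excluded=excluded,
    )
    return report


def spec_with_seed(spec: ModelSpec, seed: int) -> ModelSpec:
    """Copy of a spec with a derived per-fold seed (kept below 2^31)."""
    from dataclasses import replace

    return replace(spec, seed=int(seed) % (2**31 - 1))


def cross_validate_leaky_smote(
    spec: ModelSpec, cohort: CohortTable, cv: CVConfig | None = None
) -> float:
    """Deliberately WRONG protocol, offered only as a test harness:
    oversample the whole dataset before splitting, so synthetic neighbors of
    test rows leak into training. Returns mean fold accuracy; exists to
    demonstrate the optimistic bias that the leakage-safe harness avoids."""
    cv = cv or CVConfig()
    X, y = cohort.X, cohort.y
    X_aug, y_aug = smote_oversample(X, y, cv.smote_neighbors, seed=cv.seed)
    folds = stratified_folds(y_aug, cv.k, seed=cv.seed)
    accs = []
    for f, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(y_aug)), test_idx)
        model = build_model(spec_with_seed(spec, cv.seed * 100 + f))
        model.fit(X_aug[train_idx], y_aug[train_idx])
        pred = model.predict(X_aug[test_idx])
        accs.append(float(np.mean(pred == y_aug[test_idx])))
    return float(np.mean(accs))


# ----------------------------------------------------------------------
# Paired fold test
# ----------------------------------------------------------------------

@dataclass
class PairedTestResult:
    mean_difference: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    df: int
    exact_tie: bool = False


def paired_fold_test(
    scores_a, scores_b, alpha: float = 0.05
) -> PairedTestResult:
    """Classical paired t test on per-fold scores from identical partitions.

    Returns the mean difference (a - b), two-sided t statistic and p-value
    with df = k - 1, and the (1 - alpha) CI from the t quantile. Zero-variance
    differences yield an exact-tie report instead of a t statistic.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("score vectors must be 1-D, equal length >= 2")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    k = len(d)
    if sd == 0:
        return PairedTestResult(
            mean, float("nan"), float("nan"), mean, mean, k - 1, exact_tie=True
        )
    se = sd / np.sqrt(k)
    t = mean / se
    p = 2 * stats.t.sf(abs(t), df=k - 1)
    q = stats.t.ppf(1 - alpha / 2, df=k - 1)
    return PairedTestResult(mean, float(t), float(p), mean - q * se, mean + q * se, k - 1)


# ----------------------------------------------------------------------
# Comparison report
# ----------------------------------------------------------------------

_STAGE_NUMBER = {"simple": 1, "lr_hybrid": 2, "abc_lr_hybrid": 3}


def format_percent(x: float) -> str:
    """Two-decimal percent formatting used in the comparison report."""
    if np.isnan(x):
        return "NA"
    return f"{100 * x:.2f}"


def comparison_table(
    cohort: CohortTable,
    grid: list[ModelSpec],
    cv: CVConfig | None = None,
    metric_view: str = "fold_mean",
) -> pd.DataFrame:
    """Stage-by-base comparison report: one row per grid spec with accuracy,
    F-score, recall and precision as percentages to two decimals, grouped by
    stage. The best row (by accuracy) is flagged; a failed model run is
    marked failed with its error class and the run continues.

    ``metric_view`` selects fold-averaged (default) or pooled-count metrics.
    """
    cv = cv or CVConfig()
    rows = []
    reports: dict[str, MetricsReport] = {}
    for i, spec in enumerate(grid, start=1):
        row = {
            "No": i,
            "Stage": _STAGE_NUMBER[spec.stage],
            "Model": spec.name,
            "Model Type": "Simple" if spec.stage == "simple" else "Hybrid",
        }
        try:
            rep = cross_validate(spec, cohort, cv)
            reports[spec.name] = rep
            if metric_view == "pooled":
                vals = rep.pooled_metrics.as_dict()
            else:
                vals = {m: rep.mean_fold(m) for m in rep.fold_scores}
            row.update(
                {
                    "Acc.": round(100 * vals["accuracy"], 2),
                    "F-Score": round(100 * vals["f1"], 2),
                    "Recall": round(100 * vals["sensitivity"], 2),
                    "Precision": round(100 * vals["precision"], 2),
                    "Status": "ok",
                }
            )
        except Exception as exc:  # isolate failures to their row
            row.update(
                {
                    "Acc.": np.nan,
                    "F-Score": np.nan,
                    "Recall": np.nan,
                    "Precision": np.nan,
                    "Status": f"failed: {type(exc).__name__}",
                }
            )
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(["Stage", "No"]).reset_index(drop=True)
    table["Best"] = False
    if table["Acc."].notna().any():
        table.loc[table["Acc."].idxmax(), "Best"] = True
    table.attrs["reports"] = reports
    return table
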