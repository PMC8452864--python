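"""Classification and statistics protocol for the imbalanced cohort.

The cohort is imbalanced (many more cases than controls), so evaluation uses
repeated undersampling: each iteration draws a random majority-class subset
matching the minority size, then runs stratified five-fold cross-validation
with an L1-regularized linear SVM (scaling and model fitted on training
folds only), and metrics are averaged across folds and then across the 100
iterations.  A random-assignment "chance" classifier provides the floor.
Feature selection uses recursive feature elimination scored by the same
balanced CV AUC, and feature-to-clinical-score association uses partial
Spearman correlation with covariate adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import RobustScaler
from sklearn.svm import LinearSVC

__all__ = [
    "PerformanceSummary",
    "ProtocolConfig",
    "robust_scale",
    "roc_metrics",
    "chance_classifier",
    "balanced_repeated_cv",
    "rfecv_select",
    "partial_spearman",
]


@dataclass
class ProtocolConfig:
    """Settings of the repeated undersampled cross-validation protocol."""

    n_iterations: int = 100
    n_folds: int = 5
    svm_C: float = 1.0
    ci_method: str = "normal"  # normal | percentile
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class PerformanceSummary:
    """Metrics (in percent) averaged over the repeated CV protocol."""

    auc_pct: float
    sensitivity_pct: float
    specificity_pct: float
    accuracy_pct: float
    auc_ci_95: tuple[float, float]
    n_iterations: int
    n_folds: int
    seed: int
    model: str = ""
    iteration_auc_pct: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        lo, hi = self.auc_ci_95
        if not (lo <= self.auc_pct <= hi):
            raise ValueError("CI must bracket the mean AUC")

    def to_jsonable(self) -> dict:
        return {
            "model": self.model,
            "auc_pct": self.auc_pct,
            "auc_ci_95": list(self.auc_ci_95),
            "sensitivity_pct": self.sensitivity_pct,
            "specificity_pct": self.specificity_pct,
            "accuracy_pct": self.accuracy_pct,
            "n_iterations": self.n_iterations,
            "n_folds": self.n_folds,
            "seed": self.seed,
        }


def robust_scale(
    matrix: np.ndarray, fit_rows: np.ndarray | None = None
) -> tuple[np.ndarray, RobustScaler]:
    """Median/IQR scaling with parameters fitted on ``fit_rows`` only.

    Columns with zero IQR are passed through uncentered by scale 1 (the
    scaler's zero-scale guard).  Returns the fully transformed matrix and the
    fitted scaler (use ``scaler.transform`` for held-out rows).
    """
    X = np.asarray(matrix, dtype=float)
    fit_X = X if fit_rows is None else X[fit_rows]
    if len(fit_X) < 2:
        raise ValueError("need at least 2 rows to fit the scaler")
    scaler = RobustScaler().fit(fit_X)
    return scaler.transform(X), scaler


def roc_metrics(
    decision_scores: np.ndarray, labels: np.ndarray, threshold: float = 0.0
) -> tuple[float, float, float, float]:
    """(AUC, sensitivity, specificity, accuracy) for one test fold.

    AUC is the rank statistic (ties count one half).  Sensitivity and
    specificity use the hard decision ``score > threshold``; accuracy is
    their mean, the balanced accuracy on undersampled folds.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(decision_scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present in the fold")
    auc = float(roc_auc_score(y, s))
    pred = (s > threshold).astype(int)
    sens = float(np.mean(pred[y == 1] == 1))
    spec = float(np.mean(pred[y == 0] == 0))
    return auc, sens, spec, (sens + spec) / 2.0


def chance_classifier(n_test: int, rng: np.random.Generator) -> np.ndarray:
    """Random-assignment scores: i.i.d. uniform on (-0.5, 0.5), independent of
    features and labels, so the natural threshold 0 splits at random."""
    return rng.uniform(-0.5, 0.5, n_test)


def _fit_score_fold(
    X: np.ndarray,
    y: np.ndarray,
    train: np.ndarray,
    test: np.ndarray,
    model: str,
    svm_C: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Decision scores on the test fold; scaler/model see training rows only."""
    if model == "chance":
        return chance_classifier(len(test), rng)
    scaler = RobustScaler().fit(X[train])
    clf = LinearSVC(penalty="l1", dual=False, C=svm_C, max_iter=10000, random_state=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        clf.fit(scaler.transform(X[train]), y[train])
    return clf.decision_function(scaler.transform(X[test]))


def balanced_repeated_cv(
    X: np.ndarray,
    y: np.ndarray,
    config: ProtocolConfig | None = None,
    model: str = "svm",
) -> PerformanceSummary:
    """Repeated undersampled stratified five-fold cross-validation.

    Per iteration the majority class is randomly undersampled to the minority
    size, the folds are scored with :func:`roc_metrics` and averaged; the
    summary is the mean over iterations with a 95% CI over iteration means.
    """
    config = config or ProtocolConfig()
    if model not in ("svm", "chance"):
        raise ValueError("model must be 'svm' or 'chance'")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2 or set(classes.tolist()) != {0, 1}:
        raise ValueError("labels must be binary 0/1 (1 = case)")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    if n_min < config.n_folds:
        raise ValueError("minority class smaller than the fold count")

    rng = np.random.default_rng(config.seed)
    per_iter = np.zeros((config.n_iterations, 4))
    it = 0
    attempts = 0
    while it < config.n_iterations:
        attempts += 1
        if attempts > 10 * config.n_iterations:
            raise RuntimeError("too many degenerate folds; cannot complete protocol")
        maj_idx = np.where(y == majority)[0]
        keep = rng.choice(maj_idx, size=n_min, replace=False)
        idx = np.concatenate([np.where(y == minority)[0], keep])
        Xb, yb = X[idx], y[idx]  # label 1 is the positive (case) class

        skf = StratifiedKFold(
            n_splits=config.n_folds,
            shuffle=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        fold_metrics = []
        try:
            for train, test in skf.split(Xb, yb):
                scores = _fit_score_fold(
                    Xb, yb, train, test, model, config.svm_C, rng
                )
                fold_metrics.append(roc_metrics(scores, yb[test]))
        except ValueError:
            warnings.warn("degenerate fold encountered; resampling iteration")
            continue
        per_iter[it] = np.mean(fold_metrics, axis=0)
        it += 1

    means = per_iter.mean(axis=0) * 100.0
    auc_iters = per_iter[:, 0] * 100.0
    if config.ci_method == "percentile":
        lo, hi = np.percentile(auc_iters, [2.5, 97.5])
    else:
        half = 1.96 * auc_iters.std(ddof=1) / np.sqrt(config.n_iterations)
        lo, hi = means[0] - half, means[0] + half
    return PerformanceSummary(
        auc_pct=float(means[0]),
        sensitivity_pct=float(means[1]),
        specificity_pct=float(means[2]),
        accuracy_pct=float(means[3]),
        auc_ci_95=(float(lo), float(hi)),
        n_iterations=config.n_iterations,
        n_folds=config.n_folds,
        seed=config.seed,
        model=model,
        iteration_auc_pct=auc_iters,
    )


def rfecv_select(
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str] | None = None,
    config: ProtocolConfig | None = None,
    score_iterations: int = 10,
) -> tuple[list[str], pd.DataFrame]:
    """Recursive feature elimination scored by balanced CV AUC.

    At each step the features with the smallest absolute SVM weights (10% of
    those remaining, at least one) are dropped; every visited subset is scored
    with the repeated undersampled CV protocol (``score_iterations``
    repetitions) and the subset with the best mean AUC wins, smaller subsets
    winning ties.  Returns the selected names and the elimination path.
    """
    config = config or ProtocolConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n_features = X.shape[1]
    if n_features < 2:
        raise ValueError("need at least 2 features")
    if feature_names is None:
        feature_names = [f"x{i}" for i in range(n_features)]

    score_cfg = ProtocolConfig(
        n_iterations=score_iterations,
        n_folds=config.n_folds,
        svm_C=config.svm_C,
        seed=config.seed,
    )
    remaining = list(range(n_features))
    path_rows = []
    subsets: list[list[int]] = []
    while remaining:
        summary = balanced_repeated_cv(X[:, remaining], y, score_cfg, model="svm")
        subsets.append(list(remaining))
        path_rows.append(
            {"n_features": len(remaining), "mean_auc_pct": summary.auc_pct}
        )
        if len(remaining) == 1:
            break
        # Rank features by |weight| of a model on the full (scaled) data.
        Xs, _ = robust_scale(X[:, remaining])
        clf = LinearSVC(penalty="l1", dual=False, C=config.svm_C, max_iter=10000, random_state=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(Xs, y)
        w = np.abs(clf.coef_.ravel())
        n_drop = max(1, int(0.1 * len(remaining)))
        drop = np.argsort(w, kind="stable")[:n_drop]
        remaining = [f for i, f in enumerate(remaining) if i not in set(drop)]

    path = pd.DataFrame(path_rows)
    best_auc = path["mean_auc_pct"].max()
    # Ties (within float equality) go to the smallest subset.
    candidates = [
        (len(subsets[i]), i)
        for i in range(len(subsets))
        if path["mean_auc_pct"].iloc[i] >= best_auc
    ]
    _, best_i = min(candidates)
    selected = [feature_names[j] for j in subsets[best_i]]
    return selected, path


def partial_spearman(
    x: np.ndarray, y: np.ndarray, covariate: np.ndarray
) -> tuple[float, float]:
    """Partial Spearman correlation of x and y adjusting for one covariate.

    All three variables are rank-transformed; the statistic is the Pearson
    correlation of the residuals of x-ranks and y-ranks after linear
    regression on the covariate ranks, with a t-approximation p-value on
    n - 3 degrees of freedom.  A constant covariate degenerates to the plain
    Spearman correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(covariate, dtype=float)
    n = len(x)
    if not (len(y) == n == len(z)):
        raise ValueError("inputs must have equal length")
    if n < 5:
        raise ValueError("need at least 5 observations")
    if np.any(np.isnan(x)) or np.any(np.isnan(y)) or np.any(np.isnan(z)):
        raise ValueError("missing values are not allowed")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("x and y must have positive variance")

    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rz = stats.rankdata(z)

    def _residualize(a: np.ndarray) -> np.ndarray:
        if np.std(rz) == 0:
            return a - a.mean()
        Z = np.column_stack([np.ones(n), rz])
        beta, *_ = np.linalg.lstsq(Z, a, rcond=None)
        return a - Z @ beta

    ex, ey = _residualize(rx), _residualize(ry)
    rho = float(np.dot(ex, ey) / np.sqrt(np.dot(ex, ex) * np.dot(ey, ey)))
    df = n - 3
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p
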