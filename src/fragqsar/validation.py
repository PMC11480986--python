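"""Model validation statistics.

Implements the full metric suite used to judge the QSAR models:

* binary-classification metrics from confusion counts (sensitivity,
  specificity, precision, accuracy, F1) and ROC AUC;
* multiclass log loss (multinomial cross-entropy with probability
  clipping) and balanced accuracy;
* regression metrics R^2, RMSE, MAE;
* the Golbraikh-Tropsha external-validation statistics: through-origin
  slopes k, k' and determination coefficients R0^2, R0'^2 with the four
  acceptance criteria;
* the Y-scrambling (y-randomization) robustness test: refit the model
  on permuted activities and confirm performance collapses.

Ratios with a zero denominator return the convention value 0 together
with a ``degenerate`` flag rather than raising, so batch evaluation
never aborts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata

_CLIP = 1e-15


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class BinaryMetrics:
    sensitivity: float
    specificity: float
    precision: float
    accuracy: float
    f1: float
    auc: float | None = None
    degenerate: bool = False


@dataclass
class MulticlassMetrics:
    log_loss: float
    accuracy: float
    per_class_accuracy: dict[int, float]
    balanced_accuracy: float
    auc_per_class: dict[int, float] = field(default_factory=dict)
    auc_macro: float | None = None


@dataclass
class RegressionMetrics:
    r2: float
    rmse: float
    mae: float
    residuals: np.ndarray


@dataclass
class TropshaReport:
    """Through-origin regression statistics and the four acceptance criteria.

    criteria[0]: R^2_cv > 0.5
    criteria[1]: R^2_test > 0.6
    criteria[2]: |R^2_test - R0^2| / R^2_test < 0.1, or the primed analog
    criteria[3]: 0.85 <= k <= 1.15, or the same for k'
    """

    k: float
    k_prime: float
    r0_sq: float
    r0_prime_sq: float
    r2_cv: float
    r2_test: float
    criteria: tuple[bool, bool, bool, bool]
    c3_statistic: float
    c3_statistic_prime: float

    @property
    def overall_pass(self) -> bool:
        return all(self.criteria)


@dataclass
class YScramblingReport:
    runs: list[tuple[float, float]]  # (r2_cv, r2_test) per scramble
    n_runs: int
    seed: int

    @property
    def max_r2(self) -> float:
        if not self.runs:
            raise ValueError("empty Y-scrambling report: max undefined")
        return max(max(cv, test) for cv, test in self.runs)


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape:
        raise ValueError("length mismatch between y_true and y_pred")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("binary labels must be in {0, 1}")
    return ConfusionCounts(
        tp=int(np.sum((yt == 1) & (yp == 1))),
        tn=int(np.sum((yt == 0) & (yp == 0))),
        fp=int(np.sum((yt == 0) & (yp == 1))),
        fn=int(np.sum((yt == 1) & (yp == 0))),
    )


def _ratio(num: float, den: float) -> tuple[float, bool]:
    return (num / den, False) if den > 0 else (0.0, True)


def binary_metrics(counts: ConfusionCounts) -> BinaryMetrics:
    if counts.total == 0:
        raise ValueError("no evaluated pairs")
    sens, d1 = _ratio(counts.tp, counts.tp + counts.fn)
    spec, d2 = _ratio(counts.tn, counts.tn + counts.fp)
    prec, d3 = _ratio(counts.tp, counts.tp + counts.fp)
    acc = (counts.tp + counts.tn) / counts.total
    f1, d4 = _ratio(2 * prec * sens, prec + sens)
    return BinaryMetrics(sens, spec, prec, acc, f1, degenerate=d1 or d2 or d3 or d4)


def roc_auc(y_true, scores) -> float:
    """AUC as the Mann-Whitney probability; tied scores contribute 1/2."""
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(yt == 1))
    n_neg = int(np.sum(yt == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = rankdata(s)  # midranks handle ties
    return float((ranks[yt == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def multiclass_log_loss(y_true_onehot, probs) -> float:
    """Multinomial cross-entropy -(1/n) sum_i sum_c y_ic ln p_ic, p clipped."""
    Y = np.asarray(y_true_onehot, dtype=float)
    P = np.asarray(probs, dtype=float)
    if Y.shape != P.shape:
        raise ValueError("shape mismatch")
    if np.any(P < -1e-9) or np.any(np.abs(P.sum(axis=1) - 1) > 1e-9):
        raise ValueError("probability rows must be nonnegative and sum to 1")
    P = np.clip(P, _CLIP, 1 - _CLIP)
    return float(-(Y * np.log(P)).sum() / Y.shape[0])


def balanced_accuracy(y_true, y_pred) -> float:
    """Mean of per-class sensitivities."""
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    sens = [np.mean(yp[yt == c] == c) for c in np.unique(yt)]
    return float(np.mean(sens))


def multiclass_metrics(y_true, y_pred, probs, classes=None) -> MulticlassMetrics:
    yt = np.asarray(y_true)
    yp = np.asarray(y_pred)
    P = np.asarray(probs, dtype=float)
    cls = np.asarray(classes if classes is not None else np.unique(yt))
    onehot = (yt[:, None] == cls[None, :]).astype(float)
    per_class = {int(c): float(np.mean(yp[yt == c] == c)) for c in np.unique(yt)}
    aucs = {}
    for j, c in enumerate(cls):
        yb = (yt == c).astype(int)
        if 0 < yb.sum() < len(yb):
            aucs[int(c)] = roc_auc(yb, P[:, j])
    return MulticlassMetrics(
        log_loss=multiclass_log_loss(onehot, P),
        accuracy=float(np.mean(yt == yp)),
        per_class_accuracy=per_class,
        balanced_accuracy=balanced_accuracy(yt, yp),
        auc_per_class=aucs,
        auc_macro=float(np.mean(list(aucs.values()))) if aucs else None,
    )


def regression_metrics(y_obs, y_pred) -> RegressionMetrics:
    y = np.asarray(y_obs, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.shape != yh.shape or y.size < 2:
        raise ValueError("need >= 2 aligned observations")
    sst = np.sum((y - y.mean()) ** 2)
    if sst == 0:
        raise ValueError("constant y_obs: R^2 undefined")
    res = y - yh
    return RegressionMetrics(
        r2=float(1 - np.sum(res**2) / sst),
        rmse=float(np.sqrt(np.mean(res**2))),
        mae=float(np.mean(np.abs(res))),
        residuals=res,
    )


def tropsha_criteria(
    r2_cv: float,
    r2_test: float,
    k: float,
    k_prime: float,
    r0_sq: float,
    r0_prime_sq: float,
) -> TropshaReport:
    """Apply the four acceptance conditions to precomputed statistics."""
    c3 = abs(r2_test - r0_sq) / r2_test if r2_test else np.inf
    c3p = abs(r2_test - r0_prime_sq) / r2_test if r2_test else np.inf
    criteria = (
        r2_cv > 0.5,
        r2_test > 0.6,
        c3 < 0.1 or c3p < 0.1,
        0.85 <= k <= 1.15 or 0.85 <= k_prime <= 1.15,
    )
    return TropshaReport(k, k_prime, r0_sq, r0_prime_sq, r2_cv, r2_test,
                         criteria, c3, c3p)


def tropsha_validation(y_obs, y_pred, r2_cv: float) -> TropshaReport:
    """Through-origin slopes/determination coefficients and acceptance test.

    k  = sum(y_i yhat_i) / sum(yhat_i^2)   (observed regressed on predicted)
    k' = sum(y_i yhat_i) / sum(y_i^2)      (predicted regressed on observed)
    R0^2  = 1 - sum((y_i - k yhat_i)^2)  / sum((y_i - ybar)^2)
    R0'^2 = 1 - sum((yhat_i - k' y_i)^2) / sum((yhat_i - yhatbar)^2)
    """
    y = np.asarray(y_obs, dtype=float)
    yh = np.asarray(y_pred, dtype=float)
    if y.size < 3:
        raise ValueError("need n >= 3")
    if not (np.any(y) and np.any(yh)):
        raise ValueError("degenerate all-zero vector")
    k = float(np.sum(y * yh) / np.sum(yh**2))
    k_prime = float(np.sum(y * yh) / np.sum(y**2))
    r0_sq = float(1 - np.sum((y - k * yh) ** 2) / np.sum((y - y.mean()) ** 2))
    r0p_sq = float(1 - np.sum((yh - k_prime * y) ** 2) / np.sum((yh - yh.mean()) ** 2))
    r2_test = regression_metrics(y, yh).r2
    return tropsha_criteria(r2_cv, r2_test, k, k_prime, r0_sq, r0p_sq)


def scramble_y(y, rng: np.random.Generator) -> np.ndarray:
    """Seeded permutation of y, guaranteed to differ from y when possible."""
    y = np.asarray(y)
    if len(y) < 2 or np.all(y == y[0]):
        return y.copy()
    for _ in range(100):
        perm = rng.permutation(len(y))
        if np.any(y[perm] != y):
            return y[perm]
    raise RuntimeError("could not produce a non-identity scramble")


def y_scrambling(
    X,
    y,
    spec,
    split_plan,
    n_runs: int = 10,
    seed: int = 0,
    mode: str = "full",
) -> YScramblingReport:
    """Y-scrambling test: permute activities, retrain, record R^2 statistics.

    ``mode='full'`` reruns the entire grid search per scramble (default);
    ``mode='refit'`` refits only the grid point selected on the real data.
    Returns the (cross-validated R^2, holdout R^2) pair of each run.
    """
    from . import modeling  # local import to avoid a cycle

    if mode not in ("full", "refit"):
        raise ValueError("mode must be 'full' or 'refit'")
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    fixed_params = None
    if mode == "refit":
        base = modeling.grid_search_train(X, y, spec, split_plan)
        fixed_params = base.best_params
    runs: list[tuple[float, float]] = []
    for _ in range(n_runs):
        ys = scramble_y(y, rng)
        run_spec = spec if fixed_params is None else spec.with_grid(
            {k: [v] for k, v in fixed_params.items()})
        model = modeling.grid_search_train(X, ys, run_spec, split_plan)
        r2_cv = model.best_cv_score
        hold = split_plan.holdout_indices
        preds = modeling.predict(model, X[hold])
        r2_test = regression_metrics(ys[hold], preds.values).r2
        runs.append((float(r2_cv), float(r2_test)))
    return YScramblingReport(runs, n_runs, seed)


def write_scrambling_tsv(report: YScramblingReport, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("run\tr2_cross_validation\tr2_test\n")
        for i, (cv, test) in enumerate(report.runs, start=1):
            fh.write(f"{i}\t{cv:.6g}\t{test:.6g}\n")
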