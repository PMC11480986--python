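"""Leverage-based applicability domain and Williams plots.

The applicability domain (AD) of a QSAR model is the region of
descriptor space where its predictions are considered reliable.  Here
it is characterized by leverage, the hat-matrix diagonal

    h_i = x_i^T (X^T X)^{-1} x_i

computed in the trained model's selected-feature subspace (X is the
training descriptor matrix restricted to those columns).  A query with
leverage above the warning threshold h* = 3(p+1)/n is structurally
remote from the training cloud and its prediction is flagged.  The
Williams plot scatters leverage against standardized prediction
residuals; a point is in-domain iff h <= h* and |sigma| <= 3.

X^T X is inverted through a pseudo-inverse with relative cutoff 1e-10,
so rank-deficient (collinear) descriptor sets are handled; a molecule
with an all-zero descriptor row (no known fragments at all) is defined
out-of-domain regardless of its leverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp

SIGMA_LIMIT = 3.0


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)


@dataclass
class DomainModel:
    X_train: np.ndarray  # n x p in the selected-feature subspace
    xtx_pinv: np.ndarray  # p x p
    n: int
    p: int
    h_star: float
    residual_scale: float
    selected_features: np.ndarray

    def training_leverages(self) -> np.ndarray:
        return np.einsum("ij,jk,ik->i", self.X_train, self.xtx_pinv, self.X_train)


def warning_leverage(p: int, n: int) -> float:
    """h* = 3(p+1)/n, the standard Williams-plot warning threshold."""
    return 3.0 * (p + 1) / n


def fit_domain(
    X_train,
    selected_features: Sequence[int] | None,
    y_train=None,
    y_train_pred=None,
    h_star: float | None = None,
) -> DomainModel:
    """Fit the AD reference: pseudo-inverse of X^T X, h*, residual scale.

    ``residual_scale`` (the training RMSE, used to standardize residuals)
    is computed when observed and predicted training activities are
    given.  ``h_star`` may be overridden; the default is 3(p+1)/n.
    """
    X = _dense(X_train)
    if selected_features is not None:
        sel = np.asarray(selected_features, dtype=int)
        X = X[:, sel]
    else:
        sel = np.arange(X.shape[1])
    n, p = X.shape
    if p == 0:
        raise ValueError("empty feature set")
    if n < 2:
        raise ValueError("need n > 1 training rows")
    pinv = np.linalg.pinv(X.T @ X, rcond=1e-10)
    scale = 0.0
    if y_train is not None and y_train_pred is not None:
        res = np.asarray(y_train, dtype=float) - np.asarray(y_train_pred, dtype=float)
        scale = float(np.sqrt(np.mean(res**2)))
    return DomainModel(X, pinv, n, p,
                       h_star if h_star is not None else warning_leverage(p, n),
                       scale, sel)


def leverage(model: DomainModel, x_query) -> float:
    """h = x^T (X^T X)^+ x for one query vector in the selected subspace."""
    x = _dense(x_query).ravel()
    if x.size != model.p:
        raise ValueError(f"dimension mismatch: expected {model.p}, got {x.size}")
    return float(x @ model.xtx_pinv @ x)


def _project(model: DomainModel, X: np.ndarray) -> np.ndarray:
    """Accept either the selected subspace or the full descriptor matrix."""
    if X.shape[1] == model.p:
        return X
    if X.shape[1] > model.p and model.selected_features.max(initial=-1) < X.shape[1]:
        return X[:, model.selected_features]
    raise ValueError(f"dimension mismatch: expected {model.p} columns, got {X.shape[1]}")


def leverages(model: DomainModel, X_query) -> np.ndarray:
    X = _project(model, _dense(X_query))
    return np.einsum("ij,jk,ik->i", X, model.xtx_pinv, X)


def standardized_residual(model: DomainModel, y_obs: float, y_pred: float) -> float:
    """(y_obs - y_pred) / training RMSE; positive means under-prediction."""
    if model.residual_scale <= 0:
        raise ValueError("residual scale is zero; fit_domain needs training residuals")
    return float((y_obs - y_pred) / model.residual_scale)


@dataclass
class WilliamsPoint:
    id: str
    leverage: float
    std_residual: float
    subset: str  # training | holdout | external
    in_domain: bool
    cause: str  # "", "leverage", "residual", "leverage+residual", "no_known_fragments"


@dataclass
class WilliamsReport:
    points: list[WilliamsPoint]
    h_star: float
    summary: dict[str, dict[str, int]]  # subset -> counts by cause

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("id\tsubset\tleverage\tstd_residual\tin_domain\tcause\n")
            for pt in self.points:
                fh.write(f"{pt.id}\t{pt.subset}\t{pt.leverage:.6g}\t"
                         f"{pt.std_residual:.6g}\t{int(pt.in_domain)}\t{pt.cause}\n")


def williams_report(
    model: DomainModel,
    subsets: Mapping[str, tuple[Sequence[str], object, Sequence[float], Sequence[float]]],
    plot_path=None,
) -> WilliamsReport:
    """Leverage/residual table over named subsets (training/holdout/external).

    ``subsets`` maps a subset name to (ids, X in the selected subspace,
    y_observed, y_predicted).  Optionally renders the Williams plot with
    the h* vertical line and +-3 sigma horizontal lines.
    """
    points: list[WilliamsPoint] = []
    summary: dict[str, dict[str, int]] = {}
    for name, (ids, X, y_obs, y_pred) in subsets.items():
        Xd = _dense(X)
        zero_rows = np.all(Xd == 0, axis=1)  # before projection: no fragment at all
        hs = leverages(model, Xd)
        counts = {"total": len(ids), "in_domain": 0, "leverage": 0, "residual": 0}
        for i, rid in enumerate(ids):
            sigma = standardized_residual(model, y_obs[i], y_pred[i])
            causes = []
            if zero_rows[i]:
                causes.append("no_known_fragments")
            if hs[i] > model.h_star:
                causes.append("leverage")
                counts["leverage"] += 1
            if abs(sigma) > SIGMA_LIMIT:
                causes.append("residual")
                counts["residual"] += 1
            in_dom = not causes
            counts["in_domain"] += int(in_dom)
            points.append(WilliamsPoint(str(rid), float(hs[i]), sigma, name,
                                        in_dom, "+".join(causes)))
        summary[name] = counts
    report = WilliamsReport(points, model.h_star, summary)
    if plot_path is not None:
        plot_williams(report, plot_path)
    return report


def plot_williams(report: WilliamsReport, path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    markers = {"training": ("o", "tab:blue"), "holdout": ("s", "tab:orange"),
               "external": ("^", "tab:red")}
    by_subset: dict[str, list[WilliamsPoint]] = {}
    for pt in report.points:
        by_subset.setdefault(pt.subset, []).append(pt)
    for name, pts in by_subset.items():
        m, c = markers.get(name, ("x", "gray"))
        ax.scatter([p.leverage for p in pts], [p.std_residual for p in pts],
                   marker=m, c=c, label=name, alpha=0.7, edgecolors="none")
    ax.axvline(report.h_star, color="k", ls="--", lw=1,
               label=f"h* = {report.h_star:.3g}")
    ax.axhline(SIGMA_LIMIT, color="gray", ls=":", lw=1)
    ax.axhline(-SIGMA_LIMIT, color="gray", ls=":", lw=1)
    ax.set_xlabel("Leverage h")
    ax.set_ylabel("Standardized residual (sigma)")
    ax.set_title("Williams plot")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def ad_flag_predictions(model: DomainModel, prediction_set, X_query):
    """Fill ad_warnings: leverage above h*, or no known fragments at all.

    The residual half of the domain test needs an observed activity and
    is unavailable at prediction time; only the leverage criterion (and
    the all-zero-row convention) applies.
    """
    Xd = _dense(X_query)
    zero_rows = np.all(Xd == 0, axis=1)
    hs = leverages(model, Xd)
    prediction_set.ad_warnings = (hs > model.h_star) | zero_rows
    return prediction_set
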