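"""Structural-alert extraction.

A structural alert is a subfragment that a trained classifier relies on
to separate actives from inactives.  Fragments are ranked by seeded
permutation importance — the mean drop in the task metric (ROC AUC for
the binary task) when a single descriptor column is shuffled — measured
on rows disjoint from the final model's training set.  Class-enrichment
odds ratios and example molecules are attached as interpretive context
but play no part in the ranking.

Permutation importance over tens of thousands of columns is wasteful
when almost all of them are inert, so an optional univariate screen
(chi-squared association with the class label) preselects the
``screen_top`` strongest columns; the rest are reported with importance
exactly 0.  Set ``screen_top=None`` to score every column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.feature_selection import chi2

from . import modeling, validation


@dataclass
class AlertRecord:
    fragment_key: str
    importance: float
    enrichment_odds_ratio: float
    support_active: int
    support_inactive: int
    example_ids: list[str]
    #: other fragment keys with a bit-identical presence pattern; the
    #: record's key is the most specific (largest) member of the class
    equivalent_keys: list[str] = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.equivalent_keys is None:
            self.equivalent_keys = []


@dataclass
class AlertTable:
    records: list[AlertRecord]  # descending importance, ties by key
    n_repeats: int
    seed: int
    top_k: int

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tfragment_key\timportance\todds_ratio\t"
                     "support_active\tsupport_inactive\texample_ids\t"
                     "equivalent_keys\n")
            for rank, r in enumerate(self.records, start=1):
                fh.write(f"{rank}\t{r.fragment_key}\t{r.importance:.6g}\t"
                         f"{r.enrichment_odds_ratio:.6g}\t{r.support_active}\t"
                         f"{r.support_inactive}\t{','.join(r.example_ids)}\t"
                         f"{','.join(r.equivalent_keys)}\n")

    def keys(self) -> list[str]:
        return [r.fragment_key for r in self.records]

    def to_json(self, path) -> None:
        import json
        from dataclasses import asdict

        payload = {"n_repeats": self.n_repeats, "seed": self.seed,
                   "top_k": self.top_k,
                   "alerts": [asdict(r) for r in self.records]}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)


def _metric(task: str, model, X, y) -> float:
    if task == "regression":
        return validation.regression_metrics(y, model.pipeline.predict(X)).r2
    P = modeling._normalize_proba(model.pipeline.predict_proba(X))
    if task == "binary":
        j = list(model.classes_).index(1)
        return validation.roc_auc(y, P[:, j])
    classes = model.classes_
    onehot = (np.asarray(y)[:, None] == classes[None, :]).astype(float)
    return -validation.multiclass_log_loss(onehot, P)


def permutation_importance(
    model: modeling.TrainedModel,
    X_eval,
    y_eval,
    n_repeats: int = 5,
    seed: int = 0,
    columns=None,
    group_identical: bool = True,
) -> dict[int, float]:
    """Mean metric drop over seeded permutations of each evaluated column.

    ``X_eval``/``y_eval`` must be disjoint from the model's training
    rows (the holdout set or pooled CV validation folds).  A constant
    column has importance exactly 0 by definition — permuting it cannot
    change anything.

    Exhaustive subfragment fingerprints contain many columns with
    bit-identical presence patterns (nested fragments of the same
    substituent); no model can distribute credit among them in a
    data-driven way.  With ``group_identical`` (default) such columns
    are permuted jointly — with a single shared row permutation, so the
    within-group correlation structure is preserved — and every member
    reports the group's importance.
    """
    X = X_eval.toarray() if sp.issparse(X_eval) else np.array(X_eval)
    y = np.asarray(y_eval)
    cols = list(range(X.shape[1])) if columns is None else list(columns)
    base = _metric(model.spec.task, model, X, y)
    rng = np.random.default_rng(seed)

    if group_identical:
        pattern_of: dict[bytes, list[int]] = {}
        for j in cols:
            pattern_of.setdefault(X[:, j].tobytes(), []).append(j)
        groups = list(pattern_of.values())
    else:
        groups = [[j] for j in cols]

    out: dict[int, float] = {}
    for group in groups:
        block = X[:, group].copy()
        if np.all(block[:, 0] == block[0, 0]):
            for j in group:
                out[j] = 0.0
            continue
        drops = []
        for _ in range(n_repeats):
            X[:, group] = block[rng.permutation(len(y))]
            drops.append(base - _metric(model.spec.task, model, X, y))
        X[:, group] = block
        imp = float(np.mean(drops))
        for j in group:
            out[j] = imp
    return out


def enrichment(fragment_column, binary_labels) -> tuple[float, int, int]:
    """Class-enrichment odds ratio of a fragment, with supports per class.

    Haldane-Anscombe: 0.5 is added to every cell of the 2x2 table when
    any cell is zero, so the ratio is always finite.
    """
    col = np.asarray(fragment_column.todense() if sp.issparse(fragment_column)
                     else fragment_column).ravel().astype(bool)
    y = np.asarray(binary_labels).astype(int)
    if np.unique(y).size < 2:
        raise ValueError("both classes must be present")
    a = int(np.sum(col & (y == 1)))   # active, fragment present
    b = int(np.sum(~col & (y == 1)))  # active, absent
    c = int(np.sum(col & (y == 0)))   # inactive, present
    d = int(np.sum(~col & (y == 0)))  # inactive, absent
    aa, bb, cc, dd = (a, b, c, d)
    if min(a, b, c, d) == 0:
        aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    return float((aa / bb) / (cc / dd)), a, c


def extract_alerts(
    model: modeling.TrainedModel,
    X,
    y,
    ids,
    vocabulary,
    top_k: int = 20,
    n_repeats: int = 5,
    seed: int = 0,
    eval_indices=None,
    screen_top: int | None = 500,
    n_examples: int = 3,
) -> AlertTable:
    """Rank fragments by permutation importance; attach enrichment and examples.

    ``eval_indices`` selects the evaluation rows (defaults to the split
    plan's holdout rows, which are disjoint from training).  Ordering is
    total: descending importance, ties broken lexicographically by
    fragment key.  ``top_k`` beyond the vocabulary size is truncated.
    """
    keys = vocabulary.keys
    p = len(keys)
    top_k = min(top_k, p)
    if top_k == 0:
        return AlertTable([], n_repeats, seed, 0)
    if eval_indices is None:
        eval_indices = model.split_plan.holdout_indices
    eval_indices = np.asarray(eval_indices, dtype=int)
    X_eval = X[eval_indices]
    y_eval = np.asarray(y)[eval_indices]

    columns = None
    if screen_top is not None and screen_top < p:
        Xb = X[model.split_plan.building_indices]
        yb = np.asarray(y)[model.split_plan.building_indices]
        stat, _ = chi2(np.abs(Xb.toarray() if sp.issparse(Xb) else Xb), yb)
        stat = np.nan_to_num(stat)
        columns = np.sort(np.argsort(-stat, kind="stable")[:screen_top])
    imp = permutation_importance(model, X_eval, y_eval, n_repeats, seed, columns)
    importances = np.zeros(p)
    for j, v in imp.items():
        importances[j] = v

    # collapse columns with bit-identical presence patterns over the full
    # dataset: they are statistically indistinguishable, so they form one
    # alert whose representative is the most specific (largest) fragment
    Xd = (X.toarray() if sp.issparse(X) else np.asarray(X)).astype(bool)
    classes: dict[bytes, list[int]] = {}
    for j in range(p):
        classes.setdefault(Xd[:, j].tobytes(), []).append(j)

    def _specificity(j: int) -> tuple:
        return (-vocabulary.n_bonds.get(keys[j], 0), keys[j])

    class_list = []
    for members in classes.values():
        rep = min(members, key=_specificity)
        class_list.append((rep, sorted(members, key=_specificity)))
    class_list.sort(key=lambda t: (-max(importances[m] for m in t[1]),
                                   keys[t[0]]))

    # total importance: permute a class together with every class whose
    # pattern specializes (is a row-subset of) it, so a substituent-level
    # alert accumulates the credit the model assigned to its contextual
    # refinements; evaluated for the leading candidate classes only
    n_candidates = min(len(class_list), max(3 * top_k, 50))
    patterns = np.stack([Xd[:, rep] for rep, _ in class_list])  # classes x rows
    rng = np.random.default_rng(seed + 1)
    X_eval_d = X_eval.toarray() if sp.issparse(X_eval) else np.array(X_eval)
    base = _metric(model.spec.task, model, X_eval_d, y_eval)
    totals = []
    for ci in range(n_candidates):
        rep, members = class_list[ci]
        sub_classes = np.flatnonzero(
            ~(patterns & ~patterns[ci]).any(axis=1))  # pattern subset test
        group = [m for sc in sub_classes for m in class_list[sc][1]]
        block = X_eval_d[:, group].copy()
        drops = []
        for _ in range(n_repeats):
            X_eval_d[:, group] = block[rng.permutation(len(y_eval))]
            drops.append(base - _metric(model.spec.task, model, X_eval_d, y_eval))
        X_eval_d[:, group] = block
        totals.append((float(np.mean(drops)), rep, members))
    totals.sort(key=lambda t: (-t[0], keys[t[1]]))

    yarr = np.asarray(y).astype(int)
    ids = list(ids)
    records = []
    for total_imp, rep, members in totals[:top_k]:
        col = Xd[:, rep]
        try:
            odds, sup_a, sup_i = enrichment(col, yarr)
        except ValueError:
            odds, sup_a, sup_i = 1.0, int(col.sum()), 0
        examples = [ids[i] for i in np.flatnonzero(col)[:n_examples]]
        records.append(AlertRecord(
            keys[rep], total_imp, odds, sup_a, sup_i, examples,
            equivalent_keys=[keys[m] for m in members if m != rep]))
    return AlertTable(records, n_repeats, seed, top_k)
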