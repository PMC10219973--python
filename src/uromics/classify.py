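"""Bagged-tree classification with out-of-bag permutation importance.

The importance of a feature is the mean, over trees, of the drop in
out-of-bag (OOB) accuracy when that feature's values are permuted among the
tree's OOB samples — the classic permutation importance of bagged forests.
It is computed here directly from the bootstrap bookkeeping (sklearn's
``permutation_importance`` uses a held-out set, not OOB, and its impurity
importance is biased toward high-variance features).

Trees are sklearn ``DecisionTreeClassifier`` instances; the bootstrap, the
OOB accounting and the permutation pass are owned by this module, and all
randomness derives from a single user seed.  Only features actually used by
a tree's splits can change its predictions, so the permutation pass skips
the rest — a pure speed-up with identical results.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.tree import DecisionTreeClassifier

from .data import IntensityMatrix
from .errors import ParameterError, ValidationError


@dataclass
class ImportanceTable:
    """Per-feature OOB permutation importances with ranks."""

    records: pd.DataFrame      # feature_id, importance, rank
    n_trees: int
    oob_accuracy: float
    seed: int | None

    def importance_series(self) -> pd.Series:
        return self.records.set_index("feature_id")["importance"]

    def summary(self) -> str:
        top = self.records.nsmallest(5, "rank")
        lines = [f"random-forest importance ({self.n_trees} trees, "
                 f"OOB accuracy {self.oob_accuracy:.3f})"]
        for _, row in top.iterrows():
            lines.append(f"  #{int(row['rank']):<3d} {row['feature_id']:<16s} "
                         f"{row['importance']:+.4f}")
        return "\n".join(lines)


def rf_importance(matrix: IntensityMatrix, labels, n_trees: int = 1000,
                  seed: int | None = None,
                  max_features: str | int = "sqrt") -> ImportanceTable:
    """OOB permutation importance of every feature for separating ``labels``.

    Deterministic given ``seed``.  Features are not standardized (tree
    ensembles are scale-invariant).
    """
    X = matrix.values.T
    y = np.asarray(labels)
    if y.shape[0] != X.shape[0]:
        raise ValidationError("one label per sample required")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("need >= 2 classes")
    if n_trees < 1:
        raise ParameterError("n_trees must be >= 1")
    n, p = X.shape
    rng = np.random.default_rng(seed)

    importance_sum = np.zeros(p)
    importance_trees = np.zeros(p, dtype=int)   # trees where the feature was OOB-evaluable
    oob_votes = {c: np.zeros(n) for c in classes}

    for _ in range(n_trees):
        boot = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), boot)
        if oob.size == 0 or np.unique(y[boot]).size < 2:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)))
        tree.fit(X[boot], y[boot])

        X_oob = X[oob]
        pred = tree.predict(X_oob)
        for idx, c in zip(oob, pred):
            oob_votes[c][idx] += 1
        acc = float((pred == y[oob]).mean())

        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]
        if used.size == 0:
            continue
        # one stacked prediction call for all used features of this tree
        perm_rows = []
        for f in used:
            Xp = X_oob.copy()
            Xp[:, f] = Xp[rng.permutation(oob.size), f]
            perm_rows.append(Xp)
        stacked_pred = tree.predict(np.vstack(perm_rows))
        for k, f in enumerate(used):
            pp = stacked_pred[k * oob.size:(k + 1) * oob.size]
            importance_sum[f] += acc - float((pp == y[oob]).mean())
        importance_trees[used] += 1
        # unused features: permutation cannot change predictions -> drop 0
        unused_mask = np.ones(p, bool)
        unused_mask[used] = False
        importance_trees[unused_mask] += 1

    if importance_trees.max() == 0:
        raise ValidationError("no tree produced OOB samples; too few samples")
    importance = importance_sum / np.maximum(importance_trees, 1)

    vote_matrix = np.column_stack([oob_votes[c] for c in classes])
    voted = vote_matrix.sum(axis=1) > 0
    oob_pred = classes[np.argmax(vote_matrix[voted], axis=1)]
    oob_accuracy = float((oob_pred == y[voted]).mean()) if voted.any() else float("nan")

    order = np.argsort(-importance, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    records = pd.DataFrame({"feature_id": matrix.feature_ids,
                            "importance": importance, "rank": rank})
    return ImportanceTable(records=records, n_trees=n_trees,
                           oob_accuracy=oob_accuracy, seed=seed)


def top_features(table: ImportanceTable, min_importance: float = 0.1,
                 max_n: int = 25) -> list[str]:
    """Features with importance > ``min_importance``, best-first, capped at ``max_n``.

    Prefix-stable: the result for a smaller cap is a prefix of a larger one.
    """
    rec = table.records.sort_values("rank")
    sel = rec[rec["importance"] > min_importance]
    return sel["feature_id"].head(max_n).tolist()


def importance_spearman(table_a: ImportanceTable, table_b: ImportanceTable
                        ) -> tuple[float, float]:
    """Spearman rho between two importance vectors on the shared features.

    Average-rank ties; p from the t-approximation for n > 10 and from the
    exact permutation distribution for n <= 10.
    """
    a = table_a.importance_series()
    b = table_b.importance_series()
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValidationError(f"only {len(shared)} shared features; >= 3 required")
    if len(shared) < len(a) or len(shared) < len(b):
        import logging
        logging.getLogger(__name__).info(
            "importance tables only partially overlap: %d shared features",
            len(shared))
    x = a.loc[shared].to_numpy()
    y = b.loc[shared].to_numpy()
    n = len(shared)
    rho = float(stats.spearmanr(x, y).statistic)
    if n > 10:
        p = float(stats.spearmanr(x, y).pvalue)
    else:
        p = _exact_spearman_p(x, y)
    return rho, p


def _exact_spearman_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact permutation p for |rho| at small n (<= 10).

    Enumerates all n! orderings of one rank vector; |rho| is monotone in
    |sum rx*ry| after centering, so the tail is counted on that statistic.
    """
    from itertools import islice, permutations
    rx = stats.rankdata(x) - (len(x) + 1) / 2.0
    ry = stats.rankdata(y) - (len(y) + 1) / 2.0
    obs = abs(float(rx @ ry))
    count = 0
    total = 0
    gen = permutations(ry)
    while True:
        chunk = list(islice(gen, 200_000))
        if not chunk:
            break
        prods = np.abs(np.asarray(chunk) @ rx)
        count += int((prods >= obs - 1e-9).sum())
        total += len(chunk)
    return count / total


def _pearson_of(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    d = float(np.linalg.norm(a) * np.linalg.norm(b))
    return float(a @ b / d) if d > 0 else 0.0
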