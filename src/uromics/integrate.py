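"""Latent-variable discriminant analysis and two-block omics integration.

:class:`PLSDA` fits partial least squares against a one-hot class
indicator by NIPALS power iteration on the cross-covariance, with optional
per-component sparsity (soft-thresholding of the weight vector to a fixed
number of nonzero features — the standard sparse-PLS dialect).
:class:`TwoBlockPLS` is the canonical two-block variant; its per-component
Pearson correlation between paired block scores is the "component
correlation" used to quantify proteome-metabolome correspondence.
:func:`correlation_network` extracts the thresholded protein-volatile
Pearson edge list ("carrier-ligand" candidates).

Columns are centered and scaled to unit variance internally, exactly once.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import logging
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .data import IntensityMatrix
from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)

_MAX_NIPALS_ITER = 500
_NIPALS_TOL = 1e-12


def _standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    sd_safe = np.where(sd > 0, sd, 1.0)   # constant columns stay centered at 0
    return (X - mu) / sd_safe, mu, sd_safe


def _soft_threshold_keep(w: np.ndarray, keep: int) -> np.ndarray:
    """Soft-threshold w so exactly ``keep`` entries stay nonzero."""
    if keep >= w.size:
        return w
    a = np.abs(w)
    thr = np.partition(a, w.size - keep - 1)[w.size - keep - 1]
    return np.sign(w) * np.maximum(a - thr, 0.0)


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError("zero weight vector; data rank too low")
    return v / n


@dataclass
class PLSResults:
    """Scores/loadings of a fitted (s)PLS model, one entry per block."""

    n_components: int
    scores_x: np.ndarray           # samples x components
    weights_x: np.ndarray          # features x components (unit norm)
    loadings_x: np.ndarray
    kept_features: list = field(default_factory=list)  # per component, block X
    scores_y: np.ndarray | None = None
    weights_y: np.ndarray | None = None
    loadings_y: np.ndarray | None = None
    component_correlation: np.ndarray | None = None
    classes: np.ndarray | None = None
    labels: np.ndarray | None = None
    feature_ids: list = field(default_factory=list)
    x_center: np.ndarray | None = None
    x_scale: np.ndarray | None = None

    def transform(self, values: np.ndarray) -> np.ndarray:
        """Project new samples (rows = samples, columns = X-block features)
        onto the fitted components using the stored standardization."""
        if self.x_center is None:
            raise ParameterError("model was fitted without stored preprocessing")
        Xs = (np.asarray(values, float) - self.x_center) / self.x_scale
        R = self.weights_x @ np.linalg.inv(self.loadings_x.T @ self.weights_x)
        return Xs @ R

    def class_means(self) -> dict:
        """Per-class centroid of the X-block scores (discriminant models)."""
        if self.labels is None:
            raise ParameterError("no class labels on this model")
        return {c: self.scores_x[self.labels == c].mean(axis=0)
                for c in self.classes}

    def auc_per_component(self) -> np.ndarray:
        """Binary-class AUC of each score column (two-class models only)."""
        if self.labels is None or len(self.classes) != 2:
            raise ParameterError("per-component AUC needs exactly two classes")
        pos = self.labels == self.classes[1]
        return np.array([auc(self.scores_x[:, k], pos)
                         for k in range(self.n_components)])

    def summary(self) -> str:
        lines = [f"PLS model, {self.n_components} components"]
        if self.component_correlation is not None:
            corr = ", ".join(f"{r:.3f}" for r in self.component_correlation)
            lines.append(f"  component correlations: {corr}")
        if self.labels is not None and len(self.classes) == 2:
            aucs = ", ".join(f"{a:.3f}" for a in self.auc_per_component())
            lines.append(f"  per-component AUC: {aucs}")
        for k, kept in enumerate(self.kept_features):
            if kept is not None:
                lines.append(f"  component {k + 1}: {len(kept)} features kept")
        return "\n".join(lines)


class PLSDA:
    """(Sparse) PLS discriminant analysis of one block against class labels.

    Parameters
    ----------
    matrix : IntensityMatrix
        Feature x sample block; transposed and standardized internally.
    labels : sequence
        One class label per sample.
    n_components : int
    keep : int or sequence or None
        Nonzero features per component (None = dense).
    """

    def __init__(self, matrix: IntensityMatrix, labels, n_components: int = 2,
                 keep=None):
        X = matrix.values.T
        labels = np.asarray(labels)
        if labels.shape[0] != X.shape[0]:
            raise ValidationError("one label per sample required")
        classes = np.unique(labels)
        if classes.size < 2:
            raise ValidationError("PLS-DA needs >= 2 classes")
        if n_components < 1:
            raise ParameterError("n_components must be >= 1")
        if n_components > min(X.shape) - 1 and n_components > 1:
            raise ParameterError(f"n_components={n_components} exceeds data rank")
        if keep is not None:
            keeps = [keep] * n_components if np.isscalar(keep) else list(keep)
            if any(k > X.shape[1] or k < 1 for k in keeps):
                raise ParameterError("keep must be in [1, n_features]")
        else:
            keeps = [None] * n_components
        self._X = X
        self._labels = labels
        self._classes = classes
        self._n_components = n_components
        self._keeps = keeps
        self._feature_ids = list(matrix.feature_ids)

    def fit(self) -> PLSResults:
        X, x_mu, x_sd = _standardize(self._X)
        Y = np.zeros((X.shape[0], self._classes.size))
        for j, c in enumerate(self._classes):
            Y[:, j] = self._labels == c
        Y = Y - Y.mean(axis=0)

        n, p = X.shape
        K = self._n_components
        T = np.zeros((n, K))
        W = np.zeros((p, K))
        P = np.zeros((p, K))
        kept = []
        Xd, Yd = X.copy(), Y.copy()
        for k in range(K):
            w = _nipals_component(Xd, Yd, self._keeps[k])
            t = Xd @ w
            tt = float(t @ t)
            if tt == 0:
                raise ValidationError(f"component {k + 1}: degenerate score vector")
            pvec = Xd.T @ t / tt
            c = Yd.T @ t / tt
            Xd = Xd - np.outer(t, pvec)
            Yd = Yd - np.outer(t, c)
            # component sign is arbitrary; orient so the last class scores high
            if t[self._labels == self._classes[-1]].mean() < 0:
                t, w, pvec = -t, -w, -pvec
            T[:, k], W[:, k], P[:, k] = t, w, pvec
            kept.append(np.flatnonzero(w) if self._keeps[k] is not None else None)
        return PLSResults(n_components=K, scores_x=T, weights_x=W, loadings_x=P,
                          kept_features=kept, classes=self._classes,
                          labels=self._labels, feature_ids=self._feature_ids,
                          x_center=x_mu, x_scale=x_sd)


def _nipals_component(X: np.ndarray, Y: np.ndarray, keep: int | None) -> np.ndarray:
    """One NIPALS weight vector, optionally soft-thresholded to ``keep`` features."""
    u = Y[:, 0].copy()
    if not u.any():
        u = Y.sum(axis=1)
    w = np.zeros(X.shape[1])
    for _ in range(_MAX_NIPALS_ITER):
        w_new = X.T @ u
        if keep is not None:
            w_new = _soft_threshold_keep(w_new, keep)
        w_new = _unit(w_new)
        t = X @ w_new
        c = _unit(Y.T @ t)
        u = Y @ c
        if np.linalg.norm(w_new - w) < _NIPALS_TOL:
            w = w_new
            break
        w = w_new
    return w


def plsda(matrix: IntensityMatrix, labels, n_components: int = 2,
          keep=None) -> PLSResults:
    """Functional wrapper over :class:`PLSDA`."""
    return PLSDA(matrix, labels, n_components, keep).fit()


def cross_validated_auc(matrix: IntensityMatrix, labels, n_components: int = 1,
                        keep=None, n_splits: int = 5,
                        seed: int | None = 0) -> float:
    """Stratified k-fold cross-validated AUC of the component-1 score.

    Held-out samples are projected through the training fit; their pooled
    component-1 scores are scored against the binary labels.  In-sample
    PLS-DA scores overfit badly at omics dimensionality, so chance-level
    behaviour under permuted labels only shows up cross-validated.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValidationError("cross-validated AUC needs exactly two classes")
    rng = np.random.default_rng(seed)
    n = matrix.n_samples
    folds = np.empty(n, int)
    for c in classes:
        idx = np.flatnonzero(labels == c)
        rng.shuffle(idx)
        folds[idx] = np.arange(idx.size) % n_splits
    scores = np.empty(n)
    sample_ids = np.array(matrix.sample_ids)
    for f in range(n_splits):
        train = folds != f
        res = PLSDA(matrix.subset_samples(list(sample_ids[train])),
                    labels[train], n_components, keep).fit()
        proj = res.transform(matrix.values[:, ~train].T)[:, 0]
        # orient by training class means so folds agree on sign
        if res.scores_x[res.labels == classes[1], 0].mean() < 0:
            proj = -proj
        scores[~train] = proj
    return auc(scores, labels == classes[1])


class TwoBlockPLS:
    """Canonical two-block PLS between aligned feature blocks.

    Blocks must share the same sample set; columns are aligned by sample id
    and standardized internally.  Component-1 weights coincide with the
    leading singular vectors of the centered cross-covariance matrix.
    """

    def __init__(self, block_x: IntensityMatrix, block_y: IntensityMatrix,
                 n_components: int = 2):
        sx, sy = set(block_x.sample_ids), set(block_y.sample_ids)
        if sx != sy:
            raise ValidationError(
                f"sample sets differ; only in X: {sorted(sx - sy)}, "
                f"only in Y: {sorted(sy - sx)}")
        block_y = block_y.subset_samples(block_x.sample_ids)
        self._X = block_x.values.T
        self._Y = block_y.values.T
        self._n_components = n_components
        self._ids_x = list(block_x.feature_ids)
        self._ids_y = list(block_y.feature_ids)

    def fit(self) -> PLSResults:
        X, _, _ = _standardize(self._X)
        Y, _, _ = _standardize(self._Y)
        n = X.shape[0]
        K = self._n_components
        if K < 1 or K >= n:
            raise ParameterError(f"n_components must be in [1, {n - 1}]")
        Tx = np.zeros((n, K))
        Ty = np.zeros((n, K))
        Wx = np.zeros((X.shape[1], K))
        Wy = np.zeros((Y.shape[1], K))
        Px = np.zeros((X.shape[1], K))
        Py = np.zeros((Y.shape[1], K))
        corr = np.zeros(K)
        Xd, Yd = X.copy(), Y.copy()
        for k in range(K):
            u = Yd[:, int(np.argmax(Yd.var(axis=0)))].copy()
            wx = np.zeros(Xd.shape[1])
            for _ in range(_MAX_NIPALS_ITER):
                wx_new = _unit(Xd.T @ u)
                t = Xd @ wx_new
                wy = _unit(Yd.T @ t)
                u = Yd @ wy
                if np.linalg.norm(wx_new - wx) < _NIPALS_TOL:
                    wx = wx_new
                    break
                wx = wx_new
            t = Xd @ wx
            u = Yd @ wy
            corr[k] = _pearson(t, u)
            px = Xd.T @ t / float(t @ t)
            py = Yd.T @ u / float(u @ u)
            Xd = Xd - np.outer(t, px)       # canonical deflation: own scores
            Yd = Yd - np.outer(u, py)
            Tx[:, k], Ty[:, k], Wx[:, k], Wy[:, k] = t, u, wx, wy
            Px[:, k], Py[:, k] = px, py
        return PLSResults(n_components=K, scores_x=Tx, weights_x=Wx,
                          loadings_x=Px, scores_y=Ty, weights_y=Wy,
                          loadings_y=Py, component_correlation=corr,
                          feature_ids=self._ids_x)


def two_block_pls(block_x: IntensityMatrix, block_y: IntensityMatrix,
                  n_components: int = 2) -> PLSResults:
    """Functional wrapper over :class:`TwoBlockPLS`."""
    return TwoBlockPLS(block_x, block_y, n_components).fit()


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.linalg.norm(a) * np.linalg.norm(b)
    return float(a @ b / denom) if denom > 0 else float("nan")


def auc(scores, positive) -> float:
    """Rank-statistic AUC with ties counted half: U / (n_pos * n_neg).

    Equals the probability that a random positive outscores a random
    negative; invariant under strictly monotone transforms of the scores.
    """
    scores = np.asarray(scores, float)
    positive = np.asarray(positive, bool)
    n_pos = int(positive.sum())
    n_neg = int((~positive).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes non-empty")
    ranks = rankdata(scores)            # average ranks handle ties
    u = ranks[positive].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def correlation_network(block_x: IntensityMatrix, block_y: IntensityMatrix,
                        r_threshold: float = 0.62,
                        subset_x=None, signed: bool = True) -> pd.DataFrame:
    """Thresholded cross-block Pearson edge list.

    Computes Pearson r between every (X-feature, Y-feature) pair across the
    shared samples and keeps edges with ``r > r_threshold`` (or
    ``|r| > r_threshold`` when ``signed=False``).  Constant features have
    undefined r and are excluded with a log entry.  ``subset_x`` restricts
    the X side (e.g. to the lipocalins).
    """
    if not (0 < r_threshold < 1):
        raise ParameterError("r_threshold must be in (0, 1)")
    sx, sy = set(block_x.sample_ids), set(block_y.sample_ids)
    if sx != sy:
        raise ValidationError("blocks must share identical sample sets")
    block_y = block_y.subset_samples(block_x.sample_ids)
    if subset_x is not None:
        block_x = block_x.subset_features(list(subset_x))

    X = block_x.values
    Y = block_y.values
    n = X.shape[1]
    const_x = X.std(axis=1) == 0
    const_y = Y.std(axis=1) == 0
    if const_x.any() or const_y.any():
        log.info("excluding %d constant X and %d constant Y features from the "
                 "network", int(const_x.sum()), int(const_y.sum()))
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    xn = np.linalg.norm(Xc, axis=1)
    yn = np.linalg.norm(Yc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        R = (Xc @ Yc.T) / np.outer(np.where(xn > 0, xn, 1.0),
                                   np.where(yn > 0, yn, 1.0))
    R[const_x, :] = np.nan
    R[:, const_y] = np.nan
    crit = R > r_threshold if signed else np.abs(R) > r_threshold
    ii, jj = np.nonzero(np.nan_to_num(crit, nan=False))
    rows = [{"source": block_x.feature_ids[i], "source_layer": block_x.kind,
             "target": block_y.feature_ids[j], "target_layer": block_y.kind,
             "r": float(R[i, j]), "n": n}
            for i, j in zip(ii, jj)]
    return pd.DataFrame(rows, columns=["source", "source_layer", "target",
                                       "target_layer", "r", "n"])
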