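"""Quantile normalization and log-transform utilities.

Quantile normalization forces every sample column to share one empirical
intensity distribution: the reference is the row-wise mean of the
column-sorted matrix, and each column's values are replaced by the
reference values at their ranks.  Ties within a column receive the mean of
the reference values at the tied ranks (the "average" dialect).  Zeros are
real below-detection observations and participate like any other value.
"""
from __future__ import annotations

import numpy as np

from .data import IntensityMatrix
from .errors import ParameterError


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Quantile-normalize the columns of an intensity matrix.

    After normalization every column holds the identical multiset of values
    (up to tie averaging) and rank order within each column is preserved.
    Idempotent, and requires >= 2 samples.
    """
    if matrix.n_samples < 2:
        raise ParameterError("quantile normalization needs >= 2 samples")
    X = matrix.values
    n, m = X.shape
    reference = np.sort(X, axis=0).mean(axis=1)   # row means of sorted columns

    out = np.empty_like(X)
    for j in range(m):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        mapped = np.empty(n)
        mapped[order] = reference
        # tie groups share the mean of their reference values
        sorted_vals = col[order]
        boundaries = np.flatnonzero(np.diff(sorted_vals) != 0)
        starts = np.concatenate(([0], boundaries + 1))
        ends = np.concatenate((boundaries + 1, [n]))
        for s, e in zip(starts, ends):
            if e - s > 1:
                mapped[order[s:e]] = reference[s:e].mean()
        out[:, j] = mapped
    return matrix.copy_with(out)


def log_transform(matrix: IntensityMatrix, base: float = 2.0,
                  pseudo: float = 1.0) -> IntensityMatrix:
    """value -> log_base(value + pseudo); monotone and invertible given pseudo."""
    if pseudo <= 0:
        raise ParameterError("pseudo must be > 0")
    if base <= 1:
        raise ParameterError("base must be > 1")
    return matrix.copy_with(np.log(matrix.values + pseudo) / np.log(base))


def unlog_transform(matrix: IntensityMatrix, base: float = 2.0,
                    pseudo: float = 1.0) -> IntensityMatrix:
    """Inverse of :func:`log_transform`."""
    vals = np.power(base, matrix.values) - pseudo
    return matrix.copy_with(np.clip(vals, 0.0, None))
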