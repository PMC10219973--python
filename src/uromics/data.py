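"""Core data containers: intensity matrices and sample annotations.

An :class:`IntensityMatrix` is a nonnegative feature x sample abundance
table (GC×GC-MS peak areas or LFQ protein intensities); 0 encodes
"not detected".  A :class:`SampleTable` maps every sample column to its
group (DOM / MUS / wMUS / other), sex (M / F, NA for blanks) and role
(specimen or blank).  All downstream stages consume these two objects.

Orientation is fixed package-wide: features are rows, samples are columns.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, ParseError, ValidationError

log = logging.getLogger(__name__)

VALID_ROLES = frozenset({"specimen", "blank"})
VALID_SEXES = frozenset({"M", "F", "NA"})


def _check_unique(ids: Sequence[str], what: str) -> None:
    s = pd.Series(ids)
    dup = s[s.duplicated()].unique().tolist()
    if dup:
        raise ValidationError(f"duplicate {what}: {dup}")


class IntensityMatrix:
    """Nonnegative feature x sample abundance matrix.

    Parameters
    ----------
    values : array-like, shape (n_features, n_samples)
        Nonnegative intensities; 0 means below detection.
    feature_ids, sample_ids : sequences of unique strings
    kind : {"protein", "volatile"}
    """

    def __init__(self, values, feature_ids: Sequence[str],
                 sample_ids: Sequence[str], kind: str = "volatile"):
        arr = np.asarray(values, dtype=float)
        if arr.ndim != 2:
            raise ValidationError("values must be a 2-D matrix")
        if arr.shape != (len(feature_ids), len(sample_ids)):
            raise ValidationError(
                f"shape {arr.shape} does not match {len(feature_ids)} features "
                f"x {len(sample_ids)} samples")
        if not np.isfinite(arr).all():
            raise ValidationError("values contain non-finite entries")
        if (arr < 0).any():
            bad = int((arr < 0).sum())
            raise ValidationError(f"{bad} negative intensities; values must be >= 0")
        if kind not in ("protein", "volatile"):
            raise ValidationError(f"unknown omics kind {kind!r}")
        _check_unique(list(feature_ids), "feature ids")
        _check_unique(list(sample_ids), "sample ids")
        self.values = arr
        self.feature_ids = [str(f) for f in feature_ids]
        self.sample_ids = [str(s) for s in sample_ids]
        self.kind = kind

    # -- basic protocol ----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids,
                            columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, kind: str) -> "IntensityMatrix":
        return cls(frame.to_numpy(dtype=float), list(frame.index.astype(str)),
                   list(frame.columns.astype(str)), kind)

    def copy_with(self, values: np.ndarray) -> "IntensityMatrix":
        return IntensityMatrix(values, self.feature_ids, self.sample_ids, self.kind)

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return (self.feature_ids == other.feature_ids
                and self.sample_ids == other.sample_ids
                and self.kind == other.kind
                and np.array_equal(self.values, other.values))

    def __repr__(self) -> str:
        return (f"IntensityMatrix(kind={self.kind!r}, "
                f"{self.n_features} features x {self.n_samples} samples)")

    # -- subsetting --------------------------------------------------------
    def subset_samples(self, samples: Iterable[str]) -> "IntensityMatrix":
        """Column subset in the requested order; features unchanged."""
        samples = list(samples)
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in pos]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        idx = [pos[s] for s in samples]
        return IntensityMatrix(self.values[:, idx], self.feature_ids,
                               samples, self.kind)

    def subset_features(self, features: Iterable[str]) -> "IntensityMatrix":
        features = list(features)
        pos = {f: i for i, f in enumerate(self.feature_ids)}
        missing = [f for f in features if f not in pos]
        if missing:
            raise KeyError(f"unknown feature ids: {missing}")
        idx = [pos[f] for f in features]
        return IntensityMatrix(self.values[idx, :], features,
                               self.sample_ids, self.kind)


def subset(matrix: IntensityMatrix, samples: Iterable[str]) -> IntensityMatrix:
    """Functional alias for :meth:`IntensityMatrix.subset_samples`."""
    return matrix.subset_samples(samples)


def read_matrix(path, format: str | None = None, kind: str = "volatile") -> IntensityMatrix:
    """Read a feature x sample table (first column feature ids, header sample ids).

    Empty cells become 0 (below detection) with a logged count; negative or
    non-numeric cells are an error.  ``format`` may be "csv" or "tsv"; when
    None it is inferred from the file suffix (default tsv).
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "tsv"
    if format not in ("csv", "tsv"):
        raise ParameterError(f"unknown format {format!r}; expected csv or tsv")
    sep = "," if format == "csv" else "\t"
    try:
        frame = pd.read_csv(path, sep=sep, index_col=0, header=0,
                            dtype=str, keep_default_na=False,
                            on_bad_lines="error")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    n_empty = int((frame.to_numpy() == "").sum())
    if n_empty:
        log.info("%s: %d empty cells read as 0 (below detection)", path, n_empty)
        frame = frame.replace("", "0")
    try:
        numeric = frame.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell ({exc})") from exc
    _check_unique(list(frame.index), "feature ids")
    _check_unique(list(frame.columns), "sample ids")
    return IntensityMatrix.from_frame(numeric, kind)


def write_matrix(matrix: IntensityMatrix, path, format: str | None = None) -> None:
    """Write a matrix so that ``read_matrix`` round-trips values exactly.

    Uses repr-precision floats; decimal-representable inputs survive
    bit-for-bit.
    """
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "tsv"
    sep = "," if format == "csv" else "\t"
    matrix.to_frame().to_csv(path, sep=sep, float_format=None)


class SampleTable:
    """Validated collection of per-sample annotations.

    Wraps a DataFrame with columns ``sample_id, group, sex, role,
    individual_id``.  Blanks have sex NA; every specimen has a defined
    group and sex.
    """

    COLUMNS = ["sample_id", "group", "sex", "role", "individual_id"]

    def __init__(self, frame: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in frame.columns]
        if missing:
            raise ValidationError(f"annotation missing columns: {missing}")
        frame = frame[self.COLUMNS].astype(str).reset_index(drop=True)
        _check_unique(list(frame["sample_id"]), "sample ids")
        bad_role = frame.loc[~frame["role"].isin(VALID_ROLES)]
        if len(bad_role):
            rows = bad_role.index.tolist()
            raise ValidationError(
                f"unknown role {sorted(bad_role['role'].unique())} at rows {rows}; "
                f"legal roles: {sorted(VALID_ROLES)}")
        bad_sex = frame.loc[~frame["sex"].isin(VALID_SEXES)]
        if len(bad_sex):
            raise ValidationError(
                f"unknown sex values {sorted(bad_sex['sex'].unique())}")
        spec = frame[frame["role"] == "specimen"]
        na_spec = spec[spec["sex"] == "NA"]
        if len(na_spec):
            raise ValidationError(
                f"specimens with sex=NA: {na_spec['sample_id'].tolist()}")
        empty_grp = spec[spec["group"].isin(["", "NA"])]
        if len(empty_grp):
            raise ValidationError(
                f"specimens without group: {empty_grp['sample_id'].tolist()}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return self.frame["sample_id"].tolist()

    def specimens(self) -> pd.DataFrame:
        return self.frame[self.frame["role"] == "specimen"]

    def blanks(self) -> list[str]:
        return self.frame.loc[self.frame["role"] == "blank", "sample_id"].tolist()

    def specimen_ids(self) -> list[str]:
        return self.specimens()["sample_id"].tolist()

    def groups(self) -> list[str]:
        return sorted(self.specimens()["group"].unique())

    def cell_members(self) -> dict[tuple[str, str], list[str]]:
        """Map (group, sex) -> specimen sample ids."""
        out: dict[tuple[str, str], list[str]] = {}
        for (g, s), sub in self.specimens().groupby(["group", "sex"]):
            out[(g, s)] = sub["sample_id"].tolist()
        return out

    def labels_for(self, sample_ids: Sequence[str], what: str = "sex") -> np.ndarray:
        """Label vector (sex or group) aligned to ``sample_ids``."""
        if what not in ("sex", "group"):
            raise ValidationError(f"unknown label {what!r}")
        lookup = dict(zip(self.frame["sample_id"], self.frame[what]))
        missing = [s for s in sample_ids if s not in lookup]
        if missing:
            raise ValidationError(f"samples not annotated: {missing}")
        return np.array([lookup[s] for s in sample_ids])

    def check_covers(self, matrix: IntensityMatrix) -> None:
        missing = [s for s in matrix.sample_ids if s not in set(self.sample_ids)]
        if missing:
            raise ValidationError(f"matrix samples not annotated: {missing}")


def read_annotation(path) -> SampleTable:
    """Read and validate a sample-annotation CSV with the five named columns."""
    try:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return SampleTable(frame)


def write_annotation(table: SampleTable, path) -> None:
    table.frame.to_csv(path, index=False)
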