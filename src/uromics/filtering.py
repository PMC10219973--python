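"""Blank-aware feature filtering for volatile (and protein) tables.

The funnel has a fixed order:

1. **prevalence filter** — keep a feature only if at least ``min_count``
   specimens of one group x sex cell detected it (blanks never count);
2. **blank-only removal** — drop features present in blanks but in no
   specimen;
3. **mixture filter** — fit a two-component normal mixture to the
   per-feature log2 fold difference of specimen mean over blank mean and
   drop features whose posterior probability of the biological (high)
   component falls below a threshold.

The protein layer has no blanks and passes only through stage 1.

The per-feature audit trail (:class:`FilterReport`) records the detection
counts, blank fold difference, the bounded identity index
``LI = (specimen - blank) / (specimen + blank)`` and the drop reason for
every input feature, plus the funnel stage counts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IntensityMatrix, SampleTable
from .errors import ParameterError, ValidationError

#: LI return value for the undefined 0/0 case; outside the legal [-1, 1] range.
LI_UNDEFINED = np.nan


def identity_index(mean_specimen: float, mean_blank: float) -> float:
    """Bounded identity index (specimen - blank)/(specimen + blank) in [-1, 1].

    +1 means specimen-exclusive, -1 blank-exclusive, 0 equal means.
    Undefined (NaN) when both means are zero.
    """
    s, b = float(mean_specimen), float(mean_blank)
    if s < 0 or b < 0:
        raise ParameterError("identity_index needs nonnegative means")
    denom = s + b
    if denom == 0:
        return LI_UNDEFINED
    return (s - b) / denom


# ---------------------------------------------------------------------------
# report container


@dataclass
class FilterReport:
    """Per-feature audit trail and funnel stage counts."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)
    n_input: int = 0
    n_after_prevalence: int = 0
    n_after_blank_only: int = 0
    n_after_mixture: int = 0
    implied_fd_cutoff: float = float("nan")
    implied_li_cutoff: float = float("nan")

    RECORD_COLUMNS = [
        "feature_id", "n_specimen_detect", "detected_in_blank_only",
        "mean_specimen", "mean_blank", "fd_blank", "li", "posterior_bio",
        "kept", "drop_reason",
    ]

    def stage_counts(self) -> dict[str, int]:
        return {"n_input": self.n_input,
                "n_after_prevalence": self.n_after_prevalence,
                "n_after_blank_only": self.n_after_blank_only,
                "n_after_mixture": self.n_after_mixture}

    def to_csv(self, path) -> None:
        self.records.to_csv(path, index=False)


def _new_records(matrix: IntensityMatrix, ann: SampleTable) -> pd.DataFrame:
    spec = [s for s in matrix.sample_ids if s in set(ann.specimen_ids())]
    blanks = [s for s in matrix.sample_ids if s in set(ann.blanks())]
    sub_s = matrix.subset_samples(spec).values if spec else np.zeros((matrix.n_features, 0))
    sub_b = matrix.subset_samples(blanks).values if blanks else np.zeros((matrix.n_features, 0))
    mean_s = sub_s.mean(axis=1) if sub_s.shape[1] else np.zeros(matrix.n_features)
    mean_b = sub_b.mean(axis=1) if sub_b.shape[1] else np.zeros(matrix.n_features)
    denom = mean_s + mean_b
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(denom > 0, (mean_s - mean_b) / np.where(denom > 0, denom, 1.0),
                      LI_UNDEFINED)
        fd = np.where(mean_b > 0, mean_s / np.where(mean_b > 0, mean_b, 1.0), np.inf)
    return pd.DataFrame({
        "feature_id": matrix.feature_ids,
        "n_specimen_detect": (sub_s > 0).sum(axis=1) if sub_s.shape[1] else 0,
        "detected_in_blank_only": ((sub_s > 0).sum(axis=1) == 0) & ((sub_b > 0).sum(axis=1) > 0)
            if sub_b.shape[1] else False,
        "mean_specimen": mean_s,
        "mean_blank": mean_b,
        "fd_blank": fd,
        "li": li,
        "posterior_bio": np.nan,
        "kept": True,
        "drop_reason": "none",
    })


# ---------------------------------------------------------------------------
# stage 1: prevalence


def prevalence_filter(matrix: IntensityMatrix, annotation: SampleTable,
                      min_count: int = 3) -> tuple[IntensityMatrix, FilterReport]:
    """Keep features detected in >= ``min_count`` specimens of some group x sex cell.

    Blanks are ignored for counting.  Dropped features get
    ``drop_reason='singleton'``.
    """
    if min_count < 1:
        raise ParameterError("min_count must be >= 1")
    annotation.check_covers(matrix)
    cells = annotation.cell_members()
    present = set(matrix.sample_ids)
    keep = np.zeros(matrix.n_features, bool)
    for members in cells.values():
        members = [m for m in members if m in present]
        if not members:
            continue
        counts = (matrix.subset_samples(members).values > 0).sum(axis=1)
        keep |= counts >= min_count

    report = FilterReport(records=_new_records(matrix, annotation),
                          n_input=matrix.n_features)
    report.records.loc[~keep, "kept"] = False
    report.records.loc[~keep, "drop_reason"] = "singleton"
    report.n_after_prevalence = int(keep.sum())
    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    return matrix.subset_features(kept_ids), report


# ---------------------------------------------------------------------------
# stage 2: blank-only removal


def remove_blank_only(matrix: IntensityMatrix, annotation: SampleTable,
                      report: FilterReport | None = None
                      ) -> tuple[IntensityMatrix, FilterReport]:
    """Drop features with zero in every specimen and signal in >= 1 blank.

    A feature detected in even one specimen survives this stage ("only in
    blanks" is strict).
    """
    annotation.check_covers(matrix)
    blanks = [s for s in matrix.sample_ids if s in set(annotation.blanks())]
    if matrix.kind == "volatile" and not blanks:
        raise ValidationError(
            "volatile matrix has no blank columns; pass a matrix with blanks "
            "or skip blank-only removal explicitly")
    spec = [s for s in matrix.sample_ids if s in set(annotation.specimen_ids())]
    in_spec = (matrix.subset_samples(spec).values > 0).any(axis=1)
    in_blank = (matrix.subset_samples(blanks).values > 0).any(axis=1) if blanks else \
        np.zeros(matrix.n_features, bool)
    drop = ~in_spec & in_blank

    if report is None:
        report = FilterReport(records=_new_records(matrix, annotation),
                              n_input=matrix.n_features,
                              n_after_prevalence=matrix.n_features)
    dropped_ids = [f for f, d in zip(matrix.feature_ids, drop) if d]
    mask = report.records["feature_id"].isin(dropped_ids)
    report.records.loc[mask, "kept"] = False
    report.records.loc[mask, "drop_reason"] = "blank_only"
    report.n_after_blank_only = int((~drop).sum())
    kept_ids = [f for f, d in zip(matrix.feature_ids, drop) if not d]
    return matrix.subset_features(kept_ids), report


# ---------------------------------------------------------------------------
# stage 3: two-component normal mixture (EM), statsmodels-style Model/Results


@dataclass
class BlankMixtureResults:
    """Fitted two-component univariate normal mixture.

    Component 1 is the blank-overlap (low-mean) component, component 2 the
    biological one; the labelling invariant ``mu2 > mu1`` is enforced.
    """

    lam: float          # weight of the blank-overlap component
    mu1: float
    sigma1: float
    mu2: float
    sigma2: float
    loglik: float
    converged: bool
    n_iter: int
    loglik_path: np.ndarray = field(default_factory=lambda: np.array([]))

    def posterior_bio(self, x: np.ndarray) -> np.ndarray:
        """P(biological component | x); sums with the blank posterior to 1."""
        x = np.asarray(x, float)
        from scipy.stats import norm
        p1 = self.lam * norm.pdf(x, self.mu1, self.sigma1)
        p2 = (1.0 - self.lam) * norm.pdf(x, self.mu2, self.sigma2)
        tot = p1 + p2
        # both densities can underflow far in a tail; assign by proximity there
        far_bio = (tot == 0) & (x > (self.mu1 + self.mu2) / 2)
        out = np.where(tot > 0, p2 / np.where(tot > 0, tot, 1.0), 0.0)
        out[far_bio] = 1.0
        return out

    def summary(self) -> str:
        lines = [
            "Two-component normal mixture (blank-overlap vs biological)",
            f"  lambda (blank)   {self.lam:10.4f}",
            f"  mu1 / sigma1     {self.mu1:10.4f} / {self.sigma1:.4f}",
            f"  mu2 / sigma2     {self.mu2:10.4f} / {self.sigma2:.4f}",
            f"  log-likelihood   {self.loglik:10.4f}",
            f"  converged        {self.converged} ({self.n_iter} iterations)",
        ]
        return "\n".join(lines)


class BlankMixtureModel:
    """EM fit of a two-component normal mixture to 1-D data.

    Initialization is deterministic: the sample is split at its median and
    each half provides one component's starting moments.  The EM iteration
    stops when the log-likelihood improves by less than ``tol`` (default
    1e-8) or after ``max_iter`` (default 1000) iterations; the
    ``converged`` flag reports which.  Degenerate sigmas are floored at 1e-6.
    """

    SIGMA_FLOOR = 1e-6

    def __init__(self, x: np.ndarray):
        x = np.asarray(x, float)
        if x.ndim != 1 or x.size < 2:
            raise ParameterError("mixture fit needs a 1-D sample of size >= 2")
        if not np.isfinite(x).all():
            raise ParameterError("mixture input contains non-finite values")
        self.x = x

    def _init_params(self):
        x = self.x
        med = np.median(x)
        lo, hi = x[x <= med], x[x > med]
        if hi.size == 0:            # all values tied at the median
            lo = hi = x
        mu1, mu2 = float(np.mean(lo)), float(np.mean(hi))
        s1 = max(float(np.std(lo)), self.SIGMA_FLOOR)
        s2 = max(float(np.std(hi)), self.SIGMA_FLOOR)
        lam = lo.size / x.size if hi.size else 0.5
        lam = min(max(lam, 1e-6), 1 - 1e-6)
        return lam, mu1, s1, mu2, s2

    @staticmethod
    def _loglik(x, lam, mu1, s1, mu2, s2) -> float:
        from scipy.stats import norm
        dens = lam * norm.pdf(x, mu1, s1) + (1 - lam) * norm.pdf(x, mu2, s2)
        return float(np.log(np.maximum(dens, 1e-300)).sum())

    def fit(self, max_iter: int = 1000, tol: float = 1e-8) -> BlankMixtureResults:
        from scipy.stats import norm
        x = self.x
        lam, mu1, s1, mu2, s2 = self._init_params()
        ll = self._loglik(x, lam, mu1, s1, mu2, s2)
        path = [ll]
        converged = False
        degenerate = np.ptp(x) == 0
        it = 0
        for it in range(1, max_iter + 1):
            # E step
            p1 = lam * norm.pdf(x, mu1, s1)
            p2 = (1 - lam) * norm.pdf(x, mu2, s2)
            tot = np.maximum(p1 + p2, 1e-300)
            r1 = p1 / tot
            # M step
            w1 = r1.sum()
            w2 = x.size - w1
            if w1 < 1e-12 or w2 < 1e-12:
                degenerate = True
                break
            mu1 = float((r1 * x).sum() / w1)
            mu2 = float(((1 - r1) * x).sum() / w2)
            s1 = max(float(np.sqrt((r1 * (x - mu1) ** 2).sum() / w1)), self.SIGMA_FLOOR)
            s2 = max(float(np.sqrt(((1 - r1) * (x - mu2) ** 2).sum() / w2)), self.SIGMA_FLOOR)
            lam = float(w1 / x.size)
            new_ll = self._loglik(x, lam, mu1, s1, mu2, s2)
            path.append(new_ll)
            if abs(new_ll - ll) < tol:
                converged = True
                ll = new_ll
                break
            ll = new_ll
        if degenerate:
            converged = False
        # enforce labelling: component 2 is the biological (larger-mean) one
        if mu1 > mu2:
            lam, mu1, s1, mu2, s2 = 1 - lam, mu2, s2, mu1, s1
        return BlankMixtureResults(lam=lam, mu1=mu1, sigma1=s1, mu2=mu2,
                                   sigma2=s2, loglik=ll, converged=converged,
                                   n_iter=it, loglik_path=np.asarray(path))


def blank_fold_difference(matrix: IntensityMatrix, annotation: SampleTable,
                          pseudo: float | None = None) -> tuple[np.ndarray, float]:
    """Per-feature x = log2((specimen mean + pseudo)/(blank mean + pseudo)).

    ``pseudo`` defaults to half the smallest nonzero intensity in the matrix.
    Returns (x, pseudo used).
    """
    annotation.check_covers(matrix)
    if pseudo is None:
        nz = matrix.values[matrix.values > 0]
        if nz.size == 0:
            raise ParameterError("matrix is all-zero; cannot derive pseudo-intensity")
        pseudo = float(nz.min()) / 2.0
    if pseudo <= 0:
        raise ParameterError("pseudo must be > 0")
    spec = [s for s in matrix.sample_ids if s in set(annotation.specimen_ids())]
    blanks = [s for s in matrix.sample_ids if s in set(annotation.blanks())]
    if not blanks:
        raise ValidationError("no blank columns; mixture stage needs blanks")
    mean_s = matrix.subset_samples(spec).values.mean(axis=1)
    mean_b = matrix.subset_samples(blanks).values.mean(axis=1)
    return np.log2((mean_s + pseudo) / (mean_b + pseudo)), pseudo


def fit_blank_mixture(matrix: IntensityMatrix, annotation: SampleTable,
                      pseudo: float | None = None) -> BlankMixtureResults:
    """Fit the blank/biological mixture to the log2 fold-difference statistic."""
    x, _ = blank_fold_difference(matrix, annotation, pseudo)
    return BlankMixtureModel(x).fit()


def mixture_filter(matrix: IntensityMatrix, annotation: SampleTable,
                   fit: BlankMixtureResults,
                   posterior_threshold: float = 0.95,
                   pseudo: float | None = None,
                   report: FilterReport | None = None,
                   force: bool = False) -> tuple[IntensityMatrix, FilterReport]:
    """Keep features with P(biological | x) >= ``posterior_threshold``.

    Completes the :class:`FilterReport`: posterior per feature, the implied
    blank-FD cutoff (smallest blank fold difference among kept features) and
    the implied LI cutoff.  These cutoffs are dataset-specific readouts, not
    inputs.
    """
    if not (0 < posterior_threshold < 1):
        raise ParameterError("posterior_threshold must be in (0, 1)")
    if not fit.converged and not force:
        raise ParameterError("mixture fit did not converge; pass force=True to override")
    x, _ = blank_fold_difference(matrix, annotation, pseudo)
    post = fit.posterior_bio(x)
    keep = post >= posterior_threshold

    if report is None:
        report = FilterReport(records=_new_records(matrix, annotation),
                              n_input=matrix.n_features,
                              n_after_prevalence=matrix.n_features,
                              n_after_blank_only=matrix.n_features)
    idx = report.records["feature_id"].isin(matrix.feature_ids)
    order = report.records.loc[idx, "feature_id"].map(
        {f: i for i, f in enumerate(matrix.feature_ids)})
    report.records.loc[idx, "posterior_bio"] = post[order.to_numpy()]
    dropped = [f for f, k in zip(matrix.feature_ids, keep) if not k]
    mask = report.records["feature_id"].isin(dropped)
    report.records.loc[mask, "kept"] = False
    report.records.loc[mask, "drop_reason"] = "mixture"
    report.n_after_mixture = int(keep.sum())

    kept_ids = [f for f, k in zip(matrix.feature_ids, keep) if k]
    kept_rec = report.records[report.records["feature_id"].isin(kept_ids)]
    report.implied_fd_cutoff = float(kept_rec["fd_blank"].min()) if len(kept_rec) else np.nan
    report.implied_li_cutoff = float(kept_rec["li"].min()) if len(kept_rec) else np.nan
    return matrix.subset_features(kept_ids), report


# ---------------------------------------------------------------------------
# full funnel


def filter_pipeline(matrix: IntensityMatrix, annotation: SampleTable,
                    min_count: int = 3, posterior_threshold: float = 0.95,
                    pseudo: float | None = None, force: bool = False
                    ) -> tuple[IntensityMatrix, FilterReport, BlankMixtureResults | None]:
    """Run the full funnel: prevalence -> blank-only -> mixture.

    Protein matrices (no blanks) stop after the prevalence stage and the
    later stage counts simply carry the prevalence count forward.
    """
    m1, report = prevalence_filter(matrix, annotation, min_count)
    has_blanks = any(s in set(annotation.blanks()) for s in matrix.sample_ids)
    if matrix.kind == "protein" or not has_blanks:
        report.n_after_blank_only = report.n_after_prevalence
        report.n_after_mixture = report.n_after_prevalence
        return m1, report, None
    m2, report = remove_blank_only(m1, annotation, report)
    fit = fit_blank_mixture(m2, annotation, pseudo)
    m3, report = mixture_filter(m2, annotation, fit, posterior_threshold,
                                pseudo, report, force=force)
    return m3, report, fit


def plot_mixture(x: np.ndarray, fit: BlankMixtureResults, path) -> None:
    """Diagnostic histogram of x with the fitted component densities (PNG)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.stats import norm
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(x, bins=60, density=True, color="0.8", label="log2 FD to blanks")
    grid = np.linspace(np.min(x), np.max(x), 400)
    ax.plot(grid, fit.lam * norm.pdf(grid, fit.mu1, fit.sigma1), label="blank-overlap")
    ax.plot(grid, (1 - fit.lam) * norm.pdf(grid, fit.mu2, fit.sigma2), label="biological")
    ax.set_xlabel("log2 fold difference (specimens / blanks)")
    ax.set_ylabel("density")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
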