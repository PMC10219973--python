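"""Power-law global error model (PLGEM) differential abundance.

With few replicates per condition, per-feature variance estimates are too
noisy to test on directly.  The power-law global error model borrows
strength across features: within one well-replicated condition the
standard deviation of a feature is modelled as a power function of its
mean,

    SD(mean) = e^intercept * mean^slope,

fitted by ordinary least squares of ln(SD) on ln(mean) across features.
Differential abundance between two conditions is scored by a
signal-to-noise statistic

    STN = (mean_B - mean_A) / (SD_model(mean_A) + SD_model(mean_B)),

whose null distribution is obtained by resampling: replicates of a single
condition are repeatedly split into two pseudo-groups and their STN values
pooled.  Empirical two-sided p-values use an add-one correction so p is
never exactly 0.

The model operates on linear intensities (its native scale); zeros are
treated as non-detections and excluded from the fit and from means.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import IntensityMatrix, SampleTable
from .errors import ParameterError, ValidationError

log = logging.getLogger(__name__)

Condition = tuple[str, str]   # (group, sex) cell label


def _condition_samples(annotation: SampleTable, condition: Condition,
                       available: set[str]) -> list[str]:
    cells = annotation.cell_members()
    if condition not in cells:
        raise ValidationError(f"condition {condition} not present in annotation")
    return [s for s in cells[condition] if s in available]


def _masked_means(values: np.ndarray) -> np.ndarray:
    """Row means over nonzero (detected) entries; rows with no detection -> 0."""
    detected = values > 0
    counts = detected.sum(axis=1)
    sums = np.where(detected, values, 0.0).sum(axis=1)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


@dataclass
class PLGEMResults:
    """Fitted mean-SD power law plus the resampled STN null."""

    slope: float
    intercept: float          # natural-log scale offset
    r2: float
    fitted_condition: Condition
    n_features_fit: int
    n_zero_excluded: int
    resampled_null: np.ndarray = field(default_factory=lambda: np.array([]))
    model: "PLGEM | None" = None

    def modelled_sd(self, mean: np.ndarray) -> np.ndarray:
        mean = np.asarray(mean, float)
        with np.errstate(invalid="ignore"):
            return np.where(mean > 0, np.exp(self.intercept) * mean ** self.slope, 0.0)

    # -- statistics ------------------------------------------------------
    def stn(self, contrast: tuple[Condition, Condition]) -> pd.Series:
        """Per-feature signal-to-noise for contrast (A, B): (B - A)/(sdA + sdB).

        Features undetected in both conditions are excluded (NaN) and logged.
        """
        if self.model is None:
            raise ParameterError("results are detached from their model")
        return self.model._stn(self, contrast)

    def resample_null(self, n_iter: int = 500, seed: int | None = None,
                      condition: Condition | None = None,
                      contrast_sizes: tuple[int, int] | None = None) -> np.ndarray:
        """Build the pooled resampled STN null and store it on the results.

        ``contrast_sizes`` rescales the null variance from the pseudo-group
        sizes of the split to the replicate counts of the contrast that will
        be tested (see module docstring); without it the null reflects the
        half-split design and p-values are conservative for larger contrasts.
        """
        if self.model is None:
            raise ParameterError("results are detached from their model")
        null = self.model._resample_null(self, n_iter=n_iter, seed=seed,
                                         condition=condition,
                                         contrast_sizes=contrast_sizes)
        self.resampled_null = null
        return null

    def differential(self, contrast: tuple[Condition, Condition],
                     alpha: float = 0.05, fd_threshold: float = 2.0,
                     adjust: str | None = None) -> pd.DataFrame:
        """Differential-abundance table for contrast (male cell, female cell).

        FD follows the signed female-over-male convention: ratios below 1
        are reported as -1/FD so |FD| > fd_threshold is symmetric.
        ``significant`` requires p < alpha and |FD| > fd_threshold;
        ``adjust='bh'`` optionally applies Benjamini-Hochberg to p first.
        """
        if self.model is None:
            raise ParameterError("results are detached from their model")
        return self.model._differential(self, contrast, alpha=alpha,
                                        fd_threshold=fd_threshold, adjust=adjust)

    def summary(self) -> str:
        lines = [
            "Power-law global error model",
            f"  fitted condition   {self.fitted_condition}",
            f"  slope              {self.slope:8.4f}",
            f"  intercept (ln)     {self.intercept:8.4f}",
            f"  r-squared          {self.r2:8.4f}",
            f"  features in fit    {self.n_features_fit}"
            f" ({self.n_zero_excluded} zero-containing excluded)",
            f"  null size          {self.resampled_null.size}",
        ]
        return "\n".join(lines)


class PLGEM:
    """Power-law global error model bound to a matrix + annotation.

    Parameters
    ----------
    matrix : IntensityMatrix
        Linear-scale intensities (protein LFQ or normalized volatile areas).
    annotation : SampleTable
        Sample metadata; conditions are group x sex cells.
    """

    def __init__(self, matrix: IntensityMatrix, annotation: SampleTable):
        annotation.check_covers(matrix)
        self.matrix = matrix
        self.annotation = annotation
        self._available = set(matrix.sample_ids)

    def default_condition(self) -> Condition:
        """The group x sex cell with most replicates (ties: lexicographic)."""
        cells = self.annotation.cell_members()
        sizes = {c: len([s for s in m if s in self._available])
                 for c, m in cells.items()}
        return min(sizes, key=lambda c: (-sizes[c], c))

    def fit(self, condition: Condition | None = None) -> PLGEMResults:
        """OLS of ln(SD) on ln(mean) over features of one condition."""
        if condition is None:
            condition = self.default_condition()
        samples = _condition_samples(self.annotation, condition, self._available)
        if len(samples) < 3:
            raise ValidationError(
                f"condition {condition} has {len(samples)} replicates; >= 3 required")
        vals = self.matrix.subset_samples(samples).values
        fully_detected = (vals > 0).all(axis=1)
        n_zero_excluded = int((~fully_detected).sum())
        sub = vals[fully_detected]
        means = sub.mean(axis=1)
        sds = sub.std(axis=1, ddof=1)
        usable = sds > 0
        if not usable.any():
            raise ValidationError(
                "all features constant across replicates; SD = 0 has no logarithm")
        if usable.sum() < 30:
            log.warning("only %d usable features for the power-law fit", usable.sum())
        lx = np.log(means[usable])
        ly = np.log(sds[usable])
        slope, intercept = np.polyfit(lx, ly, 1)
        resid = ly - (slope * lx + intercept)
        ss_tot = float(((ly - ly.mean()) ** 2).sum())
        r2 = 1.0 - float((resid ** 2).sum()) / ss_tot if ss_tot > 0 else 1.0
        return PLGEMResults(slope=float(slope), intercept=float(intercept),
                            r2=r2, fitted_condition=condition,
                            n_features_fit=int(usable.sum()),
                            n_zero_excluded=n_zero_excluded, model=self)

    # -- internals used by PLGEMResults ----------------------------------
    def _condition_means(self, condition: Condition) -> np.ndarray:
        samples = _condition_samples(self.annotation, condition, self._available)
        if not samples:
            raise ValidationError(f"condition {condition} has no samples in the matrix")
        return _masked_means(self.matrix.subset_samples(samples).values)

    @staticmethod
    def _stn_from_means(res: PLGEMResults, mean_a: np.ndarray,
                        mean_b: np.ndarray) -> np.ndarray:
        denom = res.modelled_sd(mean_a) + res.modelled_sd(mean_b)
        with np.errstate(invalid="ignore", divide="ignore"):
            stn = (mean_b - mean_a) / denom
        stn[(mean_a == 0) & (mean_b == 0)] = np.nan
        return stn

    def _stn(self, res: PLGEMResults,
             contrast: tuple[Condition, Condition]) -> pd.Series:
        cond_a, cond_b = contrast
        mean_a = self._condition_means(cond_a)
        mean_b = self._condition_means(cond_b)
        stn = self._stn_from_means(res, mean_a, mean_b)
        n_undef = int(np.isnan(stn).sum())
        if n_undef:
            log.info("%d features undetected in both conditions; STN undefined",
                     n_undef)
        return pd.Series(stn, index=self.matrix.feature_ids, name="stn")

    def _resample_null(self, res: PLGEMResults, n_iter: int = 500,
                       seed: int | None = None,
                       condition: Condition | None = None,
                       contrast_sizes: tuple[int, int] | None = None) -> np.ndarray:
        if n_iter < 100:
            log.warning("n_iter=%d < 100: the null tail will be unstable", n_iter)
        condition = condition or res.fitted_condition
        samples = _condition_samples(self.annotation, condition, self._available)
        if len(samples) < 4:
            raise ValidationError(
                f"condition {condition} has {len(samples)} replicates; "
                "resampling needs >= 4 to split")
        vals = self.matrix.subset_samples(samples).values
        rng = np.random.default_rng(seed)
        k = len(samples)
        half = k // 2
        # mean-difference variance scales as sd^2*(1/n_a + 1/n_b); rescale the
        # half-split null to the contrast's replicate counts when known
        scale = 1.0
        if contrast_sizes is not None:
            na, nb = contrast_sizes
            if na < 1 or nb < 1:
                raise ParameterError("contrast sizes must be >= 1")
            scale = float(np.sqrt((1.0 / na + 1.0 / nb)
                                  / (1.0 / half + 1.0 / (k - half))))
        pools = []
        for _ in range(n_iter):
            perm = rng.permutation(k)
            a, b = perm[:half], perm[half:]
            mean_a = _masked_means(vals[:, a])
            mean_b = _masked_means(vals[:, b])
            stn = self._stn_from_means(res, mean_a, mean_b)
            pools.append(stn[np.isfinite(stn)])
        return scale * np.concatenate(pools)

    def _differential(self, res: PLGEMResults,
                      contrast: tuple[Condition, Condition],
                      alpha: float = 0.05, fd_threshold: float = 2.0,
                      adjust: str | None = None) -> pd.DataFrame:
        if res.resampled_null.size == 0:
            raise ParameterError("resampled null is empty; call resample_null first")
        cond_m, cond_f = contrast
        mean_m = self._condition_means(cond_m)
        mean_f = self._condition_means(cond_f)
        stn = self._stn_from_means(res, mean_m, mean_f)

        null_abs = np.sort(np.abs(res.resampled_null))
        n_null = null_abs.size
        # two-sided empirical p with add-one correction: p in (0, 1]
        exceed = n_null - np.searchsorted(null_abs, np.abs(stn), side="left")
        p = (exceed + 1.0) / (n_null + 1.0)
        p[~np.isfinite(stn)] = np.nan

        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = mean_f / mean_m
        fd = np.where(ratio >= 1, ratio, -1.0 / np.where(ratio > 0, ratio, np.nan))
        fd[(mean_m == 0) & (mean_f > 0)] = np.inf
        fd[(mean_f == 0) & (mean_m > 0)] = -np.inf
        fd[(mean_m == 0) & (mean_f == 0)] = np.nan

        p_eff = p.copy()
        if adjust == "bh":
            from statsmodels.stats.multitest import multipletests
            ok = np.isfinite(p)
            adj = np.full_like(p, np.nan)
            if ok.any():
                adj[ok] = multipletests(p[ok], method="fdr_bh")[1]
            p_eff = adj
        elif adjust is not None:
            raise ParameterError(f"unknown adjustment {adjust!r}")

        with np.errstate(invalid="ignore"):
            significant = (p_eff < alpha) & (np.abs(fd) > fd_threshold)
        significant &= np.isfinite(stn)
        direction = np.where(~significant, "unbiased",
                             np.where(fd > 0, "female_biased", "male_biased"))
        table = pd.DataFrame({
            "feature_id": self.matrix.feature_ids,
            "mean_A": mean_m,
            "mean_B": mean_f,
            "stn": stn,
            "p": p,
            "p_adj": p_eff if adjust else p,
            "fd": fd,
            "significant": significant,
            "direction": direction,
        })
        return table


def differential_by_sex(matrix: IntensityMatrix, annotation: SampleTable,
                        group: str, alpha: float = 0.05,
                        fd_threshold: float = 2.0, n_iter: int = 500,
                        seed: int | None = None,
                        fit_condition: Condition | None = None) -> pd.DataFrame:
    """Convenience wrapper: male-vs-female differential table within one group."""
    model = PLGEM(matrix, annotation)
    res = model.fit(fit_condition)
    cells = annotation.cell_members()
    avail = set(matrix.sample_ids)
    sizes = tuple(len([s for s in cells.get((group, sx), []) if s in avail])
                  for sx in ("M", "F"))
    res.resample_null(n_iter=n_iter, seed=seed, contrast_sizes=sizes)
    return res.differential(((group, "M"), (group, "F")), alpha=alpha,
                            fd_threshold=fd_threshold)
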