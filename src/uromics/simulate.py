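"""Synthetic urinary proteome + volatilome generator with planted ground truth.

Emulates the structure of a mouse-urine study: three groups (lab-bred DOM
and MUS, wild-derived wMUS) x two sexes of specimens plus air blanks for
the volatile layer.  The generator plants, and records in a
:class:`SimTruth`, every effect the downstream stages are supposed to
recover:

* a two-component structure in the per-feature log2 fold-difference of
  specimens vs blanks (blank-overlap component near 0, biological
  component well above it), driving the mixture filter;
* power-law mean-SD noise in the protein layer (SD = e^intercept * mean^slope),
  driving the error-model fit;
* sex-biased features with a planted fold difference, asymmetric across
  layers (more male-biased volatiles, more female-biased proteins);
* correlated protein-volatile "carrier-ligand" pairs;
* zero-inflation of low intensities (below-detection dropout).

Planted sex effects carry a *group scope*: a feature may be biased in all
three groups, only in the two M. m. musculus groups (MUS + wMUS), or only
in DOM.  This reproduces the empirical pattern that importance rankings
correlate strongly between genetically similar groups and weakly between
subspecies.
"""
from __future__ import annotations

from dataclasses import dataclass, field, asdict
import math

import numpy as np
import pandas as pd

from .data import IntensityMatrix, SampleTable
from .errors import ParameterError

GROUPS = ("DOM", "MUS", "wMUS")
SEXES = ("M", "F")

#: proportions of planted sex effects scoped to (all groups, MUS+wMUS, DOM only)
SCOPE_PROPORTIONS = {("DOM", "MUS", "wMUS"): 0.3, ("MUS", "wMUS"): 0.4, ("DOM",): 0.3}


@dataclass
class SimConfig:
    """Generator parameters; defaults mirror the study scale."""

    n_per_cell: int = 9            # specimens per group x sex cell
    n_blanks: int = 6              # air-blank columns (volatile layer only)
    n_volatiles: int = 1200
    n_proteins: int = 500
    blank_fraction: float = 0.4    # proportion of volatiles that are blank-overlap
    # log2 fold-difference-to-blank mixture: (lambda, mu_blank, sd_blank, mu_bio, sd_bio)
    mix_params: tuple = (0.4, 0.0, 1.0, 6.0, 1.0)
    sexbias_volatiles_male: int = 60
    sexbias_volatiles_female: int = 15
    sexbias_proteins_male: int = 10
    sexbias_proteins_female: int = 45
    effect_fd: float = 4.0         # planted fold difference (>2)
    plgem_slope: float = 0.75      # power-law exponent of SD on mean
    # ln-scale offset; gives ~20% CV at the median planted abundance (5e4)
    plgem_intercept: float = math.log(3.0)
    replicate_sigma: float = 0.5   # log2 SD of volatile within-feature sample noise
    n_pairs: int = 10              # planted carrier-ligand correlated pairs
    pair_r: float = 0.8
    dropout_rate: float = 0.3     # P(zero) for values below the dropout quantile
    dropout_quantile: float = 0.2
    group_shift: float = 1.0      # optional multiplicative environment shift for wMUS
    seed: int = 0

    def validate(self) -> None:
        counts = (self.n_per_cell, self.n_blanks, self.n_volatiles,
                  self.n_proteins, self.n_pairs,
                  self.sexbias_volatiles_male, self.sexbias_volatiles_female,
                  self.sexbias_proteins_male, self.sexbias_proteins_female)
        if any(c < 0 for c in counts):
            raise ParameterError("all counts must be >= 0")
        if not (0 <= self.dropout_rate < 1):
            raise ParameterError("dropout_rate must be in [0, 1)")
        if not (0 <= self.blank_fraction <= 1):
            raise ParameterError("blank_fraction must be in [0, 1]")
        lam, mu1, s1, mu2, s2 = self.mix_params
        if s1 <= 0 or s2 <= 0:
            raise ParameterError("mixture sigmas must be > 0")
        if not (0 <= lam <= 1):
            raise ParameterError("mixture weight must be in [0, 1]")
        n_bio = self.n_volatiles - int(round(self.blank_fraction * self.n_volatiles))
        if self.sexbias_volatiles_male + self.sexbias_volatiles_female + 2 * self.n_pairs > n_bio:
            raise ParameterError("planted volatile effects exceed biological volatiles")
        if self.sexbias_proteins_male + self.sexbias_proteins_female + self.n_pairs > self.n_proteins:
            raise ParameterError("planted protein effects exceed n_proteins")


@dataclass
class SimTruth:
    """Planted ground truth emitted alongside the matrices."""

    blank_origin_ids: set = field(default_factory=set)
    bio_ids: set = field(default_factory=set)
    # feature id -> (omics_kind, favored sex, true FD, groups where planted)
    sexbiased: dict = field(default_factory=dict)
    pairs: list = field(default_factory=list)   # (protein id, volatile id, target r)
    mixture: tuple = ()

    def sexbiased_in_group(self, group: str, kind: str | None = None) -> dict:
        """Planted sex effects active in ``group`` (optionally one layer)."""
        out = {}
        for fid, (k, sex, fd, groups) in self.sexbiased.items():
            if group in groups and (kind is None or k == kind):
                out[fid] = (k, sex, fd, groups)
        return out


def _sample_columns(cfg: SimConfig) -> SampleTable:
    rows = []
    for g in GROUPS:
        for s in SEXES:
            for i in range(cfg.n_per_cell):
                sid = f"{g}_{s}{i + 1:02d}"
                rows.append((sid, g, s, "specimen", f"ind_{sid}"))
    for b in range(cfg.n_blanks):
        rows.append((f"BLANK{b + 1:02d}", "blank", "NA", "blank", f"blank_{b + 1}"))
    return SampleTable(pd.DataFrame(rows, columns=SampleTable.COLUMNS))


def _assign_scopes(rng: np.random.Generator, n: int) -> list[tuple]:
    scopes = list(SCOPE_PROPORTIONS)
    probs = np.array([SCOPE_PROPORTIONS[s] for s in scopes])
    idx = rng.choice(len(scopes), size=n, p=probs / probs.sum())
    return [scopes[i] for i in idx]


def simulate_dataset(config: SimConfig):
    """Generate (protein matrix, volatile matrix, annotation, truth).

    Identical config (including seed) yields identical output.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    ann = _sample_columns(cfg)
    spec_ids = ann.specimen_ids()
    blank_ids = ann.blanks()
    sex = ann.labels_for(spec_ids, "sex")
    grp = ann.labels_for(spec_ids, "group")
    n_spec = len(spec_ids)

    truth = SimTruth(mixture=tuple(cfg.mix_params))
    lam, mu_bl, sd_bl, mu_bio, sd_bio = cfg.mix_params

    # ---------- volatile layer -------------------------------------------
    n_blank_feats = int(round(cfg.blank_fraction * cfg.n_volatiles))
    n_bio_feats = cfg.n_volatiles - n_blank_feats
    vol_ids = [f"V{i + 1:04d}" for i in range(cfg.n_volatiles)]
    is_blank_feat = np.zeros(cfg.n_volatiles, bool)
    is_blank_feat[:n_blank_feats] = True
    truth.blank_origin_ids = {vol_ids[i] for i in range(cfg.n_volatiles) if is_blank_feat[i]}
    truth.bio_ids = {vol_ids[i] for i in range(cfg.n_volatiles) if not is_blank_feat[i]}

    # blank-side mean intensity per feature (log2 scale), and the planted
    # specimen-vs-blank log2 fold difference drawn from the mixture component
    blank_log2 = rng.normal(14.0, 2.0, cfg.n_volatiles)
    delta = np.where(is_blank_feat,
                     rng.normal(mu_bl, sd_bl, cfg.n_volatiles),
                     rng.normal(mu_bio, sd_bio, cfg.n_volatiles))
    spec_log2 = blank_log2 + delta

    # per-sample replicate noise (log2) around the feature mean
    V = np.empty((cfg.n_volatiles, n_spec + cfg.n_blanks))
    V[:, :n_spec] = spec_log2[:, None] + rng.normal(
        0.0, cfg.replicate_sigma, (cfg.n_volatiles, n_spec))
    V[:, n_spec:] = blank_log2[:, None] + rng.normal(
        0.0, cfg.replicate_sigma, (cfg.n_volatiles, cfg.n_blanks))

    # planted sex effects among biological volatiles
    bio_idx = np.flatnonzero(~is_blank_feat)
    order = rng.permutation(bio_idx)
    n_m, n_f = cfg.sexbias_volatiles_male, cfg.sexbias_volatiles_female
    male_feats = order[:n_m]
    female_feats = order[n_m:n_m + n_f]
    pair_vol_feats = order[n_m + n_f:n_m + n_f + cfg.n_pairs]
    # mean-preserving sex effect: favored sex up, other down, ratio = effect_fd;
    # the pooled specimen mean (hence the fold-difference to blanks) is unchanged
    up = math.log2(2.0 * cfg.effect_fd / (1.0 + cfg.effect_fd))
    down = math.log2(2.0 / (1.0 + cfg.effect_fd))
    for feats, fav in ((male_feats, "M"), (female_feats, "F")):
        scopes = _assign_scopes(rng, len(feats))
        for j, fi in enumerate(feats):
            in_scope = np.isin(grp, scopes[j])
            favored = in_scope & (sex == fav)
            other = in_scope & (sex != fav)
            V[fi, :n_spec][favored] += up
            V[fi, :n_spec][other] += down
            truth.sexbiased[vol_ids[fi]] = ("volatile", fav, cfg.effect_fd, scopes[j])

    # optional environment shift for the wild-derived group
    if cfg.group_shift != 1.0:
        V[:, :n_spec][:, grp == "wMUS"] += math.log2(cfg.group_shift)

    # ---------- protein layer --------------------------------------------
    prot_names = [f"PROT{i + 1:04d}" for i in range(cfg.n_proteins)]
    prot_mean = np.exp(rng.normal(math.log(5e4), 1.2, cfg.n_proteins))
    order_p = rng.permutation(cfg.n_proteins)
    p_male = order_p[:cfg.sexbias_proteins_male]
    p_female = order_p[cfg.sexbias_proteins_male:
                       cfg.sexbias_proteins_male + cfg.sexbias_proteins_female]
    # carrier proteins are abundant; plant pairs clear of the dropout tail so
    # the planted correlation survives in the emitted matrix
    remaining = order_p[cfg.sexbias_proteins_male + cfg.sexbias_proteins_female:]
    floor = np.quantile(prot_mean, min(cfg.dropout_quantile + 0.15, 0.9))
    eligible = remaining[prot_mean[remaining] >= floor]
    if eligible.size < cfg.n_pairs:
        raise ParameterError("not enough abundant proteins free of planted "
                             "sex effects to host carrier-ligand pairs")
    pair_prot_feats = eligible[:cfg.n_pairs]

    # per-sample target mean, then power-law noise on the linear scale
    P_mean = np.tile(prot_mean[:, None], (1, n_spec))
    up_f = 2.0 * cfg.effect_fd / (1.0 + cfg.effect_fd)
    down_f = 2.0 / (1.0 + cfg.effect_fd)
    for feats, fav in ((p_male, "M"), (p_female, "F")):
        scopes = _assign_scopes(rng, len(feats))
        for j, fi in enumerate(feats):
            in_scope = np.isin(grp, scopes[j])
            P_mean[fi, in_scope & (sex == fav)] *= up_f
            P_mean[fi, in_scope & (sex != fav)] *= down_f
            truth.sexbiased[prot_names[fi]] = ("protein", fav, cfg.effect_fd, scopes[j])
    if cfg.group_shift != 1.0:
        P_mean[:, grp == "wMUS"] *= cfg.group_shift

    sd = math.exp(cfg.plgem_intercept) * P_mean ** cfg.plgem_slope
    P = P_mean + rng.normal(0.0, 1.0, P_mean.shape) * sd
    P = np.clip(P, 0.0, None)   # power-law noise can stray below zero at low means

    # ---------- carrier-ligand pairs -------------------------------------
    # shared latent per specimen; loading a with a^2 = pair_r gives Pearson
    # ~ pair_r between the two profiles.  Each member keeps its layer's own
    # noise scale (the volatile log2 replicate sigma, the protein power-law
    # SD) so pair features are indistinguishable from the rest marginally.
    a = math.sqrt(cfg.pair_r)
    b = math.sqrt(1.0 - cfg.pair_r)
    for k in range(cfg.n_pairs):
        z = rng.normal(0.0, 1.0, n_spec)
        e1 = rng.normal(0.0, 1.0, n_spec)
        e2 = rng.normal(0.0, 1.0, n_spec)
        vi = pair_vol_feats[k]
        pi = pair_prot_feats[k]
        V[vi, :n_spec] = spec_log2[vi] + cfg.replicate_sigma * (a * z + b * e1)
        P[pi, :] = P_mean[pi, :] + sd[pi, :] * (a * z + b * e2)
        truth.pairs.append((prot_names[pi], vol_ids[vi], cfg.pair_r))
    P = np.clip(P, 0.0, None)

    # ---------- assemble, dropout ----------------------------------------
    # below-detection dropout is applied at the feature level: features in
    # the lowest dropout_quantile of median intensity get every cell zeroed
    # independently with dropout_rate.  Zeroing specimen and blank cells of
    # a feature at the same rate leaves its specimen/blank mean ratio (the
    # mixture statistic) unbiased while still creating presence/absence
    # patterns for the prevalence filter.
    vol_values = np.exp2(V)
    for values in (vol_values, P):
        if cfg.dropout_rate > 0 and values.size:
            med = np.median(values, axis=1)
            thr = np.quantile(med, cfg.dropout_quantile)
            low_feats = med < thr
            drop = rng.random(values.shape) < cfg.dropout_rate
            values[low_feats[:, None] & drop] = 0.0

    volatile = IntensityMatrix(vol_values, vol_ids, spec_ids + blank_ids, "volatile")
    protein = IntensityMatrix(P, prot_names, spec_ids, "protein")
    return protein, volatile, ann, truth


def truth_report(truth: SimTruth) -> pd.DataFrame:
    """One machine-readable row per planted effect."""
    rows = []
    for fid, (kind, fav, fd, groups) in sorted(truth.sexbiased.items()):
        rows.append({"effect": "sex_bias", "feature_a": fid, "feature_b": "",
                     "layer": kind, "favored_sex": fav, "value": fd,
                     "groups": "+".join(groups)})
    for prot, vol, r in truth.pairs:
        rows.append({"effect": "pair", "feature_a": prot, "feature_b": vol,
                     "layer": "protein-volatile", "favored_sex": "", "value": r,
                     "groups": "+".join(GROUPS)})
    cols = ["effect", "feature_a", "feature_b", "layer", "favored_sex", "value", "groups"]
    return pd.DataFrame(rows, columns=cols)


def config_to_dict(cfg: SimConfig) -> dict:
    d = asdict(cfg)
    d["mix_params"] = list(d["mix_params"])
    return d
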