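"""Sex-bias asymmetry across omics layers and groups.

Counts significant male- and female-biased features per layer, tests the
2x2 bias-direction x layer table with Fisher's exact test (two-sided,
"probability mass <= observed" rule), and computes exclusive (UpSet-style)
intersections of biased feature sets across groups.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


@dataclass
class ContingencyResult:
    """2x2 exact-test outcome: rows M/F-biased, columns volatiles/proteins."""

    table: np.ndarray
    odds_ratio: float
    p: float
    degenerate_margin: bool = False   # a zero margin forces p = 1 by convention

    def summary(self) -> str:
        t = self.table
        return ("bias x layer contingency (volatiles, proteins)\n"
                f"  male-biased    {t[0, 0]:6d} {t[0, 1]:6d}\n"
                f"  female-biased  {t[1, 0]:6d} {t[1, 1]:6d}\n"
                f"  odds ratio {self.odds_ratio:.4g}   two-sided p {self.p:.4g}")


def bias_counts(diff_volatiles: pd.DataFrame,
                diff_proteins: pd.DataFrame) -> np.ndarray:
    """Tally significant biased features into the 2x2 table.

    Rows: male-biased, female-biased; columns: volatiles, proteins.
    """
    table = np.zeros((2, 2), dtype=int)
    for j, diff in enumerate((diff_volatiles, diff_proteins)):
        sig = diff[diff["significant"]]
        table[0, j] = int((sig["direction"] == "male_biased").sum())
        table[1, j] = int((sig["direction"] == "female_biased").sum())
    return table


def fisher_exact(table) -> ContingencyResult:
    """Two-sided Fisher's exact test on a 2x2 count table.

    The two-sided p sums hypergeometric probabilities of all tables with the
    observed margins whose probability does not exceed the observed table's.
    A zero margin leaves nothing to test: p = 1 by convention, flagged.
    The odds ratio is the cross-product, with a 0.5 continuity correction
    applied to every cell when any cell is 0.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ParameterError("table must be 2x2")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ParameterError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t < 0).any():
        raise ParameterError("table entries must be nonnegative")

    margins = [t[0].sum(), t[1].sum(), t[:, 0].sum(), t[:, 1].sum()]
    if 0 in margins:
        odds = _odds_ratio(t)
        return ContingencyResult(table=t, odds_ratio=odds, p=1.0,
                                 degenerate_margin=True)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return ContingencyResult(table=t, odds_ratio=_odds_ratio(t), p=float(p))


def _odds_ratio(t: np.ndarray) -> float:
    t = t.astype(float)
    if (t == 0).any():
        t = t + 0.5
    return float(t[0, 0] * t[1, 1] / (t[0, 1] * t[1, 0]))


def intersections(biased_sets: dict[str, set]) -> pd.DataFrame:
    """Exclusive (UpSet-semantics) intersection counts across groups.

    For every non-empty subset of groups, counts the features that belong
    to exactly those groups' sets.  Counts partition the union.
    Returns a long-format frame with columns ``subset`` ("+"-joined group
    names, sorted), ``count`` and ``features`` (";"-joined ids).
    """
    if len(biased_sets) < 2:
        raise ParameterError("intersections need >= 2 groups")
    groups = sorted(biased_sets)
    membership: dict[str, frozenset] = {}
    for fid in set().union(*biased_sets.values()):
        membership[fid] = frozenset(g for g in groups if fid in biased_sets[g])
    rows = []
    for r in range(1, len(groups) + 1):
        for combo in combinations(groups, r):
            key = frozenset(combo)
            members = sorted(f for f, m in membership.items() if m == key)
            rows.append({"subset": "+".join(combo), "count": len(members),
                         "features": ";".join(members)})
    return pd.DataFrame(rows, columns=["subset", "count", "features"])


def biased_ids(diff: pd.DataFrame, direction: str | None = None) -> set:
    """Significant feature ids from a differential table, optionally one side."""
    sig = diff[diff["significant"]]
    if direction is not None:
        sig = sig[sig["direction"] == direction]
    return set(sig["feature_id"])
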