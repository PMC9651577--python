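"""Comparative statistics across clans, host groups and collections.

Per (clan, collection) cell this module tabulates the frequency of each
C-strain metric (C_Host, C_COI, C_Tpi), and provides the inferential tests
used to compare groups of per-collection values: pooled-variance two-tailed
t-tests, 2xK Pearson chi-square homogeneity tests of trait-positive counts
across collections, and ordinary one-way ANOVA with a Tukey HSD post-test
summarised as compact significance letters.

The chi-square test is built from raw positive counts (not percentages); its
2xK table has one row per trait and one column per collection, giving
df = K - 1.
"""

from __future__ import annotations

import itertools
import string
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "frequency_table",
    "chi_square_homogeneity",
    "pooled_t_test",
    "one_way_anova",
    "TRAITS",
]

#: trait column -> positive value
TRAITS = {
    "C_Host": ("host_category", "C_Host"),
    "C_COI": ("coi_strain", "C_COI"),
    "C_Tpi": ("tpi_strain", "C_Tpi"),
}


def frequency_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per (clan, collection) frequency of each C-strain metric.

    Excluded specimens are dropped.  For each trait the denominator is the
    number of specimens in the cell whose trait value is known.  Returns a
    tidy frame with columns clan, collection, trait, numerator, denominator,
    pct (NaN for empty cells, which are excluded from the per-curve means).
    """
    df = table[~table["excluded"].astype(bool)]
    rows = []
    for (clan, collection), cell in df.groupby(["clan", "collection"],
                                               sort=True):
        for trait, (col, positive) in TRAITS.items():
            known = cell[~cell[col].isin(["unknown", "ambiguous", ""])]
            den = len(known)
            num = int((known[col] == positive).sum())
            rows.append(
                {
                    "clan": clan,
                    "collection": collection,
                    "trait": trait,
                    "numerator": num,
                    "denominator": den,
                    "pct": 100.0 * num / den if den else float("nan"),
                }
            )
    out = pd.DataFrame(rows)
    return out


def curve_means(freq: pd.DataFrame) -> pd.DataFrame:
    """Mean +/- SD of each (clan, trait) frequency curve across collections."""
    valid = freq.dropna(subset=["pct"])
    g = valid.groupby(["clan", "trait"])["pct"]
    return g.agg(mean="mean", sd=lambda x: x.std(ddof=1)).reset_index()


def chi_square_homogeneity(
    counts_a: Sequence[tuple[int, int]],
    counts_b: Sequence[tuple[int, int]],
) -> tuple[float, int, float, bool]:
    """Pearson chi-square comparing two traits' positive counts across collections.

    ``counts_a``/``counts_b`` give (numerator, denominator) per collection for
    each trait; the test is run on the 2xK table of positive counts, without
    continuity correction, df = K - 1.  Returns (chi2, df, p, low_expected)
    where ``low_expected`` warns that some expected cell is < 1.
    """
    if len(counts_a) != len(counts_b) or len(counts_a) < 2:
        raise ValueError("need matched counts for >= 2 collections")
    obs = np.array([[num for num, _ in counts_a],
                    [num for num, _ in counts_b]], dtype=float)
    if np.any(obs < 0):
        raise ValueError("counts must be non-negative")
    df_full = obs.shape[1] - 1
    # collections where neither trait was observed contribute nothing
    obs = obs[:, obs.sum(axis=0) > 0]
    if obs.shape[1] < 2 or np.any(obs.sum(axis=1) == 0):
        # a trait with zero positives everywhere leaves the test undefined
        return float("nan"), df_full, float("nan"), True
    chi2, p, df, expected = stats.chi2_contingency(obs, correction=False)
    return float(chi2), int(df), float(p), bool(np.any(expected < 1.0))


def pooled_t_test(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, int, float]:
    """Two-tailed Student's t-test with pooled variance.

    Returns (t, df, p) with df = nA + nB - 2.  With zero pooled variance the
    statistic is 0 when the means coincide and +/-inf (p = 0) otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 values")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return float(np.sign(a.mean() - b.mean()) * np.inf), df, 0.0
    res = stats.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), df, float(res.pvalue)


def _letters_from_pairs(
    k: int, significant: set[tuple[int, int]], order: Sequence[int]
) -> list[str]:
    """Compact letter display: groups share a letter iff not significantly
    different.  ``order`` lists group indices sorted by mean (insert-and-
    absorb over that ordering)."""
    letter_sets: list[set[int]] = []
    for g in order:
        placed = False
        for s in letter_sets:
            if all((min(g, h), max(g, h)) not in significant for h in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # absorb redundant sets
    letter_sets = [
        s for i, s in enumerate(letter_sets)
        if not any(s < t for j, t in enumerate(letter_sets) if i != j)
    ]
    labels = [""] * k
    for s, letter in zip(letter_sets, string.ascii_lowercase):
        for g in s:
            labels[g] += letter
    return ["".join(sorted(l)) for l in labels]


@dataclass(frozen=True)
class AnovaResult:
    f: float
    r2: float
    p: float
    df_between: int
    df_within: int
    letters: list[str]            # Tukey HSD compact letters, alpha = 0.05
    degenerate: bool              # all values identical


def one_way_anova(
    groups: Sequence[Sequence[float]], alpha: float = 0.05
) -> AnovaResult:
    """Ordinary one-way ANOVA with a Tukey HSD post-test.

    Returns the F statistic, r^2 = SS_between / SS_total, the p-value and
    per-group significance letters (groups sharing a letter are not
    significantly different at ``alpha``).  With zero total variance the
    result is flagged degenerate (F = 0, letters all 'a').
    """
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(len(g) < 2 for g in gs):
        raise ValueError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(gs)
    grand = allv.mean()
    ss_total = float(np.sum((allv - grand) ** 2))
    ss_between = float(sum(len(g) * (g.mean() - grand) ** 2 for g in gs))
    df_b = len(gs) - 1
    df_w = len(allv) - len(gs)
    if ss_total == 0.0:
        return AnovaResult(0.0, 0.0, 1.0, df_b, df_w,
                           ["a"] * len(gs), degenerate=True)
    f_res = stats.f_oneway(*gs)
    r2 = ss_between / ss_total

    order = sorted(range(len(gs)), key=lambda i: gs[i].mean())
    significant: set[tuple[int, int]] = set()
    ss_within = ss_total - ss_between
    if ss_within > 0:
        tk = stats.tukey_hsd(*gs)
        for i, j in itertools.combinations(range(len(gs)), 2):
            if tk.pvalue[i, j] < alpha:
                significant.add((i, j))
    else:
        # no within-group variance: any mean difference is significant
        for i, j in itertools.combinations(range(len(gs)), 2):
            if gs[i].mean() != gs[j].mean():
                significant.add((i, j))
    letters = _letters_from_pairs(len(gs), significant, order)
    return AnovaResult(float(f_res.statistic), r2, float(f_res.pvalue),
                       df_b, df_w, letters, degenerate=False)
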