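"""Within- and between-population sequence statistics.

Implements, from first principles on an aligned sample of n sequences over L
used sites:

* segregating sites S and singleton sites eta_s (sites whose rarest allele
  occurs in exactly one sequence);
* mean pairwise differences k_bar and nucleotide diversity pi = k_bar / L;
* haplotype diversity Hd = n/(n-1) * (1 - sum p_h^2) (Nei's sample-size
  corrected form) over haplotype frequencies p_h;
* Tajima's D, contrasting k_bar with S / a1;
* Fu & Li's F* (no outgroup), contrasting k_bar with the singleton count,
  using the corrected variance constants (the originally published constants
  contain a known misprint; both variants are available and cross-checked);
* the Hudson/Slatkin/Maddison sequence-based F_ST = 1 - Hw/Hb, where Hw is
  the average of the two populations' mean pairwise differences and Hb the
  mean difference between populations.

Sites carrying a gap or ambiguity code in any sequence of the sample are
dropped before anything is counted (complete deletion, shared with the
distance module), so S, pi, D and F* all refer to the same site set.
Multi-allelic sites count once in S, and any mismatch counts 1 pairwise
difference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .distances import encode_alignment
from .io import AlignedSequenceSet

__all__ = [
    "DiversityStats",
    "NeutralityStats",
    "FstResult",
    "diversity",
    "tajimas_d",
    "fu_li_f_star",
    "fst_pair",
    "fst_matrix",
    "tajima_constants",
    "fu_li_f_star_constants",
]

DeletionRule = Literal["complete", "pairwise"]
FStarVariant = Literal["corrected", "original"]


@dataclass(frozen=True)
class DiversityStats:
    n: int            # sequences used
    L: int            # sites used after deletion
    S: int            # segregating sites
    eta_s: int        # singleton sites
    k_bar: float      # mean pairwise differences
    pi: float         # k_bar / L
    hd: float         # haplotype diversity
    n_haplotypes: int


@dataclass(frozen=True)
class NeutralityStats:
    statistic: str                     # "tajimas_d" | "fu_li_f_star"
    value: float                       # nan when undefined
    status: Literal["ok", "undefined_S0"]
    n: int
    S: int
    eta_s: int
    k_bar: float
    constants: dict


@dataclass(frozen=True)
class FstResult:
    hw: float          # mean within-population pairwise differences
    hb: float          # mean between-population pairwise differences
    fst: float         # 1 - Hw/Hb (0 by convention when Hb == 0)
    n_a: int
    n_b: int
    degenerate: bool = False


def _used_columns(arr: np.ndarray) -> np.ndarray:
    """Complete deletion: keep columns where every sequence is unambiguous."""
    return arr[:, np.all(arr < 4, axis=0)]


def _site_counts(arr: np.ndarray) -> tuple[int, int, float]:
    """(S, eta_s, k_bar) for an encoded, already-filtered (n, L) array."""
    n = arr.shape[0]
    S = 0
    eta = 0
    k_sum = 0.0
    for col in arr.T:
        counts = np.bincount(col, minlength=4)
        alleles = counts[counts > 0]
        if len(alleles) < 2:
            continue
        S += 1
        if alleles.min() == 1:
            eta += 1
        # pairwise differences contributed by this site: C(n,2) - sum C(c,2)
        k_sum += n * (n - 1) / 2 - float(np.sum(alleles * (alleles - 1) / 2))
    k_bar = k_sum / (n * (n - 1) / 2)
    return S, eta, k_bar


def _prepare(seqs: AlignedSequenceSet) -> np.ndarray:
    arr = encode_alignment(seqs)
    used = _used_columns(arr)
    return used


def diversity(seqs: AlignedSequenceSet) -> DiversityStats:
    """Diversity summary of one population sample.

    Haplotype grouping is done on the deletion-filtered sequences, so Hd is
    consistent with S and pi (two sequences differing only at an excluded
    site share a haplotype here).
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    used = _prepare(seqs)
    L = used.shape[1]
    if L == 0:
        raise ValueError("no sites left after deletion of gapped/ambiguous columns")
    S, eta, k_bar = _site_counts(used)

    _, counts = np.unique(used, axis=0, return_counts=True)
    p = counts / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p * p)))

    return DiversityStats(
        n=n, L=L, S=S, eta_s=eta, k_bar=k_bar, pi=k_bar / L,
        hd=hd, n_haplotypes=len(counts),
    )


def tajima_constants(n: int) -> dict:
    """The standard a1..e2 constants of Tajima's D for sample size n."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(seqs: AlignedSequenceSet) -> NeutralityStats:
    """Tajima's D; ``status == "undefined_S0"`` (value NaN) when S = 0."""
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    used = _prepare(seqs)
    S, eta, k_bar = _site_counts(used)
    consts = tajima_constants(n)
    if S == 0:
        return NeutralityStats("tajimas_d", float("nan"), "undefined_S0",
                               n, S, eta, k_bar, consts)
    var = consts["e1"] * S + consts["e2"] * S * (S - 1)
    d = (k_bar - S / consts["a1"]) / math.sqrt(var)
    return NeutralityStats("tajimas_d", d, "ok", n, S, eta, k_bar, consts)


def fu_li_f_star_constants(n: int, variant: FStarVariant = "corrected") -> dict:
    """Variance constants u_F*, v_F* of Fu & Li's F* for sample size n.

    ``corrected`` uses the widely adopted corrected constants (the standard
    in sequence-analysis software); ``original`` evaluates the constants as
    first printed, retained for cross-checking.
    """
    a = sum(1.0 / i for i in range(1, n))
    b = sum(1.0 / i**2 for i in range(1, n))
    a1 = a + 1.0 / n      # harmonic number over 1..n
    v = (
        (2.0 * n**3 + 110.0 * n**2 - 255.0 * n + 153.0) / (9.0 * n**2 * (n - 1))
        + 2.0 * (n - 1) * a / n**2
        - 8.0 * b / n
    ) / (a * a + b)
    if variant == "corrected":
        u = (
            n / (n - 1.0)
            + (n + 1.0) / (3.0 * (n - 1.0))
            - 4.0 / (n * (n - 1.0))
            + 2.0 * (n + 1.0) / (n - 1.0) ** 2 * (a1 - 2.0 * n / (n + 1.0))
        ) / a - v
    elif variant == "original":
        u = ((4.0 * n**2 + 19.0 * n + 3.0 - 12.0 * (n + 1.0) * a1)
             / (3.0 * n * (n - 1.0))) / a - v
    else:
        raise ValueError(f"unknown F* variant {variant!r}")
    return {"a_n": a, "b_n": b, "a_n1": a1, "u_f": u, "v_f": v,
            "variant": variant}


def fu_li_f_star(
    seqs: AlignedSequenceSet, variant: FStarVariant = "corrected"
) -> NeutralityStats:
    """Fu & Li's F* without outgroup.

    F* = (k_bar - eta_s (n-1)/n) / sqrt(u_F* S + v_F* S^2).  Singletons are
    counted as sites whose rarest allele occurs exactly once (orientation is
    unknowable without an outgroup).  Negative values indicate an excess of
    singletons.  ``status == "undefined_S0"`` when S = 0.
    """
    n = len(seqs)
    if n < 2:
        raise ValueError("need at least 2 sequences")
    used = _prepare(seqs)
    S, eta, k_bar = _site_counts(used)
    consts = fu_li_f_star_constants(n, variant)
    if S == 0:
        return NeutralityStats("fu_li_f_star", float("nan"), "undefined_S0",
                               n, S, eta, k_bar, consts)
    var = consts["u_f"] * S + consts["v_f"] * S * S
    f = (k_bar - eta * (n - 1.0) / n) / math.sqrt(var)
    return NeutralityStats("fu_li_f_star", f, "ok", n, S, eta, k_bar, consts)


def _mean_pairwise(arr: np.ndarray) -> float:
    n = arr.shape[0]
    total = 0
    for i in range(n):
        total += int(np.sum(arr[i + 1:] != arr[i]))
    return total / (n * (n - 1) / 2)


def _mean_between(a: np.ndarray, b: np.ndarray) -> float:
    total = 0
    for i in range(a.shape[0]):
        total += int(np.sum(b != a[i]))
    return total / (a.shape[0] * b.shape[0])


def fst_pair(pop_a: AlignedSequenceSet, pop_b: AlignedSequenceSet) -> FstResult:
    """Sequence-based F_ST = 1 - Hw/Hb between two population samples.

    Hw is the unweighted average of the two within-population mean pairwise
    difference counts; Hb the mean over all between-population pairs.  Sites
    with a gap/ambiguity in *either* sample are excluded so both samples are
    scored on the same columns.  When Hb = 0 (no variation anywhere) the
    value is 0 by convention and flagged degenerate.
    """
    if len(pop_a) < 2 or len(pop_b) < 2:
        raise ValueError("each population needs at least 2 sequences")
    overlap = set(pop_a.ids) & set(pop_b.ids)
    if overlap:
        raise ValueError(f"populations share specimen ids: {sorted(overlap)}")
    merged = AlignedSequenceSet({**pop_a.records, **pop_b.records})
    arr = _used_columns(encode_alignment(merged))
    na = len(pop_a)
    a, b = arr[:na], arr[na:]
    hw = 0.5 * (_mean_pairwise(a) + _mean_pairwise(b))
    hb = _mean_between(a, b)
    if hb == 0.0:
        return FstResult(hw=hw, hb=hb, fst=0.0, n_a=na, n_b=len(pop_b),
                         degenerate=True)
    return FstResult(hw=hw, hb=hb, fst=1.0 - hw / hb, n_a=na, n_b=len(pop_b))


def fst_matrix(groups: Mapping[str, AlignedSequenceSet]):
    """Pairwise F_ST for every unordered pair of labelled groups.

    Returns ``(labels, matrix)`` where the matrix is symmetric with zero
    diagonal (NaN where a group has < 2 sequences).
    """
    labels = list(groups)
    k = len(labels)
    m = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r = fst_pair(groups[labels[i]], groups[labels[j]])
                m[i, j] = m[j, i] = r.fst
            except ValueError:
                m[i, j] = m[j, i] = float("nan")
    return labels, m
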