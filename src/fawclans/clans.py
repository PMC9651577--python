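"""Algorithmic delimitation of the two host-strain clans on a rooted tree.

The study's two clusters ("ClanC" and "ClanR") were delimited by eye on a
midpoint-rooted NJ tree and were essentially pure for the Tpi diagnostic
allele.  Here that call is made operational: ClanC is the largest clade whose
C_Tpi frequency reaches a purity threshold (default 0.95, consistent with the
observed 100% and 98% clade compositions); everything else is ClanR.  Ties in
size are broken by higher purity, then by the lexicographically smallest leaf
id, so the partition is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import dendropy
import numpy as np

from .distances import encode_alignment
from .haplotypes import HaplotypeTable
from .io import AlignedSequenceSet

__all__ = ["ClanPartition", "find_marker_clade", "classify_new_sequence"]


@dataclass(frozen=True)
class ClanPartition:
    clanC_ids: frozenset[str]
    clanR_ids: frozenset[str]
    purity: float                 # C_Tpi fraction inside ClanC (nan if none)
    threshold: float
    found: bool                   # False when no clade met the threshold

    def clan_of(self, specimen_id: str) -> str:
        if specimen_id in self.clanC_ids:
            return "ClanC"
        if specimen_id in self.clanR_ids:
            return "ClanR"
        return "unassigned"


def find_marker_clade(
    tree: dendropy.Tree,
    marker_labels: Mapping[str, str],
    purity_threshold: float = 0.95,
) -> ClanPartition:
    """Partition the leaves of a rooted tree into ClanC and ClanR.

    ``marker_labels`` maps every leaf id to ``C_Tpi`` or ``R_Tpi`` (ambiguous
    specimens must have been excluded upstream).  Among all clades whose
    C_Tpi frequency >= ``purity_threshold`` the largest is ClanC; its
    complement is ClanR.  If no clade qualifies, ``found`` is False and every
    leaf goes to ClanR.
    """
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    missing = [l for l in leaves if l not in marker_labels]
    if missing:
        raise ValueError(f"leaves without marker label: {', '.join(missing)}")
    bad = {l: marker_labels[l] for l in leaves
           if marker_labels[l] not in ("C_Tpi", "R_Tpi")}
    if bad:
        raise ValueError(f"marker labels must be C_Tpi/R_Tpi, got {bad}")

    def better(new: tuple[int, float, str], old: tuple[int, float, str]) -> bool:
        # larger clade, then higher purity, then lowest leftmost leaf id
        if new[0] != old[0]:
            return new[0] > old[0]
        if new[1] != old[1]:
            return new[1] > old[1]
        return new[2] < old[2]

    best: tuple[int, float, str] | None = None   # (size, purity, min leaf id)
    best_set: frozenset[str] | None = None
    for node in tree.preorder_node_iter():
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        purity = sum(
            1 for l in clade if marker_labels[l] == "C_Tpi") / len(clade)
        if purity < purity_threshold:
            continue
        key = (len(clade), purity, min(clade))
        if best is None or better(key, best):
            best = key
            best_set = clade

    if best_set is None:
        return ClanPartition(
            clanC_ids=frozenset(),
            clanR_ids=frozenset(leaves),
            purity=float("nan"),
            threshold=purity_threshold,
            found=False,
        )
    return ClanPartition(
        clanC_ids=best_set,
        clanR_ids=frozenset(leaves) - best_set,
        purity=best[1],
        threshold=purity_threshold,
        found=True,
    )


def classify_new_sequence(
    seq: str,
    haplotypes: HaplotypeTable,
    clan_of_haplotype: Mapping[int, str],
) -> str:
    """Assign a new aligned sequence to a clan by nearest reference haplotype.

    An exact haplotype match decides directly; otherwise the nearest
    reference by mismatch count over mutually unambiguous sites wins.  A tie
    between clans returns ``unresolved``.
    """
    if not haplotypes.haplotypes:
        raise ValueError("empty reference haplotype table")
    refs = {
        h.haplotype_id: h.sequence for h in haplotypes.haplotypes
        if clan_of_haplotype.get(h.haplotype_id) in ("ClanC", "ClanR")
    }
    if not refs:
        raise ValueError("no clan-labelled haplotypes in reference table")
    lengths = {len(s) for s in refs.values()}
    if len(lengths) != 1 or len(seq) not in lengths:
        raise ValueError("query and reference sequences must share alignment length")

    for hid, ref in refs.items():
        if seq == ref:
            return clan_of_haplotype[hid]

    ids = list(refs)
    merged = AlignedSequenceSet(
        {"__query__": seq, **{f"h{h}": refs[h] for h in ids}})
    arr = encode_alignment(merged)
    q = arr[0]
    best_d = None
    best_clans: set[str] = set()
    for row, hid in zip(arr[1:], ids):
        ok = (q < 4) & (row < 4)
        d = int(np.sum(q[ok] != row[ok]))
        if best_d is None or d < best_d:
            best_d, best_clans = d, {clan_of_haplotype[hid]}
        elif d == best_d:
            best_clans.add(clan_of_haplotype[hid])
    if len(best_clans) == 1:
        return next(iter(best_clans))
    return "unresolved"
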