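"""Haplotype collapsing and haplotype-spectrum accounting.

A haplotype is a unique aligned sequence string; collapsing a sample to its
haplotypes is the first step of the analysis and the basis for the private /
shared haplotype accounting used to contrast the two host-strain clans (one
dominated by a single widespread haplotype, the other made up mostly of
haplotypes seen exactly once).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Mapping

from .io import AlignedSequenceSet

__all__ = [
    "Haplotype",
    "HaplotypeTable",
    "HaplotypeSummary",
    "collapse_haplotypes",
    "haplotype_summary",
    "write_haplotype_table",
]

GapPolicy = Literal["strict", "ignore-terminal-gaps"]


@dataclass(frozen=True)
class Haplotype:
    haplotype_id: int
    sequence: str          # canonical (first-seen) member sequence
    specimen_ids: tuple[str, ...]
    regions: frozenset[str]

    @property
    def count(self) -> int:
        return len(self.specimen_ids)


@dataclass(frozen=True)
class HaplotypeTable:
    """Unique sequences with their specimen membership and region spectrum.

    Haplotype ids are 1-based and deterministic: descending specimen count,
    ties broken by first appearance in the input.
    """

    haplotypes: tuple[Haplotype, ...]

    @property
    def n_haplotypes(self) -> int:
        return len(self.haplotypes)

    @property
    def n_specimens(self) -> int:
        return sum(h.count for h in self.haplotypes)

    @property
    def assignment(self) -> dict[str, int]:
        """specimen_id -> haplotype_id."""
        return {
            sid: h.haplotype_id for h in self.haplotypes for sid in h.specimen_ids
        }

    def by_id(self, haplotype_id: int) -> Haplotype:
        return self.haplotypes[haplotype_id - 1]


def _identity_key(seq: str, gap_policy: GapPolicy) -> str:
    if gap_policy == "ignore-terminal-gaps":
        return seq.strip("-")
    return seq


def collapse_haplotypes(
    seqs: AlignedSequenceSet,
    gap_policy: GapPolicy = "strict",
    regions: Mapping[str, str] | None = None,
) -> HaplotypeTable:
    """Group identical sequences into haplotypes.

    Under the default ``strict`` policy two sequences share a haplotype iff
    their aligned strings are byte-identical; ``ignore-terminal-gaps`` trims
    leading/trailing gap runs before comparison (internal gaps still count).

    ``regions`` optionally maps specimen id to a region label recorded in the
    table's per-haplotype region spectrum.
    """
    groups: dict[str, list[str]] = {}
    order: dict[str, int] = {}
    for sid, seq in seqs.records.items():
        key = _identity_key(seq, gap_policy)
        if key not in groups:
            groups[key] = []
            order[key] = len(order)
        groups[key].append(sid)

    ranked = sorted(groups, key=lambda k: (-len(groups[k]), order[k]))
    haplotypes = []
    for hid, key in enumerate(ranked, start=1):
        members = tuple(groups[key])
        regs = frozenset(
            regions[sid] for sid in members) if regions is not None else frozenset()
        haplotypes.append(
            Haplotype(
                haplotype_id=hid,
                sequence=seqs.records[members[0]],
                specimen_ids=members,
                regions=regs,
            )
        )
    return HaplotypeTable(tuple(haplotypes))


@dataclass(frozen=True)
class HaplotypeSummary:
    """Headline haplotype-spectrum numbers for a surveyed specimen set.

    A *private* haplotype occurs exactly once across the whole set; a
    haplotype is *shared in all regions* when it was observed in every
    distinct region present.  Percentages are rounded to the nearest integer
    (report convention); unrounded fractions are kept alongside.
    """

    n_specimens: int
    n_haplotypes: int
    n_regions: int
    n_private_haplotypes: int
    pct_private_haplotypes: int
    n_specimens_private: int
    pct_specimens_private: int
    n_specimens_on_shared_all_regions: int
    pct_shared_all_regions: int
    dominant_haplotype_pct: int
    frac_private_haplotypes: float
    frac_specimens_private: float
    frac_shared_all_regions: float
    dominant_haplotype_frac: float


def _pct(num: int, den: int) -> int:
    return int(round(100.0 * num / den)) if den else 0


def haplotype_summary(
    table: HaplotypeTable, regions: Mapping[str, str]
) -> HaplotypeSummary:
    """Summarise private/shared haplotype structure of a collapsed sample.

    ``regions`` must label every specimen in the table.
    """
    missing = [
        sid for h in table.haplotypes for sid in h.specimen_ids
        if sid not in regions
    ]
    if missing:
        raise ValueError(
            "specimens without a region label: " + ", ".join(missing)
        )
    all_regions = {regions[sid]
                   for h in table.haplotypes for sid in h.specimen_ids}
    n_spec = table.n_specimens
    n_hap = table.n_haplotypes

    private = [h for h in table.haplotypes if h.count == 1]
    hap_regions = {
        h.haplotype_id: {regions[sid] for sid in h.specimen_ids}
        for h in table.haplotypes
    }
    shared_all = [
        h for h in table.haplotypes if hap_regions[h.haplotype_id] == all_regions
    ]
    n_shared_spec = sum(h.count for h in shared_all)
    dominant = max(h.count for h in table.haplotypes)

    return HaplotypeSummary(
        n_specimens=n_spec,
        n_haplotypes=n_hap,
        n_regions=len(all_regions),
        n_private_haplotypes=len(private),
        pct_private_haplotypes=_pct(len(private), n_hap),
        n_specimens_private=len(private),
        pct_specimens_private=_pct(len(private), n_spec),
        n_specimens_on_shared_all_regions=n_shared_spec,
        pct_shared_all_regions=_pct(n_shared_spec, n_spec),
        dominant_haplotype_pct=_pct(dominant, n_spec),
        frac_private_haplotypes=len(private) / n_hap,
        frac_specimens_private=len(private) / n_spec,
        frac_shared_all_regions=n_shared_spec / n_spec if n_spec else 0.0,
        dominant_haplotype_frac=dominant / n_spec,
    )


def write_haplotype_table(table: HaplotypeTable, path: str | Path) -> None:
    """Emit the haplotype table as TSV (one row per haplotype)."""
    with open(path, "w") as fh:
        fh.write("haplotype_id\tcount\tregions\tspecimen_ids\tsequence\n")
        for h in table.haplotypes:
            fh.write(
                f"{h.haplotype_id}\t{h.count}\t"
                f"{','.join(sorted(h.regions))}\t"
                f"{','.join(h.specimen_ids)}\t{h.sequence}\n"
            )
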