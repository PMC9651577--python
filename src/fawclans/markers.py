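"""Diagnostic-SNP strain calling for the mitochondrial COI and Z-linked Tpi markers.

Two single-nucleotide markers are conventionally used to type fall armyworm
host strains: mCOI1164D in the mitochondrial COI gene (A or G = C-strain,
T = R-strain) and gTpi183Y in the fourth Tpi exon (a C/T polymorphism; the
'Y' in the marker name is the IUPAC code for C/T).  Tpi is Z-linked, so males
(ZZ) can be heterozygous; direct sequencing of a heterozygote yields a 'Y'
basecall, and such specimens are excluded from downstream clan and diversity
computations under the default policy.

Which of C/T denotes which strain at gTpi183Y is configurable: the default
(C -> C_Tpi, T -> R_Tpi) follows the marker naming convention but can be
overridden through :class:`MarkerDefinition.allele_map`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import pandas as pd

from .io import IUPAC_DNA, AlignedSequenceSet

__all__ = [
    "MarkerDefinition",
    "COI_MARKER",
    "TPI_MARKER",
    "call_coi_strain",
    "call_tpi_strain",
    "annotate_specimens",
]

AmbiguityPolicy = Literal["exclude", "unknown"]


@dataclass(frozen=True)
class MarkerDefinition:
    """A diagnostic SNP: a 1-based column in a named alignment plus allele map.

    ``allele_map`` maps single bases to strain labels ("C-strain"/"R-strain");
    bases not in the map call as unknown.  For the heterozygote-capable Tpi
    marker, a base equal to the IUPAC union of the two mapped alleles (e.g.
    'Y' for {C,T}) calls as ambiguous, and ``ambiguity_policy`` decides
    whether the specimen is excluded from downstream statistics.
    """

    name: str
    alignment: str                # key of the alignment the column refers to
    aligned_column: int           # 1-based, counting gap columns
    allele_map: Mapping[str, str]
    ambiguity_policy: AmbiguityPolicy = "exclude"

    def __post_init__(self) -> None:
        bad = set(self.allele_map.values()) - {"C-strain", "R-strain"}
        if bad:
            raise ValueError(f"allele_map values must be strain labels, got {bad}")
        if self.aligned_column < 1:
            raise ValueError("aligned_column is 1-based and must be >= 1")


# IUPAC code for a pair of bases (used to recognise heterozygote basecalls).
_IUPAC_PAIR = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("GC"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}

COI_MARKER = MarkerDefinition(
    name="mCOI1164D",
    alignment="coi",
    aligned_column=1,
    allele_map={"A": "C-strain", "G": "C-strain", "T": "R-strain"},
    ambiguity_policy="unknown",   # mitochondrial: no heterozygotes expected
)

TPI_MARKER = MarkerDefinition(
    name="gTpi183Y",
    alignment="tpi_exon",
    aligned_column=1,
    allele_map={"C": "C-strain", "T": "R-strain"},
    ambiguity_policy="exclude",
)


def _check_base(base: str) -> str:
    if len(base) != 1:
        raise ValueError(f"expected a single base, got {base!r}")
    base = base.upper()
    if base not in IUPAC_DNA:
        raise ValueError(f"not an IUPAC DNA code: {base!r}")
    return base


def call_coi_strain(base: str, definition: MarkerDefinition = COI_MARKER) -> str:
    """Call the mitochondrial strain from the base at mCOI1164D.

    Returns ``C_COI``, ``R_COI`` or ``unknown``.  Total over single IUPAC
    codes; raises only on multi-character / non-IUPAC input.
    """
    base = _check_base(base)
    strain = definition.allele_map.get(base)
    if strain == "C-strain":
        return "C_COI"
    if strain == "R-strain":
        return "R_COI"
    return "unknown"


def call_tpi_strain(base: str, definition: MarkerDefinition = TPI_MARKER) -> str:
    """Call the nuclear strain from the base at gTpi183Y.

    Returns ``C_Tpi``, ``R_Tpi``, ``ambiguous`` (heterozygous basecall equal
    to the IUPAC union of the two mapped alleles) or ``unknown``.
    """
    base = _check_base(base)
    strain = definition.allele_map.get(base)
    if strain == "C-strain":
        return "C_Tpi"
    if strain == "R-strain":
        return "R_Tpi"
    mapped = frozenset(definition.allele_map)
    if len(mapped) == 2 and base == _IUPAC_PAIR.get(mapped):
        return "ambiguous"
    return "unknown"


def annotate_specimens(
    table: pd.DataFrame,
    alignments: Mapping[str, AlignedSequenceSet],
    definitions: Sequence[MarkerDefinition] = (COI_MARKER, TPI_MARKER),
    force: bool = False,
) -> pd.DataFrame:
    """Fill ``coi_strain`` / ``tpi_strain`` columns from the marker alignments.

    ``alignments`` is keyed by :attr:`MarkerDefinition.alignment`.  Specimens
    missing from a marker's alignment keep ``unknown`` for that marker.
    User-provided (non-``unknown``) labels are preserved unless ``force``.
    Tpi-ambiguous specimens are flagged ``excluded`` under the marker's
    ``exclude`` policy so every downstream statistic drops them.

    Returns a new annotated copy of the table.  When both markers are known
    and disagree, the nuclear Tpi call takes precedence for downstream strain
    interpretation (clans are delimited on Tpi); the disagreement is counted
    in a ``marker_conflict`` column so conflicts stay visible.
    """
    out = table.copy()
    if not definitions:
        return out
    for definition in definitions:
        aln = alignments.get(definition.alignment)
        if aln is None:
            continue
        if definition.aligned_column > aln.alignment_length:
            raise ValueError(
                f"{definition.name}: column {definition.aligned_column} exceeds "
                f"alignment length {aln.alignment_length}"
            )
        col = "coi_strain" if definition.alignment == "coi" else "tpi_strain"
        caller = call_coi_strain if col == "coi_strain" else call_tpi_strain
        for sid in out.index:
            if sid not in aln.records:
                continue
            if not force and out.at[sid, col] not in ("unknown", ""):
                continue
            base = aln.records[sid][definition.aligned_column - 1]
            label = caller(base, definition)
            out.at[sid, col] = label
            if label == "ambiguous" and definition.ambiguity_policy == "exclude":
                out.at[sid, "excluded"] = True
                reason = out.at[sid, "exclusion_reason"]
                note = f"{definition.name}-heterozygous"
                out.at[sid, "exclusion_reason"] = (
                    f"{reason};{note}" if reason else note
                )
    conflict = (
        out["coi_strain"].isin(["C_COI", "R_COI"])
        & out["tpi_strain"].isin(["C_Tpi", "R_Tpi"])
        & (out["coi_strain"].str[0] != out["tpi_strain"].str[0])
    )
    out["marker_conflict"] = conflict
    return out
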