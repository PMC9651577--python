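"""Aligned-FASTA and specimen-metadata input/output.

The pipeline works on pre-aligned, equal-length DNA sequences (e.g. the
~200-bp TpiI4a200 intron segment) keyed by specimen id, plus a tab-separated
metadata table with one row per specimen.  Both are validated on read so that
every downstream stage can assume a rectangular alignment and a closed
vocabulary for the categorical fields.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "AlignmentError",
    "AlignedSequenceSet",
    "read_aligned_fasta",
    "write_aligned_fasta",
    "read_specimen_table",
    "write_specimen_table",
    "new_specimen_table",
    "SPECIMEN_COLUMNS",
]

#: IUPAC nucleotide one-letter codes plus the alignment gap character.
IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN-")

#: Columns of the specimen metadata table (besides the specimen_id index).
SPECIMEN_COLUMNS = [
    "collection",
    "region",
    "host_category",
    "coi_strain",
    "tpi_strain",
    "clan",
    "haplotype_id",
    "excluded",
    "exclusion_reason",
]

HOST_CATEGORIES = {"C_Host", "R_Host", "unknown"}


class AlignmentError(ValueError):
    """Raised when sequence input violates the alignment invariants."""


@dataclass(frozen=True)
class AlignedSequenceSet:
    """An ordered, validated set of equal-length DNA sequences.

    Parameters
    ----------
    records
        Ordered mapping of specimen id to upper-case sequence string over
        the IUPAC DNA alphabet plus ``-``.
    """

    records: dict[str, str]

    def __post_init__(self) -> None:
        if not self.records:
            raise AlignmentError("empty sequence set")
        lengths = {sid: len(s) for sid, s in self.records.items()}
        ref_len = next(iter(lengths.values()))
        ragged = [sid for sid, n in lengths.items() if n != ref_len]
        if ragged:
            raise AlignmentError(
                f"unequal sequence lengths (expected {ref_len}): "
                + ", ".join(ragged)
            )
        for sid, seq in self.records.items():
            for pos, ch in enumerate(seq, start=1):
                if ch not in IUPAC_DNA:
                    raise AlignmentError(
                        f"non-IUPAC character {ch!r} in {sid} at position {pos}"
                    )

    @property
    def alignment_length(self) -> int:
        return len(next(iter(self.records.values())))

    @property
    def ids(self) -> list[str]:
        return list(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, specimen_id: str) -> str:
        return self.records[specimen_id]

    def subset(self, ids: Iterable[str]) -> "AlignedSequenceSet":
        """Restrict to the given specimen ids (kept in the given order)."""
        ids = list(ids)
        missing = [i for i in ids if i not in self.records]
        if missing:
            raise KeyError(f"ids absent from alignment: {', '.join(missing)}")
        return AlignedSequenceSet({i: self.records[i] for i in ids})


def read_aligned_fasta(path: str | Path) -> AlignedSequenceSet:
    """Read an aligned FASTA file into a validated :class:`AlignedSequenceSet`.

    Sequences are upper-cased.  Raises :class:`AlignmentError` on duplicate
    ids, ragged alignments, or characters outside IUPAC DNA + gap.
    """
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise AlignmentError(f"duplicate sequence id: {rec.id}")
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise AlignmentError(f"no FASTA records found in {path}")
    return AlignedSequenceSet(records)


def write_aligned_fasta(seqs: AlignedSequenceSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.records.items():
            fh.write(f">{sid}\n{seq}\n")


def new_specimen_table(specimen_ids: Iterable[str],
                       collection: Mapping[str, str] | str = "unknown",
                       region: Mapping[str, str] | str = "unknown",
                       host_category: Mapping[str, str] | str = "unknown",
                       ) -> pd.DataFrame:
    """Create a fresh specimen table with default 'unknown' annotations."""
    ids = list(specimen_ids)

    def col(v, default="unknown"):
        if isinstance(v, str):
            return [v] * len(ids)
        return [v.get(i, default) for i in ids]

    df = pd.DataFrame(
        {
            "collection": col(collection),
            "region": col(region),
            "host_category": col(host_category),
            "coi_strain": "unknown",
            "tpi_strain": "unknown",
            "clan": "unassigned",
            "haplotype_id": pd.array([pd.NA] * len(ids), dtype="Int64"),
            "excluded": False,
            "exclusion_reason": "",
        },
        index=pd.Index(ids, name="specimen_id"),
    )
    return df


def read_specimen_table(path: str | Path) -> pd.DataFrame:
    """Read the specimen metadata TSV.

    Required columns: ``specimen_id``, ``collection``, ``region``,
    ``host_category``.  Derived columns are added with defaults if absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    if "specimen_id" not in df.columns:
        raise ValueError(f"{path}: missing required column 'specimen_id'")
    if df["specimen_id"].duplicated().any():
        dups = df.loc[df["specimen_id"].duplicated(), "specimen_id"].tolist()
        raise ValueError(f"duplicate specimen ids: {', '.join(dups)}")
    df = df.set_index("specimen_id")
    for required in ("collection", "region"):
        if required not in df.columns:
            raise ValueError(f"{path}: missing required column '{required}'")
    if "host_category" not in df.columns:
        df["host_category"] = "unknown"
    bad = set(df["host_category"].replace("", "unknown")) - HOST_CATEGORIES
    if bad:
        raise ValueError(
            f"host_category outside {sorted(HOST_CATEGORIES)}: {sorted(bad)}"
        )
    df["host_category"] = df["host_category"].replace("", "unknown")
    for colname, default in (
        ("coi_strain", "unknown"),
        ("tpi_strain", "unknown"),
        ("clan", "unassigned"),
        ("exclusion_reason", ""),
    ):
        if colname not in df.columns:
            df[colname] = default
        else:
            df[colname] = df[colname].replace("", default)
    if "haplotype_id" in df.columns:
        df["haplotype_id"] = pd.array(
            [int(x) if str(x).strip() else pd.NA for x in df["haplotype_id"]],
            dtype="Int64",
        )
    else:
        df["haplotype_id"] = pd.array([pd.NA] * len(df), dtype="Int64")
    if "excluded" in df.columns:
        df["excluded"] = df["excluded"].str.lower().isin({"true", "1", "yes"})
    else:
        df["excluded"] = False
    return df[SPECIMEN_COLUMNS + [c for c in df.columns
                                  if c not in SPECIMEN_COLUMNS]]


def write_specimen_table(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out.index.name = "specimen_id"
    out.to_csv(path, sep="\t")
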