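"""Pairwise evolutionary distances between aligned DNA sequences.

Models:

* ``p`` — proportion of mismatching compared sites.
* ``JC69`` — Jukes–Cantor: d = -(3/4) ln(1 - (4/3) p).
* ``K2P`` — Kimura two-parameter from transition (P) and transversion (Q)
  proportions: d = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q).
* ``MCL`` — a Tamura–Nei-form distance with base frequencies pooled across
  all sequences in the set (the composite-likelihood idea: parameters are
  estimated jointly from the whole sample, then the per-pair distance is the
  TN93 formula evaluated at the pair's transition/transversion proportions).

Sites containing a gap or ambiguity code are dropped either alignment-wide
(``complete`` deletion, the default, so every pair sees the same site set) or
per pair (``pairwise`` deletion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from .io import AlignedSequenceSet

__all__ = [
    "DistanceModel",
    "DeletionRule",
    "SaturationError",
    "DistanceMatrix",
    "encode_alignment",
    "pairwise_distance",
    "write_phylip_matrix",
]

DistanceModel = Literal["p", "JC69", "K2P", "MCL"]
DeletionRule = Literal["complete", "pairwise"]

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_PURINE = frozenset((0, 2))


class SaturationError(ValueError):
    """Distance formula log argument <= 0 (sequences too diverged)."""


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    d: np.ndarray                 # symmetric, zero diagonal
    model: DistanceModel
    deletion: DeletionRule

    def __post_init__(self) -> None:
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and non-negative")

    def __len__(self) -> int:
        return len(self.labels)


def encode_alignment(seqs: AlignedSequenceSet) -> np.ndarray:
    """Encode sequences as an (n, L) uint8 array; A,C,G,T -> 0..3, other -> 255."""
    ids = seqs.ids
    L = seqs.alignment_length
    arr = np.full((len(ids), L), 255, dtype=np.uint8)
    for i, sid in enumerate(ids):
        row = np.frombuffer(seqs.records[sid].encode("ascii"), dtype=np.uint8)
        for base, code in _CODE.items():
            arr[i, row == ord(base)] = code
    return arr


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(#compared sites, #transitions, #transversions) for one encoded pair."""
    ok = (a < 4) & (b < 4)
    a, b = a[ok], b[ok]
    diff = a != b
    # transitions: A<->G (0,2) and C<->T (1,3): codes differ by 2
    ts = diff & (np.abs(a.astype(np.int16) - b.astype(np.int16)) == 2)
    return int(ok.sum()), int(ts.sum()), int((diff & ~ts).sum())


def _jc69(p: float, pair: str) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"JC69 saturated for pair {pair} (p={p:.4f})")
    return -0.75 * math.log(arg)


def _k2p(P: float, Q: float, pair: str) -> float:
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(f"K2P saturated for pair {pair} (P={P:.4f}, Q={Q:.4f})")
    return -0.5 * math.log(a1) - 0.25 * math.log(a2)


def _tn93(P1: float, P2: float, Q: float, freqs: np.ndarray, pair: str) -> float:
    """Tamura–Nei distance at given purine/pyrimidine transition proportions.

    ``P1`` = A<->G proportion, ``P2`` = C<->T proportion, ``Q`` transversions;
    ``freqs`` = pooled (A, C, G, T) frequencies.
    """
    gA, gC, gG, gT = freqs
    gR, gY = gA + gG, gC + gT
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gC * gT / gY if gY > 0 else 0.0
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        raise SaturationError(f"MCL/TN93 saturated for pair {pair}")
    return (
        -k1 * math.log(w1)
        - k2 * math.log(w2)
        - 2.0 * (gR * gY - gA * gG * gY / gR - gC * gT * gR / gY) * math.log(w3)
    )


def pairwise_distance(
    seqs: AlignedSequenceSet,
    model: DistanceModel = "MCL",
    deletion: DeletionRule = "complete",
) -> DistanceMatrix:
    """Compute the pairwise distance matrix under the chosen model.

    Raises :class:`SaturationError` naming the pair when a log argument is
    non-positive, and :class:`ValueError` when a pair has zero comparable
    sites.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    ids = tuple(seqs.ids)
    arr = encode_alignment(seqs)
    if deletion == "complete":
        keep = np.all(arr < 4, axis=0)
        arr = arr[:, keep]

    if model == "MCL":
        valid = arr[arr < 4]
        if valid.size == 0:
            raise ValueError("no comparable sites after deletion")
        freqs = np.bincount(valid, minlength=4).astype(float)
        freqs /= freqs.sum()

    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            pair = f"{ids[i]}/{ids[j]}"
            m, ts, tv = _pair_counts(arr[i], arr[j])
            if m == 0:
                raise ValueError(f"zero comparable sites for pair {pair}")
            p = (ts + tv) / m
            if model == "p":
                dist = p
            elif model == "JC69":
                dist = _jc69(p, pair)
            elif model == "K2P":
                dist = _k2p(ts / m, tv / m, pair)
            elif model == "MCL":
                # split transitions into purine (A<->G) and pyrimidine (C<->T)
                ok = (arr[i] < 4) & (arr[j] < 4)
                ai, bj = arr[i][ok], arr[j][ok]
                ts_mask = (ai != bj) & (
                    np.abs(ai.astype(np.int16) - bj.astype(np.int16)) == 2
                )
                pur = int(np.sum(ts_mask & np.isin(ai, (0, 2))))
                pyr = int(ts_mask.sum()) - pur
                dist = _tn93(pur / m, pyr / m, tv / m, freqs, pair)
            else:
                raise ValueError(f"unknown model {model!r}")
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(labels=ids, d=d, model=model, deletion=deletion)


def write_phylip_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a PHYLIP-style square distance matrix."""
    with open(path, "w") as fh:
        fh.write(f"{len(dm)}\n")
        for label, row in zip(dm.labels, dm.d):
            fh.write(label + "  " + "  ".join(f"{x:.8f}" for x in row) + "\n")
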