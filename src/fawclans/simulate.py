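"""Synthetic two-clan datasets with the statistical structure of field samples.

The generator emulates what the analysis assumes about the real collections:

* two deeply diverged haplogroups ("clans") separated by a set of fixed
  nucleotide differences plus a clan-fixed diagnostic Tpi allele;
* strongly contrasting within-clan diversity — the C-like clan is simulated
  with a small mutation rate and a *structured* ancestry (two ancestral
  sub-lineages merging at depth, which enriches intermediate-frequency
  variants and pushes Tajima's D / Fu & Li's F* positive), the R-like clan
  with a large mutation rate and an *exponential-growth* genealogy (excess
  singletons, negative D and F*);
* a mitochondrial haplogroup label concordant with the clan with probability
  ~0.85, and host-site labels that are only probabilistically informative
  (P(C_Host | ClanC) ~ 0.97, P(C_Host | ClanR) ~ 0.33, the discordance rates
  reported for field collections);
* sampling spread over four collections/regions with sizes scaled down
  ~10-fold from the study's sequencing effort.

Sequences evolve on a Kingman coalescent genealogy: waiting times are
exponential with rate C(k,2) while k lineages remain (rescaled by the growth
or structure mode), mutations fall on branches as a Poisson process at rate
theta/2 per lineage per coalescent time unit, and each mutation hits a
distinct, uniformly chosen alignment column (infinite sites on a finite
locus, re-drawing on collision).  This keeps Watterson's expectation
E[S] = theta * a1 exact, at the cost of disallowing recurrent mutation.
All randomness flows from a single seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .io import AlignedSequenceSet, new_specimen_table

__all__ = ["SimulationConfig", "coalescent_sample", "simulate_two_clan_dataset"]

Mode = Literal["constant", "structured", "growth"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimulationConfig:
    """Defaults are the study conditions the generator emulates."""

    #: per-region (ClanC, ClanR) sample sizes; every cell >= 4 so the
    #: neutrality statistics are defined per cell
    region_sizes: dict = field(default_factory=lambda: {
        "FLT": (33, 19), "FLL": (5, 4), "BrL": (4, 4), "ArL": (5, 4),
    })
    locus_length: int = 200
    theta_C: float = 0.8
    theta_R: float = 8.0
    clanC_mode: Mode = "structured"
    clanR_mode: Mode = "growth"
    structure_depth: float = 1.5        # extra coalescent time between sub-lineages
    growth_rate: float = 20.0           # exponential growth intensity
    divergence_sites: int = 6           # fixed differences between clan ancestors
    tpi_diagnostic_column: int = 101    # 1-based column of the diagnostic allele
    p_tpi_concordance: float = 1.0
    p_mito_concordance: float = 0.85
    p_chost_given_clanC: float = 0.97
    p_chost_given_clanR: float = 0.33
    emit_coi_sequences: bool = False
    coi_locus_length: int = 60
    coi_diagnostic_column: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_tpi_concordance, self.p_mito_concordance,
                  self.p_chost_given_clanC, self.p_chost_given_clanR):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.theta_C <= 0 or self.theta_R <= 0:
            raise ValueError("theta must be positive")
        for region, (nc, nr) in self.region_sizes.items():
            if nc < 2 or nr < 2:
                raise ValueError(
                    f"region {region}: need >= 2 specimens per clan cell")


def _mean_pairwise_tmrca(parent: np.ndarray, time: np.ndarray, n: int) -> float:
    """Mean coalescence time over all leaf pairs of a binary genealogy."""
    size = np.zeros(len(parent))
    size[:n] = 1
    order = np.argsort(time)          # children always precede parents in time
    pair_time = 0.0
    for v in order:
        p = parent[v]
        if p < 0:
            continue
        # pairs whose MRCA is p accumulate as children are attached
        pair_time += time[p] * size[p] * size[v]
        size[p] += size[v]
    return pair_time / (n * (n - 1) / 2.0)


def _coalescent_genealogy(n: int, mode: Mode, rng: np.random.Generator,
                          growth_rate: float, structure_depth: float):
    """Return (parent, node_time) arrays for nodes 0..2n-2 (leaves first)."""
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)

    def run_kingman(lineages: list[int], t0: float, nxt: int,
                    transform=None) -> tuple[int, float]:
        t_std = 0.0
        t_real = t0
        while len(lineages) > 1:
            k = len(lineages)
            t_std += rng.exponential(2.0 / (k * (k - 1)))
            if transform is None:
                t_real = t0 + t_std
            else:
                t_real = t0 + transform(t_std)
            i, j = sorted(rng.choice(k, size=2, replace=False))
            a, b = lineages[i], lineages[j]
            parent[a] = parent[b] = nxt
            time[nxt] = t_real
            lineages = [x for x in lineages if x not in (a, b)] + [nxt]
            nxt += 1
        return lineages[0], t_real

    if mode == "constant":
        run_kingman(list(range(n)), 0.0, n)
    elif mode == "growth":
        # exponential growth: cumulative standard time T maps to real time
        # t = log(1 + beta*T)/beta, compressing deep coalescences (star-like
        # genealogy, excess singletons).  The genealogy is then rescaled to
        # the constant-size expected total length 2*a1(n) so theta keeps its
        # per-locus magnitude and only the branch-length profile carries the
        # growth signature.
        beta = growth_rate
        run_kingman(list(range(n)), 0.0, n,
                    transform=lambda T: np.log1p(beta * T) / beta)
        time *= 1.0 / _mean_pairwise_tmrca(parent, time, n)
    elif mode == "structured":
        # two ancestral sub-lineages whose MRCAs merge structure_depth deeper
        # than the later of the two, enriching intermediate-frequency variants
        half = n // 2
        nxt = n
        root_a, _ = run_kingman(list(range(half)), 0.0, nxt)
        nxt = n + (half - 1)
        root_b, _ = run_kingman(list(range(half, n)), 0.0, nxt)
        nxt = 2 * n - 2
        depth = max(time[root_a], time[root_b]) + structure_depth \
            + rng.exponential(0.25 * structure_depth)
        parent[root_a] = parent[root_b] = nxt
        time[nxt] = depth
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return parent, time


def _drop_mutations(parent, time, n, theta, L, rng,
                    allowed_columns) -> list[tuple[int, int]]:
    """Place Poisson mutations; return (node_below_branch, column) pairs."""
    lengths = np.array([
        time[parent[v]] - time[v] if parent[v] >= 0 else 0.0
        for v in range(len(parent))
    ])
    total = lengths.sum()
    n_mut = rng.poisson(theta / 2.0 * total)
    allowed = list(allowed_columns)
    if n_mut > len(allowed):
        raise ValueError(
            f"{n_mut} mutations requested but only {len(allowed)} free columns; "
            "increase the locus length"
        )
    muts = []
    used: set[int] = set()
    if n_mut == 0:
        return muts
    probs = lengths / total
    branches = rng.choice(len(parent), size=n_mut, p=probs)
    for v in branches:
        while True:
            col = allowed[int(rng.integers(0, len(allowed)))]
            if col not in used:
                used.add(col)
                break
        muts.append((int(v), col))
    return muts


def _descendant_leaves(parent, n, node) -> np.ndarray:
    children: dict[int, list[int]] = {}
    for v, p in enumerate(parent):
        if p >= 0:
            children.setdefault(p, []).append(v)
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n:
            out.append(v)
        else:
            stack.extend(children.get(v, ()))
    return np.array(sorted(out), dtype=np.int64)


def coalescent_sample(
    n: int,
    theta: float,
    L: int,
    mode: Mode = "constant",
    seed: int | np.random.Generator = 0,
    ancestral: str | None = None,
    ids: list[str] | None = None,
    growth_rate: float = 20.0,
    structure_depth: float = 2.0,
    frozen_columns: frozenset[int] = frozenset(),
) -> AlignedSequenceSet:
    """Simulate n aligned sequences of length L from one panmictic sample.

    ``frozen_columns`` (0-based) are protected from mutation — used to keep
    diagnostic and clan-divergence columns fixed.  ``ancestral`` fixes the
    root sequence (random ACGT string otherwise).
    """
    if n < 2:
        raise ValueError("need n >= 2")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    if ancestral is None:
        anc = _BASES[rng.integers(0, 4, size=L)]
    else:
        if len(ancestral) != L:
            raise ValueError("ancestral length must equal L")
        anc = np.frombuffer(ancestral.encode("ascii"), dtype=np.uint8).copy()
    parent, time = _coalescent_genealogy(n, mode, rng, growth_rate,
                                         structure_depth)
    allowed = [c for c in range(L) if c not in frozen_columns]
    muts = _drop_mutations(parent, time, n, theta, L, rng, allowed)

    seqs = np.tile(anc, (n, 1))
    for node, col in muts:
        current = anc[col]
        choices = _BASES[_BASES != current]
        new_base = choices[int(rng.integers(0, 3))]
        leaves = _descendant_leaves(parent, n, node)
        seqs[leaves, col] = new_base

    if ids is None:
        ids = [f"s{i:03d}" for i in range(n)]
    records = {
        sid: seqs[i].tobytes().decode("ascii") for i, sid in enumerate(ids)
    }
    return AlignedSequenceSet(records)


def simulate_two_clan_dataset(
    cfg: SimulationConfig | None = None,
) -> tuple[dict[str, AlignedSequenceSet], pd.DataFrame]:
    """Generate the full synthetic dataset the pipeline consumes.

    Returns ``(alignments, specimen_table)`` where ``alignments`` holds the
    Tpi intron alignment under key ``"tpi"`` (its diagnostic column carries
    the clan-fixed allele: C for the C-like clan, T for the R-like clan) and,
    when ``emit_coi_sequences`` is set, a two-haplotype COI alignment under
    ``"coi"``.  The specimen table includes the truth columns ``true_clan``
    and ``coi_group`` for recovery scoring.
    """
    cfg = cfg or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    L = cfg.locus_length
    diag = cfg.tpi_diagnostic_column - 1
    if not 0 <= diag < L:
        raise ValueError("tpi_diagnostic_column outside the locus")

    # clan ancestors: identical except at divergence columns + diagnostic site
    anc = _BASES[rng.integers(0, 4, size=L)]
    candidates = [c for c in range(L) if c != diag]
    div_cols = rng.choice(candidates, size=cfg.divergence_sites, replace=False)
    anc_c = anc.copy()
    anc_r = anc.copy()
    anc_c[diag] = ord("C")
    anc_r[diag] = ord("T")
    for col in div_cols:
        b = anc[col]
        anc_r[col] = _BASES[_BASES != b][int(rng.integers(0, 3))]
    frozen = frozenset(int(c) for c in div_cols) | {diag}

    n_c = sum(nc for nc, _ in cfg.region_sizes.values())
    n_r = sum(nr for _, nr in cfg.region_sizes.values())
    ids_c, ids_r, meta = [], [], []
    for region, (nc, nr) in cfg.region_sizes.items():
        for i in range(nc):
            sid = f"{region}-C{i:03d}"
            ids_c.append(sid)
            meta.append((sid, region, "ClanC"))
        for i in range(nr):
            sid = f"{region}-R{i:03d}"
            ids_r.append(sid)
            meta.append((sid, region, "ClanR"))

    seqs_c = coalescent_sample(
        n_c, cfg.theta_C, L, mode=cfg.clanC_mode, seed=rng,
        ancestral=anc_c.tobytes().decode("ascii"), ids=ids_c,
        growth_rate=cfg.growth_rate, structure_depth=cfg.structure_depth,
        frozen_columns=frozen,
    )
    seqs_r = coalescent_sample(
        n_r, cfg.theta_R, L, mode=cfg.clanR_mode, seed=rng,
        ancestral=anc_r.tobytes().decode("ascii"), ids=ids_r,
        growth_rate=cfg.growth_rate, structure_depth=cfg.structure_depth,
        frozen_columns=frozen,
    )

    tpi_records: dict[str, str] = {}
    table_rows = []
    for sid, region, clan in meta:
        seq = (seqs_c if clan == "ClanC" else seqs_r).records[sid]
        # diagnostic-allele leakage: flip the clan-fixed base
        if rng.random() >= cfg.p_tpi_concordance:
            flip = "T" if clan == "ClanC" else "C"
            seq = seq[:diag] + flip + seq[diag + 1:]
        tpi_records[sid] = seq

        concordant = rng.random() < cfg.p_mito_concordance
        coi_group = clan if concordant else (
            "ClanR" if clan == "ClanC" else "ClanC")
        p_chost = (cfg.p_chost_given_clanC if clan == "ClanC"
                   else cfg.p_chost_given_clanR)
        host = "C_Host" if rng.random() < p_chost else "R_Host"
        table_rows.append((sid, region, host, clan, coi_group))

    table = new_specimen_table(
        [r[0] for r in table_rows],
        collection={r[0]: r[1] for r in table_rows},
        region={r[0]: r[1] for r in table_rows},
        host_category={r[0]: r[2] for r in table_rows},
    )
    table["true_clan"] = [r[3] for r in table_rows]
    table["coi_group"] = [r[4] for r in table_rows]

    alignments = {"tpi": AlignedSequenceSet(tpi_records)}
    if cfg.emit_coi_sequences:
        coi_len = cfg.coi_locus_length
        cdiag = cfg.coi_diagnostic_column - 1
        coi_anc = _BASES[rng.integers(0, 4, size=coi_len)]
        hap_c = coi_anc.copy()
        hap_r = coi_anc.copy()
        hap_c[cdiag] = ord("A")
        hap_r[cdiag] = ord("T")
        coi_records = {
            sid: (hap_c if grp == "ClanC" else hap_r).tobytes().decode("ascii")
            for sid, _, _, _, grp in table_rows
        }
        alignments["coi"] = AlignedSequenceSet(coi_records)
    return alignments, table
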