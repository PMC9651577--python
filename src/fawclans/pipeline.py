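"""End-to-end pipeline: haplotypes -> strain calls -> tree -> clans -> statistics.

A single plain-text YAML config is the only source of thresholds and model
choices; :func:`run_all` executes the stages in fixed order, writes the
report bundle (haplotype tables, Newick trees, clan partition, diversity /
neutrality / F_ST / frequency / chi-square TSVs) and a JSON run manifest that
accounts for every specimen at every stage (in = out + excluded).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .clans import find_marker_clade
from .compare import (chi_square_homogeneity, curve_means, frequency_table,
                      one_way_anova, pooled_t_test, TRAITS)
from .distances import pairwise_distance, write_phylip_matrix
from .haplotypes import collapse_haplotypes, haplotype_summary, write_haplotype_table
from .io import (AlignedSequenceSet, read_aligned_fasta, read_specimen_table,
                 write_aligned_fasta, write_specimen_table)
from .markers import COI_MARKER, TPI_MARKER, MarkerDefinition, annotate_specimens
from .njtree import bootstrap_support, midpoint_root, nj_tree, outgroup_root, \
    write_newick
from .popgen import diversity, fst_pair, fu_li_f_star, tajimas_d
from .simulate import SimulationConfig, simulate_two_clan_dataset

__all__ = ["PipelineConfig", "RunManifest", "run_all", "load_config"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "simulate": True,              # if False, tpi_fasta/metadata paths required
    "tpi_fasta": None,
    "coi_fasta": None,
    "metadata": None,
    "outgroup_ids": [],
    "distance_model": "MCL",
    "deletion": "complete",
    "bootstrap_replicates": 100,
    "purity_threshold": 0.95,
    "tpi_marker_column": 101,      # 1-based column of gTpi183Y in the tpi alignment
    "tpi_c_allele": "C",           # base denoting the C-strain at gTpi183Y
    "coi_marker_column": 30,
    "fstar_variant": "corrected",
    "alpha": 0.05,
    "gap_policy": "strict",
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str
    input_checksums: dict = field(default_factory=dict)
    stage_counts: list = field(default_factory=list)   # per-stage bookkeeping
    outputs: list = field(default_factory=list)
    completed_stages: list = field(default_factory=list)
    failed_stage: str | None = None

    def record_stage(self, stage: str, n_in: int, n_excluded: int) -> None:
        entry = {
            "stage": stage,
            "in": n_in,
            "excluded": n_excluded,
            "out": n_in - n_excluded,
        }
        self.stage_counts.append(entry)
        self.completed_stages.append(stage)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def load_config(path: str | Path | None = None,
                overrides: dict | None = None) -> dict:
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    if overrides:
        cfg.update({k: v for k, v in overrides.items() if v is not None})
    return cfg


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _tpi_marker(cfg: dict) -> MarkerDefinition:
    c = cfg["tpi_c_allele"].upper()
    r = "T" if c == "C" else "C"
    return MarkerDefinition(
        name=TPI_MARKER.name, alignment="tpi",
        aligned_column=int(cfg["tpi_marker_column"]),
        allele_map={c: "C-strain", r: "R-strain"},
        ambiguity_policy="exclude",
    )


def _group_alignments(seqs: AlignedSequenceSet, table: pd.DataFrame,
                      by: str) -> dict[str, AlignedSequenceSet]:
    keep = table[~table["excluded"].astype(bool)]
    groups: dict[str, AlignedSequenceSet] = {}
    for value, sub in keep.groupby(by, sort=True):
        ids = [i for i in sub.index if i in seqs.records]
        if len(ids) >= 2:
            groups[str(value)] = seqs.subset(ids)
    return groups


def _stats_frame(groups: dict[str, AlignedSequenceSet], variant: str
                 ) -> pd.DataFrame:
    rows = []
    for label, aln in groups.items():
        div = diversity(aln)
        d = tajimas_d(aln)
        f = fu_li_f_star(aln, variant=variant)
        rows.append({
            "group": label, "n": div.n, "L": div.L, "S": div.S,
            "eta_s": div.eta_s, "k_bar": div.k_bar, "pi": div.pi,
            "hd": div.hd, "n_haplotypes": div.n_haplotypes,
            "tajimas_d": d.value, "tajimas_d_status": d.status,
            "fu_li_f_star": f.value, "fu_li_f_star_status": f.status,
        })
    return pd.DataFrame(rows)


def _fst_frame(groups: dict[str, AlignedSequenceSet]) -> pd.DataFrame:
    labels = list(groups)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            r = fst_pair(groups[a], groups[b])
            rows.append({"group_a": a, "group_b": b, "hw": r.hw, "hb": r.hb,
                         "fst": r.fst, "degenerate": r.degenerate})
    return pd.DataFrame(rows)


def run_all(config_path: str | Path | None = None,
            out_dir: str | Path = "fawclans-out",
            overrides: dict | None = None) -> RunManifest:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns the :class:`RunManifest`.  Raises on any stage failure after
    recording the failing stage in the manifest (also written to disk).
    """
    cfg = load_config(config_path, overrides)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=dict(cfg), seed=int(cfg["seed"]),
                           version=__version__)

    def emit(name: str, writer) -> Path:
        path = out / name
        writer(path)
        manifest.outputs.append(str(path))
        return path

    try:
        # ---- stage: inputs -------------------------------------------------
        if cfg["simulate"]:
            sim_cfg = SimulationConfig(seed=int(cfg["seed"]),
                                       emit_coi_sequences=True)
            alignments, table = simulate_two_clan_dataset(sim_cfg)
            emit("tpi.fasta", lambda p: write_aligned_fasta(alignments["tpi"], p))
            emit("metadata.tsv", lambda p: write_specimen_table(table, p))
            # field data carries no COI alignment truth; derive calls below
            coi_aln = alignments.get("coi")
            cfg["coi_marker_column"] = sim_cfg.coi_diagnostic_column
            cfg["tpi_marker_column"] = sim_cfg.tpi_diagnostic_column
        else:
            if not cfg["tpi_fasta"] or not cfg["metadata"]:
                raise FileNotFoundError(
                    "config must set tpi_fasta and metadata when simulate is off")
            for key in ("tpi_fasta", "coi_fasta", "metadata"):
                if cfg[key]:
                    p = Path(cfg[key])
                    if not p.exists():
                        raise FileNotFoundError(f"{key}: {p} does not exist")
                    manifest.input_checksums[key] = _checksum(p)
            alignments = {"tpi": read_aligned_fasta(cfg["tpi_fasta"])}
            coi_aln = (read_aligned_fasta(cfg["coi_fasta"])
                       if cfg["coi_fasta"] else None)
            table = read_specimen_table(cfg["metadata"])
        tpi = alignments["tpi"]
        n_total = len(table)
        manifest.record_stage("inputs", n_total, 0)

        # ---- stage: strain calls ------------------------------------------
        marker_alignments = {"tpi": tpi}
        defs = [_tpi_marker(cfg)]
        if coi_aln is not None:
            marker_alignments["coi"] = coi_aln
            defs.append(MarkerDefinition(
                name=COI_MARKER.name, alignment="coi",
                aligned_column=int(cfg["coi_marker_column"]),
                allele_map=COI_MARKER.allele_map, ambiguity_policy="unknown"))
        table = annotate_specimens(table, marker_alignments, defs)
        n_excluded = int(table["excluded"].sum())
        manifest.record_stage("strain_call", n_total, n_excluded)

        kept = table[~table["excluded"]]
        tpi_kept = tpi.subset([i for i in kept.index if i in tpi.records])

        # ---- stage: haplotypes --------------------------------------------
        regions = kept["region"].to_dict()
        haps = collapse_haplotypes(tpi_kept, gap_policy=cfg["gap_policy"],
                                   regions=regions)
        assign = haps.assignment
        table.loc[list(assign), "haplotype_id"] = pd.array(
            [assign[i] for i in assign], dtype="Int64")
        summary = haplotype_summary(haps, regions)
        emit("haplotypes.tsv", lambda p: write_haplotype_table(haps, p))
        emit("haplotype_summary.json", lambda p: p.write_text(
            json.dumps(asdict(summary), indent=2, sort_keys=True)))
        manifest.record_stage("haplotypes", len(tpi_kept), 0)

        # ---- stage: tree ---------------------------------------------------
        # one representative per haplotype keeps the tree readable and the
        # bootstrap affordable, mirroring haplotype-level tree building
        reps = {h.specimen_ids[0]: h for h in haps.haplotypes}
        rep_aln = tpi_kept.subset(list(reps))
        dm = pairwise_distance(rep_aln, model=cfg["distance_model"],
                               deletion=cfg["deletion"])
        emit("distances.phylip", lambda p: write_phylip_matrix(dm, p))
        tree = bootstrap_support(
            rep_aln, model=cfg["distance_model"], deletion=cfg["deletion"],
            n_reps=int(cfg["bootstrap_replicates"]), seed=int(cfg["seed"]))
        outgroups = [o for o in cfg["outgroup_ids"] if o in rep_aln.records]
        rooted = (outgroup_root(tree, outgroups) if outgroups
                  else midpoint_root(tree))
        emit("tree.nwk", lambda p: p.write_text(write_newick(rooted)))
        manifest.record_stage("tree", len(rep_aln), 0)

        # ---- stage: clans ---------------------------------------------------
        marker_by_rep = {
            rep: table.at[rep, "tpi_strain"] for rep in reps
        }
        partition = find_marker_clade(rooted, marker_by_rep,
                                      purity_threshold=float(
                                          cfg["purity_threshold"]))
        # propagate the representative's clan to every member of its haplotype
        clan_by_hid = {
            reps[rep].haplotype_id: partition.clan_of(rep) for rep in reps
        }
        for sid in kept.index:
            hid = table.at[sid, "haplotype_id"]
            if pd.notna(hid):
                table.at[sid, "clan"] = clan_by_hid.get(int(hid), "unassigned")
        emit("clans.tsv", lambda p: table.loc[kept.index, ["clan"]]
             .to_csv(p, sep="\t"))
        emit("specimens.tsv", lambda p: write_specimen_table(table, p))
        manifest.record_stage("clans", len(kept), 0)

        # ---- stage: statistics ----------------------------------------------
        variant = cfg["fstar_variant"]
        stats_rows = []
        fst_rows = []
        for by in ("host_category", "clan", "collection"):
            groups = _group_alignments(tpi, table, by)
            sf = _stats_frame(groups, variant)
            sf.insert(0, "grouping", by)
            stats_rows.append(sf)
            ff = _fst_frame(groups)
            ff.insert(0, "grouping", by)
            fst_rows.append(ff)

        # per (clan x collection) cells, the grouping behind the figures
        kept2 = table[~table["excluded"]]
        cell_groups: dict[str, AlignedSequenceSet] = {}
        for (clan, coll), sub in kept2.groupby(["clan", "collection"]):
            if clan not in ("ClanC", "ClanR"):
                continue
            ids = [i for i in sub.index if i in tpi.records]
            if len(ids) >= 4:
                cell_groups[f"{clan}:{coll}"] = tpi.subset(ids)
        sf = _stats_frame(cell_groups, variant)
        sf.insert(0, "grouping", "clan_x_collection")
        stats_rows.append(sf)
        ff = _fst_frame(cell_groups)
        ff.insert(0, "grouping", "clan_x_collection")
        fst_rows.append(ff)

        stats_df = pd.concat(stats_rows, ignore_index=True)
        fst_df = pd.concat(fst_rows, ignore_index=True)
        emit("diversity_neutrality.tsv",
             lambda p: stats_df.to_csv(p, sep="\t", index=False))
        emit("fst_pairs.tsv", lambda p: fst_df.to_csv(p, sep="\t", index=False))
        manifest.record_stage("stats", len(kept2), 0)

        # ---- stage: comparisons ---------------------------------------------
        freq = frequency_table(table)
        emit("frequencies.tsv", lambda p: freq.to_csv(p, sep="\t", index=False))
        emit("frequency_means.tsv",
             lambda p: curve_means(freq).to_csv(p, sep="\t", index=False))

        chi_rows = []
        for clan in ("ClanC", "ClanR"):
            sub = freq[freq["clan"] == clan]
            colls = sorted(sub["collection"].unique())
            if len(colls) < 2:
                continue
            for t_a, t_b in (("C_Host", "C_COI"), ("C_COI", "C_Tpi"),
                             ("C_Host", "C_Tpi")):
                counts = {}
                for t in (t_a, t_b):
                    tt = sub[sub["trait"] == t].set_index("collection")
                    counts[t] = [(int(tt.at[c, "numerator"]),
                                  int(tt.at[c, "denominator"])) for c in colls]
                chi2, df_, p_, low = chi_square_homogeneity(
                    counts[t_a], counts[t_b])
                chi_rows.append({
                    "comparison": f"{clan} {t_a} vs {clan} {t_b}",
                    "chi2": chi2, "df": df_, "p": p_, "low_expected": low,
                })
        emit("chi_square.tsv", lambda p: pd.DataFrame(chi_rows)
             .to_csv(p, sep="\t", index=False))

        # ANOVA of within- vs between-group F_ST (clan grouping), per the
        # figure comparing pairwise F_ST categories
        cells = fst_df[fst_df["grouping"] == "clan_x_collection"]
        anova_summary = {}
        if len(cells) >= 4:
            def side(row, col):
                return row[col].split(":", 1)[0]
            within_c = cells[(cells["group_a"].str.startswith("ClanC"))
                             & (cells["group_b"].str.startswith("ClanC"))]
            within_r = cells[(cells["group_a"].str.startswith("ClanR"))
                             & (cells["group_b"].str.startswith("ClanR"))]
            between = cells[
                cells["group_a"].str.split(":").str[0]
                != cells["group_b"].str.split(":").str[0]]
            if min(len(within_c), len(within_r), len(between)) >= 2:
                res = one_way_anova(
                    [within_c["fst"].tolist(), within_r["fst"].tolist(),
                     between["fst"].tolist()], alpha=float(cfg["alpha"]))
                anova_summary = {
                    "F": res.f, "r2": res.r2, "p": res.p,
                    "letters": res.letters,
                    "mean_within_C": float(within_c["fst"].mean()),
                    "mean_within_R": float(within_r["fst"].mean()),
                    "mean_between": float(between["fst"].mean()),
                }
        emit("fst_anova.json", lambda p: p.write_text(
            json.dumps(anova_summary, indent=2, sort_keys=True)))
        manifest.record_stage("compare", len(kept2), 0)

    except Exception as exc:
        manifest.failed_stage = (
            manifest.completed_stages[-1] + "+1"
            if manifest.completed_stages else "inputs")
        (out / "manifest.json").write_text(manifest.to_json())
        raise

    (out / "manifest.json").write_text(manifest.to_json())
    manifest.outputs.append(str(out / "manifest.json"))
    return manifest
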