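"""End-to-end orchestration: simulate -> coverage -> profiles -> report.

A run is driven by a RunConfig (YAML on disk), executes stage by stage
into a run directory, and records a machine-readable manifest (config
hash, seed, per-stage outputs and counts).  Re-running with an identical
config and seed reproduces identical numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import yaml

from . import coverage as cov
from . import gene_profiles as gp
from . import synthetic_data as sd
from . import trna_families as tf
from . import thermo
from .genome_io import write_annotation_bed12, write_annotation_gff3, write_genome

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 20140716
    conditions: tuple[str, ...] = ("WT", "rnh")
    genome_mode: str = "random"       # multimapper mode for genome-wide tracks
    trna_mode: str = "unique_only"    # multimapper mode for tRNA heatmaps
    apply_smoothing: bool = True
    spliced_bins: tuple[int, int, int] = gp.SPLICED_BINS
    whole_gene_bins: int = 40
    epsilon: float = gp.DEFAULT_EPSILON
    force: bool = False
    sim: dict = field(default_factory=dict)  # SimSpec field overrides

    def validate(self) -> list[str]:
        """Hard-fail on unusable settings; return soft warnings."""
        warnings = []
        if self.genome_mode not in ("random", "unique_only"):
            raise ValueError(f"unknown multimapper mode {self.genome_mode!r}")
        if self.trna_mode not in ("random", "unique_only"):
            raise ValueError(f"unknown multimapper mode {self.trna_mode!r}")
        if self.genome_mode == "unique_only":
            warnings.append(
                "genome-wide stage set to unique_only; the genome-wide default "
                "assigns multimappers randomly"
            )
        if self.trna_mode == "random":
            warnings.append(
                "tRNA heatmap stage set to random; tRNA heatmaps should use "
                "uniquely mapped reads only"
            )
        bad = set(self.sim) - {f.name for f in __import__("dataclasses").fields(sd.SimSpec)}
        if bad:
            raise ValueError(f"unknown sim overrides: {sorted(bad)}")
        for cond in self.conditions:
            if cond not in sd.CONDITIONS:
                raise ValueError(f"unknown condition {cond!r}")
        return warnings

    def sim_spec(self) -> sd.SimSpec:
        overrides = dict(self.sim)
        overrides.setdefault("seed", self.seed)
        # YAML gives lists where SimSpec wants tuples
        spec = sd.SimSpec(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in overrides.items()
        })
        return spec

    def digest(self) -> str:
        payload = {
            k: v for k, v in self.__dict__.items() if k not in ("force", "out_dir")
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    for key in ("conditions", "spliced_bins"):
        if key in raw and isinstance(raw[key], list):
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages into ``config.out_dir``; returns the manifest."""
    warnings = config.validate()
    for w in warnings:
        log.warning("%s", w)
    out = config.out_dir
    manifest_path = os.path.join(out, "manifest.json")
    if os.path.exists(manifest_path) and not config.force:
        raise FileExistsError(f"{manifest_path} exists; use force to re-run")
    os.makedirs(out, exist_ok=True)
    manifest: dict = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "warnings": warnings,
        "stages": {},
    }

    def stage(name):
        manifest["stages"][name] = entry = {"outputs": [], "counts": {}}
        return entry

    def emit(entry, name):
        path = os.path.join(out, name)
        entry["outputs"].append(name)
        return path

    # --- simulate ---------------------------------------------------------
    entry = stage("simulate")
    sim = sd.make_genome(config.sim_spec())
    write_genome(sim.contigs, emit(entry, "genome.fa"))
    write_annotation_gff3(sim.annotation, emit(entry, "annotation.gff3"))
    write_annotation_bed12(sim.annotation, emit(entry, "annotation.bed12"))
    gp.write_expression(sim.expression, emit(entry, "expression.tsv"))
    sd.write_truth(sim, emit(entry, "truth.json"))
    entry["counts"]["genes"] = len(sim.annotation.genes)
    entry["counts"]["intergenic_intervals"] = len(sim.annotation.intergenic)

    readsets: dict[tuple[str, str], cov.ReadSet] = {}
    for cond in config.conditions:
        for channel in sd.CHANNELS:
            rs = sd.simulate_reads(sim, cond, channel, seed=config.seed)
            readsets[(cond, channel)] = rs
            entry["counts"][f"reads_{cond}_{channel}"] = len(rs)

    # --- coverage ---------------------------------------------------------
    entry = stage("coverage")
    lengths = sim.contig_lengths()
    tracks: dict[tuple[str, str, str], cov.EnrichmentTrack] = {}
    for (cond, channel), rs in readsets.items():
        for mode_name, mode in (("genome", config.genome_mode), ("trna", config.trna_mode)):
            track = cov.reads_to_enrichment(
                rs,
                lengths,
                sim.annotation.intergenic,
                excluded=sim.annotation.excluded_loci,
                mode=mode,
                seed=config.seed,
                apply_smoothing=config.apply_smoothing,
            )
            tracks[(cond, channel, mode_name)] = track
            if mode_name == "genome":
                track.to_bedgraph(emit(entry, f"{cond}_{channel}.bedgraph"))
                entry["counts"][f"intergenic_mean_{cond}_{channel}"] = track.intergenic_mean

    # --- recovery report --------------------------------------------------
    entry = stage("recovery")
    frames = []
    for cond in config.conditions:
        rep = sd.truth_recovery_report(tracks[(cond, "chip", "genome")], sim, cond)
        rep.insert(0, "condition", cond)
        frames.append(rep)
    import pandas as pd

    recovery = pd.concat(frames, ignore_index=True)
    recovery.to_csv(emit(entry, "recovery.tsv"), sep="\t", index=False)

    # --- gene profiles ----------------------------------------------------
    entry = stage("profiles")
    genes = sim.annotation.by_id()
    coding = [g for g in sim.annotation.genes if g.gene_class == "protein_coding"]
    grouping = gp.group_by_expression(sim.expression)
    ip = tracks[("WT", "chip", "genome")]
    inp = tracks[("WT", "input", "genome")]
    ks_rows = []
    for name in ("C1-0", "C1", "C2", "C3", "C4", "C4-max"):
        gids = grouping.groups[name]
        if not gids:
            continue
        x = [gp.gene_mean_enrichment(inp, genes[g]) for g in gids]
        y = [gp.gene_mean_enrichment(ip, genes[g]) for g in gids]
        r = gp.ks_two_sample(x, y)
        ks_rows.append((name, len(gids), r.D, r.p))
    pd.DataFrame(ks_rows, columns=["group", "n", "D", "p"]).to_csv(
        emit(entry, "ks_by_expression.tsv"), sep="\t", index=False
    )
    spliced = [g for g in coding if g.is_spliced]
    matrix = gp.metagene_spliced(ip, inp, spliced, config.spliced_bins, config.epsilon)
    matrix.to_tsv(emit(entry, "metagene_spliced.tsv"))
    exon2 = gp.exon2_boxplot_stats(matrix, genes)
    exon2.to_csv(emit(entry, "exon2_log2fc.tsv"), sep="\t", index=False)
    entry["counts"]["spliced_genes"] = len(matrix.gene_ids)

    # --- tRNA heatmaps ----------------------------------------------------
    entry = stage("trna")
    usage = tf.codon_frequencies(coding, sim.contigs)
    trna_genes = sim.annotation.genes_of_class("tRNA")
    families = tf.rank_anticodons(usage, trna_genes)
    entry["counts"]["families"] = len(families)
    hm_wt = tf.trna_heatmap(
        tracks[("WT", "chip", "trna")],
        tracks[("WT", "input", "trna")],
        families,
        genes,
        comparison="WT chip / WT input",
    )
    hm_wt.to_tsv(emit(entry, "trna_heatmap_wt_vs_input.tsv"))
    if "rnh" in config.conditions:
        hm_mut = tf.trna_heatmap(
            tracks[("rnh", "chip", "trna")],
            tracks[("WT", "chip", "trna")],
            families,
            genes,
            comparison="rnh chip / WT chip",
        )
        hm_mut.to_tsv(emit(entry, "trna_heatmap_rnh_vs_wt.tsv"))

    # --- thermo -----------------------------------------------------------
    entry = stage("thermo")
    groups = {
        "RPG i-genes": [g for g in spliced if g.is_rpg],
        "NRPG i-genes": [g for g in spliced if not g.is_rpg],
    }
    profiles = thermo.stability_metagene(sim.contigs, groups, bins=config.spliced_bins)
    for group, kinds in profiles.items():
        tag = group.replace(" ", "_")
        arr = np.vstack([kinds["dna_dna"], kinds["rna_dna"], kinds["gc"]])
        path = emit(entry, f"stability_{tag}.tsv")
        with open(path, "w") as fh:
            fh.write("# rows: dg9_dna_dna, dg9_rna_dna, gc\n")
            for row in arr:
                fh.write("\t".join(f"{v:.6g}" for v in row) + "\n")

    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
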