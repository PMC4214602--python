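"""Synthetic genomes and matched input/ChIP read sets with known truth.

The generator emulates the statistical structure of an S9.6 R-loop
ChIP-seq experiment in budding yeast: a multi-contig nuclear genome with
intergenic background, tRNA genes with free flanks, spliced protein-coding
genes (short first exons, a GC-richer second exon), intronless genes, a
family of sequence-identical retroelement copies (the multimapping
source), a repeated rDNA-like locus (excluded from analysis), and an
AT-rich mitochondrial contig.  Matched "input" and "ChIP" read sets are
drawn with per-feature-class enrichment folds and Poisson (or
negative-binomial) count noise.

Enrichment model: a ChIP fragment is enriched according to the highest
fold among the features it overlaps, so the expected interior coverage of
a feature equals fold x mean depth irrespective of the feature's length
(tRNA genes are shorter than the 200 bp fragment).  The input channel is
fold-blind.  Every simulated read is emitted at its true origin;
multimapping reads (read span fully inside a repeat copy) carry the full
candidate-location list across copies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .coverage import (
    DepthTrack,
    EnrichmentTrack,
    FRAGMENT_LENGTH,
    ReadSet,
)
from .genome_io import (
    AnnotationSet,
    Contig,
    GeneModel,
    Interval,
    derive_intergenic,
    merge_intervals,
)

__all__ = [
    "SimSpec",
    "SimulatedGenome",
    "make_genome",
    "simulate_reads",
    "simulate_depth",
    "truth_recovery_report",
    "windows_within",
    "CONDITIONS",
    "CHANNELS",
]

CONDITIONS = ("WT", "rnh")
CHANNELS = ("input", "chip")

_STOPS = ("TAA", "TAG", "TGA")
_SENSE = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT" if a + b + c not in _STOPS
)

# anticodons sampled for the simulated tRNA genes (RNA alphabet)
_ANTICODON_POOL = (
    "AGC", "UGC", "GCC", "UUG", "CAA", "GAA", "UUC", "GUU", "UCU", "CUU",
    "UUU", "GAC", "UAC", "CCA", "GUA", "UGU", "GCU", "CAU", "GUG", "UAA",
)


@dataclass
class SimSpec:
    """Study conditions for the simulator (sizes in bp, depths fragments/bp)."""

    seed: int = 20140716
    contig_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrI": 800_000, "chrII": 700_000, "chrM": 90_000}
    )
    spacing: tuple[int, int] = (4_000, 6_000)

    n_trna: int = 60
    trna_length: tuple[int, int] = (100, 160)
    trna_gc: float = 0.55

    n_spliced: int = 60
    exon1_short: tuple[int, int] = (30, 99)
    exon1_long: tuple[int, int] = (100, 250)
    intron_length: tuple[int, int] = (80, 400)
    exon2_length: tuple[int, int] = (501, 1500)
    exon1_gc: float = 0.40
    exon2_gc: float = 0.55
    intron_gc: float = 0.35

    n_intronless: int = 60
    intronless_length: tuple[int, int] = (500, 2000)
    coding_gc: float = 0.40

    retro_copies: int = 8
    retro_length: int = 2_000
    retro_gc: float = 0.42

    rdna_units: int = 2
    rdna_unit_length: int = 3_000
    rdna_gc: float = 0.45

    n_mito_genes: int = 3
    mito_gene_length: tuple[int, int] = (3_000, 8_000)
    mito_gc: float = 0.25
    background_gc: float = 0.38

    read_length: int = 50
    fragment_length: int = FRAGMENT_LENGTH
    base_depth: float = 30.0
    noise: str = "poisson"  # or "nb" or "none"
    nb_dispersion: float = 0.1

    # per-condition enrichment folds over the intergenic background
    folds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "WT": {"exon2": 2.0, "tRNA": 1.5, "retroelement": 1.0, "mito": 1.0, "rRNA_like": 8.0},
            "rnh": {"exon2": 2.0, "tRNA": 6.0, "retroelement": 4.0, "mito": 4.0, "rRNA_like": 8.0},
        }
    )

    def validate(self) -> None:
        if any(l <= 0 for l in self.contig_lengths.values()):
            raise ValueError("contig lengths must be positive")
        if "chrM" not in self.contig_lengths:
            raise ValueError("the contig plan must include chrM")
        for cond, fmap in self.folds.items():
            if any(f < 0 for f in fmap.values()):
                raise ValueError(f"{cond}: folds must be >= 0")
        if self.noise not in ("poisson", "nb", "none"):
            raise ValueError(f"unknown noise model {self.noise!r}")


@dataclass
class SimulatedGenome:
    """Genome bundle plus the ground truth needed to score recovery."""

    spec: SimSpec
    contigs: dict[str, Contig]
    annotation: AnnotationSet
    expression: pd.Series
    repeat_groups: dict[str, list[Interval]]  # identical-copy placements

    def contig_lengths(self) -> dict[str, int]:
        return {n: c.length for n, c in self.contigs.items()}

    def class_intervals(self) -> dict[str, list[Interval]]:
        """Enrichment-bearing intervals per feature class; exon2 of spliced
        genes is its own sub-feature class."""
        out: dict[str, list[Interval]] = {}
        for g in self.annotation.genes:
            if g.gene_class == "protein_coding" and g.is_spliced:
                out.setdefault("exon2", []).append(g.exons[1])
            elif g.gene_class == "tRNA":
                out.setdefault("tRNA", []).append(g.span)
            elif g.gene_class == "retroelement":
                out.setdefault("retroelement", []).append(g.span)
            elif g.gene_class == "mito":
                out.setdefault("mito", []).append(g.span)
            elif g.gene_class == "rRNA_like":
                out.setdefault("rRNA_like", []).append(g.span)
        return out

    def true_folds(self, condition: str) -> dict[str, float]:
        fmap = self.spec.folds[condition]
        return {cls: fmap.get(cls, 1.0) for cls in self.class_intervals()}


def _draw_bases(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=n, p=p)


def _codon_weights(gc: float) -> np.ndarray:
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in _SENSE])
    return w / w.sum()


def _orf(rng: np.random.Generator, length: int, gc_per_base: np.ndarray) -> str:
    """ATG + GC-targeted sense codons + stop, total ``length`` (mult of 3)."""
    assert length % 3 == 0 and length >= 9
    n_mid = length // 3 - 2
    codons = ["ATG"]
    w_cache: dict[float, np.ndarray] = {}
    for i in range(n_mid):
        gc = float(gc_per_base[3 + 3 * i])
        if gc not in w_cache:
            w_cache[gc] = _codon_weights(gc)
        codons.append(_SENSE[rng.choice(len(_SENSE), p=w_cache[gc])])
    codons.append("TAA")
    return "".join(codons)


def make_genome(spec: SimSpec | None = None) -> SimulatedGenome:
    """Place genes on the contig plan and draw sequences per segment.

    Retroelement copies and rDNA-like units are exact sequence duplicates.
    Annotation (with intergenic complement and the rDNA exclusion span) and
    a per-gene expression table are produced alongside.
    """
    spec = spec or SimSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lengths = dict(spec.contig_lengths)
    seqs = {
        name: _draw_bases(rng, L, spec.mito_gc if name == "chrM" else spec.background_gc)
        for name, L in lengths.items()
    }

    genes: list[GeneModel] = []
    repeat_groups: dict[str, list[Interval]] = {}
    nuclear = [n for n in lengths if n != "chrM"]
    cursor = {n: 0 for n in lengths}
    ci = 0  # index into nuclear contigs

    def place(total_len: int, contig: str | None = None) -> tuple[str, int]:
        nonlocal ci
        gap = int(rng.integers(*spec.spacing))
        if contig is None:
            while ci < len(nuclear):
                name = nuclear[ci]
                if cursor[name] + gap + total_len + 2000 <= lengths[name]:
                    break
                ci += 1
            else:
                need = sum(cursor.values())
                raise ValueError(
                    f"genome too small to place all genes; need more than "
                    f"{need + total_len + 2000} bp of nuclear sequence"
                )
            contig = nuclear[ci]
        else:
            if cursor[contig] + gap + total_len + 2000 > lengths[contig]:
                raise ValueError(f"contig {contig} too small")
        start = cursor[contig] + gap
        cursor[contig] = start + total_len
        return contig, start

    def paste(contig: str, start: int, seq: str) -> None:
        seqs[contig][start : start + len(seq)] = np.frombuffer(
            seq.encode(), dtype="S1"
        )

    # rDNA-like tandem repeat (placed first, on the first nuclear contig)
    unit = _draw_bases(rng, spec.rdna_unit_length, spec.rdna_gc).tobytes().decode()
    contig, start = place(spec.rdna_unit_length * spec.rdna_units, nuclear[0])
    rdna_ivs = []
    for u in range(spec.rdna_units):
        s = start + u * spec.rdna_unit_length
        paste(contig, s, unit)
        iv = Interval(contig, s, s + spec.rdna_unit_length, "+")
        rdna_ivs.append(iv)
        genes.append(
            GeneModel(f"RDN-{u + 1}", "rRNA_like", "+", (iv,))
        )
    repeat_groups["rdna"] = rdna_ivs

    # retroelement copies: identical sequence, scattered
    retro_seq = _draw_bases(rng, spec.retro_length, spec.retro_gc).tobytes().decode()
    retro_ivs = []
    for k in range(spec.retro_copies):
        contig, start = place(spec.retro_length)
        paste(contig, start, retro_seq)
        iv = Interval(contig, start, start + spec.retro_length, "+")
        retro_ivs.append(iv)
        genes.append(GeneModel(f"TY-{k + 1}", "retroelement", "+", (iv,)))
    repeat_groups["retroelement"] = retro_ivs

    # tRNA genes
    for k in range(spec.n_trna):
        tlen = int(rng.integers(spec.trna_length[0], spec.trna_length[1] + 1))
        contig, start = place(tlen)
        paste(contig, start, _draw_bases(rng, tlen, spec.trna_gc).tobytes().decode())
        strand = "+" if rng.random() < 0.5 else "-"
        anticodon = _ANTICODON_POOL[int(rng.integers(len(_ANTICODON_POOL)))]
        genes.append(
            GeneModel(
                f"tRNA-{k + 1}",
                "tRNA",
                strand,
                (Interval(contig, start, start + tlen, strand),),
                anticodon=anticodon,
            )
        )

    # spliced protein-coding genes (one intron; exon2 GC-richer)
    for k in range(spec.n_spliced):
        short = k % 2 == 0
        e1 = int(rng.integers(*spec.exon1_short) if short else rng.integers(*spec.exon1_long))
        e2 = int(rng.integers(*spec.exon2_length))
        e2 += (3 - (e1 + e2) % 3) % 3
        intron = int(rng.integers(*spec.intron_length))
        gc_per_base = np.concatenate(
            [np.full(e1, spec.exon1_gc), np.full(e2, spec.exon2_gc)]
        )
        cds = _orf(rng, e1 + e2, gc_per_base)
        intron_seq = _draw_bases(rng, intron, spec.intron_gc).tobytes().decode()
        total = e1 + intron + e2
        contig, start = place(total)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "+":
            paste(contig, start, cds[:e1] + intron_seq + cds[e1:])
            exons = (
                Interval(contig, start, start + e1, "+"),
                Interval(contig, start + e1 + intron, start + total, "+"),
            )
        else:
            rc = str(Seq(cds[:e1] + intron_seq + cds[e1:]).reverse_complement())
            paste(contig, start, rc)
            exons = (
                Interval(contig, start + intron + e2, start + total, "-"),
                Interval(contig, start, start + e2, "-"),
            )
        genes.append(
            GeneModel(
                f"IG-{k + 1}", "protein_coding", strand, exons, is_rpg=short
            )
        )

    # intronless protein-coding genes
    for k in range(spec.n_intronless):
        L = int(rng.integers(*spec.intronless_length))
        L -= L % 3
        cds = _orf(rng, L, np.full(L, spec.coding_gc))
        contig, start = place(L)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            paste(contig, start, str(Seq(cds).reverse_complement()))
        else:
            paste(contig, start, cds)
        genes.append(
            GeneModel(
                f"EG-{k + 1}",
                "protein_coding",
                strand,
                (Interval(contig, start, start + L, strand),),
            )
        )

    # mitochondrial genes
    for k in range(spec.n_mito_genes):
        L = int(rng.integers(*spec.mito_gene_length))
        contig, start = place(L, "chrM")
        paste(contig, start, _draw_bases(rng, L, spec.mito_gc + 0.05).tobytes().decode())
        genes.append(
            GeneModel(
                f"MT-{k + 1}", "mito", "+", (Interval("chrM", start, start + L, "+"),)
            )
        )

    contigs = {n: Contig(n, seqs[n].tobytes().decode()) for n in lengths}

    # expression: log-normal, RPGs high, a slice of near-silent genes
    coding = [g for g in genes if g.gene_class == "protein_coding"]
    expr = {}
    for g in coding:
        v = float(rng.lognormal(mean=0.0, sigma=1.0))
        if g.is_rpg:
            v *= 10.0
        if rng.random() < 0.05:
            v = float(rng.uniform(0.0, 0.04))
        expr[g.gene_id] = v
    expression = pd.Series(expr, name="expression").sort_index()

    annotation = AnnotationSet(
        genes=genes,
        excluded_loci=merge_intervals(rdna_ivs),
    )
    annotation.intergenic = derive_intergenic(genes, contigs)
    return SimulatedGenome(
        spec=spec,
        contigs=contigs,
        annotation=annotation,
        expression=expression,
        repeat_groups=repeat_groups,
    )


# ---------------------------------------------------------------------------
# read simulation


def _fold_per_base(sim: SimulatedGenome, condition: str) -> dict[str, np.ndarray]:
    folds = sim.spec.folds[condition]
    out = {n: np.ones(L) for n, L in sim.contig_lengths().items()}
    for cls, ivs in sim.class_intervals().items():
        f = folds.get(cls, 1.0)
        for iv in ivs:
            if f >= 1.0:
                out[iv.contig][iv.start : iv.end] = np.maximum(
                    out[iv.contig][iv.start : iv.end], f
                )
            else:
                # depleted/silenced features override the background
                out[iv.contig][iv.start : iv.end] = f
    return out


def _fragment_folds(fold_base: np.ndarray, frag_len: int, n_starts: int) -> np.ndarray:
    """max of the per-base fold over each fragment footprint [x, x+L)."""
    out = np.ones(n_starts)
    # per-base folds are piecewise constant over few features: lift each
    # run above 1 onto the fragment-start positions it covers
    above = fold_base > 1
    if above.any():
        edges = np.flatnonzero(np.diff(above.astype(int)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [len(fold_base)]))
        for s, e in zip(starts, ends):
            if not above[s]:
                continue
            f = fold_base[s:e].max()
            lo = max(s - frag_len + 1, 0)
            hi = min(e, n_starts)
            if lo < hi:
                out[lo:hi] = np.maximum(out[lo:hi], f)
    # folds below 1 deplete (and 0 vetoes) every fragment overlapping the
    # feature, so no read can land inside a silenced feature
    below = fold_base < 1
    if below.any():
        edges = np.flatnonzero(np.diff(below.astype(int)))
        starts = np.concatenate(([0], edges + 1))
        ends = np.concatenate((edges + 1, [len(fold_base)]))
        for s, e in zip(starts, ends):
            if not below[s]:
                continue
            f = fold_base[s:e].min()
            lo = max(s - frag_len + 1, 0)
            hi = min(e, n_starts)
            if lo < hi:
                out[lo:hi] = np.minimum(out[lo:hi], f)
    return out


def _channel_rng(spec: SimSpec, condition: str, channel: str, seed: int | None) -> np.random.Generator:
    root = spec.seed if seed is None else seed
    return np.random.default_rng(
        [root, CONDITIONS.index(condition), CHANNELS.index(channel)]
    )


def simulate_reads(
    sim: SimulatedGenome,
    condition: str = "WT",
    channel: str = "input",
    seed: int | None = None,
    base_depth: float | None = None,
) -> ReadSet:
    """Draw a single-end read set for one condition x channel.

    Fragment counts per start position follow the configured noise model at
    rate base_depth/fragment_length times the enrichment fold of the
    fragment (chip channel only; the input channel is fold-blind).  Reads
    are the 5'-most read_length bases of each fragment on a random strand,
    emitted at their true origin; reads lying fully inside a repeat copy
    carry candidate locations in every copy.
    """
    spec = sim.spec
    if condition not in CONDITIONS or channel not in CHANNELS:
        raise ValueError(f"unknown condition/channel {condition!r}/{channel!r}")
    depth = spec.base_depth if base_depth is None else base_depth
    if depth <= 0:
        raise ValueError("base depth must be positive")
    rng = _channel_rng(spec, condition, channel, seed)
    FL, RL = spec.fragment_length, spec.read_length
    base_rate = depth / FL
    fold_base = _fold_per_base(sim, condition) if channel == "chip" else None

    frames = []
    for name, L in sim.contig_lengths().items():
        n_starts = L - FL + 1
        if channel == "chip":
            lam = base_rate * _fragment_folds(fold_base[name], FL, n_starts)
        else:
            lam = np.full(n_starts, base_rate)
        if spec.noise == "poisson":
            counts = rng.poisson(lam)
        elif spec.noise == "nb":
            r = 1.0 / spec.nb_dispersion
            counts = rng.negative_binomial(r, r / (r + lam))
        else:  # "none": deterministic rounding of the expectation
            counts = np.round(lam).astype(np.int64)
        frag_start = np.repeat(np.arange(n_starts), counts)
        minus = rng.random(len(frag_start)) < 0.5
        read5 = np.where(minus, frag_start + FL - 1, frag_start)
        frames.append(
            pd.DataFrame(
                {
                    "contig": name,
                    "start": read5,
                    "strand": np.where(minus, "-", "+"),
                    "read_length": RL,
                    "n_hits": 1,
                }
            )
        )
    reads = pd.concat(frames, ignore_index=True)

    # multimapping: read span fully inside an identical-copy group
    read_s = np.where(
        reads["strand"].to_numpy() == "-",
        reads["start"].to_numpy() - RL + 1,
        reads["start"].to_numpy(),
    )
    read_e = read_s + RL
    candidates: dict[int, list[tuple[str, int, str]]] = {}
    n_hits = reads["n_hits"].to_numpy().copy()
    for copies in sim.repeat_groups.values():
        if len(copies) < 2:
            continue
        for iv in copies:
            inside = (
                (reads["contig"].to_numpy() == iv.contig)
                & (read_s >= iv.start)
                & (read_e <= iv.end)
            )
            for idx in np.flatnonzero(inside):
                offset = int(reads["start"].iat[idx]) - iv.start
                strand = reads["strand"].iat[idx]
                candidates[int(idx)] = [
                    (c.contig, c.start + offset, strand) for c in copies
                ]
                n_hits[idx] = len(copies)
    reads["n_hits"] = n_hits
    return ReadSet(reads=reads, candidates=candidates)


def simulate_depth(
    sim: SimulatedGenome,
    condition: str = "WT",
    channel: str = "chip",
    base_depth: float | None = None,
) -> DepthTrack:
    """Noiseless deterministic coverage: depth x per-base fold, directly.

    An idealized expectation track without fragment-edge effects, for exact
    normalization checks (intergenic windows at depth d, features at
    fold x d).
    """
    spec = sim.spec
    depth = spec.base_depth if base_depth is None else base_depth
    fold_base = (
        _fold_per_base(sim, condition)
        if channel == "chip"
        else {n: np.ones(L) for n, L in sim.contig_lengths().items()}
    )
    w = 50
    numerators = {}
    denominators = {}
    base_cov = {}
    for name, L in sim.contig_lengths().items():
        cov = depth * fold_base[name]
        base_cov[name] = cov
        n_win = -(-L // w)
        padded = np.zeros(n_win * w)
        padded[:L] = cov
        numerators[name] = padded.reshape(n_win, w).sum(axis=1)
        denominators[name] = np.full(n_win, w, dtype=np.int64)
    return DepthTrack(
        window_size=w,
        fragment_length=spec.fragment_length,
        contig_lengths=sim.contig_lengths(),
        numerators=numerators,
        denominators=denominators,
        base_coverage=base_cov,
    )


# ---------------------------------------------------------------------------
# recovery scoring


def windows_within(
    intervals: Sequence[Interval], window_size: int, n_windows: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Mask of fixed windows fully contained in the given intervals."""
    masks = {c: np.zeros(n, dtype=bool) for c, n in n_windows.items()}
    for iv in intervals:
        if iv.contig not in masks:
            continue
        first = -(-iv.start // window_size)
        last = min(iv.end // window_size, len(masks[iv.contig]))
        if first < last:
            masks[iv.contig][first:last] = True
    return masks


def truth_recovery_report(
    track: EnrichmentTrack, sim: SimulatedGenome, condition: str
) -> pd.DataFrame:
    """Per feature class: simulated fold vs median enrichment over
    feature-interior windows (classes absent from the genome are omitted;
    the excluded rDNA-like class is not scored)."""
    folds = sim.true_folds(condition)
    n_win = {c: track.n_windows(c) for c in track.scores}
    rows = []
    for cls, ivs in sorted(sim.class_intervals().items()):
        if cls == "rRNA_like" or not ivs:
            continue
        masks = windows_within(ivs, track.window_size, n_win)
        vals = np.concatenate([track.scores[c][m] for c, m in masks.items()])
        if len(vals) == 0:
            continue
        rows.append((cls, folds[cls], len(vals), float(np.median(vals))))
    return pd.DataFrame(
        rows, columns=["feature_class", "true_fold", "n_windows", "recovered_median"]
    )


def write_truth(sim: SimulatedGenome, path) -> None:
    """Machine-readable ground truth: per-condition class folds."""
    payload = {
        "seed": sim.spec.seed,
        "folds": {c: sim.true_folds(c) for c in CONDITIONS},
        "contig_lengths": sim.contig_lengths(),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
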