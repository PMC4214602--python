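"""Sequence-intrinsic R-loop favorability scores.

Two window statistics over a genomic span, both taken in transcription
orientation:

* G+C fraction in non-overlapping 100 bp windows;
* dG9: the stacking free-energy sum (kcal/mol, 37 C) over the 8
  dinucleotide steps of each non-overlapping 9-base window, computed for
  the genomic DNA/DNA duplex and for the hybrid of the nascent (pre-mRNA)
  transcript with the template strand.  More negative means more stable;
  a hybrid more stable than the corresponding DNA duplex marks sequence
  with an intrinsic R-loop propensity.

The nearest-neighbor tables ship as TSV data files (unified DNA/DNA and
RNA/DNA-hybrid dG37 parameter sets from the standard published
literature); dG9 is the plain 8-step stack sum without initiation or
terminal corrections, a comparative per-window score rather than a
melting prediction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._binning import rescale_bins
from .genome_io import Contig, GeneModel, Interval
from .gene_profiles import SPLICED_BINS, anchored_exon1_segment

__all__ = [
    "NNParamTable",
    "load_nn_table",
    "gc_windows",
    "delta_g9",
    "StabilityProfile",
    "stability_metagene",
    "GC_WINDOW",
    "DG_WINDOW",
]

GC_WINDOW = 100
DG_WINDOW = 9

_DNA_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class NNParamTable:
    """Dinucleotide-step dG37 values (kcal/mol) for one duplex kind.

    Steps are keyed 5'->3' on the reference strand: the genomic sequence
    for dna_dna, the RNA strand (with U) for rna_dna.
    """

    kind: str
    steps: Mapping[str, float]

    def __post_init__(self) -> None:
        alphabet = "ACGU" if self.kind == "rna_dna" else "ACGT"
        expected = {a + b for a in alphabet for b in alphabet}
        if set(self.steps) != expected:
            raise ValueError(f"{self.kind}: table must define all 16 steps")
        if not all(np.isfinite(v) for v in self.steps.values()):
            raise ValueError(f"{self.kind}: non-finite step value")

    def as_array(self) -> np.ndarray:
        """4x4-flattened lookup by (first_base, second_base) DNA codes.

        For rna_dna the RNA base U is indexed by the code of its DNA
        counterpart T, so lookups can share the DNA encoding.
        """
        arr = np.empty(16)
        for step, v in self.steps.items():
            a, b = (c.replace("U", "T") for c in step)
            arr[4 * _DNA_CODE[a] + _DNA_CODE[b]] = v
        return arr


def load_nn_table(kind: str, path=None) -> NNParamTable:
    """Load a step table; without a path the packaged set is used."""
    if kind not in ("dna_dna", "rna_dna"):
        raise ValueError(f"unknown duplex kind {kind!r}")
    if path is None:
        ref = resources.files("rloopscape").joinpath(f"data/nn_{kind}.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    steps = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        step, value = line.split("\t")
        steps[step] = float(value)
    return NNParamTable(kind=kind, steps=steps)


def gc_windows(
    contig: Contig, span: Interval, window: int = GC_WINDOW
) -> np.ndarray:
    """G+C fraction per non-overlapping window over the span.

    N bases are excluded from the denominator; a window of only N is
    emitted as NaN.  The trailing partial window is computed over its
    actual length.
    """
    if span.end > contig.length:
        raise ValueError("span outside contig")
    seq = contig.sequence[span.start : span.end]
    n_win = -(-len(seq) // window)
    out = np.empty(n_win)
    for i in range(n_win):
        chunk = seq[i * window : (i + 1) * window]
        informative = len(chunk) - chunk.count("N")
        if informative == 0:
            out[i] = np.nan
        else:
            out[i] = (chunk.count("G") + chunk.count("C")) / informative
    return out


@dataclass
class StabilityProfile:
    """dG9 and G+C windows over one span, transcription-oriented.

    ``starts`` are offsets of each 9 nt window from the 5' end of the span
    in transcription orientation; the trailing tail shorter than 9 nt is
    discarded.
    """

    span: Interval
    starts: np.ndarray
    dg9_dna_dna: np.ndarray
    dg9_rna_dna: np.ndarray
    gc: np.ndarray

    def per_base(self, kind: str) -> np.ndarray:
        """dG9 values painted over the bases of their window (NaN tail)."""
        vals = getattr(self, f"dg9_{kind}")
        out = np.full(self.span.length, np.nan)
        for s, v in zip(self.starts, vals):
            out[s : s + DG_WINDOW] = v
        return out


def _window_step_sums(seq: str, table: np.ndarray, window: int = DG_WINDOW) -> np.ndarray:
    """Sum of the (window-1) step values per non-overlapping window; windows
    containing N come back as NaN."""
    codes = np.array([_DNA_CODE.get(c, -1) for c in seq])
    n_win = len(seq) // window
    step_vals = np.full(max(len(seq) - 1, 0), np.nan)
    ok = (codes[:-1] >= 0) & (codes[1:] >= 0)
    step_vals[ok] = table[4 * codes[:-1][ok] + codes[1:][ok]]
    # left-to-right accumulation of the window-1 steps; NaN propagates for
    # windows containing N
    grid = np.full((n_win, window), np.nan)
    usable = min(len(step_vals), n_win * window)
    grid.reshape(-1)[:usable] = step_vals[:usable]
    out = grid[:, 0].copy()
    for j in range(1, window - 1):
        out += grid[:, j]
    return out


def delta_g9(
    contig: Contig,
    span: Interval,
    strand: str | None = None,
    dna_table: NNParamTable | None = None,
    rna_table: NNParamTable | None = None,
) -> StabilityProfile:
    """dG9 duplex-stability profile over non-overlapping 9-base windows.

    ``strand`` is the strand of the nascent transcript (defaults to the
    span's strand).  Windows are anchored at the transcription-oriented 5'
    end of the span.  dna_dna is evaluated on the genomic duplex; rna_dna
    on the hybrid of the nascent RNA (the coding-strand sequence with U)
    paired to the template strand, keyed by the RNA-strand step.
    """
    if span.length < DG_WINDOW:
        raise ValueError(f"span shorter than {DG_WINDOW} nt")
    strand = strand or span.strand
    if strand not in ("+", "-"):
        raise ValueError("transcript strand must be + or -")
    dna_table = dna_table or load_nn_table("dna_dna")
    rna_table = rna_table or load_nn_table("rna_dna")
    seq = contig.sequence[span.start : span.end]
    if strand == "-":
        seq = str(Seq(seq).reverse_complement())
    # the RNA sequence equals the coding strand with T->U; sharing the DNA
    # encoding, both duplexes are keyed by the same coding-strand steps
    dg_dna = _window_step_sums(seq, dna_table.as_array())
    dg_rna = _window_step_sums(seq, rna_table.as_array())
    n_win = len(seq) // DG_WINDOW
    starts = np.arange(n_win) * DG_WINDOW
    gc_oriented = gc_windows(
        Contig("oriented", seq), Interval("oriented", 0, len(seq), strand)
    )
    return StabilityProfile(
        span=span, starts=starts, dg9_dna_dna=dg_dna, dg9_rna_dna=dg_rna, gc=gc_oriented
    )


def _gene_segments(gene: GeneModel) -> list[Interval]:
    if gene.is_spliced:
        if gene.n_introns != 1:
            raise ValueError(f"gene {gene.gene_id}: expected exactly one intron")
        return [anchored_exon1_segment(gene), gene.introns[0], gene.exons[1]]
    return [gene.span]


def stability_metagene(
    contigs: Mapping[str, Contig],
    gene_groups: Mapping[str, Sequence[GeneModel]],
    bins: tuple[int, ...] | None = None,
    whole_gene_bins: int = 40,
    dna_table: NNParamTable | None = None,
    rna_table: NNParamTable | None = None,
) -> dict[str, dict[str, np.ndarray]]:
    """Group-averaged dG9 (both duplex kinds) and G+C metagene profiles.

    Spliced genes use the exon1-intron-exon2 scheme with the same 5'-anchor
    rule as the enrichment metagene; intronless genes are scaled over the
    whole gene body.  Window values are mapped into bins by overlap
    weighting and averaged across the genes of each group.
    """
    dna_table = dna_table or load_nn_table("dna_dna")
    rna_table = rna_table or load_nn_table("rna_dna")
    bins = bins or SPLICED_BINS
    out: dict[str, dict[str, np.ndarray]] = {}
    for group, genes in gene_groups.items():
        rows: dict[str, list[np.ndarray]] = {"dna_dna": [], "rna_dna": [], "gc": []}
        for gene in genes:
            segments = _gene_segments(gene)
            seg_bins = bins if gene.is_spliced else (whole_gene_bins,)
            per_kind: dict[str, list[np.ndarray]] = {k: [] for k in rows}
            for iv, n_bins in zip(segments, seg_bins):
                if iv.length < DG_WINDOW:
                    for k in per_kind:
                        per_kind[k].append(np.full(n_bins, np.nan))
                    continue
                prof = delta_g9(
                    contigs[gene.contig],
                    Interval(iv.contig, iv.start, iv.end, gene.strand),
                    strand=gene.strand,
                    dna_table=dna_table,
                    rna_table=rna_table,
                )
                gc_base = np.repeat(prof.gc, GC_WINDOW)[: iv.length]
                per_kind["dna_dna"].append(rescale_bins(prof.per_base("dna_dna"), n_bins))
                per_kind["rna_dna"].append(rescale_bins(prof.per_base("rna_dna"), n_bins))
                per_kind["gc"].append(rescale_bins(gc_base, n_bins))
            for k in rows:
                rows[k].append(np.concatenate(per_kind[k]))
        out[group] = {k: np.nanmean(np.vstack(v), axis=0) for k, v in rows.items()}
    return out
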