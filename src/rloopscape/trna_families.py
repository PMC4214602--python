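"""Anticodon-family ranking and positional tRNA heatmaps.

tRNA genes are grouped into families by anticodon; each family is ranked
by the summed genomic usage of the codons its anticodon can decode under
standard eukaryotic wobble rules (rank 1 = most used).  Heatmaps show, per
family, a fold-change profile over the gene body with 1 kb of 5' and 3'
flanking sequence.  Tracks feeding the heatmaps should be built in
unique-only multimapper mode so hits at one isogene cannot be attributed
to other family members.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from ._binning import fixed_bins, per_base_from_windows, rescale_bins
from .coverage import EnrichmentTrack
from .genome_io import Contig, GeneModel

__all__ = [
    "codon_frequencies",
    "standard_wobble_table",
    "load_wobble_table",
    "write_wobble_table",
    "AnticodonFamily",
    "rank_anticodons",
    "TrnaHeatmap",
    "trna_heatmap",
]

log = logging.getLogger(__name__)

STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOP_CODONS
)

# anticodon position 34 (its 5' base) pairs the codon's third position;
# A34 is read as inosine
_WOBBLE_34 = {"G": "CT", "U": "AG", "C": "G", "A": "TCA"}
_RNA_TO_DNA_COMP = {"A": "T", "C": "G", "G": "C", "U": "A"}


def codon_frequencies(
    genes: Sequence[GeneModel], contigs: Mapping[str, Contig]
) -> Counter:
    """Sense-codon counts over all protein-coding CDS in the genome.

    Exons are concatenated in transcription orientation (reverse complement
    for minus-strand genes); stop codons are excluded.  Genes whose CDS
    length is not a multiple of three, or that contain an internal stop,
    are logged and skipped.
    """
    usage: Counter = Counter()
    for gene in genes:
        if gene.gene_class != "protein_coding":
            continue
        parts = []
        for e in gene.exons:  # already 5'->3' in transcription order
            seq = contigs[gene.contig].sequence[e.start : e.end]
            parts.append(str(Seq(seq).reverse_complement()) if gene.strand == "-" else seq)
        cds = "".join(parts)
        if len(cds) % 3:
            log.warning("gene %s: CDS length %d not divisible by 3; skipped", gene.gene_id, len(cds))
            continue
        codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
        if any(c in STOP_CODONS for c in codons[:-1]):
            log.warning("gene %s: internal stop codon; skipped", gene.gene_id)
            continue
        usage.update(c for c in codons if c not in STOP_CODONS)
    return usage


def _decoded_codons(anticodon: str) -> list[str]:
    """Sense codons an anticodon can read under standard wobble rules."""
    if len(anticodon) != 3 or any(b not in "ACGU" for b in anticodon):
        raise ValueError(f"anticodon must be a 3-mer over ACGU, got {anticodon!r}")
    # codon positions 1,2 are the reverse complement of anticodon 36,35
    first_two = _RNA_TO_DNA_COMP[anticodon[2]] + _RNA_TO_DNA_COMP[anticodon[1]]
    return [
        first_two + third
        for third in _WOBBLE_34[anticodon[0]]
        if first_two + third not in STOP_CODONS
    ]


def standard_wobble_table() -> dict[str, list[str]]:
    """Anticodon -> decoded sense codons for every anticodon that decodes
    at least one sense codon (Watson-Crick plus G:U and inosine wobble)."""
    table = {}
    for a in "ACGU":
        for b in "ACGU":
            for c in "ACGU":
                anticodon = a + b + c
                codons = _decoded_codons(anticodon)
                if codons:
                    table[anticodon] = codons
    return table


def load_wobble_table(path=None) -> dict[str, list[str]]:
    """Read an anticodon -> codons table (TSV, codons comma-separated).

    Without a path the packaged standard table is used.
    """
    if path is None:
        ref = resources.files("rloopscape").joinpath("data/wobble_standard.tsv")
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    table: dict[str, list[str]] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        anticodon, codons = line.split("\t")
        table[anticodon] = codons.split(",")
    return table


def write_wobble_table(table: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("# anticodon\tcodons (comma-separated, DNA alphabet)\n")
        for anticodon in sorted(table):
            fh.write(f"{anticodon}\t{','.join(table[anticodon])}\n")


@dataclass
class AnticodonFamily:
    """tRNA genes sharing one anticodon, scored by genomic codon usage."""

    anticodon: str
    gene_ids: list[str]
    codons: list[str]
    score: int
    rank: int = 0


def rank_anticodons(
    usage: Mapping[str, int],
    trna_genes: Sequence[GeneModel],
    wobble: Mapping[str, Sequence[str]] | None = None,
) -> list[AnticodonFamily]:
    """Group tRNA genes into anticodon families ranked by codon usage.

    The family score is the sum of genomic codon counts over the codons the
    anticodon decodes; rank 1 is the highest score, ties broken by
    anticodon lexicographic order.
    """
    if wobble is None:
        wobble = load_wobble_table()
    members: dict[str, list[str]] = {}
    for gene in trna_genes:
        if gene.anticodon is None:
            raise ValueError(f"tRNA gene {gene.gene_id} has no anticodon")
        if gene.anticodon not in wobble:
            raise ValueError(
                f"anticodon {gene.anticodon!r} (gene {gene.gene_id}) absent from wobble table"
            )
        members.setdefault(gene.anticodon, []).append(gene.gene_id)
    families = [
        AnticodonFamily(
            anticodon=ac,
            gene_ids=sorted(gids),
            codons=list(wobble[ac]),
            score=sum(usage.get(c, 0) for c in wobble[ac]),
        )
        for ac, gids in members.items()
    ]
    families.sort(key=lambda f: (-f.score, f.anticodon))
    for i, fam in enumerate(families, 1):
        fam.rank = i
    return families


@dataclass
class TrnaHeatmap:
    """Families x positional bins of fold-change over tRNA genes +/- flanks."""

    row_labels: list[str]          # "rank:anticodon"
    values: np.ndarray             # (n_rows, n_bins)
    n_flank_bins: int
    body_bins: int
    comparison: str

    @property
    def body_slice(self) -> slice:
        return slice(self.n_flank_bins, self.n_flank_bins + self.body_bins)

    @property
    def boundary_bins(self) -> tuple[int, int]:
        """Bin indices of the mature-tRNA 5' and 3' boundaries (for the
        dotted-line annotation)."""
        return (self.n_flank_bins, self.n_flank_bins + self.body_bins)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"# comparison={self.comparison} flank_bins={self.n_flank_bins} "
                f"body_bins={self.body_bins}\n"
            )
            for label, row in zip(self.row_labels, self.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def _gene_profile(
    track: EnrichmentTrack, gene: GeneModel, flank: int, body_bins: int
) -> np.ndarray:
    w = track.window_size
    span = gene.span
    clen = track.contig_lengths[gene.contig]
    if span.start - flank < 0 or span.end + flank > clen:
        log.warning("tRNA gene %s: flank truncated at contig end", gene.gene_id)
    scores = track.scores[gene.contig]
    up = per_base_from_windows(scores, w, span.start - flank, span.start)
    body = per_base_from_windows(scores, w, span.start, span.end)
    dn = per_base_from_windows(scores, w, span.end, span.end + flank)
    if gene.strand == "-":
        up, dn = dn[::-1], up[::-1]
        body = body[::-1]
    return np.concatenate([fixed_bins(up, w), rescale_bins(body, body_bins), fixed_bins(dn, w)])


def trna_heatmap(
    numerator: EnrichmentTrack,
    denominator: EnrichmentTrack,
    families: Sequence[AnticodonFamily],
    genes: Mapping[str, GeneModel],
    flank: int = 1000,
    body_bins: int = 4,
    epsilon: float = 0.01,
    per_gene: bool = False,
    comparison: str = "numerator/denominator",
) -> TrnaHeatmap:
    """Per-family fold-change profiles over tRNA genes with 1 kb flanks.

    Per gene, the transcription-oriented profile covers [-flank, body,
    +flank] (flanks at fixed 50 bp resolution, body scaled to
    ``body_bins``); the per-bin value is (numerator + eps)/(denominator +
    eps) and the family row is the mean across member genes (or one row per
    gene with ``per_gene``).
    """
    n_flank_bins = flank // numerator.window_size
    labels: list[str] = []
    rows: list[np.ndarray] = []
    for fam in sorted(families, key=lambda f: f.rank):
        gene_rows = []
        for gid in fam.gene_ids:
            gene = genes[gid]
            num = _gene_profile(numerator, gene, flank, body_bins)
            den = _gene_profile(denominator, gene, flank, body_bins)
            gene_rows.append((num + epsilon) / (den + epsilon))
        if per_gene:
            for gid, row in zip(fam.gene_ids, gene_rows):
                labels.append(f"{fam.rank}:{fam.anticodon}:{gid}")
                rows.append(row)
        else:
            labels.append(f"{fam.rank}:{fam.anticodon}")
            rows.append(np.nanmean(np.vstack(gene_rows), axis=0))
    return TrnaHeatmap(
        row_labels=labels,
        values=np.vstack(rows),
        n_flank_bins=n_flank_bins,
        body_bins=body_bins,
        comparison=comparison,
    )
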