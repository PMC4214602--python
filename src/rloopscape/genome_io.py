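"""Genome, annotation and track I/O plus derived interval structures.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive GFF3 convention happens only at the file boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "Contig",
    "Interval",
    "GeneModel",
    "AnnotationSet",
    "load_genome",
    "write_genome",
    "load_annotation",
    "write_annotation_gff3",
    "write_annotation_bed12",
    "derive_intergenic",
    "merge_intervals",
    "write_track",
    "read_bedgraph",
]

_VALID_BASES = frozenset("ACGTN")
GENE_CLASSES = ("protein_coding", "tRNA", "rRNA_like", "retroelement", "mito", "other")


@dataclass(frozen=True)
class Contig:
    """A named DNA sequence over the alphabet {A,C,G,T,N}."""

    name: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.contig == other.contig
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """A gene with its exon structure, held in transcription orientation.

    ``exons`` are ordered 5'->3' along the transcript: for a minus-strand
    gene the first exon is the one with the greatest genomic start.
    """

    gene_id: str
    gene_class: str
    strand: str
    exons: tuple[Interval, ...]
    is_rpg: bool = False
    anticodon: str | None = None

    def __post_init__(self) -> None:
        if self.gene_class not in GENE_CLASSES:
            raise ValueError(f"unknown gene_class {self.gene_class!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id} has no exons")
        contigs = {e.contig for e in self.exons}
        if len(contigs) > 1:
            raise ValueError(f"gene {self.gene_id} has exons on multiple contigs")
        genomic = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(genomic, genomic[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id} has overlapping exons")
        expected = genomic if self.strand == "+" else genomic[::-1]
        if tuple(expected) != self.exons:
            raise ValueError(
                f"gene {self.gene_id}: exons not in transcription order"
            )

    @property
    def contig(self) -> str:
        return self.exons[0].contig

    @property
    def is_spliced(self) -> bool:
        return len(self.exons) >= 2

    @property
    def n_introns(self) -> int:
        return len(self.exons) - 1

    @property
    def span(self) -> Interval:
        start = min(e.start for e in self.exons)
        end = max(e.end for e in self.exons)
        return Interval(self.contig, start, end, self.strand)

    @property
    def introns(self) -> tuple[Interval, ...]:
        genomic = sorted(self.exons, key=lambda e: e.start)
        out = [
            Interval(self.contig, a.end, b.start, self.strand)
            for a, b in zip(genomic, genomic[1:])
        ]
        if self.strand == "-":
            out = out[::-1]
        return tuple(out)


@dataclass
class AnnotationSet:
    """Genes plus the derived intergenic complement and excluded loci."""

    genes: list[GeneModel]
    intergenic: list[Interval] = field(default_factory=list)
    excluded_loci: list[Interval] = field(default_factory=list)

    def by_id(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def genes_of_class(self, gene_class: str) -> list[GeneModel]:
        return [g for g in self.genes if g.gene_class == gene_class]

    def with_intergenic(self, contigs: Mapping[str, Contig]) -> "AnnotationSet":
        return AnnotationSet(
            genes=self.genes,
            intergenic=derive_intergenic(self.genes, contigs),
            excluded_loci=list(self.excluded_loci),
        )


# ---------------------------------------------------------------------------
# FASTA


def load_genome(fasta_path: str | os.PathLike) -> dict[str, Contig]:
    """Read a multi-record FASTA into a name -> Contig map.

    Sequences are uppercased and must contain only A, C, G, T or N.
    Duplicate names, empty sequences, and non-DNA characters are hard errors.
    """
    contigs: dict[str, Contig] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise ValueError(f"duplicate FASTA record name {rec.id!r}")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"empty sequence for FASTA record {rec.id!r}")
        bad = set(seq) - _VALID_BASES
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise ValueError(
                f"record {rec.id!r}: invalid character {seq[pos]!r} at position {pos}"
            )
        contigs[rec.id] = Contig(rec.id, seq)
    if not contigs:
        raise ValueError(f"no FASTA records found in {fasta_path}")
    return contigs


def write_genome(contigs: Mapping[str, Contig], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for contig in contigs.values():
            fh.write(f">{contig.name}\n")
            seq = contig.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Annotation


def _check_gene_bounds(gene: GeneModel, contigs: Mapping[str, Contig] | None) -> None:
    if contigs is None:
        return
    if gene.contig not in contigs:
        raise ValueError(f"gene {gene.gene_id}: unknown contig {gene.contig!r}")
    clen = contigs[gene.contig].length
    for e in gene.exons:
        if e.end > clen:
            raise ValueError(
                f"gene {gene.gene_id}: exon [{e.start},{e.end}) outside contig "
                f"{gene.contig} (length {clen})"
            )


def load_annotation(
    path: str | os.PathLike,
    dialect: str = "gff3",
    contigs: Mapping[str, Contig] | None = None,
) -> AnnotationSet:
    """Load gene models from GFF3 or BED12 (genes only; intergenic empty)."""
    if dialect == "gff3":
        genes = _load_gff3(path)
    elif dialect == "bed12":
        genes = _load_bed12(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    for g in genes:
        _check_gene_bounds(g, contigs)
    return AnnotationSet(genes=genes)


def _load_gff3(path: str | os.PathLike) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneModel] = []
    for feat in db.features_of_type("gene"):
        exon_feats = sorted(
            db.children(feat, featuretype="exon"), key=lambda f: f.start
        )
        if not exon_feats:
            # single-exon gene recorded without explicit exon children
            exon_feats = [feat]
        ivals = [
            Interval(f.seqid, f.start - 1, f.end, feat.strand) for f in exon_feats
        ]
        if feat.strand == "-":
            ivals = ivals[::-1]
        attrs = feat.attributes
        genes.append(
            GeneModel(
                gene_id=feat.id,
                gene_class=attrs.get("gene_class", ["other"])[0],
                strand=feat.strand,
                exons=tuple(ivals),
                is_rpg=attrs.get("is_rpg", ["0"])[0] in ("1", "true", "True"),
                anticodon=attrs["anticodon"][0] if "anticodon" in attrs else None,
            )
        )
    return genes


def _load_bed12(path: str | os.PathLike) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: BED12 requires 12 fields")
            chrom, start, _end, name, _score, strand = f[0], int(f[1]), int(f[2]), f[3], f[4], f[5]
            n_blocks = int(f[9])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise ValueError(f"{path}:{lineno}: blockCount mismatch")
            parts = name.split("|")
            gene_id = parts[0]
            gene_class = parts[1] if len(parts) > 1 and parts[1] else "other"
            is_rpg = len(parts) > 2 and parts[2] == "1"
            anticodon = parts[3] if len(parts) > 3 and parts[3] else None
            ivals = [
                Interval(chrom, start + off, start + off + size, strand)
                for off, size in zip(offsets, sizes)
            ]
            if strand == "-":
                ivals = ivals[::-1]
            genes.append(
                GeneModel(
                    gene_id=gene_id,
                    gene_class=gene_class,
                    strand=strand,
                    exons=tuple(ivals),
                    is_rpg=is_rpg,
                    anticodon=anticodon,
                )
            )
    return genes


def write_annotation_gff3(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in annotation.genes:
            span = g.span
            attrs = f"ID={g.gene_id};gene_class={g.gene_class};is_rpg={int(g.is_rpg)}"
            if g.anticodon:
                attrs += f";anticodon={g.anticodon}"
            fh.write(
                f"{g.contig}\trloopscape\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, e in enumerate(sorted(g.exons, key=lambda e: e.start), 1):
                fh.write(
                    f"{g.contig}\trloopscape\texon\t{e.start + 1}\t{e.end}\t.\t"
                    f"{g.strand}\t.\tID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


def write_annotation_bed12(annotation: AnnotationSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for g in annotation.genes:
            span = g.span
            exons = sorted(g.exons, key=lambda e: e.start)
            sizes = ",".join(str(e.length) for e in exons)
            offsets = ",".join(str(e.start - span.start) for e in exons)
            name = f"{g.gene_id}|{g.gene_class}|{int(g.is_rpg)}|{g.anticodon or ''}"
            fh.write(
                f"{g.contig}\t{span.start}\t{span.end}\t{name}\t0\t{g.strand}\t"
                f"{span.start}\t{span.end}\t0\t{len(exons)}\t{sizes}\t{offsets}\n"
            )


# ---------------------------------------------------------------------------
# Interval algebra


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted, disjoint, strandless list."""
    by_contig: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[Interval] = []
    for contig in sorted(by_contig):
        ivs = sorted(by_contig[contig], key=lambda iv: iv.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(contig, cur_s, cur_e, "."))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(contig, cur_s, cur_e, "."))
    return out


def derive_intergenic(
    genes: Sequence[GeneModel], contigs: Mapping[str, Contig]
) -> list[Interval]:
    """Strandless complement of the union of gene spans over every contig.

    The background used for normalization is everything not annotated as a
    gene; introns count as genic.
    """
    merged = merge_intervals(g.span for g in genes)
    by_contig: dict[str, list[Interval]] = {}
    for iv in merged:
        by_contig.setdefault(iv.contig, []).append(iv)
    out: list[Interval] = []
    for name in contigs:
        clen = contigs[name].length
        pos = 0
        for iv in by_contig.get(name, []):
            if iv.start > pos:
                out.append(Interval(name, pos, iv.start, "."))
            pos = max(pos, iv.end)
        if pos < clen:
            out.append(Interval(name, pos, clen, "."))
    return out


# ---------------------------------------------------------------------------
# Track I/O


def write_track(
    values: Mapping[str, np.ndarray],
    contig_lengths: Mapping[str, int],
    path: str | os.PathLike,
    fmt: str = "bedgraph",
    window_size: int = 50,
) -> None:
    """Write fixed-window values as bedGraph or fixedStep wiggle.

    Adjacent equal-valued windows are deliberately not merged so the fixed
    window grid survives a round trip.
    """
    if fmt not in ("bedgraph", "wig"):
        raise ValueError(f"unknown track format {fmt!r}")
    with open(path, "w") as fh:
        for contig, vals in values.items():
            clen = contig_lengths[contig]
            n_win = -(-clen // window_size)
            if len(vals) != n_win:
                raise ValueError(
                    f"{contig}: expected {n_win} windows, got {len(vals)}"
                )
            if fmt == "bedgraph":
                for i, v in enumerate(vals):
                    s = i * window_size
                    e = min(s + window_size, clen)
                    fh.write(f"{contig}\t{s}\t{e}\t{v:.6f}\n")
            else:
                fh.write(
                    f"fixedStep chrom={contig} start=1 step={window_size} "
                    f"span={window_size}\n"
                )
                for v in vals:
                    fh.write(f"{v:.6f}\n")


def read_bedgraph(path: str | os.PathLike, window_size: int = 50) -> dict[str, np.ndarray]:
    """Read a fixed-grid bedGraph back into per-contig window arrays."""
    per_contig: dict[str, list[tuple[int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            contig, s, _e, v = line.split("\t")
            per_contig.setdefault(contig, []).append((int(s), float(v)))
    out: dict[str, np.ndarray] = {}
    for contig, rows in per_contig.items():
        rows.sort()
        starts = np.array([r[0] for r in rows])
        if np.any(np.diff(starts) != window_size) or starts[0] != 0:
            raise ValueError(f"{contig}: windows not on a fixed {window_size} bp grid")
        out[contig] = np.array([r[1] for r in rows], dtype=float)
    return out
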