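"""Per-gene and metagene summaries of R-loop enrichment.

Covers the per-gene mean-enrichment boxplot inputs with two-sample
Kolmogorov-Smirnov comparisons, the expression-based gene grouping
(C1-0 ... C4-max), exon1-intron-exon2 metagene profiles of spliced genes
with the 5'-anchor rule, whole-gene profiles, exon-2 summary statistics,
and ChIP-QPCR ddCt arithmetic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import kolmogorov

from ._binning import fixed_bins, per_base_from_windows, rescale_bins
from .coverage import EnrichmentTrack
from .genome_io import GeneModel, Interval

__all__ = [
    "gene_mean_enrichment",
    "ExpressionGrouping",
    "group_by_expression",
    "KSResult",
    "ks_two_sample",
    "MetageneMatrix",
    "metagene_spliced",
    "metagene_whole_gene",
    "exon2_boxplot_stats",
    "whole_gene_log2fc",
    "QpcrSample",
    "qpcr_relative_enrichment",
    "anchored_exon1_segment",
    "load_expression",
    "write_expression",
    "DEFAULT_EPSILON",
    "SPLICED_BINS",
]

log = logging.getLogger(__name__)

DEFAULT_EPSILON = 0.01
SPLICED_BINS = (10, 20, 20)  # exon1, intron, exon2
ANCHOR_UPSTREAM = 100  # bp upstream of the 5' splice site for short exon 1


# ---------------------------------------------------------------------------
# per-gene enrichment


def _per_base_scores(track: EnrichmentTrack, contig: str, start: int, end: int) -> np.ndarray:
    return per_base_from_windows(track.scores[contig], track.window_size, start, end)


def gene_mean_enrichment(
    track: EnrichmentTrack, gene: GeneModel, exons_only: bool = False
) -> float:
    """Base-weighted mean window score over the gene span (or exons only)."""
    if gene.contig not in track.scores:
        raise ValueError(f"track has no contig {gene.contig}")
    if exons_only:
        spans: Sequence[Interval] = gene.exons
    else:
        spans = [gene.span]
    num = 0.0
    n = 0
    for iv in spans:
        vals = _per_base_scores(track, gene.contig, iv.start, iv.end)
        ok = ~np.isnan(vals)
        num += vals[ok].sum()
        n += int(ok.sum())
    if n == 0:
        raise ValueError(f"gene {gene.gene_id} has no track coverage")
    return num / n


# ---------------------------------------------------------------------------
# expression grouping


@dataclass
class ExpressionGrouping:
    """Expression-rank partition of genes into C1..C4 with the C1-0 and
    C4-max sub-groups (C1-0 within C1, C4-max within C4)."""

    groups: dict[str, list[str]]
    n_high: int
    n_very_high: int
    near_zero_threshold: float

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.groups.items()}

    def group_of(self) -> dict[str, str]:
        """gene_id -> main group (C1..C4)."""
        out = {}
        for name in ("C1", "C2", "C3", "C4"):
            for gid in self.groups[name]:
                out[gid] = name
        return out


# main-group proportions observed on a 5864-gene annotation; scaled to the
# table actually supplied
_REF_TOTAL, _REF_HIGH, _REF_VERY_HIGH = 5864, 500, 90


def group_by_expression(
    expression: Mapping[str, float] | pd.Series,
    n_high: int | None = None,
    n_very_high: int | None = None,
    near_zero_threshold: float = 0.05,
) -> ExpressionGrouping:
    """Partition genes by expression rank into C1 <= C2 <= C3 < C4.

    The top ``n_high`` genes form C4 (its top ``n_very_high`` also C4-max);
    the remainder is split into three equal tertiles C1/C2/C3 with any
    remainder assigned to the lower groups.  Ties are broken
    lexicographically by gene id for determinism.
    """
    series = pd.Series(dict(expression)) if not isinstance(expression, pd.Series) else expression
    total = len(series)
    if n_high is None:
        n_high = round(total * _REF_HIGH / _REF_TOTAL)
    if n_very_high is None:
        n_very_high = round(total * _REF_VERY_HIGH / _REF_TOTAL)
    if n_high >= total:
        raise ValueError("n_high must be smaller than the number of genes")
    order = sorted(series.index, key=lambda gid: (series[gid], gid))
    rest = order[: total - n_high]
    c4 = order[total - n_high :]
    c4max = c4[len(c4) - n_very_high :]
    base, r = divmod(len(rest), 3)
    n1 = base + (1 if r >= 1 else 0)
    n2 = base + (1 if r >= 2 else 0)
    c1 = rest[:n1]
    c2 = rest[n1 : n1 + n2]
    c3 = rest[n1 + n2 :]
    c10 = [gid for gid in c1 if series[gid] <= near_zero_threshold]
    return ExpressionGrouping(
        groups={"C1-0": c10, "C1": c1, "C2": c2, "C3": c3, "C4": c4, "C4-max": list(c4max)},
        n_high=n_high,
        n_very_high=n_very_high,
        near_zero_threshold=near_zero_threshold,
    )


def load_expression(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", comment="#", names=["gene_id", "expression"], header=0)
    if (df["expression"] < 0).any():
        raise ValueError("expression values must be non-negative")
    return df.set_index("gene_id")["expression"]


def write_expression(expression: pd.Series, path) -> None:
    expression.rename("expression").rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> KSResult:
    """Two-sample KS statistic with the asymptotic two-sided p-value.

    D is the supremum distance between the two ECDFs; p is taken from the
    Kolmogorov distribution at sqrt(n1*n2/(n1+n2)) * D.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    fx = np.searchsorted(x, pooled, side="right") / n1
    fy = np.searchsorted(y, pooled, side="right") / n2
    d = float(np.max(np.abs(fx - fy)))
    en = n1 * n2 / (n1 + n2)
    p = float(kolmogorov(math.sqrt(en) * d))
    return KSResult(D=d, p=min(max(p, 0.0), 1.0), n1=n1, n2=n2)


# ---------------------------------------------------------------------------
# metagene matrices


@dataclass
class MetageneMatrix:
    """Features x positional bins of enrichment or log2 fold-change.

    Rows are transcription-oriented: bin 0 is the 5'-most bin regardless of
    genomic strand.  ``segments`` names the consecutive bin blocks.
    """

    gene_ids: list[str]
    segments: tuple[tuple[str, int], ...]
    values: np.ndarray
    aggregation: str = "mean"
    description: str = ""

    def __post_init__(self) -> None:
        n_bins = sum(n for _, n in self.segments)
        if self.values.shape != (len(self.gene_ids), n_bins):
            raise ValueError("matrix shape does not match gene_ids x bins")

    def segment_slice(self, name: str) -> slice:
        start = 0
        for seg, n in self.segments:
            if seg == name:
                return slice(start, start + n)
            start += n
        raise KeyError(name)

    def aggregate(self, how: str | None = None) -> np.ndarray:
        how = how or self.aggregation
        if how == "mean":
            return np.nanmean(self.values, axis=0)
        if how == "median":
            return np.nanmedian(self.values, axis=0)
        raise ValueError(f"unknown aggregation {how!r}")

    def to_tsv(self, path) -> None:
        header = ";".join(f"{name}:{n}" for name, n in self.segments)
        with open(path, "w") as fh:
            fh.write(f"# bins\t{header}\taggregation={self.aggregation}\n")
            cols = "\t".join(
                f"{name}.{i}" for name, n in self.segments for i in range(n)
            )
            fh.write(f"gene_id\t{cols}\n")
            for gid, row in zip(self.gene_ids, self.values):
                fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def anchored_exon1_segment(gene: GeneModel) -> Interval:
    """Exon-1 window for the spliced-gene metagene.

    The 5' end is the start codon when exon 1 is >= 100 bp; for shorter
    first exons it is 100 bp upstream of the 5' splice site, so the window
    always ends at the 5' splice site.
    """
    e1 = gene.exons[0]
    if e1.length >= ANCHOR_UPSTREAM:
        return e1
    if gene.strand == "+":
        start = e1.end - ANCHOR_UPSTREAM
        if start < 0:
            log.warning("gene %s: exon-1 anchor truncated at contig start", gene.gene_id)
            start = 0
        return Interval(gene.contig, start, e1.end, "+")
    return Interval(gene.contig, e1.start, e1.start + ANCHOR_UPSTREAM, "-")


def _segment_bins(
    track: EnrichmentTrack, contig: str, iv: Interval, n_bins: int, flip: bool
) -> np.ndarray:
    vals = _per_base_scores(track, contig, iv.start, iv.end)
    if flip:
        vals = vals[::-1]
    return rescale_bins(vals, n_bins)


def metagene_spliced(
    ip: EnrichmentTrack,
    input_track: EnrichmentTrack,
    genes: Sequence[GeneModel],
    bins: tuple[int, int, int] = SPLICED_BINS,
    epsilon: float = DEFAULT_EPSILON,
) -> MetageneMatrix:
    """log2(ChIP/input) profile across exon1-intron-exon2 of one-intron genes.

    Each segment is rescaled to its configured bin count by base-weighted
    averaging of window scores; genes with more than one intron are skipped
    with a warning.
    """
    rows = []
    ids = []
    for gene in genes:
        if not gene.is_spliced:
            continue
        if gene.n_introns > 1:
            log.warning("gene %s has %d introns; skipped", gene.gene_id, gene.n_introns)
            continue
        e1 = anchored_exon1_segment(gene)
        intron = gene.introns[0]
        e2 = gene.exons[1]
        if e2.length < 1:
            raise ValueError(f"gene {gene.gene_id}: empty exon 2")
        flip = gene.strand == "-"
        row = []
        for iv, n_bins in zip((e1, intron, e2), bins):
            b_ip = _segment_bins(ip, gene.contig, iv, n_bins, flip)
            b_in = _segment_bins(input_track, gene.contig, iv, n_bins, flip)
            row.append(np.log2((b_ip + epsilon) / (b_in + epsilon)))
        rows.append(np.concatenate(row))
        ids.append(gene.gene_id)
    if not rows:
        raise ValueError("no one-intron spliced genes supplied")
    return MetageneMatrix(
        gene_ids=ids,
        segments=(("exon1", bins[0]), ("intron", bins[1]), ("exon2", bins[2])),
        values=np.vstack(rows),
        description="log2((ip+eps)/(input+eps)) per bin",
    )


def metagene_whole_gene(
    track: EnrichmentTrack,
    genes: Sequence[GeneModel],
    flank: int = 0,
    n_bins: int = 40,
    aggregation: str = "mean",
) -> MetageneMatrix:
    """Gene bodies scaled to ``n_bins``; flanks (if any) at fixed 50 bp."""
    w = track.window_size
    n_flank_bins = flank // w
    rows = []
    ids = []
    for gene in genes:
        span = gene.span
        flip = gene.strand == "-"
        body = _segment_bins(track, gene.contig, span, n_bins, flip)
        if n_flank_bins:
            up_iv = (span.start - flank, span.start)
            dn_iv = (span.end, span.end + flank)
            if flip:
                up_iv, dn_iv = dn_iv, up_iv
            up = _per_base_scores(track, gene.contig, *up_iv)
            dn = _per_base_scores(track, gene.contig, *dn_iv)
            if flip:
                up, dn = up[::-1], dn[::-1]
            row = np.concatenate([fixed_bins(up, w), body, fixed_bins(dn, w)])
        else:
            row = body
        rows.append(row)
        ids.append(gene.gene_id)
    if not rows:
        raise ValueError("no genes supplied")
    segments = (("body", n_bins),)
    if n_flank_bins:
        segments = (
            ("upstream", n_flank_bins),
            ("body", n_bins),
            ("downstream", n_flank_bins),
        )
    return MetageneMatrix(
        gene_ids=ids,
        segments=segments,
        values=np.vstack(rows),
        aggregation=aggregation,
        description="enrichment per bin",
    )


def exon2_boxplot_stats(
    matrix: MetageneMatrix, genes: Mapping[str, GeneModel]
) -> pd.DataFrame:
    """Per-gene mean log2 fold-change over exon-2 bins, labelled by gene
    group (RPG vs NRPG spliced genes) for downstream KS comparisons."""
    sl = matrix.segment_slice("exon2")
    rows = []
    for gid, row in zip(matrix.gene_ids, matrix.values):
        gene = genes[gid]
        group = "RPG i-genes" if gene.is_rpg else "NRPG i-genes"
        rows.append((gid, float(np.nanmean(row[sl])), group))
    return pd.DataFrame(rows, columns=["gene_id", "exon2_mean_log2fc", "group"])


def whole_gene_log2fc(
    ip: EnrichmentTrack,
    input_track: EnrichmentTrack,
    genes: Sequence[GeneModel],
    epsilon: float = DEFAULT_EPSILON,
) -> pd.DataFrame:
    """Per-gene log2 ratio of mean ChIP to mean input enrichment over the
    whole gene span (the intronless-gene analogue of the exon-2 table)."""
    rows = []
    for gene in genes:
        m_ip = gene_mean_enrichment(ip, gene)
        m_in = gene_mean_enrichment(input_track, gene)
        rows.append((gene.gene_id, math.log2((m_ip + epsilon) / (m_in + epsilon))))
    return pd.DataFrame(rows, columns=["gene_id", "mean_log2fc"])


# ---------------------------------------------------------------------------
# ChIP-QPCR ddCt


@dataclass(frozen=True)
class QpcrSample:
    """Ct cycle values for one QPCR target across the three ChIP channels."""

    target: str
    ct_input: float
    ct_beads: float
    ct_ip: float

    def __post_init__(self) -> None:
        for name in ("ct_input", "ct_beads", "ct_ip"):
            v = getattr(self, name)
            if v is None or not np.isfinite(v) or v <= 0:
                raise ValueError(f"{self.target}: missing or invalid {name}")


def qpcr_relative_enrichment(
    samples: Sequence[QpcrSample], reference: str
) -> pd.DataFrame:
    """ddCt relative recovery per target, normalized to a reference locus.

    Raw ratios are 2^-(Ct_channel - Ct_input) for the S9.6 IP and beads-only
    channels; both are divided by the reference target's corresponding
    ratio, so the reference reports exactly 1 (the usual CEN16 convention:
    a locus with no transcription gives background-only signal).
    """
    by_target = {s.target: s for s in samples}
    if reference not in by_target:
        raise ValueError(f"reference target {reference!r} not present")
    raw = {
        s.target: (
            2.0 ** -(s.ct_ip - s.ct_input),
            2.0 ** -(s.ct_beads - s.ct_input),
        )
        for s in samples
    }
    ref_ip, ref_noab = raw[reference]
    rows = []
    for s in samples:
        ip, noab = raw[s.target]
        rows.append(
            (
                s.target,
                ip,
                noab,
                1.0 if s.target == reference else ip / ref_ip,
                1.0 if s.target == reference else noab / ref_noab,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["target", "ip_raw", "noab_raw", "ip_relative", "noab_relative"],
    ).set_index("target")
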