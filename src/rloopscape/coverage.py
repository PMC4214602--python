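"""From aligned reads to intergenic-mean normalized enrichment tracks.

The pipeline follows the ChIP-seq normalization scheme: reads are extended
3'-ward to the estimated sonication fragment length (200 bp), fragment
coverage is averaged into fixed 50 bp windows, each window is smoothed to
the mean per-base coverage of the 100 bp centered on it, and the smoothed
depth is divided by the mean depth of intergenic windows covered by at
least one read.  Scores > 1 are above the sequencing background.

Window values are carried as exact numerator/denominator pairs (integer
base-coverage sums over integer base counts) and the background as an exact
rational, so enrichment scores are single correctly-rounded divisions.
Duplicating every read r times scales every numerator by exactly r and
leaves the scores bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome_io import Contig, Interval, write_track

__all__ = [
    "ReadSet",
    "DepthTrack",
    "EnrichmentTrack",
    "BackgroundDepth",
    "read_bed6",
    "write_bed6",
    "resolve_multimappers",
    "exclude_loci",
    "extend_and_bin",
    "smooth",
    "intergenic_mean",
    "normalize",
    "DEFAULT_SEED",
]

WINDOW_SIZE = 50
FRAGMENT_LENGTH = 200
DEFAULT_SEED = 1004716

_READ_COLUMNS = ["contig", "start", "strand", "read_length", "n_hits"]


@dataclass
class ReadSet:
    """Stranded single-end read 5'-end positions with mapping multiplicity.

    ``reads`` is a DataFrame with columns contig, start (0-based 5'-end
    position in genome orientation), strand, read_length, n_hits.
    ``candidates`` maps a row index of a multimapping read to its full
    candidate-location list [(contig, start, strand), ...].
    """

    reads: pd.DataFrame
    candidates: dict[int, list[tuple[str, int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in _READ_COLUMNS if c not in self.reads.columns]
        if missing:
            raise ValueError(f"read table missing columns {missing}")
        if len(self.reads) and (self.reads["n_hits"] < 1).any():
            raise ValueError("n_hits must be >= 1")

    def __len__(self) -> int:
        return len(self.reads)

    @property
    def n_multimappers(self) -> int:
        return int((self.reads["n_hits"].to_numpy() > 1).sum())


def read_bed6(path, sidecar=None) -> ReadSet:
    """Read aligned reads from BED6; the score column carries n_hits.

    ``sidecar`` optionally names a TSV mapping the read name to its
    comma-separated candidate list ``contig:start:strand``.
    """
    rows = []
    names = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            contig, s, e, name, score, strand = line.split("\t")[:6]
            s, e = int(s), int(e)
            start = s if strand == "+" else e - 1  # 5' end in genome orientation
            rows.append((contig, start, strand, e - s, int(score)))
            names.append(name)
    reads = pd.DataFrame(rows, columns=_READ_COLUMNS)
    candidates: dict[int, list[tuple[str, int, str]]] = {}
    if sidecar is not None:
        by_name = {n: i for i, n in enumerate(names)}
        with open(sidecar) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, cand_str = line.split("\t")
                cands = []
                for item in cand_str.split(","):
                    contig, start, strand = item.rsplit(":", 2)
                    cands.append((contig, int(start), strand))
                candidates[by_name[name]] = cands
    return ReadSet(reads=reads, candidates=candidates)


def write_bed6(readset: ReadSet, path, sidecar=None) -> None:
    df = readset.reads
    with open(path, "w") as fh:
        for i, (contig, start, strand, rlen, n_hits) in enumerate(
            zip(df["contig"], df["start"], df["strand"], df["read_length"], df["n_hits"])
        ):
            s = start if strand == "+" else start - rlen + 1
            fh.write(f"{contig}\t{s}\t{s + rlen}\tread{i}\t{n_hits}\t{strand}\n")
    if sidecar is not None:
        with open(sidecar, "w") as fh:
            for idx, cands in sorted(readset.candidates.items()):
                cand_str = ",".join(f"{c}:{s}:{st}" for c, s, st in cands)
                fh.write(f"read{idx}\t{cand_str}\n")


def resolve_multimappers(readset: ReadSet, mode: str, seed: int = DEFAULT_SEED) -> ReadSet:
    """Collapse multimapping reads to a single location, or drop them.

    mode="random": one candidate kept per read, chosen uniformly with a
    seeded generator (the genome-wide default).  mode="unique_only": reads
    with n_hits > 1 are removed (used for the tRNA-family heatmaps, where
    cross-assignment between isogenes must be excluded).
    """
    if mode not in ("random", "unique_only"):
        raise ValueError(f"unknown multimapper mode {mode!r}")
    df = readset.reads
    multi = df["n_hits"].to_numpy() > 1
    if mode == "unique_only":
        return ReadSet(reads=df.loc[~multi].reset_index(drop=True))
    rng = np.random.default_rng(seed)
    if not multi.any():
        return ReadSet(reads=df.reset_index(drop=True))
    df = df.copy()
    contig_col = df.columns.get_loc("contig")
    start_col = df.columns.get_loc("start")
    strand_col = df.columns.get_loc("strand")
    for idx in np.flatnonzero(multi):
        cands = readset.candidates.get(idx)
        if not cands:
            raise ValueError(f"multimapping read {idx} has no candidate list")
        contig, start, strand = cands[rng.integers(len(cands))]
        df.iat[idx, contig_col] = contig
        df.iat[idx, start_col] = start
        df.iat[idx, strand_col] = strand
    return ReadSet(reads=df.reset_index(drop=True))


def _read_spans(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Genomic [start, end) spans covered by the reads themselves."""
    start = df["start"].to_numpy()
    rlen = df["read_length"].to_numpy()
    plus = (df["strand"] == "+").to_numpy()
    s = np.where(plus, start, start - rlen + 1)
    return s, s + rlen


def exclude_loci(readset: ReadSet, excluded: Sequence[Interval]) -> ReadSet:
    """Drop reads whose aligned span overlaps any excluded interval.

    Mirrors the removal of rDNA-mapped reads before all downstream analysis.
    """
    if not excluded:
        return readset
    df = readset.reads
    s, e = _read_spans(df)
    drop = np.zeros(len(df), dtype=bool)
    by_contig: dict[str, list[Interval]] = {}
    for iv in excluded:
        by_contig.setdefault(iv.contig, []).append(iv)
    for contig, ivs in by_contig.items():
        ivs = sorted(ivs, key=lambda iv: iv.start)
        starts = np.array([iv.start for iv in ivs])
        ends = np.array([iv.end for iv in ivs])
        on_contig = (df["contig"] == contig).to_numpy()
        # a read [s,e) overlaps some interval iff the first interval with
        # end > s exists and has start < e
        idx = np.searchsorted(ends, s[on_contig], side="right")
        hit = idx < len(ivs)
        hit[hit] &= starts[idx[hit]] < e[on_contig][hit]
        drop[on_contig] |= hit
    keep = df.loc[~drop].reset_index(drop=True)
    candidates = {}
    if readset.candidates:
        old_to_new = -np.ones(len(df), dtype=int)
        old_to_new[~drop] = np.arange(len(keep))
        for old, cands in readset.candidates.items():
            if not drop[old]:
                candidates[int(old_to_new[old])] = cands
    return ReadSet(reads=keep, candidates=candidates)


@dataclass
class DepthTrack:
    """Per-contig fragment coverage on a fixed 50 bp window grid.

    ``numerators[c][w]`` is the (integer-valued) sum of per-base fragment
    coverage over the bases contributing to window w, and
    ``denominators[c][w]`` the number of contributing bases, so the window
    depth in fragments/bp is numerators/denominators.  For the raw track
    the denominator is the window size for every window; after smoothing
    the contributing bases are the 100 bp centered on the window, clipped
    at contig ends.
    """

    window_size: int
    fragment_length: int
    contig_lengths: dict[str, int]
    numerators: dict[str, np.ndarray]
    denominators: dict[str, np.ndarray]
    base_coverage: dict[str, np.ndarray] | None = None
    raw_numerators: dict[str, np.ndarray] | None = None
    smoothed: bool = False

    def values(self, contig: str) -> np.ndarray:
        return self.numerators[contig] / self.denominators[contig]

    def all_values(self) -> dict[str, np.ndarray]:
        return {c: self.values(c) for c in self.numerators}

    def n_windows(self, contig: str) -> int:
        return len(self.numerators[contig])

    def raw_window_sums(self, contig: str) -> np.ndarray:
        """Pre-smoothing coverage sums, used for the >=1-read exclusion."""
        if self.raw_numerators is not None:
            return self.raw_numerators[contig]
        return self.numerators[contig]


def extend_and_bin(
    readset: ReadSet,
    contigs: Mapping[str, Contig] | Mapping[str, int],
    fragment_length: int = FRAGMENT_LENGTH,
    window_size: int = WINDOW_SIZE,
) -> DepthTrack:
    """Extend each read to the fragment length and bin coverage at 50 bp.

    A read becomes a fragment starting at its 5' end and extending 3'-ward
    in read orientation (minus-strand reads extend upstream in genome
    coordinates); fragments are clipped at contig bounds.
    """
    lengths = {
        name: (c.length if isinstance(c, Contig) else int(c))
        for name, c in contigs.items()
    }
    df = readset.reads
    if len(df) and fragment_length < int(df["read_length"].max()):
        raise ValueError("fragment_length shorter than the read length")
    base_cov: dict[str, np.ndarray] = {}
    numerators: dict[str, np.ndarray] = {}
    denominators: dict[str, np.ndarray] = {}
    for name, clen in lengths.items():
        on = (df["contig"] == name).to_numpy() if len(df) else np.zeros(0, bool)
        start = df["start"].to_numpy()[on]
        plus = (df["strand"] == "+").to_numpy()[on]
        frag_s = np.where(plus, start, start - fragment_length + 1)
        frag_e = frag_s + fragment_length
        bad = (start < 0) | (start >= clen)
        if bad.any():
            raise ValueError(f"read start outside contig {name}")
        frag_s = np.clip(frag_s, 0, clen)
        frag_e = np.clip(frag_e, 0, clen)
        diff = np.zeros(clen + 1, dtype=np.int64)
        np.add.at(diff, frag_s, 1)
        np.add.at(diff, frag_e, -1)
        cov = np.cumsum(diff[:-1])
        base_cov[name] = cov
        n_win = -(-clen // window_size)
        padded = np.zeros(n_win * window_size, dtype=np.int64)
        padded[:clen] = cov
        numerators[name] = padded.reshape(n_win, window_size).sum(axis=1)
        denominators[name] = np.full(n_win, window_size, dtype=np.int64)
    return DepthTrack(
        window_size=window_size,
        fragment_length=fragment_length,
        contig_lengths=lengths,
        numerators=numerators,
        denominators=denominators,
        base_coverage=base_cov,
    )


def smooth(track: DepthTrack) -> DepthTrack:
    """Replace each window by the mean per-base coverage of the 100 bp
    centered on it (window +/- half a window each side); windows at contig
    edges average only the bases that exist."""
    if track.smoothed:
        raise ValueError("track is already smoothed")
    if track.base_coverage is None:
        raise ValueError("smoothing requires per-base coverage")
    w = track.window_size
    half = w // 2
    numerators: dict[str, np.ndarray] = {}
    denominators: dict[str, np.ndarray] = {}
    for contig, cov in track.base_coverage.items():
        clen = track.contig_lengths[contig]
        n_win = track.n_windows(contig)
        csum = np.concatenate(([0], np.cumsum(cov)))
        ws = np.arange(n_win) * w
        lo = np.clip(ws - half, 0, clen)
        hi = np.clip(ws + w + half, 0, clen)
        numerators[contig] = csum[hi] - csum[lo]
        denominators[contig] = hi - lo
    return DepthTrack(
        window_size=w,
        fragment_length=track.fragment_length,
        contig_lengths=dict(track.contig_lengths),
        numerators=numerators,
        denominators=denominators,
        base_coverage=track.base_coverage,
        raw_numerators=dict(track.numerators),
        smoothed=True,
    )


@dataclass(frozen=True)
class BackgroundDepth:
    """Intergenic mean depth as an exact rational (fragments/bp)."""

    value: Fraction
    n_windows: int

    def __float__(self) -> float:
        return float(self.value)


def _intergenic_window_mask(track: DepthTrack, intergenic: Sequence[Interval]) -> dict[str, np.ndarray]:
    """Boolean mask of windows fully contained in an intergenic interval."""
    w = track.window_size
    masks = {
        c: np.zeros(track.n_windows(c), dtype=bool) for c in track.numerators
    }
    for iv in intergenic:
        if iv.contig not in masks:
            continue
        first = -(-iv.start // w)          # first window starting inside
        last = iv.end // w                 # windows [first, last) end inside
        clen = track.contig_lengths[iv.contig]
        # the trailing partial window of the contig is only contained if the
        # interval reaches the contig end
        n_win = track.n_windows(iv.contig)
        if last > n_win:
            last = n_win
        if last == n_win and n_win * w > clen and iv.end < clen:
            last -= 1
        if first < last:
            masks[iv.contig][first:last] = True
    return masks


def intergenic_mean(
    track: DepthTrack, intergenic: Sequence[Interval]
) -> BackgroundDepth:
    """Mean depth over intergenic windows covered by at least one read.

    Windows must lie fully inside an intergenic interval; windows with zero
    pre-smoothing coverage are excluded ("covered by at least 1 read").
    """
    masks = _intergenic_window_mask(track, intergenic)
    total = Fraction(0)
    count = 0
    for contig, mask in masks.items():
        covered = mask & (track.raw_window_sums(contig) > 0)
        nums = track.numerators[contig][covered]
        dens = track.denominators[contig][covered]
        for n, d in zip(nums.tolist(), dens.tolist()):
            total += Fraction(n) / Fraction(d)
        count += int(covered.sum())
    if count == 0:
        raise ValueError(
            "no intergenic window with coverage; simulate or sequence deeper"
        )
    return BackgroundDepth(value=total / count, n_windows=count)


@dataclass
class EnrichmentTrack:
    """Dimensionless window scores: smoothed depth / intergenic mean."""

    window_size: int
    contig_lengths: dict[str, int]
    scores: dict[str, np.ndarray]
    intergenic_mean: float

    def n_windows(self, contig: str) -> int:
        return len(self.scores[contig])

    def to_bedgraph(self, path) -> None:
        write_track(self.scores, self.contig_lengths, path, "bedgraph", self.window_size)

    def to_wig(self, path) -> None:
        write_track(self.scores, self.contig_lengths, path, "wig", self.window_size)


def normalize(track: DepthTrack, bg: BackgroundDepth | float) -> EnrichmentTrack:
    """Divide every window depth by the intergenic background level.

    Given a BackgroundDepth the division is performed on exact rationals
    (one correctly-rounded float division per window), making the scores
    invariant under exact scaling of all read counts.
    """
    if float(bg) <= 0:
        raise ValueError("background depth must be positive")
    scores: dict[str, np.ndarray] = {}
    if isinstance(bg, BackgroundDepth):
        bn, bd = bg.value.numerator, bg.value.denominator
        for contig in track.numerators:
            nums = track.numerators[contig].tolist()
            dens = track.denominators[contig].tolist()
            if np.issubdtype(track.numerators[contig].dtype, np.integer):
                scores[contig] = np.array(
                    [(int(n) * bd) / (int(d) * bn) for n, d in zip(nums, dens)]
                )
            else:
                # exact rationals still: floats are binary rationals
                scores[contig] = np.array(
                    [
                        float(Fraction(n) * bd / (Fraction(d) * bn))
                        for n, d in zip(nums, dens)
                    ]
                )
    else:
        for contig in track.numerators:
            scores[contig] = track.values(contig) / float(bg)
    return EnrichmentTrack(
        window_size=track.window_size,
        contig_lengths=dict(track.contig_lengths),
        scores=scores,
        intergenic_mean=float(bg),
    )


def reads_to_enrichment(
    readset: ReadSet,
    contigs: Mapping[str, Contig] | Mapping[str, int],
    intergenic: Sequence[Interval],
    excluded: Sequence[Interval] = (),
    mode: str = "random",
    seed: int = DEFAULT_SEED,
    fragment_length: int = FRAGMENT_LENGTH,
    apply_smoothing: bool = True,
) -> EnrichmentTrack:
    """Full read -> enrichment pipeline in the canonical order: resolve
    multimappers, drop excluded loci, extend+bin, smooth, normalize by the
    intergenic mean."""
    rs = resolve_multimappers(readset, mode=mode, seed=seed)
    rs = exclude_loci(rs, list(excluded))
    track = extend_and_bin(rs, contigs, fragment_length=fragment_length)
    if apply_smoothing:
        track = smooth(track)
    bg = intergenic_mean(track, intergenic)
    return normalize(track, bg)
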