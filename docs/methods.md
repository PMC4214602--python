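# Methods

## Coverage model and normalization

Reads are single-end 5′ tags of sonicated fragments. Each read is extended
3′-ward in read orientation to the estimated fragment length (default
200 bp; minus-strand reads therefore extend upstream in genome
coordinates) and clipped at contig bounds; contigs, including the
mitochondrial one, are treated as linear. Per-base fragment coverage is
averaged into fixed 50 bp windows (the trailing partial window is divided
by the full window size, so a 30 bp tail at depth 1 scores 0.6). Smoothing
replaces each window by the mean per-base coverage of the 100 bp centered
on it — the window plus 25 bp on each side — with contig-edge windows
averaging only the bases that exist. This single centered mean was chosen
over a cascade of a per-base moving average followed by window averaging:
the latter double-smooths (triangular kernel), while the centered mean
reproduces a window's stated smoothed value directly.

The background level *b* is the mean depth of 50 bp windows that lie fully
inside the intergenic complement (everything not spanned by an annotated
gene; introns count as genic) and have non-zero pre-smoothing coverage.
The zero-coverage exclusion is applied at window granularity on the raw
depth, because windows are the unit everywhere else in the pipeline, and
the mean itself is taken on the smoothed depth by default (a flag selects
the raw depth instead). Window scores are depth/*b*.

### Exact arithmetic

Window depths are carried as integer numerator/denominator pairs (sum of
per-base counts over contributing bases) and *b* as an exact rational;
each score is a single correctly-rounded division of exact integers.
Duplicating every read r times multiplies every numerator by exactly r,
which cancels in the rational quotient, so enrichment scores are
bit-identical under exact scaling of the read set — a structural guarantee
rather than a tolerance. Division by a non-positive background, or a
background computed from zero qualifying windows, is a hard error rather
than a NaN track.

## Multimapping reads and excluded loci

A multimapping read carries its full candidate-location list. Genome-wide
tracks assign one location uniformly at random with a seeded generator
(default seed 1004716, a CLI flag); tRNA-family heatmaps drop multimappers
entirely so hits at one isogene cannot be attributed to another family
member. Reads whose aligned span overlaps an excluded locus (the rDNA-like
repeat in the simulations) are removed before binning.

## Gene profiles

Per-gene enrichment is the base-weighted mean of window scores over the
gene span (exons+introns; a flag restricts to exons). Expression classes
are rank-based: the top `n_high` genes form C4 (its top `n_very_high` also
C4-max) and the rest split into three equal tertiles C1/C2/C3, remainder
to the lower groups; ties break lexicographically by gene id so the
partition is a deterministic, permutation-invariant function of the
(id, value) multiset. Defaults scale the 1788/1788/1788/500 partition of a
5864-gene annotation proportionally to the table supplied. C1-0 is the
subset of C1 at or below a near-zero expression threshold (default
0.05 reads per exon base).

The two-sample KS statistic is the exact sup-distance between ECDFs; the
p-value is the asymptotic Kolmogorov tail at sqrt(n₁n₂/(n₁+n₂))·D, without
finite-sample continuity corrections — D is the quantity the comparisons
rest on, and the asymptotic p keeps the formula transparent.

Spliced-gene metagenes use exactly one intron per gene (multi-intron genes
are skipped with a warning). The exon-1 window runs from the anchor to the
5′ splice site: the anchor is the start codon when exon 1 is at least
100 bp, otherwise 100 bp upstream of the 5′ splice site, so short first
exons contribute a fixed-width promoter-proximal window. Segments are
rescaled to 10/20/20 bins (exon1/intron/exon2; configurable — the bin
counts are a resolution choice comparable to 50 bp windows on typical
yeast genes, not a fixed constant of the method) by base-weighted averaging via
cumulative sums, which makes the width-weighted mean of a gene's bins
equal its plain span mean to rounding error. Matrix entries are
log₂((ChIP+ε)/(input+ε)) with ε = 0.01 enrichment units (configurable);
the pseudocount only matters for windows near zero coverage and cancels
exactly when numerator and denominator tracks coincide. Minus-strand genes
are flipped so bin 0 is always transcriptionally 5′; because binning uses
cumulative sums, mirror-image inputs agree to ~1e-12 rather than bitwise
(summation order reverses).

ΔΔCt arithmetic: raw recovery is 2^−(Ct_channel − Ct_input) for the S9.6
and beads-only channels; both are divided by the reference target's
corresponding ratio, so the reference (a non-transcribed centromeric
locus) reports exactly 1 by construction.

## tRNA anticodon families

Codon usage counts every sense codon across all protein-coding CDS read in
transcription orientation (reverse complement on the minus strand); CDS
whose length is not a multiple of three or that contain an internal stop
are logged and skipped, and stop codons are excluded. The wobble table
ships as an editable TSV generated from standard eukaryotic decoding
rules — Watson–Crick pairing plus G34:U, U34:{A,G}, C34:G only, and A34
read as inosine decoding {U,C,A} — rather than hard-coding decoding inside
the ranking. A family's score is the raw genomic count sum over its
decoded codons; families sort descending with lexicographic tie-break and
receive ranks 1..N. Heatmap rows are family means (a per-gene mode exists)
of (numerator+ε)/(denominator+ε) profiles over 20+4+20 bins (1 kb flanks
at 50 bp, body rescaled); flanks truncated by a contig end contribute NaN
bins which are excluded from family means.

## Duplex stability (ΔG₉) and G+C

ΔG₉ is the sum of the 8 dinucleotide-step ΔG°₃₇ values of each
non-overlapping 9-base window, anchored at the transcription-oriented 5′
end of the span; tails shorter than 9 nt are discarded, windows containing
N are emitted as missing. The DNA/DNA steps use the unified
oligonucleotide parameters (SantaLucia 1998); the hybrid steps use the
RNA/DNA parameters of Sugimoto et al. (1995), keyed by the RNA-strand
dinucleotide of the nascent transcript (coding strand with U) paired to
the template. Initiation and terminal corrections are deliberately
omitted: ΔG₉ is a comparative per-window score, not a melting prediction,
and the 8-step stack sum preserves all between-window contrasts. More
negative means more stable. G+C is counted in non-overlapping 100 bp
windows excluding N from the denominator. Both statistics map into the
same metagene frames as the enrichment profiles by overlap weighting.

## Synthetic data

The generator is the package's test bed and defines its study conditions.
Defaults: two nuclear contigs (800 kb + 700 kb) and a 90 kb AT-rich
mitochondrial contig; 60 tRNA genes of 100–160 bp (GC 0.55, anticodons
drawn from a 20-anticodon pool so families have multiple members); 60
one-intron coding genes alternating short (30–99 bp) and long (100–250 bp)
first exons — short-exon1 genes are flagged as ribosomal-protein genes —
with introns of 80–400 bp and second exons of ~0.5–1.5 kb whose GC target
sits 0.15 above exon 1 (0.55 vs 0.40); 60 intronless genes; 8
sequence-identical 2 kb retroelement copies (the multimapping source); a
tandem pair of identical 3 kb rDNA-like units recorded as the exclusion
list; 3 mitochondrial genes. Coding sequences are real ORFs (ATG, sense
codons sampled with GC-targeted weights, one stop), so the codon-usage
stage runs on the emitted FASTA unmodified. Genes are placed with 4–6 kb
spacing; sequencing uses 50 bp reads, 200 bp fragments, a mean depth of 30
fragments/bp and Poisson counts (negative binomial with dispersion 0.1
available; a separate deterministic-depth mode emits the noiseless
expectation for exact normalization checks). Enrichment folds over the
intergenic background, per condition: wild type {exon2 2, tRNA 1.5,
retroelement 1, mito 1}; RNase H null {exon2 2, tRNA 6, retroelement 4,
mito 4}; the rDNA-like class is set high (8) but excluded from scoring.

The enrichment model applies a feature's fold to every fragment that
overlaps it (taking the maximum over overlapped features), so the expected
interior coverage equals fold × depth regardless of feature length — with
a start-position-only model, features shorter than the fragment (every
tRNA gene) could never reach their nominal fold. A fold below 1 instead
depletes, and 0 vetoes, every overlapping fragment, so a silenced feature
yields no interior reads. Two consequences are worth knowing when reading
recovery numbers: enriched fragments bleed up to 200 bp into flanks, and
those flanks are intergenic, so the measured background is inflated by a
few percent at the default geometry and recovered folds sit systematically
~5 % below truth; and the input channel is exactly fold-blind by
construction.

What the simulator does **not** emulate: sequencing errors and quality
scores, GC-dependent amplification bias, fragment-length variation,
chromatin accessibility structure, copy-number differences of the rDNA
array, positional enrichment shape within a feature (folds are flat per
sub-feature), or correlated biological replicates. Passing tests therefore
demonstrate that the pipeline arithmetic recovers planted structure under
idealized noise — not that the biological signal in real data is correctly
modelled.

## Numerical and degenerate-input choices

Coordinates are 0-based half-open internally; GFF3 conversion happens only
at the file boundary, and round-trips reproduce original coordinates
exactly. Interval complements come from sorted merges; an empty gene list
returns whole contigs. Binning uses cumulative sums with fractional edges
(NaN-aware: missing bases drop out of both numerator and weight). The
fixed-grid bedGraph writer never merges equal-valued windows so the 50 bp
grid survives a round trip at six decimals. Problem sizes in the test
suite and the acceptance script (a ~1.6 Mb genome at depth 30, ~280 k
reads per channel; smaller genomes for unit tests) were chosen so the
medians being tested rest on at least ~50–1000 windows per class while a
full run stays in the seconds-to-a-minute range.

## Known limitations

GFF3 input expects `gene` features with `exon` children and the
`gene_class`/`is_rpg`/`anticodon` attributes the writers emit; BED12
carries the same metadata packed into the name field. Only single-end
reads are supported (no duplicate removal, no GC correction). Spliced-gene
metagenes handle exactly one intron. The mitochondrial contig is linear
for read extension; whether a circular treatment is preferable is left
open, and at the simulated sizes the difference is confined to two
windows per contig end.
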