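# Methods

## Coordinate frame and read anatomy

All positions are ORF-relative on the coding strand: 0-based, half-open,
with position 0 at the first nucleotide of the start codon; upstream (5′
UTR) positions are negative. Genomic projection — splicing of exon blocks,
reverse complementation of minus-strand genes, clipping of flanks at contig
ends — happens once, at reference load. Each ORF model carries its coding
sequence (start through stop codon), ≥60-nt flanks, and an optional genomic
placement. Overlapping ORFs are allowed and counted independently; this is
the simplest reproducible rule where annotation practice varies.

Footprint reads are poly-A-tailed: the sequenced read is the protected
fragment followed by an in-vitro adenosine tail. Footprint length is
inferred by stripping the maximal trailing-A run and checking the reference
base at the inferred boundary: if it is an A the tail start cannot be
located and the read's length is **ambiguous**. This includes reads whose
footprint itself ends in genomic adenosines and reads that match the
reference end-to-end but end in A — in every such case a shorter footprint
plus a tail beginning on a genomic A is equally consistent, so no length can
be assigned. Ambiguous reads are excluded from all length-specific analyses
but retained in the unsplit pool used for expression counting. On random
(uniform-composition) sequence this excludes ≈44% of reads (1 − 0.75²);
the exclusion is position-specific around A-rich codons and produces the
characteristic density dip ~10–13 nt upstream of AAA codons in queuing
metaplots (a computational artifact, not biology — the package reproduces
it because real libraries show it).

Reads are placed by exact match of their 5′ 21-mer against the reference
(unique hits only; collisions and misses are dropped with counts).
Mismatch-tolerant, genome-scale alignment is deliberately out of scope:
the placer serves synthetic references and pre-mapped 5′-end tables from an
external aligner are accepted as input.

## P-site calibration

For each read length L ∈ {25..31}, the 5′-end metagene relative to start
codons is built over the window [−40, +20) nt. Initiating ribosomes hold
the start codon in their P site, so the modal upstream peak at distance d
gives the P-site offset for that length; the frame shift into the 28-mer
frame is offset(28) − d (negative = 3′-ward shift). Calibration demands at
least 200 start-proximal reads per length and a peak ≥3× the mean upstream
background; both thresholds are configurable (the window and background
criterion are this package's choices — the source analysis names the peak
but not its detection rule). Ties are broken toward the published
28-mer-consistent distance. On failure the caller may fall back to the
fixed published table (25:0, 26:0, 27:0, 28:0, 29:−1, 30:−1, 31:−2 relative
to the 12-nt 28-mer offset), with a warning recorded.

Pooling applies the frame shift to every non-ambiguous record and
accumulates two per-ORF count layers over [−60, L+30): `shifted` (28-mer
frame, length-specific analyses) and `unsplit` (raw positions, all retained
reads, expression counting). No operation creates counts; every drop is
logged with exact totals.

## Metacodon profiles and bulk occupancy

The 21-position window for an instance at first-nt c covers 5′-end
positions [c−21, c); with the 12-nt 28-mer offset this maps window peaks to
ribosomal sites as {0:−2, 3:−1, 6:A, 9:P, 12:E, 15:+1, 18:+2} (−2/−1 hold
codons the ribosome has not yet reached; +1/+2 codons that have exited the
E site). The normalizer is the arithmetic mean of the four outer-site
*peak* values (indices 0, 3, 15, 18): codon identity is not expected to
influence dwell in the outer sites, and peak-value averaging matches a
normalization stated in terms of peak heights. Instances within 7 codons of
either ORF end are excluded so the full window and the ±2-site codons lie
in covered track space (an explicit design choice; the sums could instead
run to the ORF edge). Amino-acid-pair metaplots extend the window by one
codon (24 positions, origin at the first codon of the pair) so that index 9
corresponds to the first codon in P and the second in A simultaneously;
their outer sites are indices {0, 3, 18, 21}.

Bulk occupancy ratios between identically processed samples are reported
per (codon, site) with log2 values; zero or missing denominators propagate
as flagged NaNs rather than errors.

## Single-codon occupancy and K-S comparison

Occupancy of a codon instance in site k is the in-frame 5′-end count at the
site's position (A: 15, P: 12, E: 9 nt upstream of the codon's first nt;
±1/±2 continue in 3-nt steps) divided by the gene's mean in-frame read
density. For the denominator, an in-frame 5′ end at position p is
attributed to its A-site codon (index (p+15)/3), so numerator and
denominator share one site frame and uniform coverage gives occupancy
exactly 1. The first 4 codons and codons with no in-frame reads are
excluded from both the record set and the denominator's codon count.
Records require a positive numerator, so occupancy is always > 0 and scale
invariance holds exactly under per-gene count scaling. Replicates are
pooled by positionwise count addition *before* any occupancy computation.

Genome-wide distributions per (codon, site) are compared between conditions
with the two-sample two-sided K-S test: exact p-values (scipy's exact
method, verified against exhaustive label-arrangement enumeration for
n₁+n₂ ≤ 8) when min(n₁, n₂) ≤ 10, asymptotic otherwise. The 61 × 7 grid is
reported raw — no multiple-testing correction — matching how such grids are
usually displayed; significance calling for expression lives with an
external count-model tool and is out of scope here.

Per-instance fold changes (mutant/WT occupancy, instances matched by gene,
codon index and site, both occupancies positive) are binned by WT numerator
reads in half-open log2 bins of width 0.2, with per-codon-set means per
bin. The read-support filter (default ≥32 reads) is configurable as
"each" (both conditions) or "combined" (summed) because the source
descriptions of the threshold differ between displays; the mode used is
carried in output metadata.

## Queuing metaplots

Candidates are AAA/CAA instances with fold change ≥2 and adequate read
support. For each candidate the surrounding window ([−45, +30] nt; one
footprint width upstream plus margin — no window is published) is aligned
so position 0 holds the codon in the A site (5′ ends at codon start − 15),
counts are divided by the host ORF's mean per-nt density, and each window
position is divided by the number of candidates whose host ORF covers it.
Two stated normalizations differ by a per-gene constant (mean per-nt
density vs total gene reads); mean per-nt density is used because it makes
a uniform-coverage gene exactly flat at 1, and the choice is recorded in
output metadata. "Covers" means the ORF interval [0, L) in track
coordinates, applied to numerator and denominator alike. A stacked trailing
ribosome appears as a secondary peak at −(5′-to-5′ spacing); with 28-mer
reads the injected-geometry recovery is exact.

The initiation-limited argument the queuing analysis feeds: at the cited
mean density of one ribosome per 164 nt, ribosomes are ~54.7 codons apart,
so a stall must outlast the translation time of ~50 codons before
elongation, not initiation, limits output on an average transcript.

## Expression and enrichment

Window counting uses the unsplit pool over [3·8 − 12, L_stop − 14) =
[12, L_stop − 14): the 8-codon head exclusion dominates the 12-nt upstream
pad at the 5′ side because the head exclusion applies to all expression
calculations; both pads and the exclusion are configurable. RPKM is
window reads / (window length in kb) / (library ORF-window reads in
millions); tiny ORFs with empty windows are flagged and excluded from the
library total. Per-gene log2 fold changes average positionally paired
replicates; a configurable minimum-expression filter drops genes failing in
any sample (counted). RNA-seq reads are counted under the same window rules
as footprints, keeping fold-change comparisons symmetric. Enrichment: the
upper-tail hypergeometric P(X ≥ overlap) over an explicit background (the
background definition — genes with confident expression in all datasets —
is configurable and recorded with every result, since no precise filter is
published); target-set shifts use the two-sample K-S test with per-group
median fold changes reported on the linear scale.

## The simulator: what it emulates, and what it does not

The generator is the analysis run backwards. A ribosome's P-site codon
position is drawn with probability ∝ gene flux × Π over the seven sites of
the dwell multiplier of the codon occupying that site; dwell effects are
multiplicative across sites (additive pair effects on dwell *time* are
multiplicative on sampling rates, which is why a 2× P-site and a 2× A-site
multiplier compound to ~4× for an adjacent pair). Positions whose 7-codon
context leaves the ORF are excluded. Footprint lengths follow a
configurable distribution (default 28-mer-dominated: 25:0.02, 26:0.06,
27:0.15, 28:0.45, 29:0.20, 30:0.08, 31:0.04, roughly the shape of real
nuclease digests); 5′ ends are deterministic given length via the standard
offsets {25–28: 12, 29: 13, 30: 13, 31: 14}, consistent with the published
shift table. Poly-A tails are ≥4 nt with a short-tailed default
distribution. A configurable fraction of reads (default 0.1) comes from
initiating ribosomes with the start codon in the P site, emulating the
start-codon accumulation seen in cycloheximide-treated cells — without it
the start-codon metagene would carry no calibration peak. Queue injection
adds, per leading read whose A site is at a designated stall position and
with configurable probability, one trailing read at a fixed 5′-to-5′
spacing. RNA-seq controls place 5′ ends uniformly per transcript with
gene weights ∝ abundance × length.

The regime is initiation-limited: positions are sampled independently, with
no explicit ribosome traffic or exclusion (no TASEP), no digestion jitter
by default, no sequencing errors, no rRNA contamination, no multimapping
ambiguity beyond exact 21-mer collisions, and no UMI structure. Passing
recovery tests therefore demonstrates the correctness of the positional
arithmetic, normalizations and statistics — not robustness to mapping
artifacts or traffic effects in real libraries.

## Problem sizes and numerical choices

Recovery tests use 6–50 genes of 60–250 codons and 2×10⁵–10⁶ reads per
library — sizes at which a 1.5× single-site multiplier is recovered within
±10% and the three perturbed codon–site pairs rank strictly first among all
427 K-S comparisons, while the whole suite stays interactive. The
acceptance script uses 10–20 genes and 5×10⁴–2.5×10⁵ reads per library,
routing calibration targets through FASTQ emission and sequence-level read
placement. All randomness flows through explicit integer seeds
(numpy default_rng); reruns are byte-identical. Degenerate inputs fail
loudly and specifically: missing contigs, empty samples, zero library
totals, sets outside the enrichment background, and stall positions without
a host ORF all raise errors naming the offender, while zero outer-peak
means and unnormalizable profiles are flagged and propagated as missing
values rather than exceptions.

## Known limitations

- The 21-mer exact placer is for synthetic or pre-mapped data; real
  libraries should arrive as mapped 5′-end tables.
- A-site attribution in the occupancy denominator is a convention; any
  consistent site frame would do, but mixing frames between numerator and
  denominator would bias uniform-coverage genes away from 1.
- The K-S grid's raw p-values are a display convention; formal inference
  across 427 cells needs correction.
- Compositional effects of fixed sequencing depth propagate into RPKM fold
  changes (boosting one gene deflates the rest); no compositional
  normalization is applied.
- Bulk occupancy ratios for codons perturbed in one site pick up a small
  (~2–3% at 1.5× on three codons) genome-wide dilution through the outer
  -site normalizer; at the simulated effect sizes this stays well inside
  the recovery tolerances.
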