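# Methods notes

## Scope and data model

The package operates strictly downstream of array normalization: its inputs
are probe-level tables (chrom, span, fold enrichment vs whole-cell extract,
P[X̄]), a genome FASTA, a multi-isoform GFF3 annotation, PWM libraries,
per-system expression tables (gene, signed fold ratio, FDR-adjusted p), and a
cytological band map with a stained-locus list. All internal coordinates are
0-based half-open; emitted GFF3 is 1-based inclusive and BED 0-based
half-open, per those formats' specifications.

## Segment calling

The vendor error/neighborhood models that originally produced bound segments
are not reproduced. The caller here is a thresholded run-joiner: maximal runs
of probes with P[X̄] < 10⁻³, bridging at most one interior non-significant
probe, kept when at least two significant probes participate. Downstream
analyses consume segments as given, so the caller only needs to produce the
correct data shape and to recover planted truth, which it does exactly in the
noise-free limit (peak error 0, span edges within one probe spacing). The
peak is the center of the lowest-P[X̄] probe; ties break to the higher fold
change, then leftmost, making the assignment order-invariant.

Mock filtering drops a segment only when it is fully contained in the union
of overlapping mock segments *and* its min P[X̄] is not at least 100-fold
lower than the best overlapping mock segment's ("much stronger" is not
otherwise quantified; the worked example in the source data differs by ~10⁷,
so 100 is deliberately permissive). Every decision carries its reason.

## Match p-values

A PWM match p-value is the single-window, single-strand tail probability of
the log-odds score under an i.i.d. background, computed exactly on a
discretized score lattice (bin width 10⁻³) by positionwise convolution.
Scanning scores each window on the same lattice, so scan p-values and the
distribution agree bin-for-bin; the test suite checks them against exhaustive
enumeration for widths ≤ 6. No multiple-testing correction is applied inside
the scanner — the printed cut-offs (10⁻⁴, 10⁻⁵, 5×10⁻⁴) are per-match
thresholds, and the Bonferroni correction of the library screen applies to
the per-PWM chi-square p-values multiplied by library size (the alternative
reading — correcting the match p-values themselves — is available by passing
a scaled `p_match`). Background frequencies default to uniform; the
pseudocount defaults to 1% of the largest column total, which avoids −∞
scores without moving threshold crossings for well-populated matrices.
Windows containing N are skipped and counted. With a non-uniform,
non-complement-symmetric background the minus-strand null would differ
slightly from the plus-strand null; the default background is symmetric.

## Positional enrichment

Matches are binned by start offset into 50-bp windows over ±2500 bp of each
peak; a match straddling a boundary is not split. The center-vs-flank test
is a one-degree-of-freedom goodness-of-fit chi-square of counts in
−500..+500 against ±550..1000, with expectation proportional to the covered
interval lengths (1001:902 when untruncated — a 1:1 split would be biased by
the 11% length difference). Peaks near chromosome ends contribute truncated
scans, and the expectation is adjusted by the per-offset coverage the
histogram records. The test's type-I error is calibrated by simulation in the
acceptance suite (1000 uniform-null replicates). With zero total matches the
test is undefined and flagged rather than fabricated.

## Site classification

Promoters are bidirectional: within 1250 bp of any isoform TSS. Sites inside
a transcribed span are intragenic; those additionally near a TSS form the
ambiguous promoter-intragenic class; remaining intragenic sites are labeled
exon/intron ordinally on the nearest-TSS containing isoform. Non-intragenic
sites within 1250 bp of a TSS are intergenic promoters; within 1250 bp past a
3′ end, "downstream" (that radius is a convention — the source material uses
the label without defining one); otherwise intergenic. Signed TSS distances
are positive downstream of the TSS in transcription direction. Genome
composition (intragenic / promoter / intronic base-pair fractions) is
interval-union arithmetic, verified against a per-base brute-force oracle.

Cytological overlap forms, over all bands of the map, the 2×2 table of (band
within the offset tolerance of a site-bearing band, same chromosome) ×
(band in the stained-locus list), tested by Pearson chi-square, df=1, no
continuity correction. Band-index tolerance never crosses chromosomes. Using
all bands as the universe is a choice; a universe restricted to, e.g.,
gene-bearing bands can be emulated by subsetting the band map.

## Expression integration

Fold changes follow the signed-ratio convention (|r| ≥ 1, −1.5 = 1.5-fold
down); log2 conversion is internal. Differential calls use an inclusive
2-fold threshold and a strict FDR < 0.01, matching the wording of the
filters the tables were built with; Benjamini–Hochberg stands in for the
vendor's unnamed FDR method. All 2×2 tests are Pearson chi-squares without
continuity correction — validated by recovering the published p = 0.0198
from the insulator-binding-by-induction table (3/8 vs 66/38). "Induced" for
that analysis means up-calls in the cell system only. Clustering is
agglomerative with Manhattan distance and unweighted average linkage
(scipy's deterministic tie-breaking); term enrichment is a one-sided
hypergeometric tail with BH adjustment, with the background set supplied by
the caller (e.g. all intron-bearing genes for intron-site analyses).

## The synthetic study

The generator's defaults mirror the study conditions: 434 segments of
~1.4 kb; category mix 27% promoter / 35% intron / 10% exon / 28% intergenic;
a probe every 233 bp (60-mers) with ~1% of the genome repeat-masked,
including one always-planted super-gap ≥ 10× the spacing (so the
"nearest site beyond a probe desert" phenomenon is exercisable); HSE
consensus instances planted uniformly in −400..+300 bp of peaks; 81% of
segments retain RT binding attenuated 5-fold (per-segment log-normal ratio,
σ=0.10); per-system responsive fractions of 5% with 8% overlap; an
HSF-mutant system retaining 8 weakly induced genes; and insulator-motif
planting at 27% (induced) vs 66% (non-induced) of bound promoters with the
induced fraction set to 11/115.

Scale: 4 chromosomes × 2.25 Mb and 600 genes (uniform 4–8 kb lengths, 2–5
exons, Poisson-distributed alternative-TSS isoforms), chosen so the full
pipeline runs in seconds while transcribed sequence covers ~40% of the
genome, near the euchromatic figure the composition background refers to.
Gene lengths are uniform so the expected transcript coverage is available in
closed form for the coverage test.

Signal model: probe folds follow a semicircular profile `1 + (F−1)·√(1−(d/h)²)`
over each planted span (peak fold F ~ clipped log-normal, support 15–100)
with multiplicative log-normal noise (σ=0.15); P[X̄] is
`10^(−3(fold_clean−1))` with Gaussian noise (σ=0.5) on the exponent, clipped
to (10⁻³⁰⁵, 1]. The gain of 3 keeps the exponent above the double-precision
floor at fold 100, so P[X̄] is a strictly monotone transform of the clean
fold and the lowest-P[X̄] probe is exactly the highest-fold probe in the
noise-free limit. Nothing in the source data constrains these distributions;
log-normal is the conventional choice for ratio noise, and the parameters
are stipulated, not inferred.

Two constructions make recovery invariants well-posed. Planted peaks are
snapped to the nearest probe midpoint — a peak is by definition the center
of a probe, and without snapping, 233-bp quantization alone would exceed a
probe-length tolerance. And planted peaks are kept ≥ 5.4 kb apart so one
peak's planted elements never appear in a neighbor's ±2.5 kb scan window;
real data has clustered sites (adjacent heat-shock-gene arrays), which this
generator therefore does not emulate, and passing recovery tests say nothing
about peak deconvolution in such clusters.

Promoter-category peaks are placed within ±350 bp of the principal isoform's
TSS — HSF promoter binding is TSS-proximal — and insulator motifs are
planted 20–180 bp upstream of that same TSS, matching the reported
concentration of BEAF sites immediately upstream of TSSs. Motif *presence*
for the contingency analysis is therefore scanned over the first 200 bp
upstream of the principal TSS (both strands) at p < 5×10⁻⁴. A wider
(±1250 bp) presence scan at that cut-off would carry an O(1) chance-hit
probability per promoter and swamp the planted rates; even the 200-bp window
has an exactly computable chance-hit probability (~0.15 at the default
matrix), which the recovery analyses deconvolve rather than ignore. The
published presence percentages embed whatever chance-hit behavior the
original scans had; the planted probabilities here are plant rates, an
explicit modeling choice.

Other known limitations of the generator: no scanner/dye artifacts, no
amplification bias, no array normalization residue (all declared out of
scope); uniform base composition by default (configurable); expression noise
is a single log-normal dispersion with uniform null p-values rather than a
fitted error model; polytene staining intensities are decorative ordinals.

## Statistical power at the published scale

With 11 induced vs 104 non-induced bound promoters and presence rates of
27% vs 66%, the noncentrality of the df=1 chi-square is ≈6.4, giving
detection power ≈0.75 at α=0.05 (confirmed by simulation in the acceptance
suite). The association is therefore expected to be detected in most, but
not all, replicate studies at this scale; a single seeded run can fall on
either side of α. The acceptance suite states the stronger power bound it
aims for and reports the measured value honestly.

## Numerical conventions

Score lattice bin 10⁻³; chi-squares never use Yates correction; undefined
tests (zero totals, zero marginals) return flagged p=1 rather than raising;
BH adjustment is returned in input order; clustering rejects non-finite
input naming the offending genes; scans shorter than the matrix width return
empty match sets. All generator stages draw from per-stage generators seeded
deterministically from the config seed, so identical configurations produce
byte-identical output files.
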