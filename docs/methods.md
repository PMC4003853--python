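# Methods

## Model and assumptions

The package segments the genome of a pair of closely related inbred
strains into identity-by-descent (IBD) and divergent-ancestry regions
using only the *local density* of homozygous differences. The underlying
model is a two-regime mosaic: every base belongs either to a segment where
both strains inherited the same founder haplotype (differences are
post-separation mutations, rate ~5 × 10⁻⁶ per bp between strains) or to a
segment fixed from different founder haplotypes (differences at the
founder population's polymorphism density, ~1.5 × 10⁻³ per bp). Because the
two rates are separated by roughly three orders of magnitude, the
distribution of per-window difference density (OSD) over 100-kb windows is
bimodal, and a single threshold at the valley — the Polymorphism
Enrichment Threshold (PET) — classifies windows.

Assumptions this rests on:

* both strains are fully inbred, so genotype calls are homozygous and a
  difference is a fixed strain difference, not within-strain variation
  (heterozygous and missing calls are dropped, and counted in a filter
  log);
* segments are long relative to the window (the defaults assume ~0.2–1.5
  Mb divergent segments against 100-kb windows), so most windows are pure
  one-regime windows;
* coverage gaps are marked and excluded from the OSD denominator — a
  window's OSD is differences per *callable* base, where callable means
  outside the union of both strains' zero-coverage intervals.

## Pipeline stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `window_size` | 100,000 | bp | OSD window; fixed, non-overlapping tiling |
| `grid_points` | 401 | – | KDE grid resolution on [0, max OSD] |
| `bandwidth` | oversmoothed selector | OSD (bp⁻¹) | explicit override for the KDE |
| `min_callable_frac` | 0.10 | – | usable-window floor (fraction of window size) |
| `pet_override` | none | OSD (bp⁻¹) | skip valley detection, classify at this value |

**OSD.** Each retained SNV is assigned to exactly one window by
`(pos − 1) // window_size` (VCF positions are 1-based; all internal
intervals 0-based half-open, so position 100,000 belongs to window 0 and
100,001 to window 1). Windows whose callable bases fall below 10% of the
window size get an undefined OSD: they are excluded from density
estimation and break block runs, because a ratio over a few thousand bases
is too unstable to classify. The trailing partial window of each
chromosome is kept (with its smaller denominator) and flagged, so the
whole genome participates; blocks containing a partial window are excluded
from block-length statistics by default since their length is not a whole
number of windows.

**Density estimation.** The OSD values are smoothed by a binned kernel
density estimate: linear binning onto 401 equally spaced grid points,
then convolution with a Gaussian kernel. The default bandwidth is the
oversmoothed selector for the Gaussian kernel,

    h = (243 / (70 √π))^(1/5) · σ̂ · n^(−1/5) ≈ 1.1439 · σ̂ · n^(−1/5),

with σ̂ the sample standard deviation. Oversmoothing is deliberate: it is
an upper bound on the MISE-optimal bandwidth, so sampling wiggles are
suppressed and a detected valley reflects real bimodality. The grid spans
[0, max(OSD)] rather than a symmetric extension beyond the data: the IBD
spike sits at zero and must remain *inside* the first peak for the valley
rule to apply.

**Bandwidth floor (count discreteness).** OSD is a count ratio, so in a
comparison with little or no divergent sequence its values quantise to
0, 1/callable, 2/callable, …. The selector's σ̂ then collapses to that
quantisation scale and the kernel would resolve each integer-count spike
as a separate mode, manufacturing a valley at ~½ SNV per window inside
pure-IBD data (the reference binned-KDE implementation behaves
identically). Pipeline callers therefore floor the *selected* bandwidth at
the OSD quantum, 1/window_size (10⁻⁵ at the default window): structure
finer than one count cannot be evidence of a diversity class. Genuinely
bimodal comparisons are unaffected — at the study rates the selected
bandwidth is ~8× the floor. An explicit `bandwidth` override is always
honoured as given.

**PET detection.** Scanning the density from grid index 0 upward, a local
extremum is a point strictly greater (maximum) or smaller (minimum) than
both neighbours; runs of exactly equal values are collapsed to their first
index (deterministic, scan-order consistent), and the grid boundaries
count with their single neighbour. The PET is the grid value at the first
local minimum strictly after the first local maximum. If no maximum
exists, or no minimum follows it, the distribution is unimodal and a
`NoValleyError` is raised; the pipeline treats this as "no divergent class
detectable", completes with an empty block list, and flags the summary
`unimodal`.

**Block merging.** Maximal runs of adjacent windows (same chromosome, end
of one equals start of the next) with OSD ≥ PET become one divergent
haplotype block; undefined-OSD windows break runs. Raising the PET can
never increase total block length. Per-comparison summaries report windows
above the PET, block count and length mean/SD, the arithmetic mean window
OSD on each side of the PET, and the share of SNVs falling inside blocks.
The mean-OSD-per-side statistic is one of two defensible readings of a
per-regime "average OSD"; the locations of the two density modes are
exposed as an alternative (`density_peak_modes`) without asserting which a
given publication used. The PET is computed per comparison, never pooled
across pairs.

## Downstream mapping

**QTL intersection.** Narrowing = 100 − (% of QTL bases covered by
blocks). Genome-wide totals are computed on the union of the QTL
intervals, so bases shared by overlapping QTL count once; per-trait rows
keep the intervals separate.

**Genotyping-panel blocks.** A panel block spans from the monomorphic SNP
immediately left of a polymorphic run to the monomorphic SNP immediately
right of it (both flanking SNPs included; chromosome bounds substitute at
the edges). SNPs with a missing call in either strain are uninformative
and ignored. OSD blocks are classified against panel blocks by overlap
with their best partner: `novel` (no overlap), `refined` (strictly
inside a longer panel block), `extended` (reaching beyond the partner on
either side), `concordant` (same span). The label set is this package's
own reporting convention.

**Consequence filtering.** Class labels map to predictor output terms:
non_synonymous = {NON_SYNONYMOUS_CODING}, splice_site = {SPLICE_SITE,
ESSENTIAL_SPLICE_SITE}, frameshift = {FRAMESHIFT_CODING}, stop_gained =
{STOP_GAINED}. A variant annotated with terms from several wanted classes
is retained once with every matching label. Consequence prediction itself
is out of scope; its output is consumed as a table.

**Fisher enrichment.** Carrier status means homozygous for the minor
allele; strains with heterozygous or missing calls at a variant are
excluded from that variant's 2×2 table, with a logged count. Excluded
strains (e.g. reference-identical substrains, or strains with confounding
phenotypes) are removed from panel and groups before the table is built.
The two-tailed p-value follows the point-probability convention: the sum
of hypergeometric probabilities of all tables with the observed margins
whose probability is at most that of the observed table, with a 10⁻⁷
relative tie tolerance against floating-point near-ties. The
implementation enumerates the hypergeometric pmf directly; the test suite
checks it against an exact integer-combinatorics oracle (agreement
≤ 10⁻¹² for all margins ≤ 30) and against an independent library
implementation. No multiple-testing correction is applied by default
(raw p-values are reported); a Benjamini–Hochberg column is available via
`enrich_many(..., fdr=True)`.

## The synthetic-data generator

`simulate_mosaic` emulates, per strain pair and chromosome: alternating
shared/divergent segments — divergent lengths exponential with mean
`seg_length_mean` (default 0.9 Mb), truncated so their total is exactly
`divergent_fraction` (default 0.15) of the chromosome, starts placed by
uniform spacings; homozygous SNV differences as Poisson processes at
`rate_divergent` (1.5 × 10⁻³/bp) inside and `rate_ibd` (5 × 10⁻⁶/bp)
outside the segments, each difference carried by one randomly chosen
strain of the pair; and per-strain zero-coverage gaps (default 2% of the
genome, 5-kb mean length — sparse short gaps of the kind deep short-read
resequencing leaves) from independent random substreams, so changing the
gap parameters never moves a variant. One global seed drives
per-chromosome, per-purpose substreams keyed by name, so chromosome
iteration order cannot change results; the same seed is bit-reproducible.
The exponential segment-length law is this package's minimal-assumption
choice (a Poisson process of segment boundaries); real block-length
distributions are only summarised by their mean/SD in published tables
and may be heavier-tailed.

What the generator does **not** emulate: linkage phase, residual
within-strain heterozygosity, mutation spectra and context dependence,
coverage-correlated gap placement (real gaps cluster in repeats shared by
both strains), multi-strain genealogical consistency (each pair's mosaic
is drawn independently; strains outside the focal pair are written as
missing calls so pairwise comparisons stay independent), and read-level
error. Passing the recovery tests therefore shows the segmentation logic
is correct under the stated two-regime model, not that real data meet the
model's assumptions.

## Problem sizes and numerical checks

The validation suite runs at desk scale by design: parameter recovery
uses ten 50-Mb single-chromosome mosaics (500 windows each) at the study
rates — enough windows for a stable valley while keeping a full
ten-seed study in seconds. At this scale the detected PET sits higher
(~7 × 10⁻⁴) than in a 27,199-window genome-wide scan (~3.7 × 10⁻⁴)
because the oversmoothed bandwidth shrinks as n^(−1/5); block boundaries
are correspondingly slightly conservative, which the recovery thresholds
(Jaccard ≥ 0.90 against truth, ≥ 95% of SNVs inside blocks) account for.
The binned KDE is held to within 1% relative error of the exact
direct-sum estimate at every grid point on 500-value samples
(linear-binning error scales as (grid step / bandwidth)², ~5 × 10⁻⁴
here). Multi-allelic VCF records are decomposed into biallelic sites
before the homozygous-difference test; a site where the two strains are
homozygous for two *different* alternate alleles is dropped and counted
separately rather than double-counted (vanishingly rare in inbred
pairwise data). Indels pass through the same machinery but are tallied in
a separate stream throughout.

## Known limitations

* Window-quantised block boundaries: a block edge is resolved to 100 kb,
  so short divergent segments (< ~1 window after the callable-base floor)
  can be missed and boundary windows with mixed ancestry are classified
  by their average density.
* The valley rule needs both classes present in non-trivial proportions;
  very small divergent fractions leave too few supra-PET windows to form
  a distinct second peak.
* No HMM or multi-strain joint segmentation: each pair is analysed
  independently, matching the method's definition.
* The enrichment test treats strains as independent samples; shared
  pedigree among panel strains violates this, so p-values rank candidates
  rather than calibrate error rates.
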