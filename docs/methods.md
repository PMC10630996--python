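# Methods

## Coordinate conventions

Genomic coordinates are 0-based half-open (BED convention) everywhere;
GTF input (1-based closed) is converted at parse time. Positions within
an exon are negative offsets from the downstream, junction-side exon
boundary in transcript orientation: −1 is the junction-adjacent
nucleotide, −L the 5′-most base of an exon of length L (plus strand:
`g − end`; minus strand: `start − g − 1`). This makes "27 nt upstream of
the junction" the single position −27 on either strand.

One representative transcript is kept per gene: most exons, ties broken
by larger summed exonic length, remaining ties by lexicographically
smallest transcript id (the last rule is our determinism convention;
"exonic size" is read as summed exon length, not genomic span). Exons
are classed first/internal/last; single-exon transcripts form a fourth
class `single` — they undergo no splicing, so they are excluded from the
first/internal/last tallies rather than shoehorned into them.

## Detection models

**SRD (eCLIP).** Stop rate at a position counts only reads that either
arrest there (5′ end at the position) or read through it (cover it with
a 5′ end further upstream); reads ending 3′ of the position carry no
information about arrest at it and do not enter the denominator. The
per-replicate test against the pooled SMInput is the 2×2 Pearson
chi-square with 1 df and no continuity correction; a table with any zero
marginal is degenerate and assigned p = 1. Significance additionally
requires the replicate stop rate to exceed the control's (the test is
used one-sidedly), and ≥2 of 3 replicates must pass at α = 0.05. No
multiple-testing correction is applied at position level — the
replication requirement and the exon-level window are the specificity
mechanism, so isolated false-positive positions (≈0.1% of covered
positions) are expected and tolerated. The exon window is [−32, −23];
both bounds are used inclusively, and exons shorter than 32 nt are
scored on the truncated window and flagged. A secondary-signal analysis
runs identically with window [−22, −13] (same 10-nt half-width
convention around −18) and all-3-replicate significance.

Positions lacking control data use control rate 0 and are flagged;
positions lacking data in some replicate average the SRD over the
replicates that have data.

**ipaRt.** "Median coverage" is the median across window positions of
the per-position depth, computed per exon per library after discarding
zero-depth positions; a wholly uncovered window yields an undefined
median, and any undefined median makes the exon *undetected* (excluded),
not unloaded. The threshold is the 95th percentile of the enrichment
ratio among consistently detected last exons, by linear interpolation
between order statistics, raised to the next order statistic whenever
interpolation alone would leave more than 5% of the calibration ratios
strictly above it — the defining guarantee of an empirical null cut-off
(plain type-7 interpolation leaves up to one extra calibration exon
above the line at some sample sizes). At least 20 calibration exons are
required. The loaded call uses strict inequality.

**Integration.** Expression bins are equal-count (quantile) deciles of
per-exon RPKM with ties broken stably by exon id; equal-width bins would
be nearly empty at high RPKM. Peak agreement extends both peak sets by
5 nt per end, requires same-strand ≥1 bp overlap, counts intersections
from the first set's perspective and forms the union by
inclusion–exclusion; the count-based index is direction-dependent under
many-to-one overlaps, which is reported rather than hidden.

## The synthetic generator

The generator reproduces the data-generating process the analysis
assumes, with defaults chosen as a desk-scale image of a fly-like
experiment (~500 genes, 2–8 exons of 60–600 nt per gene, log-uniform
expression spanning two orders of magnitude, three IP replicates, two
controls, 120k reads per library, read length 35):

* **Deposition**: every first/internal exon of an expressed gene carries
  an EJC with probability `deposition_prob` (default 1); last/single
  exons never do.
* **eCLIP**: crosslink positions are drawn per loaded exon within the
  footprint [−32, −23] with weight `kernel(d) × u(d)`, where `kernel` is
  a Gaussian (sd 2 nt) centred on the canonical −27 contact point and
  `u(d)` is 10 for uridines, 1 otherwise; an exon whose footprint holds
  no uridine crosslinks at 0.25 efficiency. Truncation reads start
  exactly at the crosslink; with probability 0.15 the RT reads through
  and the 5′ end lands a geometric (p = 0.5) overshoot upstream of the
  crosslink. 10% of each eCLIP library is background. The positional
  kernel is what makes the aggregate 5′-end mode recover −27; with a
  flat within-footprint preference the mode would land on whichever
  position is uridine-richest, which contradicts the single canonical
  contact the model encodes.
* **SMInput / mRNA-seq**: fragments with 5′ ends uniform over exonic
  positions, gene weight ∝ expression × length.
* **ipaRt**: protected fragments spanning [−36, −10] with ±3 nt uniform
  end jitter, counts ∝ expression, plus the same 10% mRNA-like
  background admixture. The background is what gives last exons enough
  window coverage to serve as the calibration null; a RIP library
  without mRNA contamination would make the empirical threshold
  uncomputable (and does not exist in practice).
* Per-library read totals are exact (multinomial allocation); all
  randomness derives from one integer seed through fixed-purpose child
  seeds, so equal configurations give byte-identical outputs. Reads are
  emitted as aligned BED6 confined to single exons; sequencing errors,
  junction-spanning reads, PCR duplicates and alternative splicing are
  deliberately absent.

What passing recovery tests therefore shows: the statistics recover the
geometry and the per-exon truth *under the assay model's own
assumptions* (clean alignments, single-isoform annotation, stationary
background). They do not certify performance against mapping artefacts,
isoform ambiguity, or structured background in real libraries.

## Problem sizes and numerical choices

The test suite runs the full pipeline at 500 genes (default conditions;
meta-exon peak recovery, calibration, integration), 500 genes with
`deposition_prob = 0.5` (sensitivity ≥ 0.9 on loaded above-median-
expression exons, false-positive rates ≤ 5% on unloaded internal and on
last exons), and 3000 genes with proportionally scaled depth for the
bias stratifications — chosen so the few-percent effects between
uridine strata are resolvable; uridine counts are pooled into strata
{0, 1, ≥2} because exact higher counts hold too few exons to order
reliably at any realistic scale. Expression deciles for stratified
rates are computed over first/internal exons only, mirroring the
exclusion of last exons from the rate tables. Profile peak ties resolve
toward the junction; read midpoints use floor((rel5′+rel3′)/2); the
profile scale factor 10⁶ is cosmetic (all downstream uses are
shape-based). Chi-square p-values are computed in closed form and
match `scipy.stats.chi2_contingency(correction=False)` to 1e-12.

## Known limitations

The A-perspective Jaccard can exceed 1 under many-to-one peak overlaps
(visible, not masked). The SRD route's sensitivity is intrinsically
expression- and uridine-limited — on synthetic data as on real data,
low-expression exons fall below the significance floor, which is
precisely the bias the integration stage is there to overcome. PureCLIP
peak calling is consumed as external BED input only; UMI handling,
demultiplexing and mapping are upstream of this package's scope.
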