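# Methods

`enhancerscape` implements a histone-mark ChIP-seq analysis of the enhancer
landscape: from aligned tags to a catalogue of cis-regulatory elements, with
differential H3K27ac quantification corrected for immunoprecipitation (IP)
efficiency, super-enhancer and transcribed-region classification,
GC-corrected motif enrichment, and enhancer-to-gene expression linkage.
This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.

## Tag preprocessing

An aligned read is reduced to a *tag*: a single-bp signal position at half
the typical fragment size from the read's 5' end (+ strand tags move
+`fragment_size`//2, − strand tags move the opposite way; the half-fragment
rounds toward zero for odd sizes). The default `fragment_size` of 160 bp
sits in the middle of the 140–180 bp range typical of sonicated/MNase ChIP
libraries. Coordinates are 0-based and half-open throughout; genome bins are
`[i*1000, (i+1)*1000)`.

Spurious high-signal regions are blacklisted from the *input* samples: all
1 kb bins whose tag count exceeds mean + 3 SD computed over every bin of the
genome (zeros included; population SD, which is deterministic on small test
genomes and indistinguishable from the sample SD at genome scale).
Per-sample blacklists are unioned. Library complexity is the number of
unique (position, strand) pairs divided by total mapped reads; batches below
90% complexity are deduplicated to one read per position and strand.

## Enrichment-region calling

Regions of enrichment (RoE) are called per sample with a windowed Poisson
z-score: chromosomes are tiled in 500 bp windows, the expected IP count per
window is `(input_count + 0.5) * ip_total / input_total`, and windows with
`z = (obs − exp)/sqrt(exp) >= 4` are merged into regions. The 0.5
pseudocount avoids zero expectations in sparse input windows.

Because the expectation is taken from a single noisy input window, the
z statistic has roughly twice the nominal variance and a residual
false-positive rate of ~0.2% per window at z ≥ 4. Single-sample calls are
therefore never used directly: H3K27ac regions must be supported by ≥ 2 of
the 6 samples (2 replicates × 3 conditions), and H3K4me3 regions by ≥ 2 of
the per-condition samples, before entering the catalogue. The
reproducibility filter takes the union of per-sample RoEs and keeps each
union component overlapped by calls from the required number of distinct
samples.

Replicate quality is assessed ENCODE-style on point peaks (local maxima of
the σ = 100 bp smoothed profile above an empirical-FDR 0.05 threshold
estimated from the matched input profile; maxima closer than 2σ are reduced
to the highest by non-maximum suppression, since the kernel cannot resolve
binding positions below that scale). Peaks from two replicates within
90 bp are matched one-to-one (greedy nearest-neighbour, ties toward the
lower coordinate); unmatched peaks receive signal 0 on the missing side.
The irreproducible discovery rate per pair comes from a pluggable
estimator; the default is a two-component mixture on rank-transformed
signals — a correlated bivariate normal (reproducible) against independent
standard normals (noise) — fitted by EM, reporting the posterior noise
probability (local irreproducibility). Peak counting uses the aggregated
definition: peaks are ranked by local irreproducibility and the global IDR
of the top t peaks is their mean local value; Nt is the largest tier with
global IDR below 0.01. The decision rule is the ENCODE criterion: Nt for
true replicates must exceed 50% of the same count (Np) for pooled-and-split
pseudoreplicates. Numerical equivalence with the published copula-based IDR
estimator is not a goal; the Nt/Np rule is the tested contract.

## Element classification

Active TSSs are TSSs overlapping an H3K4me3 region in any condition.
H3K27ac regions overlapping both an active TSS and an H3K4me3 region are
promoters; regions more than 1 kb from any H3K4me3 region and more than
2 kb from any active TSS are enhancers; everything else is ambiguous and
excluded from element-specific analyses. Distances are minimal bp
separations (0 for overlap). The three classes partition the input by
construction.

## Signal, fold-change and IP-efficiency correction

Signal at a region is reads-per-million in the region plus a pseudocount of
1. Enrichment is IP signal over input signal. Fold-change between
conditions divides IP signals only: input noise roughly doubles the
variance of a ratio of ratios while contributing no systematic difference
between conditions.

Library-size normalization leaves a constant multiplicative offset between
IP samples whose pulldown efficiency differs (the fraction of informative
vs background fragments varies between experiments). Because the bulk of
promoters is unaffected by the perturbations studied, that offset is
identifiable as the mode of the promoter log2 fold-change distribution.
`fit_ip_efficiency` estimates the mode by Gaussian-KDE (Silverman
bandwidth) argmax on a 0.01-log2-unit grid over [−3, 3] and returns
`2^(−mode)` per sample against a chosen reference (reference factor 1).
The mode, rather than median or mean, is robust to the asymmetric tail of
genuinely affected regions. Factors are fitted pairwise against the
reference; cross-pair consistency is reported as a diagnostic, not
enforced. The correction is applied only to marks with a stable region
class (H3K27ac over promoters); other sample sets fall back to library-size
normalization.

Browser profiles are Gaussian-smoothed (σ = 100 bp, truncated at 4σ,
default 10 bp step) tag densities scaled to per-million, written as
bedGraph or fixed-step wiggle.

## Super-enhancers

H3K27ac RoEs (reproducibility-filtered, TSS-proximal regions retained) are
stitched when edge-to-edge gaps are ≤ 12.5 kb (single linkage). Per
stitched region, signal is computed only on portions not intersecting
H3K4me3 regions — this suppresses false positives from stitched clusters
spanning active promoters — as input-subtracted IP RPM floored at 0.
Regions whose masked width is zero are excluded from ranking. The
super-enhancer cutoff is geometric: both the rank axis and the signal axis
are scaled to [0, 1] and regions above the first point where the discrete
slope of the ranked-signal curve exceeds 1 are flagged super.

## Transcribed regions

PolII and input counts in 100 bp bins are segmented bottom-up: starting
from one segment per bin, adjacent segments are merged while the merge
reduces a modified BIC, `−2 logL + λ·3k·log(n)`, with a read-level binomial
likelihood (each read in a segment is PolII vs input with a per-segment
probability), k breakpoints and n bins. The 3·log(n) charge per breakpoint
(versus log(n) in plain BIC) additionally accounts for the breakpoint's
estimated *location*; with the plain charge, the ~n candidate positions
make spurious breakpoints in homogeneous data essentially certain, while
the location-aware charge yields a single segment on homogeneous signal and
still localizes a 10× rate step to within a few bins. The merger considers
both single-breakpoint and double-breakpoint (three-segment) merges; the
latter are needed because an outlier bin can only be absorbed by removing
both of its breakpoints at once, which no sequence of single merges
achieves. λ (default 1) scales the penalty; λ → ∞ collapses to one
segment and λ = 0 keeps every bin. Segments with mean per-bin log2
enrichment (library-scaled, 0.5-count pseudocount) above 0.1 are
transcribed. The segmented mark is a parameter; the demonstration pipeline
uses the wild-type H3K27ac sample when no PolII sample is supplied.

## Motif analysis

PWMs are built from aligned site sequences with a 0.5 pseudo-count per
cell (probability `(count + 0.5)/(n + 2)`), avoiding log-odds infinities.
GC content of a PWM is the mean over positions of P(C)+P(G).

The scanner computes log-odds scores against a mononucleotide background
(genome frequencies by default) on both strands, discretized to 0.05-bit
units; p-values are exact for the discretized score via dynamic programming
over positions, so they are super-uniform under the background by
construction. Cross-genome count matching keeps the best-scoring matches up
to the largest p cutoff that yields at most the target number, dropping all
matches tied at the cutoff.

Enhancer sensitivity classes follow two rule sets. With replicates
(MEF-style): sensitive = more than 2× signal reduction in each replicate
and more than 4× on (geometric) average; insensitive = less than 2× change
in each replicate and less than 1.5× on average; everything else is
excluded. Single-comparison (cell-line-style): sensitive = more than 2×
change in the direction of interest; insensitive = fold-change within
(1/1.5, 1.5).

Motif enrichment in sensitive vs insensitive enhancers is GC-corrected: a
lowess curve (span 0.3, 3 robustness iterations) of
`log((sensitive + 1)/(insensitive + 1))` against PWM GC content is fitted
across the motif collection; the expected sensitive count per motif is
`(insensitive + 1) · exp(curve)` and enrichment is observed/expected. In
the zero-pseudocount limit the enrichment is exactly invariant to uniform
count rescaling. Motif similarity is the Pearson correlation of PWM
matrices over the best ungapped alignment (offsets up to 3 columns, both
orientations, unmatched columns padded with 0.25).

## Gene linkage and GO

Each enhancer links to its closest active TSS within 100 kb (edge-to-TSS
distance); expression analyses keep links 5–100 kb away so promoter signal
does not contaminate the enhancer categories. Expression change is
`log2((mutant + 5)/(WT + 5))` on gene-level normalized counts, restricted
to genes with an OK status in the differential table. Enhancer fold-change
categories are >3× loss, 1.5–3× loss, <1.5× change, and >1.5× gain, with
boundaries assigned to the milder category; group differences use Welch
two-sided t-tests and boxplot summaries (quartiles, 1.5×IQR whiskers).
Sensitive enhancers for GO require both replicate ratios below 1 and a
geometric-mean ratio below 1/2. GO enrichment is the hypergeometric upper
tail per term with Benjamini–Hochberg q-values; the gene universe is a
parameter (all expressed genes or enhancer-linked genes).

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, in a
2-replicate × 3-condition design:

- **Background**: Poisson tag arrivals at `background_rate` per bp
  (default 0.02, matching a few tens of millions of reads on a mammalian
  genome).
- **Sites**: 1 kb enriched sites on a jittered grid, spaced ≥ ~7 site
  widths apart so the planted promoter/enhancer truth is unambiguous under
  the 1 kb / 2 kb distance rules. TSS-proximal sites carry H3K27ac and
  H3K4me3 plus a TSS at their centre; distal sites carry H3K27ac only.
- **Perturbation**: a fraction (default 0.3) of distal sites is sensitive;
  their H3K27ac drops to `sensitive_fold_change` (default 0.25) in mutant
  conditions. Promoters and H3K4me3 are unaffected.
- **IP efficiency**: enriched (pulled-down) fragments are scaled by a
  per-sample efficiency against a constant background admixture — exactly
  the constant multiplicative distortion the promoter-mode correction must
  invert. Expected-count helpers expose the model analytically (including
  the fragment-shift spill at site edges) so tests can compare estimates to
  truth-implied targets rather than to naive 1/efficiency ratios.
- **Motifs**: occurrence counts per (motif, region) are Poisson with a rate
  coupled to the product of motif GC and region GC (sensitive regions are
  drawn GC-richer), so raw sensitive/insensitive ratios are confounded with
  GC exactly as the lowess correction assumes; zero confound strength gives
  uniform placement. A plant factor multiplies a chosen motif's rate in
  sensitive regions.
- **Expression**: per-gene mutant/WT log2 ratio equals a coupling times the
  planted fold-change of the nearest distal site, with negative-binomial
  counts (variance μ + φμ²); φ = 0 returns exact means. The significance
  column of the emitted differential table is a synthetic stand-in (binomial
  test + BH) for an external differential-expression caller.

What the generator does **not** emulate: mappability and GC bias of real
sequencing, fragment-length variation, copy-number structure, correlated
biological replicates beyond Poisson noise, bidirectional promoter
structure, or realistic motif sequence content (motif maps are planted
positions, not sequence matches). Passing tests therefore demonstrate the
correctness and calibration of the algorithms under the stated model, not
robustness to every artefact of real libraries.

## Evaluation experiments and problem sizes

`enhancerscape.evaluation` runs the property experiments reported by
`scripts/acceptance.py`: a 6-sample IP-efficiency recovery on 2,000
promoters + 4,000 distal sites (62 Mb genome); 1,000 random layouts against
a brute-force classifier; 500 random stitching instances against
union-find single linkage plus the 99-vs-1 super-enhancer toy; the
hand-computed sensitivity labels; an 80-motif GC-confounded null and 100
plant/recover runs at 40 motifs; 50 Monte-Carlo GO instances; 100-seed
segmentation recovery (1,000 bins); and the end-to-end demonstration
(600 sites on a 6 Mb genome, ~10 s). These sizes keep each experiment in
the seconds-to-a-minute range while leaving the acceptance thresholds
comfortable sampling margins.

## Known limitations

- The windowed z-caller is a transparent analog of broad-cluster callers,
  not a reimplementation; its per-sample calls are only meaningful after
  the reproducibility filter.
- The IDR estimator is a simplified mixture, adequate for the Nt/Np
  decision rule but not for calibrated per-peak IDR values.
- Pairwise-vs-reference normalization leaves the reference factor at 1; a
  jointly scaled parameterization would distribute the correction
  differently (the pairwise modes are what is zeroed either way).
- The segmentation merger is greedy (with double-merge moves) rather than
  an exact dynamic program; it can in principle retain a suboptimal
  breakpoint set, though the evaluation shows it recovers planted structure
  reliably at these sizes.
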