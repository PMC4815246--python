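# Methods

`dipseq` implements a region-level analysis of DIP-Seq (MeDIP/hMeDIP)
data: immunoprecipitation enriches methylated (5mC) or hydroxymethylated
(5hmC) DNA fragments, so the signal is fragment-scale tag density, never
single-base methylation. The pipeline starts from uniquely-mapped tag 5'
positions and proceeds through enrichment segmentation, differential
region calling between a sham and an irradiated condition, directional
spatial overlap between the two marks' differential regions, annotation
densities, and density profiles. All coordinates are 0-based half-open
(BED convention) internally; wiggle export converts to the format's
1-based convention at the I/O boundary. Tags are represented by their 5'
end and are not extended to fragment length; extension, where wanted,
belongs upstream of this package.

## Enrichment segmentation

Tags are counted in fixed windows of width `W` (default 1000 bp). The
default step equals `W` (tiling), which keeps window counts
sum-conserving and makes the randomization null cheap; a half-window step
is available, and merging recovers any continuity a sliding step would
have provided. The count threshold `t` is chosen by Monte-Carlo
randomization: each of `B` iterations (default 20) places the library's
`N` tags uniformly over the genome and re-counts windows. For each
integer `t`, the empirical FDR is

    eFDR(t) = E_null[#windows with count >= t] / max(#observed windows >= t, 1)

and the returned `t` is the smallest with `eFDR(t) <= alpha` (default
5%). The search extends past the largest observed count, so a track with
no real enrichment receives a threshold above every window — zero
domains — rather than a spurious low one; only a library with no tags at
all raises an error. The randomization uses no mappability or GC
structure; it is the exact null of the homogeneous-Poisson background the
synthetic genome implements, and real-data users with mappability
concerns should mask upstream.

Windows with counts at or above `t` are merged into enriched domains,
allowing gaps up to `g` bp (default one window — the minimal nontrivial
slack) between significant windows; domain tag totals are recomputed over
the merged interval (exactly from the tag list when available; from the
tiling window sums otherwise — with overlapping windows a non-overlapping
subset of constituent windows is summed instead, a documented
approximation). Window size can itself be selected by rerunning the full
procedure over candidate sizes and keeping the argmax of the domain
count, ties to the smallest window; a single candidate is accepted and
returned trivially.

Replicate libraries are pooled within mark x tissue x condition before
segmentation (per-library mode available), mirroring a two-replicate
design whose per-replicate coverage is too thin to segment alone.

### Null calibration check

At the *selected* threshold, the selection rule pins the
expected-to-observed ratio by construction (expected <= alpha x observed),
so comparing the two there says nothing about calibration on null data —
on pure background the selected threshold simply runs past the data and
both counts are near zero. The calibration property we verify instead is
that the Monte-Carlo expected-false curve tracks the observed
window-count curve across thresholds; the test compares the two at the
deepest threshold whose expectation is stably estimated (expected >= 5)
and requires the ratio of totals over 20 background simulations to lie in
[0.5, 2].

## Differential region calling

Domains called in each condition are unioned (overlapping or abutting
spans merge) into candidate regions; a regions x libraries count matrix
is built from the per-library tag positions. Two tests are provided:

- **Chi-square (default).** Replicates are pooled within condition and
  the 2x2 table `[[c_A, N_A - c_A], [c_B, N_B - c_B]]` (region count vs
  rest of library) is tested with the Pearson statistic, 1 df, no
  continuity correction. Regions with any expected cell below 1 are
  flagged low-count; a region with zero counts in both conditions gets
  p = 1.
- **Negative binomial.** A common NB2 dispersion is shared across
  regions — two replicates per condition cannot support per-region
  estimation — and estimated by method of moments on counts scaled to the
  median library size: `alpha = sum(v - m) / sum(m^2 - v/n)` pooled over
  regions and conditions, where the `v/n` correction removes the sampling
  variance of the replicate mean from the denominator (without it the
  estimator is biased low and the test anti-conservative). A negative
  estimate falls back to Poisson with a warning. The condition effect is
  a likelihood-ratio test between intercept-only NB GLMs (log link,
  offset = log library size) fitted per condition vs jointly, by a
  vectorized Newton iteration on the concave 1-D intercept problem;
  the statistic is referred to chi-square with 1 df. Dispersions below
  1e-6 switch to the exact Poisson forms: the analytic NB-Poisson gap is
  O(alpha) there, while the large-`1/alpha` gammaln terms cost ~1e-5 of
  floating-point precision.

p-values are Benjamini-Hochberg adjusted within mark x tissue (the
adjustment scope is a declared choice; the alternative scopes are a
one-line change). Calls are regions with q < 0.01. Direction and fold
change come from per-condition count sums scaled to the median library
size, with a 0.5 pseudocount per condition sum to stabilize zeros:
direction is "up" iff log2FC > 0 (irradiated over sham).

Known limitation: the chi-square conditions on total library size, so
when the planted differential mass is unbalanced between directions the
irradiated library total shifts and every null region inherits a small
opposite-direction proportion shift. On the default synthetic study (40
of 100 domains differential at fold 3) this inflates the realized FDR at
q < 0.01 to roughly 0.02-0.04 and attenuates recovered |log2FC| by about
0.1; both effects shrink with the differential fraction. This is a
property of testing against library totals, shared with any pipeline
using this statistic, not of the simulation alone.

## Directional overlap (DMR vs DHMR)

Significant regions of each mark are stratified by direction (up/down)
and each of the four direction pairs is scored. A region of set A is
*paired* when some region of set B lies within `w` bp (default 25 kb) of
it on the same chromosome, measured edge-to-edge (overlap = gap 0); each
A region counts once however many partners it has. "Within a window" is
deliberately read as edge gap — the least restrictive anchor — and is
configurable.

Significance conditions on the universe of all tested regions of mark A
(where regions *could* have been called), not the whole genome: with `K`
of `M` universe regions paired to set B, the p-value is the upper
hypergeometric tail of observing >= `n_paired` paired regions among
`|A|` draws. A permutation mode shuffles the significant label over the
universe (preserving set sizes) and reports `(1 + #exceedances)/(1 + B)`;
it agrees with the hypergeometric by construction and serves as a check.
The four-pair summary ranks pairs by p and flags the most significant
(ties share the flag). No attempt is made to reproduce any particular
printed p-value from real data; the nulls here are the two stated ones.

## Annotation and repeat densities

Tags (1-bp intervals) and regions are assigned to exactly one of TSS /
exon / intron / intergenic. The TSS feature is a window of +/- 1 kb
(default; the width is a convention, exposed as a parameter) around the
strand-aware 5' end. When an input overlaps several features, "closest"
is operationalized as midpoint-to-midpoint distance with the fixed
priority TSS > exon > intron on ties; no overlap at all is intergenic. A
coarse intragenic/intergenic two-way split is also provided. Category
counts over a library sum exactly to the library size.

Repeat densities are counts per million repeat-overlapping tags: a tag
in several repeats goes exclusively to the closest (same midpoint rule);
`CPM_c = 1e6 * n_c / n_repeat_tags`, so the classes sum to 1e6 per
library. An alternative denominator (total library size) is available by
flag, since "per million repeat sequences" admits both readings. Tissue
contrasts are per-class two-sided Welch t-tests on per-library CPM
(n = 4 libraries per tissue per mark in the emulated design), significant
at p < 0.05; the t-test choice is the documented reading of an unnamed
test.

Differential regions are mapped to genes by ranking on q (ties: |log2FC|
descending, then coordinate), keeping the top 2000, dropping regions
with no TSS within 50 kb, assigning each to the nearest TSS (signed
distance, negative upstream on the gene's strand, 0 on overlap), and
collapsing duplicate genes to the best-ranked region. The gene lists are
exported for external ontology/pathway tools; no enrichment statistics
are computed here.

## Density profiles

The metagene matrix stacks per-gene densities: fixed 500-bp flank bins
(default 5-kb flanks) plus a length-normalized gene body in 40 bins
(flank width and body bin count are conventions, both configurable), rows
ordered by descending expression, minus-strand genes reversed so the 5'
end is leftmost, values scaled to tags per million. Genes shorter than
the body bin count are skipped with a warning. For display the matrix is
clipped at the 80th quantile of its nonzero values and min-max scaled to
[0, 1]; the quantile uses the "lower" order statistic so that rescaling
an already-scaled matrix is an exact no-op. The heatmap PNG is a
rendering convenience; all tests assert on the numeric matrix.

Browser tracks are fixedStep wiggle: per-bin median-scaled tag density
emitted only where the raw bin count clears the segmentation threshold
(enrichment above background at the segmentation FDR), zero elsewhere;
the bin width should match the window the threshold was calibrated for.

## Synthetic data generator

The generator emulates the study design the pipeline targets: two
tissues (hippocampus, ventricle) x two conditions (sham, proton) x two
replicates per mark (5mC, 5hmC) — 8 libraries per mark. Defaults: two
5-Mb chromosomes; background rate lambda0 = 0.01 tags/bp per library
(so lambda0*W = 10 with the 1-kb window, a deliberately desk-scale
stand-in for >30M-read libraries on a 2.5-Gb genome); 100 enriched
domains per tissue x mark of 1-3 kb at 8x background; 40 of them
differential at fold phi = 3 (up or down in the irradiated condition with
equal probability); coupling kappa = 0.5 of 5hmC differential domains
placed within 25 kb of a 5mC differential domain of the paired direction
(default pairing: 5mC down with 5hmC up, the demethylation-coupling
hypothesis); 200 genes with 1-10 exons; 400 repeats over all seven
classes; log-normal expression.

Background is homogeneous Poisson — the exact null of the segmentation
randomization; there is no mappability, GC, or copy-number structure, no
read-level simulation, and no antibody cross-reactivity. Passing tests
therefore demonstrate the statistical machinery under its own model
assumptions, not robustness to those real-data artifacts. Domains are
rejection-sampled non-overlapping with a minimum separation of 5 kb so
that distinct planted domains are not merged by the one-window merge
slack; differential regions coincide with whole enriched domains (the
spatial unit actually tested is the merged domain, so sub-domain
differential signal would only measure dilution, not recovery). Inside a
differential domain the irradiated-condition rate is `e*lambda0*phi`
(up) or `e*lambda0/phi` (down). Coupled 5hmC domains are
rejection-sampled within the 25-kb window of a randomly chosen partner.
One seed drives everything; per-library substreams are derived from fixed
(seed, stream-id) pairs, so libraries are independent yet the whole study
is bit-reproducible.

## Pipeline and reproducibility

Stages hand off through plain BED/TSV files with stable names; every
intermediate is inspectable. The manifest records package version, a
config hash, the seed and per-stage row counts, and deliberately no
timestamps: two runs with one seed are byte-identical, which the test
suite and the acceptance script both verify. Stage seeds derive
deterministically from the one global seed. The per-tag genomic-category
stage subsamples each library to a cap (default 20,000 tags) before the
per-tag tree queries; the subsample is seeded and proportions are
unbiased, only their Monte-Carlo error changes.

## Verification scale

The test suite and `scripts/acceptance.py` run everything at desk scale:
10-Mb single-chromosome genomes for segmentation recovery (200 domains),
20-repeat simulations for FDR/power/coupling checks, 2000 regions for
negative-binomial calibration, and the default two-tissue study for the
end-to-end determinism check. These sizes were chosen so the complete
verification runs in minutes while leaving the binomial/Poisson error of
every estimated rate an order of magnitude inside its acceptance band.
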