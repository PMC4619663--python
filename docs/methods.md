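# Methods

`fetalmeth` re-implements, as a tested library, a catalogue-style analysis of
DNA methylation dynamics in human fetal tissues measured on 450k-style
arrays: tissue-specific hypomethylation signatures, developmental gain/loss
of methylation, clustering of called CpGs into regions, annotation-based
enrichment, an empirical permutation test for overlap with binding peaks,
and the integration of expression trends.  Because the analysis is defined
by fixed rules rather than fitted models, correctness is established on
synthetic data with planted truth rather than on a reference dataset.

## Data model and coordinates

Beta values are methylation fractions in [0, 1] per CpG probe per sample.
The design is tissue x gestational week x biological replicate; the default
study conditions are four tissues (amnion, muscle, adrenal, pancreas), weeks
9/18/22, and three replicates per cell.  Probe positions are 1-based
(manifest convention); interval tracks (CpG islands, chromatin states,
peaks, exported regions) are 0-based half-open (BED convention).  The single
conversion rule — `[start, end)` covers 1-based positions `start+1 .. end` —
is implemented once (`fetalmeth.io.position_in_intervals`) and used for
every membership query.

## Probe QC

An observation fails when its bead count is below 3 or its detection
P-value exceeds 0.01; a probe is dropped when its success rate across
samples falls below 95% (boundary inclusive: exactly 95% is kept), or when
it appears on an ambiguous-mapping exclusion list.  Missing betas are
allowed on input; a probe missing a value in any group required by a caller
is excluded from that caller and counted in the log.

## Threshold callers

All comparisons use replicate means per (tissue, week); sample SDs use the
n−1 denominator; thresholds are inclusive (≥).

*Tissue-specific hypomethylation* — a probe is called for a target tissue
when the mean beta of every other tissue exceeds the target mean by at
least `delta = 0.20` at every week, and the SD of the target tissue's
samples pooled over weeks is below `sd_max = 0.10`.  The strict
"every other tissue" reading is the default; `comparison="max"` gives the
weaker against-the-maximum variant.  The SD filter pools the target tissue's
samples across weeks, which reads the filter as stability "within the
tissue of interest"; the dynamic caller instead filters per (tissue, week)
replicate group, reading its filter as stability within a time point.  Both
readings are deliberate and kept separate.

*Dynamic methylation (GOM/LOM)* — with weeks w_lo < w_mid < w_hi, a probe
gains methylation when mean(w_hi) − mean(w_lo) ≥ 0.20 and the middle week
lies between the endpoints up to a tolerance of 0.05 on either side
(mean(w_mid) ≥ mean(w_lo) − 0.05 and mean(w_mid) ≤ mean(w_hi) + 0.05); loss
is the mirror image.  The tolerance rule is implemented literally — the
middle week is not required to be strictly monotonic beyond it.  Probes
whose replicate SD reaches 0.10 in any (tissue, week) group are discarded
first; groups with fewer than two replicates have undefined SDs and their
probes are excluded with a logged warning.

An open choice: the per-week "difference" is computed between group means,
not between all replicate pairs.  Means are the natural estimator at n = 3
and make the inclusive-threshold semantics unambiguous.

## Region calling

Called CpGs cluster into regions (tHRs for hypomethylation, dDMRs for
GOM/LOM).  A region starts and ends with a matching probe, contains at
least 3 matching probes and at most 3 non-matching probes (budget counted
over the whole region), and never spans more than 1,000 bp between
consecutive member probes (matching or not).  Non-matching probes are array
probes failing the criterion, including probes removed by the SD filters
(configurable to treat such probes as absent instead).

The normative semantics are *maximal* valid intervals: every candidate
interval is filtered by the four constraints, intervals contained in a
surviving interval are dropped, and remaining overlaps are resolved by
repeatedly keeping the leftmost-starting candidate (the longer on equal
starts) and discarding candidates sharing probes with it.
`enumerate_regions_bruteforce` implements this definition directly (O(n³));
the production scan (`call_regions`) is linear-time and exactly equivalent
(two-pointer sliding window per gap-segment over prefix match/mismatch
counts; the tests compare the two on thousands of random instances).

Known property: coverage is *not* monotone under relaxing `max_gap` or the
mismatch budget.  Relaxing `max_gap` can merge two gap-segments so that the
leftmost maximal interval absorbs the shared mismatch budget and the
disjoint-selection step drops a downstream region.  This follows from the
maximal-interval semantics itself (the brute-force reference exhibits it),
so the tests assert the weaker true property: regions called under strict
parameters remain valid intervals under relaxed parameters.

## Annotation

CGI axis: a probe inside a (merged) CpG island is `CGI`; within 2,000 bp of
an island edge, `SHO` (shore); within 2,000–4,000 bp, `SHE` (shelf);
otherwise `NC`.  Outer boundaries are inclusive toward the nearer-island
class (exactly 2,000 bp is shore, exactly 4,000 bp is shelf) — the band
definition ("±2 kb") does not fix the boundary side, so it is pinned here
and tested explicitly.

Genic axis, strand-aware around the TSS/TES: distal promoter `DP`
(−10 kb..−1.5 kb), proximal promoter `PP` (−1.5 kb..+0.5 kb), gene body
`GB` (+0.5 kb..TES), downstream `DS` (TES..+5 kb), remainder `IG`.  A probe
falling in windows of several genes or classes takes the precedence
PP > DP > GB > DS (promoter assignments dominate in the source annotation
scheme; the order is configurable).  Degenerate genes with tx_start ==
tx_end are accepted (TSS == TES, empty body).

Summaries: the median beta per combined (CGI x genic) feature per (tissue,
week) is taken over probe-level replicate means; empty feature cells are
reported as missing, never zero.  Methylation-class fractions split the
replicate means at 0.25/0.75 into hypo-/intermediately/hyper-methylated
(lower edge inclusive for the middle class).

## Enrichment, nearest genes, metaprofiles

Enrichment of a called probe set against a background (all QC-passing array
probes — the background for the odds ratios is not pinned by the source
description; the full surviving array is the analogous choice at probe
level) is a per-category 2x2 odds ratio OR = (a·d)/(b·c) with a = called in
category, b = called outside, c = background in category, d = background
outside.  Zero cells take the Haldane–Anscombe +0.5 on all four cells; a
table with an all-zero column (category covering the whole background or
none of it) carries no contrast and reports OR = 1.  Significance is the
Pearson chi-squared on raw counts, 1 df, no continuity correction; no
multiple-testing correction across categories.  Chromatin-state enrichment
induces a per-probe state label from a segmentation track (probes outside
any state are `unsegmented`) and reuses the same 2x2 machinery.

Nearest-gene mapping minimises min(|pos − TSS|, |pos − TES|), with distance
0 for positions inside the gene span; regions are represented by their
midpoint; ties break by smaller |TSS distance|, then lexicographic gene id.
The signed distance is negative left of the span, positive right of it.

Signal metaprofiles around regions aggregate tag midpoints (weighted by a
numeric score column when present) into `n_bins` bins per segment —
upstream flank, length-scaled body, downstream flank (default flank
5,000 bp) — and report the mean per bin across regions.

## Permutation overlap test

The observed statistic is the number of regions whose genomic span
intersects (≥ 1 bp) at least one peak.  The null resamples "DMR-like"
regions from the probe manifest: runs of consecutive probes with
inter-probe gaps < 1 kb and length k = 3 + Poisson(2) (mean 5, minimum 3,
matching the minimum region size).  Null regions are sampled from probe
space, not genome base space, because called regions are themselves
probe-defined.  Regions are placed sequentially, a (length, start) pair
being redrawn when it would share probes with an already-placed region;
lengths longer than any available run are likewise redrawn.  The two-sided
p doubles the smaller add-one-corrected tail, (#{null ≥ obs}+1)/(n_perm+1),
capped at 1 — it can never be exactly zero, and an observation beyond every
null draw gives exactly 2/(n_perm+1).

Calibration: on null data the doubled discrete p is conservative — with
~100 regions the realised type-I error at α = 0.05 is about 0.02–0.04
rather than 0.05.  This is a property of doubling a discrete tail, not an
implementation artefact; the calibration test asserts the realised rate
within 0.05 ± 0.04.

## Expression trends

CPM = count / library size × 10⁶, no further normalisation.  Per gene and
week the arithmetic mean over biological replicates is taken; a gene set is
summarised per week by the median and IQR over genes.  The direction test
is a two-sided exact binomial (sign) test on the numbers of genes rising
vs falling between the first and last week, ties (including genes at zero
at both endpoints) excluded, p₀ = 0.5 — the simplest test of up/down
enrichment; the underlying "probability test" is not further specified in
the source description, so the sign test is pinned here and is
configurable in principle by replacing `direction_test`.

## Synthetic data generator

The generator is first-class, tested code; every downstream stage is
validated against its truth table.

* **Geometry** — probes are laid out in clusters (3–12 probes, intra-cluster
  gaps 50–400 bp) separated by 5–15 kb, so consecutive-CpG regions and the
  DMR-like null sampler see realistic run structure.  CpG islands cover a
  leading sub-span of a cluster (≥ 3 probes) so the remaining cluster
  probes fall in the shore/shelf bands.  Genes are placed adjacent to
  dynamic blocks (one linked gene per GOM/LOM block, up to `n_genes`) with
  the remainder placed uniformly.
* **Signals** — planted blocks carry per-week mean trajectories: by default
  tissue-hypomethylated blocks sit at background − 0.30 flat across weeks
  in one tissue; GOM blocks rise 0.20→0.35→0.50 and LOM blocks fall
  0.50→0.35→0.20 in one tissue; everything else sits at 0.50.
* **Noise** — each observation is Beta(μκ, (1−μ)κ) with κ = 200 by default
  (SD ≈ 0.035 at μ = 0.5, comfortably below the 0.10 SD filter).  The
  replicate-level variance of the real data is not published; κ is a free
  parameter of the config.
* **Peaks** — a configurable fraction of LOM blocks receives a peak
  (600 bp, centred on the block); decoy peaks avoid all planted blocks.
* **Expression** — negative-binomial counts (dispersion 0.1, lognormal base
  means around 200) with LOM-linked genes rising two-fold and GOM-linked
  genes falling two-fold from the first to the last week *in the block's
  target tissue only*; library sizes vary at least two-fold.  Dispersion 0
  is the deterministic limit (counts = rounded means) so exact-recovery
  tests are meaningful.
* **Chromatin states** — random 2–10 kb segments labelled
  TSS/Enhancer/Transcribed/Repressed/Quiescent, with planted hypomethylated
  and LOM blocks overwritten as Enhancer and GOM blocks as Repressed, so
  state enrichment is checkable against truth.
* **Determinism** — one integer seed; streams are spawned by
  `SeedSequence(seed).spawn` and consumed in the fixed order layout, beta,
  expression, states; peak simulation takes its own seed.

What the generator does **not** emulate: probe type I/II chemistry bias,
sex chromosomes, cell-type mixtures, spatially varying array noise,
correlated replicate effects, GC-dependent peak placement.  Passing tests
therefore demonstrate the correctness of the rules and statistics on data
satisfying the stated design, not robustness to those real-data artefacts.

## Problem sizes used in the test suite

The default synthetic study is 20,000 probes (2,000 planted in 400 blocks
of 5) across 4 chromosomes; parameter-recovery checks pool 20 simulation
seeds.  The permutation-calibration study uses a 3,000-probe background
manifest, 100 observed regions, 400 random 4-kb peaks and 200 repetitions
of 1,000 permutations.  The region-caller equivalence check runs 1,000
random instances of up to 30 probes against the brute-force reference.
Expression checks use 2,000 genes with 200 LOM-linked.  These sizes were
chosen so the full suite exercises every path at meaningful scale while
remaining quick to run on a laptop.

## Known limitations

* The acceptance analyses run on synthetic data; the headline counts of the
  original catalogue depend on a raw-intensity normalisation stack
  (background/colour correction, quantile normalisation, BMIQ) that is out
  of scope, so no attempt is made to reproduce dataset-specific numbers.
* The region caller's coverage is not monotone in `max_gap` /
  `max_nonmatching` (see above).
* The permutation test's doubled discrete p is conservative near α = 0.05.
* CPM ratios of trending gene sets carry a small composition bias when
  trending genes are a large fraction of the transcriptome; the generator's
  defaults keep that fraction small.
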