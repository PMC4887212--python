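# Methods

This note documents the statistical models, defaults and design choices of
the methylmem pipeline, and what the synthetic-data experiments do and do
not establish.

## Input model

The unit of observation is a strand-specific cytosine with context
(CG, CHG, CHH) and read counts (meth, total), carried per sample as a
DataFrame in a CX-report-style tab-separated format (chrom, 1-based
position, strand, meth, unmeth, context, trinucleotide). Read-quality
filtering is assumed to have happened upstream of the count tables.
Interval data (genes as GFF3, TEs as BED6 with the superfamily in the name
column) are converted at the I/O boundary to 0-based half-open coordinates;
cytosine positions stay 1-based, as reported by WGBS callers. An option to
merge the two strands of a CG dyad into one record exists but is off by
default, since strand-specific reporting is the more common convention.

## Non-conversion rate and site calls

Incomplete bisulfite conversion makes truly unmethylated cytosines read as
methylated. The rate `e` is estimated from the chloroplast genome, which is
unmethylated in somatic plant tissue: `e = Σ meth / Σ total` over all
chloroplast cytosines (pooling samples when available). A site is called
methylated when the one-sided upper-tail binomial p-value
P(X ≥ meth | n = total, p = e) survives BH correction at `site_fdr = 0.05`,
applied per sample. The analysis universe is restricted to positions covered
by ≥ `min_cov = 3` reads in strictly more than half of the samples.

## DMPs

Positions are matched on (chrom, pos, strand, context). Only pairs whose
methylation frequencies differ by at least `min_diff = 0.30` are tested; the
boundary is inclusive and the comparison is done on integer cross products
(|meth_a·total_b − meth_b·total_a| ≥ min_diff·total_a·total_b), so exact
rational frequencies — not rounded percentages — decide the filter. The test
is the two-sided Fisher exact test on the 2×2 read-count table, BH-corrected
per pairwise comparison at FDR 0.05. The pipeline driver only compares
samples of the same treatment group, which excludes methylation differences
caused by batch-to-batch growth fluctuations. No replicate-discordance
masking is applied before testing. The literature does not pin down the
correction scheme for this family of pipelines; BH is used and is
configurable.

## Methylated regions (MR): two-state HMM

Cytosines ordered along a chromosome are emissions of a hidden chain with
states Low and High. Emissions are beta-binomial: for state `s` and context
`c` the methylated count is BetaBin(total, α, β) with mean `m_{s,c}` and a
shared per-state intra-class correlation `ρ_s` (α+β = (1−ρ)/ρ). The
beta-binomial absorbs the overdispersion of pooled-plant samples that a
plain binomial emission cannot. Whether the original region callers
conditioned on context with separate chains or a joint emission is not
documented in the accessible literature; the joint-emission form (one chain,
context-specific means) is a declared choice here.

Defaults: `distance_break = 250` bp (gaps larger than this re-initialize
the chain at its stationary distribution, as do chromosome ends),
`min_sites = 4`, `posterior_threshold = 0.5`, self-transition 0.99 at
initialization, emission means initialized from the 90th/10th percentile of
per-site frequencies per context, dispersions at 0.1. These are consistent
with the few-hundred-bp median MR length scale reported for Arabidopsis
leaf methylomes and are all configurable; they are not claimed to equal any
published caller's internal values.

Fitting is generalized EM: the E-step is scaled forward–backward; the
M-step re-estimates transitions from expected counts and the emission
means/dispersions by bounded scalar likelihood maximization, with the
current value kept whenever the optimizer fails to improve the weighted
likelihood. An iteration's update is accepted only if the total
log-likelihood improves by at least `tol`, so the log-likelihood is
non-decreasing over accepted updates and `tol = inf` returns the initial
parameters after a single E-step. Degenerate fits — High/Low means closer
than 0.05 on average, or a state with (near-)zero posterior occupancy —
raise an error instructing re-initialization rather than returning a
one-state model silently.

MRs are maximal runs of sites with High posterior ≥ threshold, at least
`min_sites` cytosines and no internal gap > `distance_break`; the interval
spans the first to last site, half-open at last coordinate + 1. Replicate
MR sets merge by interval union (idempotent), carrying contributor ids.

In pipeline runs the HMM is fitted once on the first sample and the fitted
parameters are shared across samples (`hmm_fit_mode = "shared"`): the
methylation landscape being segmented is a property of the genome, not of
the sample, and per-sample refitting (`"per-sample"`) changes MR calls only
marginally while multiplying cost.

## DMR testing

Breakpoints are all MR starts/ends across samples; every breakpoint pair
lying entirely inside at least one sample's MR is a candidate segment — a
combinatorial set that deliberately contains nested duplicates. A segment is
eligible when one sample's MR set covers it end to end ("high methylation
state throughout"). For a group pair, meth/total counts are pooled per group
over all sites in the segment; the pair is tested (two-sided Fisher) when
the pooled |Δfreq| ≥ `min_diff_region = 0.10` — a guard against significance
arising from depth alone — and every sample in each group agrees in
direction against the other group's pooled frequency (the replicate-
consistency requirement standing in for an undocumented published test; this
is the pipeline's principal deviation risk from its antecedents). BH runs
over all (segment, pair) tests of the run. Because nested candidates are
guaranteed, overlapping significant segments of a pair are resolved greedily
by ascending q, then descending length.

Within a generation the four groups are: non-stressed (P0/P1/P2 controls),
stressed (salt-treated P0), stressed-P1, stressed-P2. Hyper/hypo
classification subtracts the pooled combined-control frequency from the
sample frequency (positive = hyper); this subtraction order is an
interpretive decision consistent with stress-elevated P0 regions being
called hypermethylated. The DMR frequency matrix holds unweighted means of
per-site frequencies; DMRs not covered in every sample are dropped before
clustering.

## Clustering

Complete-linkage hierarchical clustering on euclidean distances between
sample rows of the DMR frequency matrix, with per-node support from an
ordinary bootstrap over DMR columns (support = fraction of resampled trees
containing the identical sample cluster). This replaces multiscale-bootstrap
approximately-unbiased p-values, which belong to an R-side tool outside this
package's scope; ordinary bootstrap support is coarser but sufficient to
flag unstable nodes. PCA scores are computed on the column-centered matrix.

## Annotation and enrichment

Positions and regions are assigned hierarchically in the order
CDS > intron > 5'UTR > 3'UTR > transposon > intergenic; regions are
assigned per basepair, so composition counts always sum to the region
length. The auxiliary 2-kb-upstream flag is strand-aware using gene strand.
Overlap counting (optionally with ±flank windows) counts each query element
once regardless of partner multiplicity, matching set-overlap percentages.
Nearest-feature distances are edge-to-edge gaps (0 on overlap; missing on
feature-less chromosomes; ties broken toward the lower start coordinate).

TE-superfamily enrichment compares a query TE set against the genome-wide
profile: expected count `Se = (wgs/wgt)·st` (wgs = genome-wide count of the
superfamily, wgt = genome-wide total, st = query total), so Σ Se = st by
construction; per-superfamily p-values come from a two-sided binomial test.

The chromatin-mark intersection table reports, per mark and per query set
(hypo DMRs, hyper DMRs, MRs), strict-overlap counts against increased and
decreased mark regions and a percentage = (increased + decreased overlaps) /
set size, rounded to the nearest integer (raw fractions retained). Of the
two percentages quoted alongside the published intersection summary this
package reconstructs, the 38% hyper-DMR figure follows from the printed
counts ((7+99)/280) while the companion 63% figure does not (the printed
counts give (3+15+7+99)/350 = 36%); the operation therefore reports only the
computable definition, and the reconstruction experiment checks 13% (MRs)
and 38% (hyper DMRs).

## Synthetic methylomes

The generator emulates a multigenerational stress design: generations
G1/G3/G5, lineages P0 (treated) / P1 / P2 (unstressed descendants),
treatments control / 25 / 75 mM NaCl, in duplicate — 54 samples by default,
restrictable for tests. What it plants:

* **Methylated blocks** = TE intervals (half clustered in a central
  pericentromere-like fifth of each chromosome); inside blocks the
  per-context means are CG 0.85, CHG 0.65, CHH 0.35; outside, CG 0.02,
  CHG 0.015, CHH 0.01.
* **Labile regions** (default 40): placed inside TEs when they lose
  methylation under stress, adjacent (≤ 2 kb) when they gain; gaining
  regions start from a low baseline (CHG/CHH 0.10). Under stress the non-CG
  contexts shift by ±`p0_nonCG_gain = 0.4` in P0; P1 and P2 retain
  `p1_retention = 0.6` and `p2_retention = 0.05` of the shift. A fraction
  `hyper_fraction = 0.81` of regions gain. The per-context magnitude of
  real stress-induced shifts is not published; 0.4 was fixed once as a
  moderate, recoverable effect and is not a fitted quantity.
* **CG epimutation**: each CG dyad flips state with probability
  1−(1−r)^g, r = 1e-4 per generation, g = elapsed generations — the
  stochastic CG noise that decorrelates CG changes from treatment.
* **Counts**: coverage is negative binomial around `coverage_mean = 20`
  with dispersion 0.3 (realistic overdispersion with one extra parameter);
  methylated counts are binomial in f + (1−f)·`conversion_error`
  (default 0.005). CG sites are emitted on both dyad strands with symmetric
  frequencies; CHG/CHH on one strand. Zero-coverage sites are absent from a
  sample's table.
* **Chloroplast**: one extra unmethylated chromosome for error-rate
  estimation.

Per-sample randomness is keyed on (seed, sample_id), so identical
configurations are byte-identical and design subsets reproduce exactly.
The 25 and 75 mM treatments carry the same effect size; a dose multiplier
was considered and rejected as an extra unconstrained parameter. Gene models
are simplified (UTR order not strand-flipped); only gene strand feeds the
strand-aware upstream windows. The ground-truth MR set is the merged TE
blocks, identical across samples; MR recovery is scored on control samples
so stress shifts at labile regions do not blur the truth.

What the generator does **not** emulate: read-level errors and mapping
bias, sequence-dependent cytosine spacing, partial methylation gradients at
block edges, linkage between CG epimutations, gamete-specific methylomes,
and genome-scale TE landscapes. Passing recovery tests therefore shows the
statistical machinery is correct and calibrated under the assumed generative
model — not that real-data DMR counts would be reproduced.

## Validation experiments and problem sizes

`methylmem.validation` holds the seeded experiments shared by the test
suite and the reproduction script; sizes were chosen as the smallest that
give stable statistics:

* MR recovery: one control sample, 150 kb genome (~33k sites), F1 vs truth
  (observed ≈ 0.99, threshold 0.90).
* DMR recovery: 200 kb, 30 labile regions, six replicates per group,
  stressed-vs-non-stressed; recall ≥ 0.80 and empirical FDR ≤ 0.05 against
  truth (observed: recall 1.0, FDR < 0.01).
* Pattern emulation: 20 replicates of an 80 kb, 9-sample generation;
  hyper fraction among recovered regions within 3 binomial SE of the
  planted 0.81, and the dendrogram 3-cut isolating stressed P0, isolating
  stressed-P1, and co-clustering stressed-P2 with controls in ≥ 90% of
  replicates.
* Null control: no-effect simulation; fractions of tested positions and
  segments at q ≤ 0.05 within 0.05 + 3 SE (observed ≈ 0).
* Oracles: Fisher p-values vs. hypergeometric enumeration (margins ≤ 50
  exhaustively random, ≤ 200 sampled) to 1e-10; forward–backward posteriors
  vs. full path enumeration (≤ 12 sites) to 1e-8; interval operations vs.
  naive all-pairs scans.

## Numerical notes and limitations

* Fisher tests use scipy's exact implementation; frequency-difference
  boundaries are decided on integer cross products with a 1e-9 relative
  guard against float rounding.
* Forward–backward is scaled per position; emission log-densities are
  max-shifted per site before exponentiation.
* The combinatorial candidate set grows quadratically in breakpoints per
  merged MR; this is intended at desk scale, and nested duplicates are
  resolved after testing rather than pruned before (pruning would change
  the BH family).
* `merge_intervals` coalesces touching intervals (end == start), which is
  the desired semantics for MR unions.
* Empty segments, segments without control coverage, and samples without
  coverage in a segment are skipped (logged), never fatal.
* Manifests carry no timestamps, so identical runs of `run_pipeline` are
  byte-identical; re-running a config reproduces every output checksum.
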