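# methylmem

A whole-genome bisulfite sequencing (WGBS) differential-methylation pipeline
for multigenerational stress-memory experiments, together with a seeded
synthetic methylome generator that emulates the study design so every stage
can be run and verified at desk scale.

## The scientific problem

Plants exposed to repeated hyperosmotic (salt) stress acquire DNA
methylation changes — predominantly non-CG (CHG/CHH) gains at discrete,
epigenetically labile regions within or near transposable elements (TEs).
These changes are partially transmitted to the next unstressed generation
(P1) and largely reset by the second (P2). Detecting this pattern from WGBS
read counts requires a chain of statistical steps, each of which this
package implements as a tested, reusable library function:

1. **Methylated-site calling.** Every cytosine carries counts
   (meth, total). The bisulfite non-conversion ("false methylation") rate
   `e` is estimated from the unmethylated chloroplast genome as
   `e = Σ meth / Σ total`. A site is methylated when a one-sided binomial
   test of `meth` out of `total` against `e` is significant after
   Benjamini–Hochberg correction. Positions enter the analysis only when
   covered by ≥ 3 reads in more than half of the samples.
2. **DMPs.** A differentially methylated position between samples *a* and
   *b* requires |meth_a/total_a − meth_b/total_b| ≥ 0.30 (inclusive) and a
   significant two-sided Fisher exact test on
   [[meth_a, unmeth_a], [meth_b, unmeth_b]] (BH-corrected). Only samples of
   the same treatment group are compared.
3. **MRs.** Each sample's methylome is segmented by a two-state
   (High/Low) HMM with beta-binomial emissions per context
   (CG/CHG/CHH) and a shared per-state dispersion, fitted by EM; maximal
   runs of High-posterior sites (≥ 4 sites, no gap > 250 bp) are methylated
   regions.
4. **DMRs.** MR breakpoints pooled over all samples define candidate
   segments (every breakpoint pair inside at least one sample's MR). Counts
   are pooled per group — 'non-stressed' (all controls), 'stressed'
   (salt-treated P0), 'stressed-P1', 'stressed-P2' — and tested with a
   two-sided Fisher exact test (pooled |Δfreq| ≥ 0.10, all replicates
   agreeing in direction, BH over all segment×pair tests).
5. **Interpretation.** DMRs are classified hyper/hypo against the combined
   controls of the generation, annotated per basepair in the hierarchy
   CDS > intron > 5'UTR > 3'UTR > transposon > intergenic, tested for
   TE-superfamily enrichment against expected counts
   `Se = (wgs / wgt) · st`, intersected with altered chromatin-mark regions,
   and used for complete-linkage clustering / PCA of samples.

The synthetic generator (`methylmem.simulate`) plants all of this structure
— TE-dense methylated blocks, labile regions with retention-decaying non-CG
shifts across P0/P1/P2, stochastic CG epimutation, negative-binomial
coverage, non-conversion errors, and an unmethylated chloroplast — and
returns the ground truth for recovery scoring.

## Worked example

`examples/04_call_dmrs_and_cluster.py` simulates one generation
(9 samples), calls MRs and DMRs, and clusters samples on the DMR frequency
matrix:

```
390 candidate segments, 309 tested, 87 DMRs at q <= 0.05

mean |net methylation change| vs combined controls (decays across lineages):
stressed       0.382
stressed-P1    0.227
stressed-P2    0.028

clustered 9 samples on 87 DMRs
  cluster 1: ['G3_P0_control_r1', 'G3_P1_control_r1', 'G3_P2_25_r1',
              'G3_P2_75_r1', 'G3_P2_control_r1']
  cluster 2: ['G3_P1_25_r1', 'G3_P1_75_r1']
  cluster 3: ['G3_P0_25_r1', 'G3_P0_75_r1']
```

The net change decays P0 → P1 → P2 (transient memory), and the 3-way cut of
the complete-linkage dendrogram separates stressed P0, places stressed-P1 in
its own subcluster, and co-clusters stressed-P2 with the controls. The other
examples cover simulation (`01`), site/DMP calling (`02`), HMM segmentation
with basepair-F1 scoring (`03`), and annotation/TE-enrichment plus the
chromatin-mark intersection table (`05`).

A thin CLI mirrors the stages:

```bash
methylmem simulate --out sim/ --seed 1
methylmem dmr --mrs sim/ --samples sim/samples.tsv --generation G1 --out dmrs.tsv
methylmem run --config run.yaml   # end-to-end with a checksummed manifest
```

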