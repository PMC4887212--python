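"""Call DMRs between treatment groups and cluster samples on DMR frequencies.

Candidate segments come from the pooled MR breakpoints of all samples; each
is tested by pooling read counts per group (Fisher exact, BH-corrected).
Samples are then clustered (complete linkage) on the DMR frequency matrix:
stressed P0 separates, stressed-P1 forms a distinct subcluster, and
stressed-P2 co-clusters with controls — the transient-memory signature.
"""

import methylmem as mm

cfg = mm.SimConfig(genome_length=100_000, n_te=20, n_genes=6,
                   n_labile_regions=16, chloroplast_length=5_000, seed=5)
annot = mm.simulate_annotation(cfg)
design = mm.default_design(generations=("G3",), replicates=1)  # 9 samples
tables = mm.simulate_samples(cfg, annot, design)
nuclear = {s: mm.nuclear_table(df) for s, df in tables.items()}

first = nuclear["G3_P0_control_r1"]
params = mm.fit_hmm(first, mm.initial_params(first), tol=1.0, max_iter=10)
mr_sets = {s: mm.segment_mrs(df, params, sample_id=s) for s, df in nuclear.items()}

groups = mm.assign_groups(design, "G3")
candidates = mm.build_segments(mr_sets)
result = mm.test_dmrs(candidates, nuclear, groups, mr_sets=mr_sets,
                      group_pairs=[("non-stressed", "stressed")])
dmrs = mm.significant_dmrs(result)
print(f"{len(candidates)} candidate segments, {len(result)} tested, "
      f"{len(dmrs)} DMRs at q <= 0.05")

controls = [s for s, g in groups.items() if g == "non-stressed"]
stressed = [s for s, g in groups.items() if g != "non-stressed"]
directions = mm.classify_direction(dmrs, nuclear, controls, stressed)
net = directions.groupby(directions["sample_id"].map(groups))["abs_change"].mean()
print("\nmean |net methylation change| vs combined controls (decays across lineages):")
print(net.round(3).to_string())

matrix = mm.dmr_frequency_matrix(dmrs, nuclear)
res = mm.cluster_samples(matrix, n_boot=200, seed=5)
print(f"\nclustered {len(res.labels)} samples on {matrix.shape[1]} DMRs")
print("dendrogram (newick):", res.newick)
cut = res.cut(3)
for c in sorted(set(cut.values())):
    print(f"  cluster {c}:", sorted(s for s, k in cut.items() if k == c))
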