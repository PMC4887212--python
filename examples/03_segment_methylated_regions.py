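"""Segment a methylome into methylated regions (MRs) with the two-state HMM.

Fits beta-binomial emission parameters by EM, decodes High-posterior runs
into MRs, and scores basepair-level recovery against the simulator's truth.
"""

import numpy as np

import methylmem as mm

cfg = mm.SimConfig(genome_length=150_000, n_te=25, n_genes=10,
                   n_labile_regions=15, chloroplast_length=5_000, seed=11)
annot = mm.simulate_annotation(cfg)
tables = mm.simulate_samples(cfg, annot, [mm.SampleMeta("s", "G1", "P0", "control", 1)])
records = mm.nuclear_table(tables["s"])

init = mm.initial_params(records)  # 90th/10th percentile emission means
params = mm.fit_hmm(records, init, tol=1.0, max_iter=15)
print("fitted High means:", {k: round(v, 3) for k, v in params.mean_high.items()})
print("fitted Low  means:", {k: round(v, 3) for k, v in params.mean_low.items()})
print("transition matrix:\n", params.trans.round(4))

mrs = mm.segment_mrs(records, params, sample_id="s")
lengths = mrs["end"] - mrs["start"]
print(f"\n{len(mrs)} MRs, median length {int(np.median(lengths))} bp "
      f"(mean {int(lengths.mean())} bp)")

scores = mm.bp_f1(mrs, annot.truth.mr_truth)
print(f"basepair recovery vs truth: precision {scores['precision']:.3f}, "
      f"recall {scores['recall']:.3f}, F1 {scores['f1']:.3f}")

# merging replicate MR sets yields the common set used for DMR candidates
merged = mm.merge_mrs([mrs, mrs.assign(sample_id="s2")])
print(f"merged common set: {len(merged)} regions (idempotent interval union)")
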