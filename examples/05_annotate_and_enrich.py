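"""Hierarchical genomic annotation, TE-superfamily enrichment, and the
chromatin-mark intersection table.

Positions and regions are assigned per basepair in the order
CDS > intron > 5'UTR > 3'UTR > transposon > intergenic; TE enrichment uses
the expected count Se = (wgs/wgt)*st against the genome-wide superfamily
profile.
"""

import pandas as pd

import methylmem as mm
from methylmem.validation import chromatin_summary_table

cfg = mm.SimConfig(genome_length=120_000, n_te=30, n_genes=10,
                   n_labile_regions=15, chloroplast_length=5_000, seed=8)
annot = mm.simulate_annotation(cfg)
hierarchy = mm.build_hierarchy(annot.genes, annot.tes)

# per-basepair composition of the labile regions (can span several elements)
comp = mm.annotate_regions(annot.labile[["chrom", "start", "end"]], hierarchy)
cats = ["CDS", "intron", "5'UTR", "3'UTR", "transposon", "intergenic"]
totals = comp[cats].sum()
print("labile-region composition (bp per category):")
print(totals.to_string())
print(f"regions overlapping a 2-kb upstream TSS window: {int(comp['upstream_2kb'].sum())}")

# distance of each labile region to the nearest TE (0 = overlapping)
dist = mm.nearest_feature_distance(annot.labile, annot.tes)
print(f"\nlabile regions within 2 kb of a TE: {(dist <= 2000).sum()} of {len(dist)}")

# TE-superfamily enrichment of TEs near labile regions vs the genome profile
near = annot.tes[mm.overlap_with_window(annot.tes, annot.labile, flank=2000)["a_mask"]]
enrich = mm.te_enrichment(mm.count_superfamilies(near),
                          mm.count_superfamilies(annot.tes))
print("\nTE-superfamily enrichment (observed vs expected Se):")
print(enrich[["superfamily", "observed", "expected", "ratio", "p"]]
      .round(3).to_string(index=False))

# chromatin-mark intersection summary rebuilt from interval sets
table = chromatin_summary_table()
k27 = table[table["mark"] == "H3K27me3"]
print("\nH3K27me3 intersection summary (reconstructed from intervals):")
print(k27[["set", "set_size", "overlap_increased", "overlap_decreased", "percent"]]
      .to_string(index=False))
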