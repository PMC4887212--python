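import numpy as np
import pandas as pd
import pytest

import methylmem as mm
from methylmem.annotation import AnnotationHierarchy
from conftest import naive_overlap_counts, naive_nearest


def _iv(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


@pytest.fixture()
def hierarchy():
    cats = {
        "CDS": _iv([("chr1", 100, 200), ("chr1", 400, 500)]),
        "intron": _iv([("chr1", 200, 300)]),
        "5'UTR": _iv([("chr1", 80, 100)]),
        "3'UTR": _iv([("chr1", 500, 550)]),
        "transposon": _iv([("chr1", 150, 350), ("chr1", 700, 900)]),
    }
    return AnnotationHierarchy(categories=cats)


class TestHierarchy:
    def test_cds_wins_over_transposon(self, hierarchy):
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [160]})  # in CDS and TE
        assert mm.annotate_positions(pos, hierarchy)[0] == "CDS"

    def test_unannotated_is_intergenic(self, hierarchy):
        pos = pd.DataFrame({"chrom": ["chr1"], "pos": [5000]})
        assert mm.annotate_positions(pos, hierarchy)[0] == "intergenic"

    def test_order_within_hierarchy(self, hierarchy):
        # 250 is in intron and transposon -> intron; 320 only transposon
        pos = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [251, 321]})
        cats = mm.annotate_positions(pos, hierarchy)
        assert list(cats) == ["intron", "transposon"]

    def test_region_composition_conserves_length(self, hierarchy):
        regions = _iv([("chr1", 250, 350)])  # half intron, half transposon
        comp = mm.annotate_regions(regions, hierarchy)
        row = comp.iloc[0]
        assert row["intron"] == 50 and row["transposon"] == 50
        assert sum(row[c] for c in
                   ["CDS", "intron", "5'UTR", "3'UTR", "transposon", "intergenic"]) == 100

    def test_random_regions_conserve_length(self, hierarchy):
        rng = np.random.default_rng(0)
        starts = rng.integers(0, 2000, size=200)
        regions = _iv([("chr1", int(s), int(s + rng.integers(1, 400))) for s in starts])
        comp = mm.annotate_regions(regions, hierarchy)
        cats = ["CDS", "intron", "5'UTR", "3'UTR", "transposon", "intergenic"]
        lengths = regions["end"] - regions["start"]
        assert (comp[cats].sum(axis=1).to_numpy() == lengths.to_numpy()).all()

    def test_region_outside_bounds_rejected(self, hierarchy):
        with pytest.raises(ValueError, match="bounds"):
            mm.annotate_regions(_iv([("chr1", 900, 1200)]), hierarchy, {"chr1": 1000})

    def test_upstream_tss_flag_is_strand_aware(self):
        genes = pd.DataFrame(
            [
                ("chr1", 5000, 7000, "g1", 0.0, "+", "gene"),
                ("chr1", 20000, 22000, "g2", 0.0, "-", "gene"),
            ],
            columns=["chrom", "start", "end", "name", "score", "strand", "feature"],
        )
        h = mm.build_hierarchy(genes, _iv([]).assign(name=None))
        regions = _iv([
            ("chr1", 4000, 4100),   # upstream of g1 (+)
            ("chr1", 7100, 7200),   # downstream of g1: not upstream
            ("chr1", 23000, 23100), # upstream of g2 (-)
        ])
        comp = mm.annotate_regions(regions, h)
        assert list(comp["upstream_2kb"]) == [True, False, True]


class TestOverlapWindow:
    def test_flank_arithmetic(self):
        a = _iv([("chr1", 1000, 1100)])
        b = _iv([("chr1", 1550, 1600)])
        assert mm.overlap_with_window(a, b, flank=500)["n_a_overlapping"] == 1
        assert mm.overlap_with_window(a, b, flank=400)["n_a_overlapping"] == 0

    def test_zero_flank_is_strict_overlap(self):
        a = _iv([("chr1", 0, 10)])
        b = _iv([("chr1", 10, 20)])  # adjacent, not overlapping
        assert mm.overlap_with_window(a, b, flank=0)["n_a_overlapping"] == 0

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            mm.overlap_with_window(_iv([("chr1", 0, 10)]), _iv([("chr1", 5, 8)]), flank=-1)

    def test_counts_match_naive_all_pairs_oracle(self):
        rng = np.random.default_rng(17)
        def rand_set(n):
            s = rng.integers(0, 100_000, size=n)
            return pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2", "chr3"], size=n),
                "start": s,
                "end": s + rng.integers(1, 800, size=n),
            })
        for flank in (0, 100, 2000):
            a, b = rand_set(300), rand_set(300)
            res = mm.overlap_with_window(a, b, flank=flank)
            assert res["n_a_overlapping"] == naive_overlap_counts(a, b, flank)
            assert res["n_b_overlapping"] == naive_overlap_counts(b, a, flank)


class TestNearest:
    def test_gap_distance(self):
        q = _iv([("chr1", 1000, 1100)])
        f = _iv([("chr1", 1300, 1500)])
        assert mm.nearest_feature_distance(q, f)[0] == 200

    def test_overlap_is_zero(self):
        q = _iv([("chr1", 1000, 1400)])
        f = _iv([("chr1", 1300, 1500)])
        assert mm.nearest_feature_distance(q, f)[0] == 0

    def test_chromosome_without_features_is_nan(self):
        q = _iv([("chr9", 0, 10)])
        f = _iv([("chr1", 100, 200)])
        assert np.isnan(mm.nearest_feature_distance(q, f)[0])

    def test_matches_brute_force(self):
        rng = np.random.default_rng(23)
        def rand_set(n):
            s = rng.integers(0, 50_000, size=n)
            return pd.DataFrame({
                "chrom": rng.choice(["chr1", "chr2"], size=n),
                "start": s,
                "end": s + rng.integers(1, 300, size=n),
            })
        q, f = rand_set(200), rand_set(150)
        got = mm.nearest_feature_distance(q, f)
        want = naive_nearest(q, f)
        assert np.allclose(got, want, equal_nan=True)


class TestTeEnrichment:
    def test_expected_formula(self):
        res = mm.te_enrichment({"Helitron": 50}, {"Helitron": 10, "Copia": 90})
        row = res[res["superfamily"] == "Helitron"].iloc[0]
        assert row["expected"] == pytest.approx((10 / 100) * 50)
        assert row["expected"] == pytest.approx(5.0)

    def test_proportional_profile_has_unit_ratio(self):
        genome = {"Helitron": 40, "Copia": 30, "HAT": 20, "LINE/L1": 10}
        sample = {k: v // 10 for k, v in genome.items()}
        res = mm.te_enrichment(sample, genome)
        assert np.allclose(res["ratio"], 1.0)
        assert np.allclose(res["p"], 1.0)

    def test_expected_sums_to_sample_total(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            genome = {f"fam{i}": int(rng.integers(1, 200)) for i in range(6)}
            sample = {f"fam{i}": int(rng.integers(0, 50)) for i in range(6)}
            res = mm.te_enrichment(sample, genome)
            st = sum(sample.values())
            assert res["expected"].sum() == pytest.approx(st)
            assert res["observed"].sum() == st

    def test_unknown_superfamily_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            mm.te_enrichment({"Mystery": 1}, {"Helitron": 10})


class TestChromatinTable:
    def test_all_zero_when_no_overlap(self):
        dmrs = {"hypo": _iv([("chr1", 0, 10)]), "hyper": _iv([("chr1", 50, 60)])}
        mrs = _iv([("chr1", 100, 110)])
        marks = {"H3K27me3": {"increased": _iv([("chr2", 0, 10)]), "decreased": _iv([])}}
        table = mm.chromatin_overlap_table(dmrs, mrs, marks)
        assert (table["overlap_increased"] == 0).all()
        assert (table["percent"] == 0).all()

    def test_empty_dmr_set_gives_zero_row(self):
        dmrs = {"hypo": _iv([])}
        mrs = _iv([("chr1", 100, 110)])
        marks = {"H3K4me2": {"increased": _iv([("chr1", 100, 105)]), "decreased": _iv([])}}
        table = mm.chromatin_overlap_table(dmrs, mrs, marks)
        hypo = table[table["set"] == "hypo"].iloc[0]
        assert hypo["set_size"] == 0 and hypo["percent"] == 0


class TestWindowedFrequency:
    def _rec(self, rows):
        return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "total"])

    def test_single_site(self):
        rec = self._rec([("chr1", 100, "+", "CG", 4, 10)])
        out = mm.windowed_genome_frequency(rec, window=1000)
        assert out.iloc[0]["mean_frequency"] == pytest.approx(0.4)

    def test_unweighted_mean(self):
        rec = self._rec([
            ("chr1", 100, "+", "CG", 0, 10),
            ("chr1", 200, "+", "CG", 5, 5),
        ])
        out = mm.windowed_genome_frequency(rec, window=1000)
        assert out.iloc[0]["mean_frequency"] == pytest.approx(0.5)

    def test_empty_windows_missing_unless_tiled(self):
        rec = self._rec([("chr1", 100, "+", "CG", 1, 2)])
        out = mm.windowed_genome_frequency(rec, window=100, contexts=("CG",))
        assert len(out) == 1
        tiled = mm.windowed_genome_frequency(
            rec, window=100, contexts=("CG",), chrom_lengths={"chr1": 300}
        )
        assert len(tiled) == 3 and tiled["mean_frequency"].isna().sum() == 2

    def test_invalid_window_rejected(self):
        with pytest.raises(ValueError):
            mm.windowed_genome_frequency(self._rec([]), window=0)

    def test_pericentromeric_block_elevates_windows(self, small_sim):
        cfg, annot, design, tables = small_sim
        rec = mm.nuclear_table(tables[design[0].sample_id])
        out = mm.windowed_genome_frequency(rec, window=10_000, contexts=("CG",))
        out = out[out["chrom"] == "chr1"].set_index("window_start")
        peri = annot.truth.mr_truth
        dense = peri[(peri["end"] - peri["start"]) > 500]
        # windows containing large methylated blocks exceed the genome median
        med = out["mean_frequency"].median()
        covered = set((10_000 * (dense["start"] // 10_000)).tolist())
        assert out.loc[sorted(covered & set(out.index)), "mean_frequency"].mean() > med
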