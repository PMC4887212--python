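import numpy as np
import pandas as pd
import pytest
from scipy import stats

import methylmem as mm


def _zero_background():
    return {
        "methylated": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        "unmethylated": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
        "labile": {"CG": 0.0, "CHG": 0.0, "CHH": 0.0},
    }


class TestConfig:
    def test_rates_must_be_probabilities(self):
        with pytest.raises(ValueError):
            mm.SimConfig(conversion_error=1.5)

    def test_densities_must_fit(self):
        with pytest.raises(ValueError):
            mm.SimConfig(cg_density=0.5, chg_density=0.4, chh_density=0.3)


class TestAnnotation:
    def test_zero_te_request_gives_empty_set(self):
        cfg = mm.SimConfig(n_te=0, n_labile_regions=0, te_proximal=False, seed=1)
        annot = mm.simulate_annotation(cfg)
        assert len(annot.tes) == 0
        assert len(annot.truth.annotation_truth["tes"]) == 0

    def test_same_seed_identical_coordinates(self):
        cfg = mm.SimConfig(seed=1)
        a1 = mm.simulate_annotation(cfg)
        a2 = mm.simulate_annotation(cfg)
        pd.testing.assert_frame_equal(a1.tes, a2.tes)
        pd.testing.assert_frame_equal(a1.genes, a2.genes)
        pd.testing.assert_frame_equal(a1.labile, a2.labile)

    def test_labile_regions_are_te_proximal(self):
        cfg = mm.SimConfig(n_labile_regions=50, n_te=40, genome_length=400_000, seed=3)
        annot = mm.simulate_annotation(cfg)
        dist = mm.nearest_feature_distance(annot.labile, annot.tes)
        assert (dist <= 2000).sum() >= 50 * 0.95

    def test_intervals_within_chromosome_bounds(self):
        cfg = mm.SimConfig(seed=4)
        annot = mm.simulate_annotation(cfg)
        for df in (annot.tes, annot.genes, annot.labile):
            assert (df["start"] >= 0).all()
            assert (df["end"] <= cfg.genome_length).all()

    def test_superfamilies_from_configured_vocabulary(self):
        annot = mm.simulate_annotation(mm.SimConfig(seed=5))
        assert set(annot.tes["name"]) <= set(mm.simulate.TE_SUPERFAMILY_FREQS)

    def test_infeasible_placement_raises(self):
        cfg = mm.SimConfig(genome_length=2_000, n_te=4, n_genes=0,
                           n_labile_regions=0, seed=1)
        with pytest.raises(mm.PlacementError):
            mm.simulate_annotation(cfg)


class TestSamples:
    def test_unknown_sample_vocabulary_rejected(self):
        with pytest.raises(Exception, match="treatment"):
            mm.SampleMeta("x", "G1", "P0", "150", 1)

    def test_zero_everything_gives_zero_meth(self):
        cfg = mm.SimConfig(
            genome_length=30_000, n_te=5, n_genes=2, n_labile_regions=0,
            conversion_error=0.0, cg_epimutation_rate=0.0,
            background_meth=_zero_background(), p0_nonCG_gain=0.0,
            chloroplast_length=5_000, seed=6,
        )
        annot = mm.simulate_annotation(cfg)
        tables = mm.simulate_samples(cfg, annot, [mm.SampleMeta("s", "G1", "P0", "75", 1)])
        assert (tables["s"]["meth"] == 0).all()

    def test_conversion_error_recovered_within_three_se(self):
        cfg = mm.SimConfig(
            genome_length=100_000, n_te=0, n_genes=0, n_labile_regions=0,
            te_proximal=False, conversion_error=0.005, cg_epimutation_rate=0.0,
            background_meth=_zero_background(), chloroplast_length=5_000, seed=7,
        )
        annot = mm.simulate_annotation(cfg)
        tables = mm.simulate_samples(cfg, annot, [mm.SampleMeta("s", "G1", "P0", "control", 1)])
        df = mm.nuclear_table(tables["s"])
        n = df["total"].sum()
        frac = df["meth"].sum() / n
        se = np.sqrt(0.005 * 0.995 / n)
        assert abs(frac - 0.005) <= 3 * se

    def test_meth_never_exceeds_total(self, small_sim):
        _, _, _, tables = small_sim
        for df in tables.values():
            assert (df["meth"] <= df["total"]).all()
            assert (df["total"] >= 1).all()

    def test_identical_config_byte_identical_output(self, tmp_path):
        cfg = mm.SimConfig(genome_length=40_000, n_te=8, n_genes=3,
                           n_labile_regions=5, chloroplast_length=5_000, seed=8)
        design = [mm.SampleMeta("s", "G1", "P0", "25", 1)]
        out = []
        for run in range(2):
            annot = mm.simulate_annotation(cfg)
            tables = mm.simulate_samples(cfg, annot, design)
            p = tmp_path / f"run{run}.cx.tsv"
            mm.write_cytosine_table(tables["s"], p)
            out.append(p.read_bytes())
        assert out[0] == out[1]

    def test_labile_chh_gain_shifts_stressed_frequency(self):
        """A 0.4 CHH gain on a 0.1 baseline puts stressed-P0 pooled frequency
        near 0.5 while control stays near 0.1."""
        cfg = mm.SimConfig(
            genome_length=300_000, n_te=40, n_labile_regions=30, n_genes=5,
            p0_nonCG_gain=0.4, hyper_fraction=1.0, conversion_error=0.0,
            cg_epimutation_rate=0.0, chloroplast_length=5_000, seed=9,
        )
        annot = mm.simulate_annotation(cfg)
        design = [
            mm.SampleMeta("ctrl", "G1", "P0", "control", 1),
            mm.SampleMeta("salt", "G1", "P0", "75", 1),
        ]
        tables = mm.simulate_samples(cfg, annot, design)

        def pooled_chh_freq(df):
            lab = annot.labile
            sel = np.zeros(len(df), dtype=bool)
            for r in lab.itertuples(index=False):
                sel |= (
                    (df["chrom"] == r.chrom)
                    & (df["pos"] - 1 >= r.start)
                    & (df["pos"] - 1 < r.end)
                ).to_numpy()
            sub = df[sel & (df["context"] == "CHH").to_numpy()]
            return sub["meth"].sum() / sub["total"].sum()

        assert pooled_chh_freq(tables["ctrl"]) == pytest.approx(0.1, abs=0.03)
        assert pooled_chh_freq(tables["salt"]) == pytest.approx(0.5, abs=0.03)

    def test_monotone_decay_across_lineages(self):
        cfg = mm.SimConfig(
            genome_length=200_000, n_te=30, n_labile_regions=25, n_genes=5,
            hyper_fraction=1.0, conversion_error=0.0, cg_epimutation_rate=0.0,
            chloroplast_length=5_000, seed=10,
        )
        annot = mm.simulate_annotation(cfg)
        design = [mm.SampleMeta(f"{lin}", "G1", lin, "75", 1) for lin in ("P0", "P1", "P2")]
        design.append(mm.SampleMeta("ctrl", "G1", "P0", "control", 1))
        tables = mm.simulate_samples(cfg, annot, design)

        def shift(sample):
            lab = annot.labile
            out = []
            for df in (tables[sample], tables["ctrl"]):
                sel = np.zeros(len(df), dtype=bool)
                for r in lab.itertuples(index=False):
                    sel |= (
                        (df["chrom"] == r.chrom)
                        & (df["pos"] - 1 >= r.start)
                        & (df["pos"] - 1 < r.end)
                    ).to_numpy()
                sub = df[sel & df["context"].isin(["CHG", "CHH"]).to_numpy()]
                out.append(sub["meth"].sum() / sub["total"].sum())
            return abs(out[0] - out[1])

        s0, s1, s2 = shift("P0"), shift("P1"), shift("P2")
        assert s0 >= s1 >= s2
        assert s1 == pytest.approx(s0 * cfg.p1_retention, abs=0.05)

    def test_zero_retention_indistinguishable_from_control(self):
        """With p1_retention = p2_retention = 0 the stressed-lineage P1/P2
        labile-region counts pass a two-sided test vs. controls in at least
        95% of replicates (alpha = 0.01)."""
        rejections = 0
        n_reps = 20
        for rep in range(n_reps):
            cfg = mm.SimConfig(
                genome_length=60_000, n_te=15, n_labile_regions=10, n_genes=2,
                p1_retention=0.0, p2_retention=0.0, cg_epimutation_rate=0.0,
                chloroplast_length=2_000, seed=100 + rep,
            )
            annot = mm.simulate_annotation(cfg)
            design = [
                mm.SampleMeta("c", "G1", "P1", "control", 1),
                mm.SampleMeta("s", "G1", "P1", "75", 1),
            ]
            tables = mm.simulate_samples(cfg, annot, design)
            counts = []
            for sid in ("c", "s"):
                df = tables[sid]
                sel = np.zeros(len(df), dtype=bool)
                for r in annot.labile.itertuples(index=False):
                    sel |= (
                        (df["chrom"] == r.chrom)
                        & (df["pos"] - 1 >= r.start)
                        & (df["pos"] - 1 < r.end)
                    ).to_numpy()
                sub = df[sel & df["context"].isin(["CHG", "CHH"]).to_numpy()]
                counts.append((int(sub["meth"].sum()), int(sub["total"].sum())))
            (m1, t1), (m2, t2) = counts
            table = np.array([[m1, t1 - m1], [m2, t2 - m2]])
            p = stats.chi2_contingency(table)[1]
            if p < 0.01:
                rejections += 1
        assert rejections <= max(1, int(0.05 * n_reps))

    def test_chloroplast_is_unmethylated_apart_from_error(self, small_sim):
        cfg, _, design, tables = small_sim
        chloro = mm.chloroplast_table(tables[design[0].sample_id])
        rate = chloro["meth"].sum() / chloro["total"].sum()
        assert rate < 3 * cfg.conversion_error

    def test_cg_sites_emitted_on_both_strands(self, small_sim):
        _, _, design, tables = small_sim
        df = mm.nuclear_table(tables[design[0].sample_id])
        cg = df[df["context"] == "CG"]
        assert set(cg["strand"]) == {"+", "-"}
        non_cg = df[df["context"] != "CG"]
        # CHG/CHH sites are single-stranded records at distinct positions
        assert non_cg.duplicated(["chrom", "pos"]).sum() == 0

    def test_median_mr_block_length_within_truth_quartiles(self, small_sim):
        cfg, annot, design, tables = small_sim
        nuc = mm.nuclear_table(tables["G1_P0_control_r1"])
        params = mm.fit_hmm(nuc, mm.initial_params(nuc), tol=1.0, max_iter=10)
        mrs = mm.segment_mrs(nuc, params, sample_id="s")
        q25, q50, q75 = annot.truth.block_length_quartiles
        med = float(np.median(mrs["end"] - mrs["start"]))
        assert q25 <= med <= q75
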