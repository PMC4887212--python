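import pandas as pd
import pytest

import methylmem as mm
from conftest import fisher_two_sided_oracle


def _mr(ivs, sample="a"):
    return pd.DataFrame(
        [{"chrom": "chr1", "start": s, "end": e, "sample_id": sample} for s, e in ivs],
        columns=["chrom", "start", "end", "sample_id"],
    )


def _rec(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "strand", "context", "meth", "total"])


def _uniform_records(start, end, meth_of_20, spacing=10, context="CHH"):
    rows = []
    for p in range(start + 1, end + 1, spacing):  # 1-based positions
        rows.append(("chr1", p, "+", context, meth_of_20, 20))
    return _rec(rows)


class TestBuildSegments:
    def test_two_sample_breakpoint_combinatorics(self):
        cands = mm.build_segments({"A": _mr([(100, 200)], "A"), "B": _mr([(150, 250)], "B")})
        got = set(zip(cands["start"], cands["end"]))
        assert got == {(100, 150), (100, 200), (150, 200), (150, 250), (200, 250)}

    def test_single_mr_gives_single_candidate(self):
        cands = mm.build_segments({"A": _mr([(0, 100)])})
        assert len(cands) == 1
        assert (cands.iloc[0]["start"], cands.iloc[0]["end"]) == (0, 100)

    def test_no_mrs_no_candidates(self):
        assert len(mm.build_segments({"A": _mr([])})) == 0


class TestTestDmrs:
    def _run(self, meth_a, meth_b, n_sites=10, **kw):
        rows_a, rows_b = [], []
        for i in range(n_sites):
            rows_a.append(("chr1", 10 * i + 1, "+", "CHH", meth_a, 10))
            rows_b.append(("chr1", 10 * i + 1, "+", "CHH", meth_b, 10))
        records = {"a1": _rec(rows_a), "b1": _rec(rows_b)}
        cands = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 10 * n_sites}])
        groups = {"a1": "stressed", "b1": "non-stressed"}
        return mm.test_dmrs(cands, records, groups, **kw)

    def test_pooled_fisher_matches_enumeration_oracle(self):
        res = self._run(9, 1)
        # pooled 90/100 vs 10/100
        oracle = fisher_two_sided_oracle(90, 10, 10, 90)
        assert res.iloc[0]["p"] == pytest.approx(oracle, abs=1e-10)

    def test_identical_counts_not_significant(self):
        res = self._run(5, 5)
        assert len(res) == 0  # fails the min_diff_region filter, p would be 1

    def test_direction_agreement_required(self):
        # two samples in group a that disagree in direction vs b -> not tested
        rows_up = [("chr1", 10 * i + 1, "+", "CHH", 9, 10) for i in range(10)]
        rows_dn = [("chr1", 10 * i + 1, "+", "CHH", 1, 10) for i in range(10)]
        rows_b = [("chr1", 10 * i + 1, "+", "CHH", 5, 10) for i in range(10)]
        records = {"a1": _rec(rows_up), "a2": _rec(rows_dn), "b1": _rec(rows_b)}
        cands = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        groups = {"a1": "stressed", "a2": "stressed", "b1": "non-stressed"}
        res = mm.test_dmrs(cands, records, groups)
        assert len(res) == 0

    def test_empty_segment_skipped_without_exception(self):
        records = {"a1": _uniform_records(0, 100, 10), "b1": _uniform_records(0, 100, 0)}
        cands = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 100},
                {"chrom": "chr1", "start": 5000, "end": 6000},  # no sites
            ]
        )
        groups = {"a1": "stressed", "b1": "non-stressed"}
        res = mm.test_dmrs(cands, records, groups)
        assert len(res) == 1

    def test_eligibility_requires_full_mr_coverage(self):
        records = {"a1": _uniform_records(0, 200, 18), "b1": _uniform_records(0, 200, 1)}
        cands = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 200}])
        groups = {"a1": "stressed", "b1": "non-stressed"}
        covered = {"a1": _mr([(0, 200)], "a1"), "b1": _mr([], "b1")}
        partial = {"a1": _mr([(0, 100)], "a1"), "b1": _mr([], "b1")}
        res_full = mm.test_dmrs(cands, records, groups, mr_sets=covered)
        res_part = mm.test_dmrs(cands, records, groups, mr_sets=partial)
        assert res_full.iloc[0]["eligible"] and res_full.iloc[0]["significant"]
        assert not res_part.iloc[0]["eligible"] and not res_part.iloc[0]["significant"]

    def test_nested_significant_segments_resolved_to_lowest_q(self):
        records = {"a1": _uniform_records(0, 300, 18), "b1": _uniform_records(0, 300, 1)}
        cands = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 300},
                {"chrom": "chr1", "start": 0, "end": 150},
                {"chrom": "chr1", "start": 150, "end": 300},
            ]
        )
        groups = {"a1": "stressed", "b1": "non-stressed"}
        res = mm.test_dmrs(cands, records, groups)
        sig = mm.significant_dmrs(res)
        assert len(sig) == 1
        assert (sig.iloc[0]["start"], sig.iloc[0]["end"]) == (0, 300)


class TestClassifyDirection:
    def test_hyper_vs_combined_controls(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        records = {
            "ctrl": _uniform_records(0, 100, 10),  # freq 0.5
            "s": _uniform_records(0, 100, 16),  # freq 0.8
        }
        out = mm.classify_direction(dmrs, records, ["ctrl"], ["s"])
        row = out.iloc[0]
        assert row["direction"] == "hyper"
        assert row["difference"] == pytest.approx(0.3)

    def test_equal_is_unchanged(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        records = {"ctrl": _uniform_records(0, 100, 10), "s": _uniform_records(0, 100, 10)}
        out = mm.classify_direction(dmrs, records, ["ctrl"], ["s"])
        assert out.iloc[0]["direction"] == "unchanged"

    def test_monotone_decay_of_net_change(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        records = {
            "ctrl": _uniform_records(0, 100, 10),  # 0.5
            "P0": _uniform_records(0, 100, 18),  # 0.9
            "P1": _uniform_records(0, 100, 14),  # 0.7
            "P2": _uniform_records(0, 100, 10),  # 0.5
        }
        out = mm.classify_direction(dmrs, records, ["ctrl"], ["P0", "P1", "P2"])
        changes = out.set_index("sample_id")["abs_change"]
        assert changes["P0"] == pytest.approx(0.4)
        assert changes["P1"] == pytest.approx(0.2)
        assert changes["P2"] == pytest.approx(0.0)
        assert changes["P0"] >= changes["P1"] >= changes["P2"]

    def test_missing_control_coverage_skips_segment(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 5000, "end": 5100}])
        records = {"ctrl": _uniform_records(0, 100, 10), "s": _uniform_records(0, 100, 16)}
        out = mm.classify_direction(dmrs, records, ["ctrl"], ["s"])
        assert len(out) == 0


class TestFrequencyMatrix:
    def test_unweighted_mean_entry(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50}])
        rec = _rec([
            ("chr1", 10, "+", "CHH", 2, 10),  # 0.2
            ("chr1", 20, "+", "CHH", 4, 5),  # 0.8
        ])
        matrix = mm.dmr_frequency_matrix(dmrs, {"s": rec, "t": rec})
        assert matrix.loc["s"].iloc[0] == pytest.approx(0.5)

    def test_uncovered_sample_drops_dmr(self):
        dmrs = pd.DataFrame(
            [
                {"chrom": "chr1", "start": 0, "end": 50},
                {"chrom": "chr1", "start": 100, "end": 150},
            ]
        )
        rec_full = _rec([
            ("chr1", 10, "+", "CHH", 2, 10),
            ("chr1", 110, "+", "CHH", 2, 10),
        ])
        rec_partial = _rec([("chr1", 10, "+", "CHH", 2, 10)])
        matrix = mm.dmr_frequency_matrix(dmrs, {"a": rec_full, "b": rec_partial})
        assert matrix.shape[1] == 1

    def test_empty_matrix_rejected(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 50}])
        rec_empty = _rec([("chr2", 10, "+", "CHH", 2, 10)])
        with pytest.raises(ValueError, match="covered in all samples"):
            mm.dmr_frequency_matrix(dmrs, {"a": rec_empty})

    def test_difference_sign_matches_direction_classification(self):
        dmrs = pd.DataFrame([{"chrom": "chr1", "start": 0, "end": 100}])
        records = {
            "ctrl": _uniform_records(0, 100, 10),
            "s": _uniform_records(0, 100, 16),
        }
        matrix = mm.dmr_frequency_matrix(dmrs, records)
        diff = matrix.loc["s"].iloc[0] - matrix.loc["ctrl"].iloc[0]
        cls = mm.classify_direction(dmrs, records, ["ctrl"], ["s"]).iloc[0]["direction"]
        assert (diff > 0) == (cls == "hyper")


class TestGroupAssignment:
    def test_study_grouping(self):
        metas = mm.default_design(generations=("G3",), replicates=1)
        groups = mm.assign_groups(metas, "G3")
        assert groups["G3_P0_control_r1"] == "non-stressed"
        assert groups["G3_P1_control_r1"] == "non-stressed"
        assert groups["G3_P0_75_r1"] == "stressed"
        assert groups["G3_P1_25_r1"] == "stressed-P1"
        assert groups["G3_P2_75_r1"] == "stressed-P2"

    def test_other_generations_excluded(self):
        metas = mm.default_design(replicates=1)
        groups = mm.assign_groups(metas, "G1")
        assert all(s.startswith("G1") for s in groups)
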