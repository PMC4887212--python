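"""Differentially methylated regions (DMRs) between treatment groups.

Candidate segments are built combinatorially from the pooled MR breakpoints
of all samples: every (start, end) pair of breakpoints that lies entirely
inside at least one sample's methylated region is a candidate. Candidates
are tested between sample groups by pooling methylated/total read counts per
group over all cytosines in the segment and applying a two-sided Fisher
exact test; a segment-pair is only tested when the pooled frequency
difference is at least ``min_diff_region`` and every sample within each
group agrees in direction of change against the other group. BH correction
runs over all tested (segment, pair) combinations; nested/overlapping
significant segments of a group pair are resolved greedily to the lowest-q,
longest segment.

Within a generation the four groups follow the study design: 'non-stressed'
(all control samples of P0/P1/P2), 'stressed' (salt-treated P0),
'stressed-P1' and 'stressed-P2' (unstressed descendants of stressed P0).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import SampleMeta
from .hmm import CONTEXTS

logger = logging.getLogger(__name__)

GROUPS = ("non-stressed", "stressed", "stressed-P1", "stressed-P2")


def assign_groups(metas: Sequence[SampleMeta], generation: str) -> dict[str, str]:
    """Map sample_id -> group label within one generation.

    Control samples of all lineages are 'non-stressed'; salt-treated P0 are
    'stressed'; P1/P2 descendants of salt-treated P0 are 'stressed-P1' and
    'stressed-P2'.
    """
    out: dict[str, str] = {}
    for m in metas:
        if m.generation != generation:
            continue
        if m.treatment == "control":
            out[m.sample_id] = "non-stressed"
        elif m.lineage == "P0":
            out[m.sample_id] = "stressed"
        elif m.lineage == "P1":
            out[m.sample_id] = "stressed-P1"
        else:
            out[m.sample_id] = "stressed-P2"
    return out


# ---------------------------------------------------------------------------
# candidate segments
# ---------------------------------------------------------------------------


def build_segments(mr_sets: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Candidate segments from the pooled MR breakpoints of all samples.

    Breakpoints are all MR starts/ends per chromosome across samples; every
    breakpoint pair (start < end) fully inside at least one sample's MR is a
    candidate. Deduplicated, sorted by (chrom, start, end).
    """
    per_chrom_points: dict[str, set[int]] = {}
    for df in mr_sets.values():
        for row in df.itertuples(index=False):
            per_chrom_points.setdefault(row.chrom, set()).update((row.start, row.end))
    candidates: set[tuple[str, int, int]] = set()
    for sample, df in mr_sets.items():
        for row in df.itertuples(index=False):
            pts = np.array(sorted(per_chrom_points[row.chrom]))
            inside = pts[(pts >= row.start) & (pts <= row.end)]
            for i in range(len(inside)):
                for j in range(i + 1, len(inside)):
                    candidates.add((row.chrom, int(inside[i]), int(inside[j])))
    out = pd.DataFrame(sorted(candidates), columns=["chrom", "start", "end"])
    return out


# ---------------------------------------------------------------------------
# per-segment count pooling
# ---------------------------------------------------------------------------


class _SegmentCounter:
    """Prefix sums of per-sample (meth, total) along sorted site coordinates,
    per chromosome and context, for O(log n) segment count queries."""

    def __init__(self, records: pd.DataFrame):
        self._data: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        df = records.sort_values(["chrom", "pos"], kind="mergesort")
        coord = df["pos"].to_numpy(np.int64) - 1  # 0-based site coordinate
        for (chrom, ctx), sub in df.assign(_coord=coord).groupby(["chrom", "context"]):
            c = sub["_coord"].to_numpy(np.int64)
            meth = np.concatenate([[0], np.cumsum(sub["meth"].to_numpy(np.int64))])
            total = np.concatenate([[0], np.cumsum(sub["total"].to_numpy(np.int64))])
            self._data[(chrom, ctx)] = (c, meth, total)

    def counts(self, chrom: str, start: int, end: int, context: str | None = None):
        """(meth, total, n_sites) pooled over sites in [start, end)."""
        keys = (
            [(chrom, context)]
            if context
            else [(chrom, c) for c in CONTEXTS]
        )
        meth = total = nsites = 0
        for key in keys:
            if key not in self._data:
                continue
            coords, cm, ct = self._data[key]
            i = np.searchsorted(coords, start, side="left")
            j = np.searchsorted(coords, end, side="left")
            meth += int(cm[j] - cm[i])
            total += int(ct[j] - ct[i])
            nsites += int(j - i)
        return meth, total, nsites


def pooled_frequency(
    counter: "_SegmentCounter", chrom: str, start: int, end: int, context: str | None = None
) -> float:
    meth, total, _ = counter.counts(chrom, start, end, context)
    return meth / total if total else np.nan


# ---------------------------------------------------------------------------
# DMR testing
# ---------------------------------------------------------------------------


def test_dmrs(
    candidates: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    groups: Mapping[str, str],
    mr_sets: Mapping[str, pd.DataFrame] | None = None,
    fdr: float = 0.05,
    min_diff_region: float = 0.10,
    group_pairs: Sequence[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Test candidate segments for differential methylation between groups.

    For each candidate and group pair, meth/total counts are pooled per
    group over all sites in the segment (all contexts); the 2x2 pooled table
    is tested with a two-sided Fisher exact test when the pooled absolute
    frequency difference is >= ``min_diff_region`` and every sample within
    each group changes in the same direction relative to the other group's
    pooled frequency. BH correction is applied over all tested
    (segment, pair) combinations of the run; overlapping significant
    segments of a pair are resolved to the lowest-q, longest one.

    When ``mr_sets`` is given, a segment is only eligible for a sample group
    if at least one sample's MR set covers the whole segment ("high
    methylation state throughout"); the eligibility flag is stored.
    """
    counters = {s: _SegmentCounter(df) for s, df in records.items()}
    group_members: dict[str, list[str]] = {}
    for sample, g in groups.items():
        group_members.setdefault(g, []).append(sample)
    present = sorted(group_members)
    if group_pairs is None:
        group_pairs = [
            (a, b) for i, a in enumerate(present) for b in present[i + 1 :]
        ]
    coverage = _mr_coverage_index(mr_sets) if mr_sets is not None else None

    rows = []
    for seg in candidates.itertuples(index=False):
        eligible = (
            _segment_eligible(coverage, seg.chrom, seg.start, seg.end)
            if coverage is not None
            else True
        )
        pooled = {}
        per_sample_freq = {}
        skip_pair: set[tuple[str, str]] = set()
        for g, members in group_members.items():
            m = t = 0
            freqs = {}
            for s in members:
                sm, stt, _ = counters[s].counts(seg.chrom, seg.start, seg.end)
                if stt == 0:
                    freqs[s] = np.nan
                else:
                    freqs[s] = sm / stt
                m += sm
                t += stt
            pooled[g] = (m, t)
            per_sample_freq[g] = freqs
        for ga, gb in group_pairs:
            if ga not in pooled or gb not in pooled:
                continue
            ma, ta = pooled[ga]
            mb, tb = pooled[gb]
            if ta == 0 or tb == 0:
                logger.debug(
                    "segment %s:%d-%d skipped for (%s, %s): no covered sites",
                    seg.chrom, seg.start, seg.end, ga, gb,
                )
                continue
            fa, fb = ma / ta, mb / tb
            if abs(fa - fb) < min_diff_region:
                continue
            sign = np.sign(fa - fb)
            agree = all(
                np.isfinite(f) and np.sign(f - fb) == sign
                for f in per_sample_freq[ga].values()
            ) and all(
                np.isfinite(f) and np.sign(fa - f) == sign
                for f in per_sample_freq[gb].values()
            )
            if not agree:
                continue
            p = stats.fisher_exact([[ma, ta - ma], [mb, tb - mb]])[1]
            row = {
                "chrom": seg.chrom,
                "start": seg.start,
                "end": seg.end,
                "group_a": ga,
                "group_b": gb,
                "meth_a": ma,
                "total_a": ta,
                "meth_b": mb,
                "total_b": tb,
                "freq_a": fa,
                "freq_b": fb,
                "p": p,
                "eligible": bool(eligible),
                "sample_freqs": {
                    **{s: per_sample_freq[ga][s] for s in per_sample_freq[ga]},
                    **{s: per_sample_freq[gb][s] for s in per_sample_freq[gb]},
                },
            }
            for ctx in CONTEXTS:
                cm_a = ct_a = cm_b = ct_b = 0
                for s in group_members[ga]:
                    m_, t_, _ = counters[s].counts(seg.chrom, seg.start, seg.end, ctx)
                    cm_a += m_
                    ct_a += t_
                for s in group_members[gb]:
                    m_, t_, _ = counters[s].counts(seg.chrom, seg.start, seg.end, ctx)
                    cm_b += m_
                    ct_b += t_
                row[f"freq_a_{ctx}"] = cm_a / ct_a if ct_a else np.nan
                row[f"freq_b_{ctx}"] = cm_b / ct_b if ct_b else np.nan
                row[f"n_sites_{ctx}"] = counters[next(iter(records))].counts(
                    seg.chrom, seg.start, seg.end, ctx
                )[2]
            rows.append(row)
    result = pd.DataFrame(rows)
    if result.empty:
        return result
    reject, q, *_ = multipletests(result["p"], alpha=fdr, method="fdr_bh")
    result["q"] = q
    result["significant"] = reject & result["eligible"]
    return _resolve_overlaps(result)


def _mr_coverage_index(mr_sets: Mapping[str, pd.DataFrame]):
    from .intervals import merge_intervals

    index = {}
    for sample, df in mr_sets.items():
        merged = merge_intervals(df)
        index[sample] = {
            chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
            for chrom, sub in merged.groupby("chrom")
        }
    return index


def _segment_eligible(coverage, chrom: str, start: int, end: int) -> bool:
    for per_chrom in coverage.values():
        if chrom not in per_chrom:
            continue
        starts, ends = per_chrom[chrom]
        i = np.searchsorted(starts, start, side="right") - 1
        if i >= 0 and starts[i] <= start and ends[i] >= end:
            return True
    return False


def _resolve_overlaps(result: pd.DataFrame) -> pd.DataFrame:
    """Among significant segments of each group pair, greedily keep the
    lowest-q (ties: longest) segment and drop overlapping ones."""
    keep = np.ones(len(result), dtype=bool)
    result = result.reset_index(drop=True)
    result["length"] = result["end"] - result["start"]
    for (ga, gb), sub in result[result["significant"]].groupby(["group_a", "group_b"]):
        order = sub.sort_values(["q", "length"], ascending=[True, False]).index
        taken: dict[str, list[tuple[int, int]]] = {}
        for idx in order:
            row = result.loc[idx]
            ivs = taken.setdefault(row["chrom"], [])
            if any(row["start"] < e and row["end"] > s for s, e in ivs):
                keep[idx] = False
            else:
                ivs.append((row["start"], row["end"]))
    out = result.copy()
    out.loc[~keep, "significant"] = False
    out["retained"] = keep & out["significant"]
    return out


def significant_dmrs(result: pd.DataFrame) -> pd.DataFrame:
    """Significant, overlap-resolved DMRs."""
    if result.empty:
        return result
    return result[result["significant"]].reset_index(drop=True)


# ---------------------------------------------------------------------------
# direction classification & frequency matrices
# ---------------------------------------------------------------------------


def classify_direction(
    dmrs: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    control_samples: Sequence[str],
    target_samples: Sequence[str],
) -> pd.DataFrame:
    """Hyper/hypo classification of DMRs per sample vs. combined controls.

    The reference for each DMR is the pooled methylation frequency over the
    combined control samples; the difference is sample frequency minus the
    combined-control frequency (positive = hyper, negative = hypo, zero =
    unchanged). Also reports the absolute net change ``abs_change``.
    """
    counters = {s: _SegmentCounter(records[s]) for s in set(control_samples) | set(target_samples)}
    rows = []
    for seg in dmrs.itertuples(index=False):
        cm = ct = 0
        for s in control_samples:
            m, t, _ = counters[s].counts(seg.chrom, seg.start, seg.end)
            cm += m
            ct += t
        if ct == 0:
            logger.debug(
                "segment %s:%d-%d skipped: no control coverage", seg.chrom, seg.start, seg.end
            )
            continue
        control_freq = cm / ct
        for s in target_samples:
            m, t, _ = counters[s].counts(seg.chrom, seg.start, seg.end)
            if t == 0:
                continue
            diff = m / t - control_freq
            rows.append(
                {
                    "chrom": seg.chrom,
                    "start": seg.start,
                    "end": seg.end,
                    "sample_id": s,
                    "sample_freq": m / t,
                    "control_freq": control_freq,
                    "difference": diff,
                    "abs_change": abs(diff),
                    "direction": "hyper" if diff > 0 else ("hypo" if diff < 0 else "unchanged"),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom", "start", "end", "sample_id", "sample_freq",
            "control_freq", "difference", "abs_change", "direction",
        ],
    )


def net_change_by_class(directions: pd.DataFrame, classes: Mapping[str, str]) -> pd.Series:
    """Mean absolute net methylation change per sample class across all DMRs."""
    df = directions.assign(cls=directions["sample_id"].map(classes))
    return df.groupby("cls")["abs_change"].mean()


def dmr_frequency_matrix(
    dmrs: pd.DataFrame,
    records: Mapping[str, pd.DataFrame],
    context: str | None = None,
) -> pd.DataFrame:
    """Sample x DMR matrix of mean per-site methylation frequencies.

    Entries are unweighted means of per-site frequencies inside the DMR;
    DMRs not covered in all samples are dropped (as in the clustering input
    rule). ``context`` restricts sites to one methylation context.
    """
    seen = set()
    intervals = []
    for seg in dmrs.itertuples(index=False):
        key = (seg.chrom, seg.start, seg.end)
        if key not in seen:
            seen.add(key)
            intervals.append(key)
    samples = sorted(records)
    data = np.full((len(samples), len(intervals)), np.nan)
    for si, s in enumerate(samples):
        df = records[s]
        if context:
            df = df[df["context"] == context]
        df = df.sort_values(["chrom", "pos"], kind="mergesort")
        coord = df["pos"].to_numpy(np.int64) - 1
        chroms = df["chrom"].to_numpy()
        freq = (df["meth"] / df["total"]).to_numpy()
        by_chrom = {}
        for chrom in np.unique(chroms):
            sel = chroms == chrom
            by_chrom[chrom] = (coord[sel], freq[sel])
        for di, (chrom, start, end) in enumerate(intervals):
            if chrom not in by_chrom:
                continue
            c, f = by_chrom[chrom]
            i, j = np.searchsorted(c, (start, end), side="left")
            if j > i:
                data[si, di] = f[i:j].mean()
    cols = [f"{c}:{s}-{e}" for c, s, e in intervals]
    matrix = pd.DataFrame(data, index=samples, columns=cols)
    matrix = matrix.dropna(axis=1, how="any")
    if matrix.shape[1] == 0:
        raise ValueError("no DMR is covered in all samples; frequency matrix is empty")
    return matrix
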