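"""Hierarchical genomic annotation, overlap/nearest analyses, TE enrichment.

Every genomic base maps to exactly one category, assigned hierarchically in
the order CDS > intron > 5'UTR > 3'UTR > transposon > intergenic (first
containing category wins; bases in no element are intergenic). Regions are
annotated by basepair, so one region can stretch over several elements and
its composition sums exactly to its length.

TE-superfamily enrichment compares the superfamily profile of a query TE set
(e.g. TEs next to hypermethylated DMRs) against the genome-wide profile: the
expected count for a superfamily is ``Se = (wgs / wgt) * st`` where ``wgs``
is the genome-wide count of that superfamily, ``wgt`` the genome-wide total,
and ``st`` the query-set total, with a two-sided binomial test per
superfamily.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import (
    contains_points,
    covered_length,
    merge_intervals,
    nearest_distance,
    overlaps_any,
    subtract,
)

HIERARCHY_ORDER = ["CDS", "intron", "5'UTR", "3'UTR", "transposon", "intergenic"]


@dataclass
class AnnotationHierarchy:
    """Ordered category -> interval-frame mapping plus gene TSS windows.

    ``categories`` maps each category (except the implicit ``intergenic``)
    to an interval frame. ``tss_windows`` is the strand-aware 2-kb-upstream
    window set of annotated transcription starts, used as an auxiliary flag.
    """

    categories: dict[str, pd.DataFrame]
    tss_windows: pd.DataFrame | None = None
    order: Sequence[str] = tuple(HIERARCHY_ORDER[:-1])

    def __post_init__(self) -> None:
        self._merged: dict[str, dict[str, tuple[np.ndarray, np.ndarray]]] = {}
        for cat in self.order:
            df = self.categories.get(cat, pd.DataFrame(columns=["chrom", "start", "end"]))
            merged = merge_intervals(df) if len(df) else df
            self._merged[cat] = {
                chrom: (sub["start"].to_numpy(np.int64), sub["end"].to_numpy(np.int64))
                for chrom, sub in merged.groupby("chrom", sort=True)
            } if len(merged) else {}


def build_hierarchy(
    gene_features: pd.DataFrame,
    transposons: pd.DataFrame,
    upstream_bp: int = 2000,
) -> AnnotationHierarchy:
    """Assemble the hierarchy from a GFF-style gene feature frame and a TE set.

    ``gene_features`` needs a ``feature`` column with (at least) ``CDS``,
    ``intron``, ``five_prime_UTR``, ``three_prime_UTR`` and ``gene`` rows;
    gene rows supply strand-aware TSS windows of ``upstream_bp`` bp.
    """
    fmap = {
        "CDS": "CDS",
        "intron": "intron",
        "five_prime_UTR": "5'UTR",
        "three_prime_UTR": "3'UTR",
    }
    cats: dict[str, pd.DataFrame] = {v: gene_features[gene_features["feature"] == k][
        ["chrom", "start", "end"]
    ].reset_index(drop=True) for k, v in fmap.items()}
    cats["transposon"] = transposons[["chrom", "start", "end"]].reset_index(drop=True)
    genes = gene_features[gene_features["feature"] == "gene"]
    windows = []
    for row in genes.itertuples(index=False):
        if getattr(row, "strand", "+") == "-":
            windows.append((row.chrom, row.end, row.end + upstream_bp))
        else:
            windows.append((row.chrom, max(0, row.start - upstream_bp), row.start))
    tss = pd.DataFrame(windows, columns=["chrom", "start", "end"])
    tss = tss[tss["start"] < tss["end"]].reset_index(drop=True)
    return AnnotationHierarchy(categories=cats, tss_windows=tss)


def annotate_positions(positions: pd.DataFrame, hierarchy: AnnotationHierarchy) -> np.ndarray:
    """Category per position (frame with ``chrom`` and 1-based ``pos``)."""
    chroms = positions["chrom"].to_numpy()
    pts = positions["pos"].to_numpy(np.int64) - 1  # to 0-based
    out = np.full(len(positions), "intergenic", dtype=object)
    unassigned = np.ones(len(positions), dtype=bool)
    for cat in hierarchy.order:
        per_chrom = hierarchy._merged[cat]
        for chrom, (starts, ends) in per_chrom.items():
            sel = unassigned & (chroms == chrom)
            if not sel.any():
                continue
            hit = contains_points(pts[sel], starts, ends)
            idx = np.flatnonzero(sel)[hit]
            out[idx] = cat
            unassigned[idx] = False
    return out


def annotate_regions(
    regions: pd.DataFrame,
    hierarchy: AnnotationHierarchy,
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-basepair category composition of each region.

    Returns one row per region with a count column per category (summing to
    the region length) and ``upstream_2kb``: whether the region overlaps the
    2-kb window upstream of any annotated transcription start.
    """
    if chrom_lengths is not None:
        for row in regions.itertuples(index=False):
            length = chrom_lengths.get(row.chrom)
            if length is not None and (row.start < 0 or row.end > length):
                raise ValueError(
                    f"region {row.chrom}:{row.start}-{row.end} outside chromosome bounds"
                )
    rows = []
    for row in regions.itertuples(index=False):
        remaining_s = np.array([row.start], dtype=np.int64)
        remaining_e = np.array([row.end], dtype=np.int64)
        comp = {}
        for cat in hierarchy.order:
            starts, ends = hierarchy._merged[cat].get(row.chrom, (np.empty(0), np.empty(0)))
            bp = sum(
                covered_length(s, e, np.asarray(starts), np.asarray(ends))
                for s, e in zip(remaining_s, remaining_e)
            )
            comp[cat] = int(bp)
            if bp and len(starts):
                remaining_s, remaining_e = subtract(
                    remaining_s, remaining_e, np.asarray(starts), np.asarray(ends)
                )
        comp["intergenic"] = int((remaining_e - remaining_s).sum())
        rows.append({"chrom": row.chrom, "start": row.start, "end": row.end, **comp})
    out = pd.DataFrame(rows, columns=["chrom", "start", "end"] + HIERARCHY_ORDER)
    if hierarchy.tss_windows is not None and len(out):
        out["upstream_2kb"] = overlaps_any(out, hierarchy.tss_windows)
    elif len(out):
        out["upstream_2kb"] = False
    return out


def overlap_with_window(
    set_a: pd.DataFrame, set_b: pd.DataFrame, flank: int = 0
) -> dict:
    """Overlap of two interval sets allowing a +-``flank`` bp window.

    An a-element counts iff [a.start - flank, a.end + flank) intersects any
    b-element; each element counts once regardless of how many partners it
    touches. Returns counts for both directions and the pair list.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    a_hits = overlaps_any(set_a, set_b, flank=flank) if len(set_b) else np.zeros(len(set_a), bool)
    b_hits = overlaps_any(set_b, set_a, flank=flank) if len(set_a) else np.zeros(len(set_b), bool)
    pairs = []
    for ia, ra in set_a.reset_index(drop=True).iterrows():
        if not a_hits[ia]:
            continue
        sub = set_b[(set_b["chrom"] == ra["chrom"])
                    & (set_b["start"] < ra["end"] + flank)
                    & (set_b["end"] > ra["start"] - flank)]
        for ib in sub.index:
            pairs.append((ia, int(ib)))
    return {
        "n_a": int(len(set_a)),
        "n_b": int(len(set_b)),
        "n_a_overlapping": int(a_hits.sum()),
        "n_b_overlapping": int(b_hits.sum()),
        "fraction_a": float(a_hits.mean()) if len(set_a) else 0.0,
        "pairs": pairs,
        "a_mask": a_hits,
        "b_mask": b_hits,
    }


def nearest_feature_distance(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    """Gap in bp between each query and the closest feature edge (0 = overlap;
    NaN on chromosomes without features)."""
    return nearest_distance(query, features)


def te_enrichment(
    sample_counts: Mapping[str, int], genome_counts: Mapping[str, int]
) -> pd.DataFrame:
    """Observed vs. expected TE-superfamily counts.

    Expected count per superfamily: ``Se = (wgs / wgt) * st``; p-value from a
    two-sided binomial test of the observed count with n = st, p = wgs/wgt.
    """
    wgt = sum(genome_counts.values())
    if wgt <= 0:
        raise ValueError("genome-wide TE count must be positive")
    unknown = set(sample_counts) - set(genome_counts)
    if unknown:
        raise ValueError(
            f"superfamilies absent genome-wide: {', '.join(sorted(unknown))}"
        )
    st = sum(sample_counts.values())
    rows = []
    for fam in sorted(genome_counts):
        wgs = genome_counts[fam]
        observed = int(sample_counts.get(fam, 0))
        se = (wgs / wgt) * st
        p = (
            stats.binomtest(observed, n=st, p=wgs / wgt, alternative="two-sided").pvalue
            if st > 0
            else 1.0
        )
        rows.append(
            {
                "superfamily": fam,
                "observed": observed,
                "st": st,
                "wgs": wgs,
                "wgt": wgt,
                "expected": se,
                "ratio": observed / se if se > 0 else np.nan,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def count_superfamilies(te_set: pd.DataFrame, name_col: str = "name") -> dict[str, int]:
    """Tally TE intervals by superfamily label."""
    return te_set[name_col].value_counts().to_dict()


def chromatin_overlap_table(
    dmr_sets: Mapping[str, pd.DataFrame],
    mr_set: pd.DataFrame,
    mark_sets: Mapping[str, Mapping[str, pd.DataFrame]],
) -> pd.DataFrame:
    """Intersection counts of DMR/MR sets with altered chromatin-mark regions.

    ``mark_sets[mark]`` maps ``"increased"``/``"decreased"`` to interval
    frames of regions where the mark changed after stress. For each mark and
    each query set (e.g. hypo DMRs, hyper DMRs, MRs) the strict-overlap
    counts against both directions are reported, plus the percentage
    (increased + decreased overlaps over the set size, rounded to the
    nearest integer; the raw fraction is retained).
    """
    query_sets = dict(dmr_sets)
    query_sets["MRs"] = mr_set
    rows = []
    for mark, directions in mark_sets.items():
        for qname, qset in query_sets.items():
            counts = {}
            for direction in ("increased", "decreased"):
                marks = directions.get(direction, pd.DataFrame(columns=["chrom", "start", "end"]))
                if len(qset) == 0 or len(marks) == 0:
                    counts[direction] = 0
                else:
                    counts[direction] = int(overlaps_any(qset, marks, flank=0).sum())
            size = len(qset)
            frac = (counts["increased"] + counts["decreased"]) / size if size else 0.0
            rows.append(
                {
                    "mark": mark,
                    "set": qname,
                    "set_size": size,
                    "overlap_increased": counts["increased"],
                    "overlap_decreased": counts["decreased"],
                    "fraction": frac,
                    "percent": int(round(frac * 100)),
                }
            )
    return pd.DataFrame(rows)


def windowed_genome_frequency(
    records: pd.DataFrame,
    window: int = 250_000,
    contexts: Sequence[str] = ("CG", "CHG", "CHH"),
    chrom_lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Mean methylation frequency per non-overlapping genomic window.

    The entry for (chrom, window, context) is the unweighted mean of
    per-site frequencies; windows without covered sites are absent (or NaN
    when ``chrom_lengths`` forces a complete tiling).
    """
    if window <= 0:
        raise ValueError("window must be positive")
    df = records[records["context"].isin(contexts)].copy()
    df["window_start"] = ((df["pos"] - 1) // window) * window
    df["frequency"] = df["meth"] / df["total"]
    out = (
        df.groupby(["chrom", "window_start", "context"], as_index=False)["frequency"]
        .mean()
        .rename(columns={"frequency": "mean_frequency"})
    )
    if chrom_lengths:
        full = []
        for chrom, length in chrom_lengths.items():
            for ws in range(0, length, window):
                for c in contexts:
                    full.append((chrom, ws, c))
        grid = pd.DataFrame(full, columns=["chrom", "window_start", "context"])
        out = grid.merge(out, on=["chrom", "window_start", "context"], how="left")
    return out
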