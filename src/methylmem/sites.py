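"""Methylated-site calling and differentially methylated positions (DMPs).

A cytosine is called *methylated* in a sample when its methylated-read count
is incompatible with the bisulfite non-conversion (false methylation) rate,
estimated from the unmethylated chloroplast genome: a one-sided binomial
test against the error rate, Benjamini-Hochberg corrected per sample.

A *DMP* between two samples is a position with a methylation-frequency
difference of at least ``min_diff`` (boundary inclusive) whose 2x2 read
count table [[meth_a, unmeth_a], [meth_b, unmeth_b]] is significant under a
two-sided Fisher exact test after BH correction. The pipeline driver only
compares samples belonging to the same treatment group, so that methylation
changes due to batch fluctuations between growth rounds are excluded.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def estimate_error_rate(chloroplast_records: pd.DataFrame) -> float:
    """Pooled false-methylation rate over all chloroplast cytosines.

    ``rate = sum(meth) / sum(total)`` — the chloroplast genome is
    unmethylated, so any methylated read is a non-conversion event.
    """
    total = int(chloroplast_records["total"].sum())
    if total <= 0:
        raise ValueError("zero coverage on the chloroplast control chromosome")
    return float(chloroplast_records["meth"].sum()) / total


def coverage_universe(
    tables: Mapping[str, pd.DataFrame],
    min_cov: int = 3,
    min_fraction_samples: float = 0.5,
) -> pd.DataFrame:
    """Positions entering the analysis universe.

    A (chrom, pos, strand) site is retained iff it is covered by at least
    ``min_cov`` reads in *strictly more* than ``min_fraction_samples`` of the
    samples.
    """
    n_samples = len(tables)
    counts = None
    for df in tables.values():
        ok = df.loc[df["total"] >= min_cov, ["chrom", "pos", "strand"]]
        c = ok.groupby(["chrom", "pos", "strand"]).size()
        counts = c if counts is None else counts.add(c, fill_value=0)
    if counts is None:
        raise ValueError("no sample tables supplied")
    keep = counts[counts > min_fraction_samples * n_samples]
    out = keep.reset_index()[["chrom", "pos", "strand"]]
    return out.sort_values(["chrom", "pos", "strand"], kind="mergesort").reset_index(drop=True)


def call_methylated_sites(
    tables: Mapping[str, pd.DataFrame],
    error_rate: float,
    min_cov: int = 3,
    min_fraction_samples: float = 0.5,
    site_fdr: float = 0.05,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Call methylated cytosines per sample within the coverage universe.

    Returns ``(calls, universe)`` where ``calls[sample]`` adds columns
    ``frequency, p_site, q_site, is_methylated`` to the sample's records
    restricted to the universe, and ``universe`` is the retained-site frame.
    """
    if not 0 <= error_rate < 1:
        raise ValueError(f"error_rate must be in [0, 1), got {error_rate}")
    universe = coverage_universe(tables, min_cov, min_fraction_samples)
    key = pd.MultiIndex.from_frame(universe)
    calls: dict[str, pd.DataFrame] = {}
    for sample, df in tables.items():
        idx = pd.MultiIndex.from_frame(df[["chrom", "pos", "strand"]])
        sub = df[idx.isin(key)].reset_index(drop=True)
        sub = sub.copy()
        sub["frequency"] = sub["meth"] / sub["total"]
        sub["p_site"] = binomial_tail_p(
            sub["meth"].to_numpy(), sub["total"].to_numpy(), error_rate
        )
        if len(sub):
            reject, q, *_ = multipletests(sub["p_site"], alpha=site_fdr, method="fdr_bh")
        else:
            reject, q = np.zeros(0, bool), np.zeros(0)
        sub["q_site"] = q
        sub["is_methylated"] = reject
        calls[sample] = sub
    return calls, universe


def binomial_tail_p(meth: np.ndarray, total: np.ndarray, error_rate: float) -> np.ndarray:
    """One-sided upper-tail binomial p-value P(X >= meth | n=total, p=error_rate)."""
    return stats.binom.sf(np.asarray(meth) - 1, np.asarray(total), error_rate)


def call_dmps(
    records_a: pd.DataFrame,
    records_b: pd.DataFrame,
    min_diff: float = 0.30,
    fdr: float = 0.05,
    sample_a: str = "a",
    sample_b: str = "b",
) -> pd.DataFrame:
    """Differentially methylated positions between two samples.

    Positions are matched on (chrom, pos, strand, context); only pairs with
    an exact frequency difference of at least ``min_diff`` are tested (the
    boundary is inclusive and the comparison is carried out on integer cross
    products, so 3/10 vs 0/10 is tested at ``min_diff=0.30``).

    Returns one row per tested position with two-sided Fisher ``p``,
    BH-corrected ``q``, ``significant`` flag and ``direction`` =
    sign(freq_b - freq_a).
    """
    merged = records_a.merge(
        records_b,
        on=["chrom", "pos", "strand", "context"],
        suffixes=("_a", "_b"),
    )
    if (merged["total_a"] <= 0).any() or (merged["total_b"] <= 0).any():
        raise ValueError("zero-coverage position reached the DMP test")
    ma = merged["meth_a"].to_numpy(np.int64)
    ta = merged["total_a"].to_numpy(np.int64)
    mb = merged["meth_b"].to_numpy(np.int64)
    tb = merged["total_b"].to_numpy(np.int64)
    # |ma/ta - mb/tb| >= min_diff, decided on integers: |ma*tb - mb*ta| >= min_diff*ta*tb
    lhs = np.abs(ma * tb - mb * ta)
    rhs = min_diff * ta * tb
    tested = lhs >= rhs - 1e-9 * ta * tb
    sub = merged[tested].reset_index(drop=True)
    p = np.empty(len(sub))
    for i, (m1, t1, m2, t2) in enumerate(
        zip(sub["meth_a"], sub["total_a"], sub["meth_b"], sub["total_b"])
    ):
        p[i] = stats.fisher_exact(
            [[m1, t1 - m1], [m2, t2 - m2]], alternative="two-sided"
        )[1]
    out = sub[["chrom", "pos", "strand", "context"]].copy()
    out["sample_a"] = sample_a
    out["sample_b"] = sample_b
    out["freq_a"] = sub["meth_a"] / sub["total_a"]
    out["freq_b"] = sub["meth_b"] / sub["total_b"]
    out["p"] = p
    if len(out):
        reject, q, *_ = multipletests(p, alpha=fdr, method="fdr_bh")
    else:
        reject, q = np.zeros(0, bool), np.zeros(0)
    out["q"] = q
    out["significant"] = reject
    out["direction"] = np.sign(out["freq_b"] - out["freq_a"]).astype(int)
    return out


def dmps_to_bed(dmps: pd.DataFrame) -> pd.DataFrame:
    """Significant DMPs as a BED-style interval frame (pos-1, pos)."""
    sig = dmps[dmps["significant"]]
    return pd.DataFrame(
        {
            "chrom": sig["chrom"],
            "start": sig["pos"] - 1,
            "end": sig["pos"],
            "name": sig["context"],
            "score": sig["q"],
            "strand": sig["strand"],
        }
    ).reset_index(drop=True)
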