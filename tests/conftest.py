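import numpy as np
import pandas as pd
import pytest

import methylmem as mm


def fisher_two_sided_oracle(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by brute-force enumeration of all 2x2 tables with
    the observed margins, summing hypergeometric probabilities <= observed."""
    from scipy.stats import hypergeom

    row1, row2, col1 = a + b, c + d, a + c
    n = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    dist = hypergeom(n, row1, col1)
    p_obs = dist.pmf(a)
    total = 0.0
    for x in range(lo, hi + 1):
        px = dist.pmf(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def hmm_posterior_oracle(ll: np.ndarray, trans: np.ndarray, pi: np.ndarray) -> np.ndarray:
    """Posterior state marginals by explicit enumeration of all state paths."""
    n = ll.shape[0]
    post = np.zeros((n, 2))
    z = 0.0
    for code in range(2 ** n):
        path = [(code >> t) & 1 for t in range(n)]
        logp = np.log(pi[path[0]]) + ll[0, path[0]]
        for t in range(1, n):
            logp += np.log(trans[path[t - 1], path[t]]) + ll[t, path[t]]
        w = np.exp(logp)
        z += w
        for t in range(n):
            post[t, path[t]] += w
    return post / z


def naive_overlap_counts(set_a: pd.DataFrame, set_b: pd.DataFrame, flank: int) -> int:
    count = 0
    for ra in set_a.itertuples(index=False):
        for rb in set_b.itertuples(index=False):
            if ra.chrom == rb.chrom and ra.start - flank < rb.end and ra.end + flank > rb.start:
                count += 1
                break
    return count


def naive_nearest(query: pd.DataFrame, features: pd.DataFrame) -> np.ndarray:
    out = np.full(len(query), np.nan)
    for i, rq in enumerate(query.itertuples(index=False)):
        best = np.inf
        for rf in features.itertuples(index=False):
            if rf.chrom != rq.chrom:
                continue
            if rq.start < rf.end and rq.end > rf.start:
                best = 0
            else:
                best = min(best, max(rf.start - rq.end, rq.start - rf.end))
        if np.isfinite(best):
            out[i] = best
    return out


def naive_interval_union(df: pd.DataFrame) -> set:
    """Set of covered (chrom, base) pairs — the O(n * len) union oracle."""
    covered = set()
    for r in df.itertuples(index=False):
        for b in range(r.start, r.end):
            covered.add((r.chrom, b))
    return covered


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded simulation shared by read-only tests."""
    cfg = mm.SimConfig(
        genome_length=120_000, n_te=20, n_genes=8, n_labile_regions=15,
        chloroplast_length=15_000, seed=7,
    )
    annot = mm.simulate_annotation(cfg)
    design = mm.default_design(generations=("G1",), replicates=1)
    tables = mm.simulate_samples(cfg, annot, design)
    return cfg, annot, design, tables
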