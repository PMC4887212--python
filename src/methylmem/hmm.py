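"""Two-state HMM segmentation of a methylome into methylated regions (MRs).

Each sample's cytosines, ordered along a chromosome, are modelled as
emissions of a two-state (High / Low methylation) hidden Markov chain.
Observations are (meth, total, context) read-count triples; emissions are
beta-binomial with per-context means and a shared per-state dispersion, so
the model tolerates the overdispersion of pooled-plant samples. The chain is
re-initialized at its stationary distribution at chromosome ends and
whenever consecutive cytosines are further apart than ``distance_break``.

Maximal runs of High-posterior sites (posterior decoding) with at least
``min_sites`` cytosines become MRs. Parameters can be fitted per sample by
expectation-maximization (:func:`fit_hmm`); EM here is generalized EM with a
numeric M-step, and an update is only accepted when it improves the total
log-likelihood by at least ``tol``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import betaln, gammaln

from .intervals import merge_intervals

CONTEXTS = ("CG", "CHG", "CHH")
LOW, HIGH = 0, 1


class DegenerateFitError(RuntimeError):
    """EM collapsed the two states; re-initialize with separated means."""


@dataclass
class HmmParams:
    """Parameters of the two-state methylated-region HMM.

    ``mean_low``/``mean_high`` map context -> beta-binomial mean methylation
    frequency; ``disp_low``/``disp_high`` are the intra-class correlations
    rho in (0, 1) (shared across contexts within a state); ``trans`` is the
    2x2 row-stochastic transition matrix in state order (Low, High).
    """

    mean_low: dict[str, float]
    mean_high: dict[str, float]
    disp_low: float = 0.1
    disp_high: float = 0.1
    trans: np.ndarray = field(
        default_factory=lambda: np.array([[0.99, 0.01], [0.01, 0.99]])
    )
    distance_break: int = 250
    min_sites: int = 4
    posterior_threshold: float = 0.5

    def __post_init__(self) -> None:
        self.trans = np.asarray(self.trans, dtype=float)
        if self.trans.shape != (2, 2) or not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValueError("transition matrix must be 2x2 with rows summing to 1")
        for ctx in self.mean_high:
            if self.mean_high[ctx] <= self.mean_low.get(ctx, np.nan):
                raise ValueError(
                    f"emission mean(High) must exceed mean(Low) for context {ctx}"
                )
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")

    def stationary(self) -> np.ndarray:
        a = self.trans[LOW, HIGH]
        b = self.trans[HIGH, LOW]
        if a + b == 0:
            return np.array([0.5, 0.5])
        return np.array([b / (a + b), a / (a + b)])

    def to_dict(self) -> dict:
        return {
            "mean_low": self.mean_low,
            "mean_high": self.mean_high,
            "disp_low": self.disp_low,
            "disp_high": self.disp_high,
            "trans": self.trans.tolist(),
            "distance_break": self.distance_break,
            "min_sites": self.min_sites,
            "posterior_threshold": self.posterior_threshold,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HmmParams":
        d = dict(d)
        d["trans"] = np.asarray(d["trans"], dtype=float)
        return cls(**d)


def _ab(mean: float, rho: float) -> tuple[float, float]:
    # rho = 1 / (1 + alpha + beta)
    nu = (1.0 - rho) / rho
    return mean * nu, (1.0 - mean) * nu


def log_betabinom(k: np.ndarray, n: np.ndarray, a: float, b: float) -> np.ndarray:
    k = np.asarray(k, dtype=float)
    n = np.asarray(n, dtype=float)
    return (
        gammaln(n + 1)
        - gammaln(k + 1)
        - gammaln(n - k + 1)
        + betaln(k + a, n - k + b)
        - betaln(a, b)
    )


def emission_loglik(records: pd.DataFrame, params: HmmParams) -> np.ndarray:
    """Per-site log emission densities, shape (n_sites, 2)."""
    k = records["meth"].to_numpy(np.int64)
    n = records["total"].to_numpy(np.int64)
    ctx = records["context"].to_numpy()
    ll = np.empty((len(records), 2))
    for state, (means, rho) in enumerate(
        ((params.mean_low, params.disp_low), (params.mean_high, params.disp_high))
    ):
        col = np.empty(len(records))
        for c in np.unique(ctx):
            sel = ctx == c
            a, b = _ab(means[c], rho)
            col[sel] = log_betabinom(k[sel], n[sel], a, b)
        ll[:, state] = col
    return ll


def iter_chunks(records: pd.DataFrame, distance_break: int) -> Iterator[slice]:
    """Index slices of runs with no inter-site gap above ``distance_break``."""
    chroms = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy(np.int64)
    if len(records) == 0:
        return
    new_chrom = np.concatenate([[True], chroms[1:] != chroms[:-1]])
    big_gap = np.concatenate([[False], np.diff(pos) > distance_break])
    breaks = np.flatnonzero(new_chrom | big_gap)
    bounds = np.append(breaks, len(records))
    for i in range(len(breaks)):
        yield slice(bounds[i], bounds[i + 1])


def _check_sorted(records: pd.DataFrame) -> None:
    chroms = records["chrom"].to_numpy()
    pos = records["pos"].to_numpy()
    same = chroms[1:] == chroms[:-1]
    if np.any(same & (np.diff(pos) < 0)):
        raise ValueError("records must be sorted by (chrom, pos)")


def forward_backward(
    ll: np.ndarray, trans: np.ndarray, pi: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Scaled forward-backward.

    Returns (posteriors gamma (n,2), expected transition counts xi (2,2),
    log-likelihood).
    """
    n = ll.shape[0]
    emis = np.exp(ll - ll.max(axis=1, keepdims=True))
    alpha = np.empty((n, 2))
    scale = np.empty(n)
    alpha[0] = pi * emis[0]
    scale[0] = alpha[0].sum()
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ trans) * emis[t]
        scale[t] = alpha[t].sum()
        alpha[t] /= scale[t]
    beta = np.empty((n, 2))
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = trans @ (emis[t + 1] * beta[t + 1])
        beta[t] /= scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    xi = np.zeros((2, 2))
    for t in range(n - 1):
        m = np.outer(alpha[t], emis[t + 1] * beta[t + 1]) * trans / scale[t + 1]
        xi += m
    loglik = float(np.log(scale).sum() + ll.max(axis=1).sum())
    return gamma, xi, loglik


def _e_step(records: pd.DataFrame, params: HmmParams):
    ll = emission_loglik(records, params)
    pi = params.stationary()
    gamma = np.empty_like(ll)
    xi = np.zeros((2, 2))
    total_ll = 0.0
    for sl in iter_chunks(records, params.distance_break):
        g, x, l = forward_backward(ll[sl], params.trans, pi)
        gamma[sl] = g
        xi += x
        total_ll += l
    return gamma, xi, total_ll


def _optimize_mean(k, n, w, rho, current: float) -> float:
    def neg(m):
        a, b = _ab(m, rho)
        return -float(np.sum(w * log_betabinom(k, n, a, b)))

    res = minimize_scalar(neg, bounds=(1e-3, 1 - 1e-3), method="bounded")
    return float(res.x) if res.fun <= neg(current) else current


def _optimize_disp(records, gamma_col, means, current: float) -> float:
    k = records["meth"].to_numpy(np.int64)
    n = records["total"].to_numpy(np.int64)
    ctx = records["context"].to_numpy()

    def neg(rho):
        tot = 0.0
        for c in np.unique(ctx):
            sel = ctx == c
            a, b = _ab(means[c], rho)
            tot -= float(np.sum(gamma_col[sel] * log_betabinom(k[sel], n[sel], a, b)))
        return tot

    res = minimize_scalar(neg, bounds=(1e-4, 0.8), method="bounded")
    return float(res.x) if res.fun <= neg(current) else current


def _m_step(records: pd.DataFrame, params: HmmParams, gamma: np.ndarray, xi: np.ndarray) -> HmmParams:
    row_sums = xi.sum(axis=1, keepdims=True)
    trans = params.trans.copy()
    for s in range(2):
        if row_sums[s] > 0:
            trans[s] = xi[s] / row_sums[s]
    k = records["meth"].to_numpy(np.int64)
    n = records["total"].to_numpy(np.int64)
    ctx = records["context"].to_numpy()
    new_means = [dict(params.mean_low), dict(params.mean_high)]
    disps = [params.disp_low, params.disp_high]
    for s in range(2):
        cur_means = new_means[s]
        for c in np.unique(ctx):
            sel = ctx == c
            cur_means[c] = _optimize_mean(
                k[sel], n[sel], gamma[sel, s], disps[s], cur_means[c]
            )
        disps[s] = _optimize_disp(records, gamma[:, s], cur_means, disps[s])
    # keep the High state the one with the larger coverage-weighted mean
    if np.mean(list(new_means[HIGH].values())) < np.mean(list(new_means[LOW].values())):
        new_means = new_means[::-1]
        disps = disps[::-1]
        trans = trans[::-1, ::-1]
    return HmmParams(
        mean_low={c: min(new_means[LOW][c], new_means[HIGH][c] - 1e-6) for c in new_means[LOW]},
        mean_high=new_means[HIGH],
        disp_low=disps[LOW],
        disp_high=disps[HIGH],
        trans=trans,
        distance_break=params.distance_break,
        min_sites=params.min_sites,
        posterior_threshold=params.posterior_threshold,
    )


def initial_params(
    records: pd.DataFrame,
    distance_break: int = 250,
    min_sites: int = 4,
    posterior_threshold: float = 0.5,
) -> HmmParams:
    """Percentile-based initialization: High/Low means from the 90th/10th
    percentile of per-site frequencies per context; self-transition 0.99."""
    freq = records["meth"] / records["total"]
    mean_low, mean_high = {}, {}
    for c in CONTEXTS:
        f = freq[records["context"] == c]
        lo = float(np.quantile(f, 0.10)) if len(f) else 0.01
        hi = float(np.quantile(f, 0.90)) if len(f) else 0.8
        lo = min(max(lo, 0.005), 0.4)
        hi = min(max(hi, lo + 0.1), 0.995)
        mean_low[c], mean_high[c] = lo, hi
    return HmmParams(
        mean_low=mean_low,
        mean_high=mean_high,
        distance_break=distance_break,
        min_sites=min_sites,
        posterior_threshold=posterior_threshold,
    )


def fit_hmm(
    records: pd.DataFrame,
    init: HmmParams,
    tol: float = 1e-3,
    max_iter: int = 50,
) -> HmmParams:
    """Fit HMM parameters by (generalized) expectation-maximization.

    Each iteration computes a candidate M-step update and accepts it only if
    the total log-likelihood improves by at least ``tol``; with ``tol=inf``
    the initial parameters are returned unchanged after one E-step. Raises
    :class:`DegenerateFitError` when the fitted High and Low emission means
    come closer than 0.05 on average (states collapsed).
    """
    _check_sorted(records)
    params = init
    gamma, xi, ll = _e_step(records, params)
    for _ in range(max_iter):
        candidate = _m_step(records, params, gamma, xi)
        g2, x2, ll2 = _e_step(records, candidate)
        if ll2 - ll < tol:
            break
        params, gamma, xi, ll = candidate, g2, x2, ll2
    sep = np.mean(
        [params.mean_high[c] - params.mean_low[c] for c in params.mean_high]
    )
    if sep < 0.05:
        raise DegenerateFitError(
            "High and Low emission means collapsed (mean separation "
            f"{sep:.4f} < 0.05); re-initialize with separated means"
        )
    occupancy = gamma.sum(axis=0)
    if occupancy.min() < max(1.0, 1e-3 * len(records)):
        raise DegenerateFitError(
            "one state has (near-)zero posterior occupancy; the data do not "
            "support two methylation states — re-initialize or segment with "
            "fixed parameters"
        )
    return params


def posterior_high(records: pd.DataFrame, params: HmmParams) -> np.ndarray:
    """Posterior probability of the High state at every site."""
    _check_sorted(records)
    gamma, _, _ = _e_step(records, params)
    return gamma[:, HIGH]


def segment_mrs(
    records: pd.DataFrame, params: HmmParams, sample_id: str = "."
) -> pd.DataFrame:
    """Posterior decoding into methylated regions.

    Maximal runs of sites with High posterior >= ``posterior_threshold``,
    containing at least ``min_sites`` cytosines and no internal gap above
    ``distance_break``, become MRs; the interval spans the first to last
    site (half-open, end = last 0-based site coordinate + 1).
    """
    _check_sorted(records)
    ll = emission_loglik(records, params)
    pi = params.stationary()
    pos = records["pos"].to_numpy(np.int64)
    chroms = records["chrom"].to_numpy()
    freq = (records["meth"] / records["total"]).to_numpy()
    ctx = records["context"].to_numpy()
    rows = []
    for sl in iter_chunks(records, params.distance_break):
        gamma, _, _ = forward_backward(ll[sl], params.trans, pi)
        high = gamma[:, HIGH] >= params.posterior_threshold
        for run_start, run_end in _runs(high):
            if run_end - run_start < params.min_sites:
                continue
            i0 = sl.start + run_start
            i1 = sl.start + run_end  # exclusive
            row = {
                "chrom": chroms[i0],
                "start": int(pos[i0] - 1),
                "end": int(pos[i1 - 1]),
                "sample_id": sample_id,
                "n_sites": int(i1 - i0),
            }
            for c in CONTEXTS:
                sel = ctx[i0:i1] == c
                row[f"n_{c}"] = int(sel.sum())
                row[f"freq_{c}"] = float(freq[i0:i1][sel].mean()) if sel.any() else np.nan
            row["mean_freq"] = float(freq[i0:i1].mean())
            rows.append(row)
    cols = ["chrom", "start", "end", "sample_id", "n_sites"] + [
        x for c in CONTEXTS for x in (f"n_{c}", f"freq_{c}")
    ] + ["mean_freq"]
    return pd.DataFrame(rows, columns=cols)


def _runs(mask: np.ndarray) -> Iterator[tuple[int, int]]:
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            yield i, j
            i = j
        else:
            i += 1


def merge_mrs(mr_sets: list[pd.DataFrame]) -> pd.DataFrame:
    """Union of MR interval sets into a common set (idempotent).

    The merged MR carries the comma-joined ids of contributing samples.
    """
    frames = [df for df in mr_sets if len(df)]
    if not frames:
        return pd.DataFrame(columns=["chrom", "start", "end", "sample_id"])
    allmr = pd.concat(
        [df[["chrom", "start", "end", "sample_id"]] for df in frames], ignore_index=True
    )
    # re-split previously joined contributor lists so merging stays idempotent
    allmr = allmr.assign(sample_id=allmr["sample_id"].str.split(",")).explode("sample_id")
    merged = merge_intervals(allmr, carry="sample_id")
    return merged.rename(columns={"sample_id": "sample_id"})
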