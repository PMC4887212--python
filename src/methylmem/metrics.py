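"""Recovery metrics against a simulation's ground truth."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .intervals import merge_intervals, overlaps_any


def _total_len(df: pd.DataFrame) -> int:
    if len(df) == 0:
        return 0
    m = merge_intervals(df[["chrom", "start", "end"]])
    return int((m["end"] - m["start"]).sum())


def _intersection_len(a: pd.DataFrame, b: pd.DataFrame) -> int:
    if len(a) == 0 or len(b) == 0:
        return 0
    ma = merge_intervals(a[["chrom", "start", "end"]])
    mb = merge_intervals(b[["chrom", "start", "end"]])
    total = 0
    for chrom, sub in ma.groupby("chrom"):
        tb = mb[mb["chrom"] == chrom]
        if tb.empty:
            continue
        bs = tb["start"].to_numpy(np.int64)
        be = tb["end"].to_numpy(np.int64)
        for s, e in zip(sub["start"], sub["end"]):
            lo = np.maximum(bs, s)
            hi = np.minimum(be, e)
            total += int(np.clip(hi - lo, 0, None).sum())
    return total


def bp_f1(predicted: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Basepair-level precision/recall/F1 of predicted vs. true regions."""
    inter = _intersection_len(predicted, truth)
    p_len = _total_len(predicted)
    t_len = _total_len(truth)
    precision = inter / p_len if p_len else 0.0
    recall = inter / t_len if t_len else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return {"precision": precision, "recall": recall, "f1": f1}


def region_recovery(
    called: pd.DataFrame, truth: pd.DataFrame, flank: int = 0
) -> dict[str, float]:
    """Recall of true regions and empirical FDR of called regions.

    A true region is recovered when a called region overlaps it (within
    ``flank``); a called region is a false discovery when it overlaps no
    true region.
    """
    if len(truth) == 0:
        return {"recall": float("nan"), "fdr": float(len(called) > 0), "n_called": len(called)}
    recovered = overlaps_any(truth, called, flank=flank) if len(called) else np.zeros(len(truth), bool)
    false_calls = (~overlaps_any(called, truth, flank=flank)) if len(called) else np.zeros(0, bool)
    return {
        "recall": float(recovered.mean()),
        "fdr": float(false_calls.mean()) if len(called) else 0.0,
        "n_called": int(len(called)),
        "n_truth": int(len(truth)),
    }
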