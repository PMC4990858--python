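"""Truth-based evaluation of exon-level copy-number calls.

Conventions: an exon is truth-aberrant when its true tumor genotype differs
from the diploid heterozygous (2, 1); a call is aberrant when its decoded
state is not copy-neutral.  Sensitivity and specificity are computed over
truth-aberrant and truth-normal exons respectively; copy-number accuracy is
the fraction of evaluated exons whose called total copy number equals the
truth.  Cluster-cellularity error compares the estimated cellularity vector
with the truth after nearest matching.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .states import NHET_STATE_ID


class AlignmentError(ValueError):
    pass


def align_calls_to_truth(
    calls: pd.DataFrame, truth: pd.DataFrame
) -> pd.DataFrame:
    """Inner-join per-exon calls and truth on (chrom, start).

    ``calls`` may be a per-exon call table or a segment table; segments are
    expanded over the truth exons they span.
    """
    if "n_exons" in calls.columns and "state_id" in calls.columns:
        return _join_segments(calls, truth)
    merged = truth.merge(
        calls, on=["chrom", "start"], suffixes=("_true", "_call"), how="inner"
    )
    if len(merged) == 0:
        raise AlignmentError("calls and truth share no exons")
    return merged


def _join_segments(segments: pd.DataFrame, truth: pd.DataFrame) -> pd.DataFrame:
    out_rows = []
    for chrom, tgrp in truth.groupby("chrom", sort=False):
        sgrp = segments[segments["chrom"] == chrom]
        if len(sgrp) == 0:
            continue
        seg_start = sgrp["start"].to_numpy()
        seg_end = sgrp["end"].to_numpy()
        idx = np.searchsorted(seg_start, tgrp["start"].to_numpy(), side="right") - 1
        inside = (idx >= 0) & (tgrp["start"].to_numpy() < seg_end[np.maximum(idx, 0)])
        sub = tgrp.loc[inside].copy()
        take = sgrp.iloc[idx[inside]]
        sub["state_id_call"] = take["state_id"].to_numpy()
        sub["total_cn_call"] = take["total_cn"].to_numpy()
        sub["cellularity_call"] = take["cellularity"].to_numpy()
        out_rows.append(sub)
    if not out_rows:
        raise AlignmentError("calls and truth share no exons")
    merged = pd.concat(out_rows, ignore_index=True)
    merged = merged.rename(
        columns={"total_cn": "total_cn_true", "cellularity": "cellularity_true"}
    )
    return merged


def _columns(merged: pd.DataFrame):
    cn_call = merged["total_cn_call"].to_numpy()
    cn_true = merged["total_cn_true"].to_numpy()
    cell_call = merged["cellularity_call"].to_numpy()
    cell_true = merged["cellularity_true"].to_numpy()
    state_col = "state_id_call" if "state_id_call" in merged.columns else "state_id"
    state_call = merged[state_col].to_numpy()
    return cn_true, cn_call, cell_true, cell_call, state_call


def exon_metrics(merged: pd.DataFrame) -> dict:
    """Sensitivity, specificity and copy-number accuracy from a joined table."""
    cn_true, cn_call, cell_true, cell_call, state_call = _columns(merged)
    truth_aberrant = (cn_true != 2) | (merged.get("major_cn", pd.Series(
        np.ones(len(merged)))).to_numpy() != 1)
    call_aberrant = state_call != NHET_STATE_ID
    tp = int(np.sum(truth_aberrant & call_aberrant))
    fn = int(np.sum(truth_aberrant & ~call_aberrant))
    tn = int(np.sum(~truth_aberrant & ~call_aberrant))
    fp = int(np.sum(~truth_aberrant & call_aberrant))
    sens = tp / (tp + fn) if (tp + fn) else np.nan
    spec = tn / (tn + fp) if (tn + fp) else np.nan
    acc = float(np.mean(cn_call == cn_true))
    both = truth_aberrant & call_aberrant
    cell_mae = (
        float(np.mean(np.abs(cell_call[both] - cell_true[both])))
        if both.any() else np.nan
    )
    return {
        "n_exons": len(merged),
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "sensitivity": sens,
        "specificity": spec,
        "cn_accuracy": acc,
        "exon_cellularity_mae": cell_mae,
    }


def match_cellularities(
    est: np.ndarray, true: np.ndarray
) -> list[tuple[float, float]]:
    """Optimal 1:1 matching of estimated to true cluster cellularities.

    Minimum-cost assignment on absolute differences; when the cluster
    counts differ, the surplus clusters stay unmatched (the count mismatch
    is reported separately as k_est/k_true).
    """
    from scipy.optimize import linear_sum_assignment

    est = sorted(float(b) for b in est)
    true = sorted(float(b) for b in true)
    if not est or not true:
        return []
    cost = np.abs(np.subtract.outer(true, est))
    rows, cols = linear_sum_assignment(cost)
    return [(true[i], est[j]) for i, j in zip(rows, cols)]


def cellularity_metrics(est: np.ndarray, true: np.ndarray) -> dict:
    pairs = match_cellularities(est, true)
    t = np.array([p[0] for p in pairs])
    e = np.array([p[1] for p in pairs])
    mae = float(np.mean(np.abs(e - t))) if len(pairs) else np.nan
    corr = (
        float(np.corrcoef(t, e)[0, 1]) if len(pairs) > 1 and np.std(t) > 0
        else np.nan
    )
    return {
        "k_true": len(true), "k_est": len(est),
        "cellularity_mae": mae, "cellularity_corr": corr,
        "pairs": pairs,
    }


def evaluate_sample(
    calls: pd.DataFrame,
    truth_exons: pd.DataFrame,
    est_betas: np.ndarray | None = None,
    truth_betas: np.ndarray | None = None,
    est_purity: float | None = None,
    truth_purity: float | None = None,
) -> dict:
    """All metrics for one sample; cluster/purity parts are optional."""
    merged = align_calls_to_truth(calls, truth_exons)
    metrics = exon_metrics(merged)
    if est_betas is not None and truth_betas is not None:
        metrics.update(cellularity_metrics(np.asarray(est_betas),
                                           np.asarray(truth_betas)))
    if est_purity is not None and truth_purity is not None:
        metrics["purity_error"] = float(abs(est_purity - truth_purity))
    return metrics
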