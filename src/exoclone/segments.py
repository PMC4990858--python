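"""Posterior decoding, segment merging, reliability scores and summaries."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .em import FitResult
from .hmm import PosteriorMatrix
from .params import CompositeSpace
from .states import NHET_STATE_ID, state_by_id

SEGMENT_COLUMNS = [
    "chrom", "start", "end", "n_exons", "state_id", "aberration_type",
    "total_cn", "major_cn", "cluster", "cellularity", "reliability",
    "mean_lcr", "mean_maf",
]


def decode(posterior: PosteriorMatrix | np.ndarray, space: CompositeSpace):
    """Per-exon maximum-posterior composite state.

    Returns ``(state_id, cluster, call_index)`` arrays.  The composite space
    is laid out NHET-first then state-major/cluster-minor, so numpy's
    first-maximum argmax realizes the tie-break (neutral first, then lower
    state id, then lower cluster).
    """
    gamma = posterior.gamma if isinstance(posterior, PosteriorMatrix) else posterior
    call = np.argmax(gamma, axis=1)
    return space.state_id[call], space.cluster[call], call


def merge_segments(
    calls: np.ndarray, exons: pd.DataFrame
) -> pd.DataFrame:
    """Run-length merge of identical consecutive composite calls.

    ``calls`` are composite-state indices aligned to the coordinate-sorted
    ``exons`` rows; runs never cross chromosome boundaries.  Returns one row
    per segment with exon index bounds [i0, i1).
    """
    n = len(calls)
    if n != len(exons):
        raise ValueError("calls and exons misaligned")
    chrom = exons["chrom"].to_numpy()
    new_seg = np.ones(n, dtype=bool)
    new_seg[1:] = (calls[1:] != calls[:-1]) | (chrom[1:] != chrom[:-1])
    starts = np.flatnonzero(new_seg)
    ends = np.append(starts[1:], n)
    return pd.DataFrame(
        {
            "i0": starts,
            "i1": ends,
            "chrom": chrom[starts],
            "start": exons["start"].to_numpy()[starts],
            "end": exons["end"].to_numpy()[ends - 1],
            "call": calls[starts],
        }
    )


def expand_segments(seg_runs: pd.DataFrame) -> np.ndarray:
    """Inverse of :func:`merge_segments` on the call vector."""
    return np.repeat(
        seg_runs["call"].to_numpy(), (seg_runs["i1"] - seg_runs["i0"]).to_numpy()
    )


def reliability_score(gamma_block: np.ndarray, call: int) -> float:
    """Geometric mean of the posterior mass on the called composite state."""
    p = np.clip(gamma_block[:, call], 1e-300, 1.0)
    return float(np.exp(np.mean(np.log(p))))


def segment_table(
    fit: FitResult, signals: pd.DataFrame
) -> pd.DataFrame:
    """Full segment output: coordinates, state, cellularity, reliability."""
    space = fit.params.space
    state_id, cluster, call = decode(fit.posterior, space)
    runs = merge_segments(call, signals)
    gamma = fit.posterior.gamma
    lcr = signals["lcr"].to_numpy()
    maf = signals["maf"].to_numpy()
    rows = []
    for rec in runs.itertuples(index=False):
        i0, i1 = int(rec.i0), int(rec.i1)
        st = state_by_id(int(space.state_id[rec.call]))
        k = int(space.cluster[rec.call])
        seg_maf = maf[i0:i1]
        rows.append(
            {
                "chrom": rec.chrom,
                "start": int(rec.start),
                "end": int(rec.end),
                "n_exons": i1 - i0,
                "state_id": st.state_id,
                "aberration_type": st.aberration_type,
                "total_cn": st.total_cn,
                "major_cn": -1 if st.major_cn is None else st.major_cn,
                "cluster": 0 if st.is_neutral else k + 1,
                "cellularity": 0.0 if st.is_neutral else float(fit.params.beta[k]),
                "reliability": reliability_score(gamma[i0:i1], int(rec.call)),
                "mean_lcr": float(np.mean(lcr[i0:i1])),
                "mean_maf": (
                    float(np.nanmean(seg_maf))
                    if np.isfinite(seg_maf).any() else np.nan
                ),
            }
        )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def exon_calls_table(fit: FitResult, signals: pd.DataFrame) -> pd.DataFrame:
    """Per-exon calls (useful for truth-based evaluation)."""
    space = fit.params.space
    state_id, cluster, call = decode(fit.posterior, space)
    neutral = state_id == NHET_STATE_ID
    cellularity = np.where(neutral, 0.0, fit.params.beta[cluster])
    return pd.DataFrame(
        {
            "chrom": signals["chrom"],
            "start": signals["start"],
            "end": signals["end"],
            "state_id": state_id,
            "total_cn": space.total_cn[call],
            "cluster": np.where(neutral, 0, cluster + 1),
            "cellularity": cellularity,
            "posterior": fit.posterior.gamma[np.arange(len(call)), call],
        }
    )


@dataclass
class SampleSummary:
    """Sample-level estimates reported after model selection."""

    K: int
    cellularities: list[float]
    tumor_purity: float | None     # None when no aberrant segment was called
    baseline_shift: float
    loglik: float
    bic: float
    genome_fraction: dict[str, float] = field(default_factory=dict)
    empty_clusters: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "cellularities": [round(b, 6) for b in self.cellularities],
            "tumor_purity": (
                None if self.tumor_purity is None else round(self.tumor_purity, 6)
            ),
            "baseline_shift": round(self.baseline_shift, 6),
            "loglik": round(self.loglik, 4),
            "bic": round(self.bic, 4),
            "genome_fraction": {k: round(v, 6) for k, v in
                                self.genome_fraction.items()},
            "empty_clusters": self.empty_clusters,
        }


def summarize(fit: FitResult, segments: pd.DataFrame, bic: float) -> SampleSummary:
    """Purity = cellularity of the largest (clonal) cluster.

    Clonal events are carried by every tumor cell, so the maximum cluster
    cellularity is the tumor-cell fraction of the sample.
    """
    n_exons = segments["n_exons"].to_numpy()
    frac = (
        segments.groupby("aberration_type")["n_exons"].sum() / n_exons.sum()
    ).to_dict()
    aberrant = segments["state_id"] != NHET_STATE_ID
    occupied = set(segments.loc[aberrant, "cluster"].astype(int)) - {0}
    if occupied:
        purity = float(max(fit.params.beta[k - 1] for k in occupied))
    else:
        purity = None
    return SampleSummary(
        K=fit.params.K,
        cellularities=[float(b) for b in fit.params.beta],
        tumor_purity=purity,
        baseline_shift=float(fit.params.o),
        loglik=float(fit.loglik),
        bic=float(bic),
        genome_fraction=frac,
        empty_clusters=[int(k + 1) for k in np.flatnonzero(fit.empty_clusters())],
    )


def segments_to_bed9(segments: pd.DataFrame) -> pd.DataFrame:
    """BED9 view for genome browsers; score = round(1000 * reliability)."""
    colors = {
        "HOMD": "165,0,38", "HEMD": "244,109,67", "NHET": "180,180,180",
        "NLOH": "116,173,209", "AHET": "69,117,180", "ALOH": "49,54,149",
    }
    return pd.DataFrame(
        {
            "chrom": segments["chrom"],
            "chromStart": segments["start"],
            "chromEnd": segments["end"],
            "name": [
                f"{t}_cn{c}_k{k}" for t, c, k in zip(
                    segments["aberration_type"], segments["total_cn"],
                    segments["cluster"],
                )
            ],
            "score": (segments["reliability"] * 1000).round().astype(int),
            "strand": ".",
            "thickStart": segments["start"],
            "thickEnd": segments["end"],
            "itemRgb": segments["aberration_type"].map(colors),
        }
    )
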