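"""Choosing the number of clonal clusters K by BIC.

Starting from tumor homogeneity (K=1), K is incremented until the BIC
(-2 logL + p log n) stops decreasing or K reaches 10.  The K+1 grid is
warm-started with the selected K solution plus one new cellularity inserted
at the largest gap, which keeps successive solutions nested.  Fits that
leave a cluster essentially unoccupied are treated as non-improving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em import (
    DEFAULT_O_GRID,
    FitResult,
    SignalArrays,
    build_grid,
    grid_search_fit,
)
from .params import ModelParams
from .states import N_STATES

logger = logging.getLogger(__name__)

MAX_CLUSTERS = 10


@dataclass
class ModelScore:
    K: int
    loglik: float
    n_free_params: int
    n_obs: int
    bic: float
    fit: FitResult | None = None
    has_empty_cluster: bool = False
    n_chains: int = 1


def count_free_params(K: int, n_states: int = N_STATES) -> int:
    """Free parameters at K clusters over the pinned composite space.

    K betas + o + (sigma_l, nu_l, sigma_m, nu_m) + (rho_c, rho_k) +
    (|composite| - 1) initial probabilities, |composite| = (C-1)K + 1.
    """
    if not 1 <= K <= MAX_CLUSTERS:
        raise ValueError(f"K must be in 1..{MAX_CLUSTERS}")
    composite = (n_states - 1) * K + 1
    return K + 1 + 4 + 2 + (composite - 1)


def score_fit(fit: FitResult, n_obs: int, n_chains: int = 1) -> ModelScore:
    """BIC with a split-resolution penalty.

    Parameters fitted against per-exon observations (betas, o, the four
    noise parameters, the two self-transition scalars) are priced at
    log(n_obs).  The initial-distribution entries, however, are informed
    only by the per-chromosome chain starts; pricing the 11 extra pi
    entries each added cluster brings at log(n_obs) would charge ~115
    nats per cluster for parameters the data barely constrain, and makes
    the BIC loop reject clearly occupied clusters.  They are therefore
    priced at log(n_chains).
    """
    K = fit.params.K
    p = count_free_params(K)
    p_pi = (N_STATES - 1) * K  # composite size minus the sum-to-1 constraint
    p_obs = p - p_pi
    bic = -2.0 * fit.loglik + p_obs * np.log(n_obs) \
        + p_pi * np.log(max(n_chains, 2))
    return ModelScore(
        K=K, loglik=fit.loglik, n_free_params=p, n_obs=n_obs,
        bic=float(bic), fit=fit,
        has_empty_cluster=bool(fit.vacuous_clusters().any()),
        n_chains=n_chains,
    )


def select_from_trace(trace: list[ModelScore]) -> ModelScore:
    """Pure selection rule on an ordered K=1.. trace.

    Walks the trace and keeps the last model whose BIC improved on its
    predecessor and that has no empty cluster; the first non-improvement
    ends the walk.
    """
    if not trace:
        raise ValueError("empty trace")
    best = trace[0]
    for score in trace[1:]:
        if score.has_empty_cluster or score.bic >= best.bic:
            break
        best = score
    return best


def _warm_starts(params: ModelParams) -> list[ModelParams]:
    """Extend a K-cluster solution to K+1 candidates.

    One candidate per inter-cluster gap (midpoint insertion), largest gap
    first, so both weak low-cellularity clusters and splits of existing
    ones are reachable.  The first candidate (largest gap) preserves the
    nesting property used by the BIC loop.
    """
    beta = params.beta
    edges = np.concatenate(([0.05], beta, [0.95]))
    gaps = np.diff(edges)
    order = np.argsort(gaps)[::-1]
    out = []
    for i in order:
        if gaps[i] < 0.08:  # too narrow to host a distinct cluster
            continue
        new_b = float(edges[i] + gaps[i] / 2.0)
        new_beta = np.sort(np.append(beta, new_b))
        if np.any(np.diff(new_beta) < 1e-3):
            continue
        out.append(
            ModelParams(
                K=params.K + 1, beta=new_beta, o=params.o,
                sigma_l=params.sigma_l, nu_l=params.nu_l,
                sigma_m=params.sigma_m, nu_m=params.nu_m,
                rho_c=params.rho_c, rho_k=params.rho_k,
            )
        )
    return out


def select_k(
    signals: pd.DataFrame | SignalArrays,
    k_max: int = MAX_CLUSTERS,
    *,
    o_grid: tuple[float, ...] = DEFAULT_O_GRID,
    seed: int = 17,
    tol: float = 1e-5,
    max_iter: int = 200,
    n_burn: int = 5,
    inner_maxiter: int = 6,
) -> tuple[ModelScore, list[ModelScore]]:
    """BIC loop over K.  Returns (selected score, full trace)."""
    if not 1 <= k_max <= MAX_CLUSTERS:
        raise ValueError(f"k_max must be in 1..{MAX_CLUSTERS}")
    sig = signals if isinstance(signals, SignalArrays) else SignalArrays(signals)
    trace: list[ModelScore] = []
    warm: list[ModelParams] = []
    for K in range(1, k_max + 1):
        # all ploidy baselines stay in play at every K: with one cluster the
        # baselines are barely distinguishable, so locking in K=1's choice
        # can trap the whole ladder in an aliased solution
        starts = build_grid(sig, K, o_grid=o_grid, warm=warm, seed=seed,
                            prescan=(K == 1))
        try:
            fit = grid_search_fit(
                sig, K, starts, n_burn=n_burn, max_iter=max_iter, tol=tol,
                inner_maxiter=inner_maxiter, seed=seed,
            )
        except RuntimeError:
            if K == 1:
                raise
            logger.warning("all starts failed at K=%d; stopping", K)
            break
        score = score_fit(fit, sig.n_obs, sig.n_chains)
        trace.append(score)
        logger.info(
            "K=%d loglik=%.2f BIC=%.2f empty=%s",
            K, score.loglik, score.bic, score.has_empty_cluster,
        )
        if K > 1 and (score.has_empty_cluster or score.bic >= trace[-2].bic):
            break
        warm = _warm_starts(fit.params)
    return select_from_trace(trace), trace


def bic_trace_frame(trace: list[ModelScore]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "K": [s.K for s in trace],
            "loglik": [s.loglik for s in trace],
            "n_free_params": [s.n_free_params for s in trace],
            "bic": [s.bic for s in trace],
            "empty_cluster": [s.has_empty_cluster for s in trace],
        }
    )
    df["delta_bic"] = df["bic"].diff()
    return df
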