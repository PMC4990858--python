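"""EM fitting of the factorial copy-number HMM for a fixed number of clusters.

E-step: scaled forward-backward posteriors over the composite space.
M-step: the continuous block (beta_1:K, o, sigma_l, nu_l, sigma_m, nu_m) is
updated by bounded quasi-Newton (L-BFGS-B with analytic gradients) on the
EM auxiliary Q; the initial distribution and the two chain self-transition
probabilities have closed-form expected-count updates.  Any update that
would lower Q is rejected, so the observed-data log-likelihood never
decreases (generalized EM).

A grid of starting points (baseline shifts o for ploidy ambiguity, several
cellularity seed vectors) is triaged with a few burn-in EM iterations each;
the best start by log-likelihood is run to convergence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import digamma

from .hmm import PosteriorMatrix, forward_backward
from .params import (
    BETA_BOUNDS,
    NU_BOUNDS,
    O_BOUNDS,
    RHO_BOUNDS,
    SIGMA_L_BOUNDS,
    SIGMA_M_BOUNDS,
    ModelParams,
)
from .states import (
    LCR_FLOOR,
    NORMAL_MAF,
    folded_median_shift,
    folded_median_shift_slope,
    folded_t_logdensity,
    t_logdensity,
)

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)
DEFAULT_O_GRID = (0.0, -0.58, -1.0)
#: Clusters whose expected exon occupancy falls below this are "empty".
MIN_CLUSTER_EXONS = 50.0
#: Clusters below this cellularity are unidentifiable against copy-neutral
#: (every state's emission means converge to the neutral ones as beta -> 0)
#: and are treated as vacuous by model selection.
MIN_CLUSTER_BETA = 0.05


class SignalArrays:
    """Observation vectors extracted from a signals DataFrame."""

    def __init__(self, signals: pd.DataFrame):
        self.lcr = np.maximum(signals["lcr"].to_numpy(dtype=float), LCR_FLOOR)
        maf = signals["maf"].to_numpy(dtype=float)
        self.maf_mask = np.isfinite(maf)
        self.maf = np.where(self.maf_mask, maf, NORMAL_MAF)
        # per-SNP BAF noise scale, sizing the folding-bias correction
        if "snp_depth" in signals.columns:
            depth = signals["snp_depth"].to_numpy(dtype=float)
        else:
            depth = np.full(len(maf), np.nan)
        sd = np.where(depth > 0, 0.5 / np.sqrt(np.maximum(depth, 1.0)), np.nan)
        default = float(np.nanmedian(sd)) if np.isfinite(sd).any() else 0.05
        self.baf_sd = np.where(np.isfinite(sd), sd, default)
        # the exon MAF is a median over n_snps values: its scale shrinks
        # like 1/sqrt(n); sigma_m is the scale of a single-SNP exon
        if "n_snps" in signals.columns:
            k = np.maximum(signals["n_snps"].to_numpy(dtype=float), 1.0)
        else:
            k = np.ones(len(maf))
        self.maf_scale = 1.0 / np.sqrt(k)
        from .states import FOLD_K_MAX

        self.fold_k = np.clip(k, 1, FOLD_K_MAX).astype(np.int64)
        # depth-aware relative LCR noise scale (median 1)
        if "lcr_scale" in signals.columns:
            self.lcr_scale = signals["lcr_scale"].to_numpy(dtype=float)
        else:
            self.lcr_scale = np.ones(len(maf))
        chroms = signals["chrom"].to_numpy()
        breaks = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
        self.chain_offsets = np.concatenate(([0], breaks, [len(chroms)]))
        self.n = len(self.lcr)
        self.n_obs = int(self.n + self.maf_mask.sum())
        self.n_chains = len(self.chain_offsets) - 1


@dataclass
class FitResult:
    params: ModelParams
    posterior: PosteriorMatrix
    n_iter: int
    converged: bool
    init_id: int = 0
    loglik_history: list = field(default_factory=list)
    param_history: list = field(default_factory=list)
    n_fallback: int = 0

    def diagnostics_frame(self) -> pd.DataFrame:
        """Per-iteration log-likelihood and parameter snapshots."""
        return pd.DataFrame(self.param_history)

    @property
    def loglik(self) -> float:
        return self.posterior.loglik

    def cluster_occupancy(self) -> np.ndarray:
        """Expected number of exons assigned to aberrant states per cluster."""
        sp = self.params.space
        occ = np.zeros(sp.K)
        mass = self.posterior.gamma[:, ~sp.is_nhet].sum(axis=0)
        np.add.at(occ, sp.cluster[~sp.is_nhet], mass)
        return occ

    def empty_clusters(self) -> np.ndarray:
        return self.cluster_occupancy() < MIN_CLUSTER_EXONS

    def vacuous_clusters(self) -> np.ndarray:
        """Empty or below the identifiable-cellularity floor."""
        return self.empty_clusters() | (self.params.beta < MIN_CLUSTER_BETA)


# ----------------------------------------------------------------------
# emission matrix and expected log-likelihood


def maf_emission_locations(
    sig: SignalArrays, mu_m: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Fold-bias-corrected MAF emission locations, per exon and state.

    The exon MAF statistic is a median of folded per-SNP B-allele
    frequencies; folding pushes its center above the model mean mu_m by an
    amount set by the per-SNP binomial noise s_i = 0.5/sqrt(depth).  The
    emission location used is 0.5 + s_i * x(delta/s_i) — the population
    median of |N(delta, s_i)| with delta = mu_m - 0.5 — which reduces to
    mu_m when the aberration signal dominates the noise and to
    0.5 + 0.6745 s_i for a copy-neutral exon.

    Returns ``(location, d location / d mu_m)`` as (N, S) arrays.
    """
    delta = np.maximum(mu_m - NORMAL_MAF, 0.0)
    s = sig.baf_sd[:, None]
    k = sig.fold_k[:, None]
    r = delta[None, :] / s
    loc = NORMAL_MAF + s * folded_median_shift(r, k)
    dloc = folded_median_shift_slope(r, k)
    return loc, dloc


def emission_matrix(sig: SignalArrays, params: ModelParams) -> np.ndarray:
    """(N, S) log emission densities; the MAF factor is dropped when missing.

    The MAF factor uses the folded (reflected at 0.5) t density around the
    fold-bias-corrected location, matching the folded nature of the MAF
    statistic.
    """
    mu_l, mu_m = params.emission_mean_vectors()
    loge = t_logdensity(
        sig.lcr[:, None], mu_l[None, :],
        (params.sigma_l * sig.lcr_scale)[:, None], params.nu_l,
    )
    loc, _ = maf_emission_locations(sig, mu_m)
    lm = folded_t_logdensity(
        sig.maf[:, None], loc,
        (params.sigma_m * sig.maf_scale)[:, None], params.nu_m,
    )
    loge += np.where(sig.maf_mask[:, None], lm, 0.0)
    return loge


def expected_loglik(
    gamma: np.ndarray, sig: SignalArrays, params: ModelParams
) -> tuple[float, float]:
    """Expected partial log-likelihoods (E[LL_lcr], E[LL_maf]) under gamma."""
    mu_l, mu_m = params.emission_mean_vectors()
    e_l = float(
        (gamma * t_logdensity(sig.lcr[:, None], mu_l[None, :],
                              (params.sigma_l * sig.lcr_scale)[:, None],
                              params.nu_l)).sum()
    )
    wm = gamma * sig.maf_mask[:, None]
    loc, _ = maf_emission_locations(sig, mu_m)
    e_m = float(
        (wm * folded_t_logdensity(sig.maf[:, None], loc,
                                  (params.sigma_m * sig.maf_scale)[:, None],
                                  params.nu_m)).sum()
    )
    return e_l, e_m


# ----------------------------------------------------------------------
# M-step


def _unpack(phi: np.ndarray, K: int):
    return phi[:K], phi[K], phi[K + 1], phi[K + 2], phi[K + 3], phi[K + 4]


try:
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


if _HAVE_NUMBA:

    @_njit(cache=True, fastmath=True)
    def _q_grad_kernel(  # pragma: no cover - exercised via _q_and_grad
        lcr, maf, maf_ok, baf_sd, maf_scale, lcr_scale, fold_k, gamma,
        cluster, n_c, ncmuc, is_nhet,
        beta, o, s_l, v_l, s_m, v_m,
        const_l, dv_const_l, const_m, dv_const_m,
        fold_x, fold_dr, grad,
    ):
        N, S = gamma.shape
        K = beta.shape[0]
        n_tab = fold_x.shape[1]
        q = 0.0
        g_o = 0.0
        g_sl = 0.0
        g_vl = 0.0
        g_sm = 0.0
        g_vm = 0.0
        for k in range(K + 5):
            grad[k] = 0.0
        for s in range(S):
            b = beta[cluster[s]]
            y = 2.0 * (1.0 - b) + n_c[s] * b
            degenerate = y <= 1e-12
            if degenerate:
                y = 1e-12
            z_num = (1.0 - b) + ncmuc[s] * b
            mu_l_raw = np.log2(y / 2.0) + o
            clipped = mu_l_raw <= -6.0
            mu_l = mu_l_raw if not clipped else -6.0
            mu_m = 0.5 if degenerate else z_num / y
            delta = mu_m - 0.5
            if delta < 0.0:
                delta = 0.0
            dmul_db = 0.0 if clipped else (n_c[s] - 2.0) / (y * 0.6931471805599453)
            if degenerate:
                dmum_db = 0.0
            else:
                dmum_db = (
                    (ncmuc[s] - 1.0) * y - z_num * (n_c[s] - 2.0)
                ) / (y * y)
            g_mu_l_s = 0.0
            g_mu_m_s = 0.0
            for i in range(N):
                g = gamma[i, s]
                if g <= 1e-12:  # negligible posterior mass
                    continue
                # LCR t term with per-exon scale
                sl_i = s_l * lcr_scale[i]
                zl = (lcr[i] - mu_l) / sl_i
                zl2 = zl * zl
                dl = v_l + zl2
                q += g * (const_l - np.log(lcr_scale[i])
                          - (v_l + 1.0) * 0.5 * np.log1p(zl2 / v_l))
                g_mu_l_s += g * ((v_l + 1.0) * zl / (sl_i * dl))
                g_sl += g * (-1.0 / s_l + (v_l + 1.0) * zl2 / (s_l * dl))
                g_vl += g * (
                    dv_const_l - 0.5 * np.log1p(zl2 / v_l)
                    + (v_l + 1.0) * zl2 / (2.0 * v_l * dl)
                )
                if not maf_ok[i]:
                    continue
                # folded MAF term around the bias-corrected location
                sd = baf_sd[i]
                r = delta / sd
                ri = r / fold_dr
                ii = int(ri)
                row = fold_k[i] - 1
                if ii < n_tab - 1:
                    frac = ri - ii
                    x = fold_x[row, ii] \
                        + frac * (fold_x[row, ii + 1] - fold_x[row, ii])
                    dx = (fold_x[row, ii + 1] - fold_x[row, ii]) / fold_dr
                else:
                    x = r
                    dx = 1.0
                loc = 0.5 + sd * x
                sm_i = s_m * maf_scale[i]
                z1 = (maf[i] - loc) / sm_i
                z2 = ((1.0 - maf[i]) - loc) / sm_i
                z1sq = z1 * z1
                z2sq = z2 * z2
                d1 = v_m + z1sq
                d2 = v_m + z2sq
                lf1 = -(v_m + 1.0) * 0.5 * np.log1p(z1sq / v_m)
                lf2 = -(v_m + 1.0) * 0.5 * np.log1p(z2sq / v_m)
                if lf1 >= lf2:
                    lfold = lf1 + np.log1p(np.exp(lf2 - lf1))
                else:
                    lfold = lf2 + np.log1p(np.exp(lf1 - lf2))
                w1 = np.exp(lf1 - lfold)
                w2 = 1.0 - w1
                q += g * (const_m - np.log(maf_scale[i]) + lfold)
                dmu1 = (v_m + 1.0) * z1 / (sm_i * d1)
                dmu2 = (v_m + 1.0) * z2 / (sm_i * d2)
                g_mu_m_s += g * (w1 * dmu1 + w2 * dmu2) * dx
                g_sm += g * (
                    w1 * (-1.0 / s_m + (v_m + 1.0) * z1sq / (s_m * d1))
                    + w2 * (-1.0 / s_m + (v_m + 1.0) * z2sq / (s_m * d2))
                )
                g_vm += g * (
                    w1 * (dv_const_m - 0.5 * np.log1p(z1sq / v_m)
                          + (v_m + 1.0) * z1sq / (2.0 * v_m * d1))
                    + w2 * (dv_const_m - 0.5 * np.log1p(z2sq / v_m)
                            + (v_m + 1.0) * z2sq / (2.0 * v_m * d2))
                )
            if not is_nhet[s]:
                grad[cluster[s]] += g_mu_l_s * dmul_db + g_mu_m_s * dmum_db
            if not clipped:
                g_o += g_mu_l_s
        grad[K] = g_o
        grad[K + 1] = g_sl
        grad[K + 2] = g_vl
        grad[K + 3] = g_sm
        grad[K + 4] = g_vm
        return q


def _q_and_grad_numba(phi, K, space, gamma, sig):
    beta, o, s_l, v_l, s_m, v_m = _unpack(phi, K)
    from .states import _FOLD_R, _FOLD_X

    const_l = float(t_logdensity(0.0, 0.0, s_l, v_l))
    const_m = float(t_logdensity(0.0, 0.0, s_m, v_m))
    dv_l = float(0.5 * digamma((v_l + 1.0) / 2.0) - 0.5 * digamma(v_l / 2.0)
                 - 0.5 / v_l)
    dv_m = float(0.5 * digamma((v_m + 1.0) / 2.0) - 0.5 * digamma(v_m / 2.0)
                 - 0.5 / v_m)
    grad = np.empty(K + 5)
    q = _q_grad_kernel(
        sig.lcr, sig.maf, sig.maf_mask, sig.baf_sd, sig.maf_scale,
        sig.lcr_scale, sig.fold_k, np.ascontiguousarray(gamma),
        space.cluster, space.n_c, space.nc_mu_c, space.is_nhet,
        np.ascontiguousarray(beta, dtype=float), float(o),
        float(s_l), float(v_l), float(s_m), float(v_m),
        const_l, dv_l, const_m, dv_m,
        _FOLD_X, float(_FOLD_R[1] - _FOLD_R[0]), grad,
    )
    return -q, -grad


def _q_and_grad(phi, K, space, gamma, gamma_m, sig):
    """Negative EM auxiliary and its gradient over the continuous block."""
    if _HAVE_NUMBA:
        return _q_and_grad_numba(phi, K, space, gamma, sig)
    return _q_and_grad_numpy(phi, K, space, gamma, gamma_m, sig)


def _q_and_grad_numpy(phi, K, space, gamma, gamma_m, sig):
    """Vectorized numpy reference path (also the no-numba fallback)."""
    beta, o, s_l, v_l, s_m, v_m = _unpack(phi, K)
    b = beta[space.cluster]
    y = 2.0 * (1.0 - b) + space.n_c * b
    y_safe = np.maximum(y, 1e-12)
    z_num = (1.0 - b) + space.nc_mu_c * b
    mu_l_raw = np.log2(y_safe / 2.0) + o
    clipped = (mu_l_raw <= LCR_FLOOR) | (y <= 1e-12)
    mu_l = np.maximum(mu_l_raw, LCR_FLOOR)
    mu_m = np.where(y > 1e-12, z_num / y_safe, NORMAL_MAF)

    # LCR block with per-exon scale
    sl_i = (s_l * sig.lcr_scale)[:, None]
    zl = (sig.lcr[:, None] - mu_l[None, :]) / sl_i
    zl2 = zl * zl
    denom_l = v_l + zl2
    const_l = t_logdensity(0.0, 0.0, s_l, v_l) \
        - np.log(sig.lcr_scale)[:, None]
    q_l = gamma * (const_l - (v_l + 1.0) / 2.0 * np.log1p(zl2 / v_l))
    dmu_l = gamma * ((v_l + 1.0) * zl / (sl_i * denom_l))
    g_mu_l = dmu_l.sum(axis=0)
    g_sl = float((gamma * (-1.0 / s_l + (v_l + 1.0) * zl2 / (s_l * denom_l))).sum())
    g_vl = float(
        (gamma * (
            0.5 * digamma((v_l + 1.0) / 2.0) - 0.5 * digamma(v_l / 2.0)
            - 0.5 / v_l - 0.5 * np.log1p(zl2 / v_l)
            + (v_l + 1.0) * zl2 / (2.0 * v_l * denom_l)
        )).sum()
    )

    # MAF block: folded density f(m) + f(1-m) around the bias-corrected
    # location, with per-exon scale sigma_m/sqrt(n_snps);
    # branch-weighted gradients
    loc, dloc = maf_emission_locations(sig, mu_m)
    sm_i = (s_m * sig.maf_scale)[:, None]
    z1 = (sig.maf[:, None] - loc) / sm_i
    z2 = ((1.0 - sig.maf)[:, None] - loc) / sm_i
    z1sq, z2sq = z1 * z1, z2 * z2
    d1, d2 = v_m + z1sq, v_m + z2sq
    lf1 = -(v_m + 1.0) / 2.0 * np.log1p(z1sq / v_m)
    lf2 = -(v_m + 1.0) / 2.0 * np.log1p(z2sq / v_m)
    lfold = np.logaddexp(lf1, lf2)
    w1 = np.exp(lf1 - lfold)
    w2 = 1.0 - w1
    const_m = t_logdensity(0.0, 0.0, s_m, v_m) \
        - np.log(sig.maf_scale)[:, None]
    q_m = gamma_m * (const_m + lfold)
    dmu1 = (v_m + 1.0) * z1 / (sm_i * d1)
    dmu2 = (v_m + 1.0) * z2 / (sm_i * d2)
    dmu_m = gamma_m * (w1 * dmu1 + w2 * dmu2) * dloc
    g_mu_m = dmu_m.sum(axis=0)
    ds1 = -1.0 / s_m + (v_m + 1.0) * z1sq / (s_m * d1)
    ds2 = -1.0 / s_m + (v_m + 1.0) * z2sq / (s_m * d2)
    g_sm = float((gamma_m * (w1 * ds1 + w2 * ds2)).sum())
    dv_common = 0.5 * digamma((v_m + 1.0) / 2.0) - 0.5 * digamma(v_m / 2.0) \
        - 0.5 / v_m
    dv1 = dv_common - 0.5 * np.log1p(z1sq / v_m) \
        + (v_m + 1.0) * z1sq / (2.0 * v_m * d1)
    dv2 = dv_common - 0.5 * np.log1p(z2sq / v_m) \
        + (v_m + 1.0) * z2sq / (2.0 * v_m * d2)
    g_vm = float((gamma_m * (w1 * dv1 + w2 * dv2)).sum())

    q = float(q_l.sum() + q_m.sum())

    # chain rule to beta and o
    dmul_db = np.where(clipped, 0.0, (space.n_c - 2.0) / (y_safe * LN2))
    dmum_db = np.where(
        y > 1e-12,
        ((space.nc_mu_c - 1.0) * y_safe - z_num * (space.n_c - 2.0)) / (y_safe ** 2),
        0.0,
    )
    g_beta = np.zeros(K)
    contrib = g_mu_l * dmul_db + g_mu_m * dmum_db
    np.add.at(g_beta, space.cluster[~space.is_nhet], contrib[~space.is_nhet])
    g_o = float(g_mu_l[~clipped].sum())

    grad = np.concatenate((g_beta, [g_o, g_sl, g_vl, g_sm, g_vm]))
    return -q, -grad


def m_step(
    posterior: PosteriorMatrix,
    sig: SignalArrays,
    params: ModelParams,
    *,
    inner_maxiter: int = 6,
    update_mask: dict | None = None,
) -> tuple[ModelParams, int]:
    """One generalized M-step.  Returns (new params, fallback count).

    ``update_mask`` can freeze parameter groups, e.g. ``{"beta": False}``;
    recognized keys: beta, o, sigma_l, nu_l, sigma_m, nu_m, pi, rho.
    """
    mask = {k: True for k in
            ("beta", "o", "sigma_l", "nu_l", "sigma_m", "nu_m", "pi", "rho")}
    if update_mask:
        mask.update(update_mask)
    K, space = params.K, params.space
    gamma = posterior.gamma
    gamma_m = gamma * sig.maf_mask[:, None]

    phi0 = np.concatenate(
        (params.beta,
         [params.o, params.sigma_l, params.nu_l, params.sigma_m, params.nu_m])
    )
    bounds = (
        [BETA_BOUNDS] * K
        + [O_BOUNDS, SIGMA_L_BOUNDS, NU_BOUNDS, SIGMA_M_BOUNDS, NU_BOUNDS]
    )
    free_groups = [mask["beta"]] * K + [
        mask["o"], mask["sigma_l"], mask["nu_l"], mask["sigma_m"], mask["nu_m"]
    ]
    bounds = [
        bd if free else (v, v)
        for bd, free, v in zip(bounds, free_groups, phi0)
    ]
    phi0 = np.clip(phi0, [b[0] for b in bounds], [b[1] for b in bounds])

    res = minimize(
        _q_and_grad, phi0, args=(K, space, gamma, gamma_m, sig),
        method="L-BFGS-B", jac=True, bounds=bounds,
        options={"maxiter": inner_maxiter, "maxls": 20},
    )
    q0 = _q_and_grad(phi0, K, space, gamma, gamma_m, sig)[0]
    n_fallback = 0
    if res.fun <= q0 + 1e-9:
        phi = res.x
    else:  # optimizer failed to improve: keep current point
        phi = phi0
        n_fallback = 1
    beta, o, s_l, v_l, s_m, v_m = _unpack(phi, K)
    beta = np.asarray(beta, dtype=float).copy()

    # closed-form pi update from chain-start posteriors
    if mask["pi"]:
        pi = posterior.start_gamma.mean(axis=0)
        pi = np.maximum(pi, 1e-10)
        pi = pi / pi.sum()
    else:
        pi = params.pi.copy()

    # rho updates: expected same-label transition fractions
    rho_c, rho_k = params.rho_c, params.rho_k
    if mask["rho"]:
        xi = posterior.xi_sum
        total = xi.sum()
        if total > 0:
            same_c = xi[space.state_id[:, None] == space.state_id[None, :]].sum()
            rho_c = float(np.clip(same_c / total, *RHO_BOUNDS))
        nn = ~space.is_nhet
        xi_nn = xi[np.ix_(nn, nn)]
        tot_nn = xi_nn.sum()
        if tot_nn > 0 and K > 1:
            same_k = xi_nn[
                space.cluster[nn][:, None] == space.cluster[nn][None, :]
            ].sum()
            rho_k = float(np.clip(same_k / tot_nn, *RHO_BOUNDS))

    # relabel so beta stays ascending
    order = np.argsort(beta, kind="stable")
    if not np.array_equal(order, np.arange(K)):
        beta = beta[order]
        pi = pi[space.permute_clusters(order)]
    beta = _enforce_distinct(beta)

    new = ModelParams(
        K=K, beta=beta, o=float(o), sigma_l=float(s_l), nu_l=float(v_l),
        sigma_m=float(s_m), nu_m=float(v_m), rho_c=rho_c, rho_k=rho_k,
        pi=pi, space=space,
    )
    return new, n_fallback


def _enforce_distinct(beta: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    """Keep sorted betas strictly increasing (EM can collide clusters)."""
    beta = np.clip(beta.copy(), BETA_BOUNDS[0], 1.0)
    for i in range(1, len(beta)):
        if beta[i] <= beta[i - 1] + eps:
            beta[i] = beta[i - 1] + eps
    # collisions near the upper bound are resolved downward instead
    beta[-1] = min(beta[-1], 1.0)
    for i in range(len(beta) - 2, -1, -1):
        if beta[i] >= beta[i + 1] - eps / 2:
            beta[i] = beta[i + 1] - eps
    return beta


# ----------------------------------------------------------------------
# EM driver


def fit_em(
    signals: pd.DataFrame | SignalArrays,
    K: int,
    init: ModelParams,
    *,
    max_iter: int = 200,
    tol: float = 1e-5,
    inner_maxiter: int = 6,
    init_id: int = 0,
) -> FitResult:
    """EM until the relative log-likelihood change drops below ``tol``."""
    sig = signals if isinstance(signals, SignalArrays) else SignalArrays(signals)
    params = init.copy()
    history: list[float] = []
    param_history: list[dict] = []
    n_fallback = 0
    posterior = None
    converged = False
    n_iter = 0
    prev_ll = None
    for _ in range(max_iter + 1):
        loge = emission_matrix(sig, params)
        posterior = forward_backward(
            loge, params.pi, params.transition_matrix(), sig.chain_offsets
        )
        ll = posterior.loglik
        if not np.isfinite(ll):
            raise FloatingPointError("non-finite log-likelihood; start failed")
        history.append(ll)
        snap = {"iteration": len(history) - 1, "loglik": ll,
                "o": params.o, "sigma_l": params.sigma_l,
                "nu_l": params.nu_l, "sigma_m": params.sigma_m,
                "nu_m": params.nu_m, "rho_c": params.rho_c,
                "rho_k": params.rho_k}
        for j, b in enumerate(params.beta, start=1):
            snap[f"beta_{j}"] = float(b)
        param_history.append(snap)
        if prev_ll is not None:
            rel = abs(ll - prev_ll) / (abs(prev_ll) + 1.0)
            if rel < tol:
                converged = True
                break
        if n_iter >= max_iter:
            break
        prev_ll = ll
        params, nf = m_step(
            posterior, sig, params, inner_maxiter=inner_maxiter
        )
        n_fallback += nf
        n_iter += 1
    return FitResult(
        params=params, posterior=posterior, n_iter=n_iter, converged=converged,
        init_id=init_id, loglik_history=history, param_history=param_history,
        n_fallback=n_fallback,
    )


# ----------------------------------------------------------------------
# grid search over starts


def default_sigma_init(sig: SignalArrays) -> tuple[float, float]:
    mad_l = float(np.median(np.abs(sig.lcr - np.median(sig.lcr)))) * 1.4826
    sigma_l = float(np.clip(mad_l, *SIGMA_L_BOUNDS))
    if sig.maf_mask.any():
        m = sig.maf[sig.maf_mask]
        mad_m = float(np.median(np.abs(m - NORMAL_MAF))) * 1.4826
    else:
        mad_m = 0.03
    sigma_m = float(np.clip(max(mad_m, 0.01), *SIGMA_M_BOUNDS))
    return sigma_l, sigma_m


def prescan_beta(
    sig: SignalArrays, *, o: float = 0.0, seed_grid: np.ndarray | None = None
) -> float:
    """Coarse K=1 scan: the single cellularity with the best log-likelihood."""
    if seed_grid is None:
        seed_grid = np.arange(0.15, 0.96, 0.05)
    sigma_l, sigma_m = default_sigma_init(sig)
    best_b, best_ll = float(seed_grid[0]), -np.inf
    for b in seed_grid:
        p = ModelParams(K=1, beta=np.array([b]), o=o,
                        sigma_l=sigma_l, sigma_m=sigma_m)
        post = forward_backward(
            emission_matrix(sig, p), p.pi, p.transition_matrix(),
            sig.chain_offsets,
        )
        if post.loglik > best_ll:
            best_ll, best_b = post.loglik, float(b)
    return best_b


def build_grid(
    sig: SignalArrays,
    K: int,
    *,
    o_grid: tuple[float, ...] = DEFAULT_O_GRID,
    warm: ModelParams | list[ModelParams] | None = None,
    seed: int = 17,
    prescan: bool = True,
) -> list[ModelParams]:
    """Starting points: o baselines x cellularity seed vectors (+ warm starts).

    Warm starts (extensions of the selected K-1 solution) are tried first;
    cold starts cover the diploid/triploid/tetraploid baselines with
    equispaced cellularity seeds, plus a coarse one-cluster prescan seed at
    the diploid baseline.
    """
    del seed  # start construction is deterministic; kept for interface stability
    sigma_l, sigma_m = default_sigma_init(sig)
    starts: list[ModelParams] = []
    if warm is not None:
        starts.extend([warm] if isinstance(warm, ModelParams) else warm)
    seed_sets = [np.linspace(0.25, 0.85, K)]
    if prescan:
        b_star = prescan_beta(sig)
        pre = np.linspace(max(0.1, b_star / (K + 0.0) if K > 1 else b_star),
                          b_star, K)
        pre = _enforce_distinct(np.sort(pre), eps=0.02)
        if not any(np.allclose(pre, s, atol=0.02) for s in seed_sets):
            seed_sets.append(pre)
    for o in o_grid:
        for j, bs in enumerate(seed_sets):
            if j > 0 and o != 0.0:
                continue  # prescan seed only at the diploid baseline
            starts.append(
                ModelParams(K=K, beta=bs.copy(), o=o,
                            sigma_l=sigma_l, sigma_m=sigma_m)
            )
    return starts


def grid_search_fit(
    signals: pd.DataFrame | SignalArrays,
    K: int,
    starts: list[ModelParams] | None = None,
    *,
    n_burn: int = 5,
    n_refine: int = 3,
    max_iter: int = 200,
    tol: float = 1e-5,
    inner_maxiter: int = 6,
    seed: int = 17,
) -> FitResult:
    """Burn in every start for a few EM iterations, finish the best few.

    Early log-likelihood ranks can be unreliable when basins differ in
    convergence speed, so the top ``n_refine`` burned starts are each run
    to convergence and the best final fit wins.
    """
    sig = signals if isinstance(signals, SignalArrays) else SignalArrays(signals)
    if starts is None:
        starts = build_grid(sig, K, seed=seed)
    if not starts:
        raise ValueError("empty start grid")
    if len(starts) == 1:
        return fit_em(sig, K, starts[0], max_iter=max_iter, tol=tol,
                      inner_maxiter=inner_maxiter, init_id=0)
    burned: list[FitResult] = []
    failures = []
    for i, st in enumerate(starts):
        try:
            fr = fit_em(sig, K, st, max_iter=n_burn, tol=tol,
                        inner_maxiter=inner_maxiter, init_id=i)
            burned.append(fr)
        except FloatingPointError as exc:
            failures.append((i, str(exc)))
    if not burned:
        raise RuntimeError(f"all grid starts failed: {failures}")
    burned.sort(key=lambda fr: fr.loglik, reverse=True)
    finals: list[FitResult] = []
    for fr in burned[:max(1, n_refine)]:
        if fr.converged:
            finals.append(fr)
            continue
        finals.append(
            fit_em(sig, K, fr.params, max_iter=max_iter, tol=tol,
                   inner_maxiter=inner_maxiter, init_id=fr.init_id)
        )
    # a solution with a vacuous cluster must not mask a proper one at the
    # same K; fall back to it only when nothing better converged
    proper = [fr for fr in finals if not fr.vacuous_clusters().any()]
    pool = proper or finals
    return max(pool, key=lambda fr: fr.loglik)
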