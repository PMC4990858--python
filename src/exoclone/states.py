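"""Copy-number aberration states and the Student's-t emission model.

The hidden state of the caller factorizes into an *aberration* chain over a
fixed alphabet of 12 allele-specific copy-number states (total copy number
0..5 with every major-allele configuration, folded so that mirrored
genotypes such as AAB/ABB collapse to one state) and a *cluster* chain over
K clonal clusters, each cluster k carrying a cellularity beta_k — the
fraction of all cells in the sample that harbor that cluster's events.

For an exon in aberration state c and cluster k, the expected tumor signals
are mixtures of the normal-cell genome (2 copies, expected major-allele
frequency 0.5) and the aberrant tumor genome:

    y_ck = n_s (1 - beta_k) + n_c beta_k            (total copies)
    z_ck = n_s mu_s (1 - beta_k) + n_c mu_c beta_k  (major-allele copies)

    mu_l = log2(y_ck / 2) + o        (expected log read-count ratio)
    mu_m = z_ck / y_ck               (expected major-allele frequency)

with o a genome-wide baseline shift absorbing tumor aneuploidy.  Both
observed signals are modelled as Student's-t around these means, which keeps
single-exon outliers from dragging segment calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

# Normal (stromal) genome constants: diploid, heterozygous.
NORMAL_COPY = 2.0          # n_s
NORMAL_MAF = 0.5           # mu_s

#: Floor for log2 read-count ratios and their expected values.  A homozygous
#: deletion at cellularity 1 has y=0 and would otherwise give -inf.
LCR_FLOOR = -6.0

NHET_STATE_ID = 3


@dataclass(frozen=True)
class AberrationState:
    """One row of the aberration-state table."""

    state_id: int
    total_cn: int
    major_cn: int | None     # None only for the homozygous deletion
    genotypes: str
    aberration_type: str

    @property
    def mu_c(self) -> float:
        """Expected tumor MAF; the n_c*mu_c product is 0 for HOMD."""
        if self.major_cn is None:
            return 0.0
        return self.major_cn / self.total_cn if self.total_cn else 0.0

    @property
    def is_neutral(self) -> bool:
        return self.state_id == NHET_STATE_ID


#: The 12-state alphabet: total copy 0..5, all folded major configurations.
STATE_TABLE: tuple[AberrationState, ...] = (
    AberrationState(1, 0, None, "N/A", "HOMD"),
    AberrationState(2, 1, 1, "A, B", "HEMD"),
    AberrationState(3, 2, 1, "AB", "NHET"),
    AberrationState(4, 2, 2, "AA, BB", "NLOH"),
    AberrationState(5, 3, 2, "AAB, ABB", "AHET"),
    AberrationState(6, 3, 3, "AAA, BBB", "ALOH"),
    AberrationState(7, 4, 2, "AABB", "AHET"),
    AberrationState(8, 4, 3, "AAAB, ABBB", "AHET"),
    AberrationState(9, 4, 4, "AAAA, BBBB", "ALOH"),
    AberrationState(10, 5, 3, "AAABB, AABBB", "AHET"),
    AberrationState(11, 5, 4, "AAAAB, ABBBB", "AHET"),
    AberrationState(12, 5, 5, "AAAAA, BBBBB", "ALOH"),
)

N_STATES = len(STATE_TABLE)


def state_by_id(state_id: int) -> AberrationState:
    return STATE_TABLE[state_id - 1]


def state_table_frame():
    """The state alphabet as a DataFrame (exportable as TSV)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "state_id": [s.state_id for s in STATE_TABLE],
            "total_cn": [s.total_cn for s in STATE_TABLE],
            "major_cn": [
                "N/A" if s.major_cn is None else s.major_cn for s in STATE_TABLE
            ],
            "genotypes": [s.genotypes for s in STATE_TABLE],
            "aberration_type": [s.aberration_type for s in STATE_TABLE],
        }
    )


def parse_state_table(df) -> tuple[AberrationState, ...]:
    """Re-read an exported state table (round-trip of :func:`state_table_frame`)."""
    rows = []
    for rec in df.itertuples(index=False):
        major = None if str(rec.major_cn) == "N/A" else int(rec.major_cn)
        rows.append(
            AberrationState(
                int(rec.state_id), int(rec.total_cn), major,
                str(rec.genotypes), str(rec.aberration_type),
            )
        )
    return tuple(rows)


def emission_means(
    state: AberrationState, beta_k: float, o: float = 0.0
) -> tuple[float, float]:
    """Expected (LCR, MAF) for one aberration state at cellularity ``beta_k``.

    ``mu_l`` is floored at :data:`LCR_FLOOR`; ``mu_m`` is 0.5 in the fully
    deleted degenerate case (only normal reads remain, or none at all).
    """
    if not 0.0 < beta_k <= 1.0:
        raise ValueError(f"cellularity must be in (0, 1], got {beta_k}")
    y = NORMAL_COPY * (1.0 - beta_k) + state.total_cn * beta_k
    z = NORMAL_COPY * NORMAL_MAF * (1.0 - beta_k) + state.total_cn * state.mu_c * beta_k
    if y <= 0.0:
        return LCR_FLOOR, NORMAL_MAF
    mu_l = max(np.log2(y / 2.0) + o, LCR_FLOOR)
    mu_m = z / y
    return float(mu_l), float(mu_m)


def t_logdensity(x, mu, sigma, nu):
    """Log density of the location-scale Student's t.

    Vectorized over any broadcastable combination of arguments.
    """
    sigma = np.asarray(sigma, dtype=float)
    nu = np.asarray(nu, dtype=float)
    if np.any(sigma <= 0) or np.any(nu <= 0):
        raise ValueError("sigma and nu must be positive")
    z = (np.asarray(x, dtype=float) - mu) / sigma
    return (
        gammaln((nu + 1.0) / 2.0)
        - gammaln(nu / 2.0)
        - 0.5 * np.log(np.pi * nu)
        - np.log(sigma)
        - (nu + 1.0) / 2.0 * np.log1p(z * z / nu)
    )


#: Number of SNPs beyond which the folded-median location is treated as
#: converged to the many-SNP limit.
FOLD_K_MAX = 6


def _build_fold_tables(r_max: float = 8.0, n: int = 65, n_mc: int = 120_000):
    """Location x_k(r) of the per-exon MAF statistic, in noise units.

    The exon MAF is the sample median of k folded values |N(delta, s)|;
    x_k(r) with r = delta/s is the median of that statistic, so that the
    emission location is 0.5 + s * x_k(delta/s).  x_k(0) is 0.6745 for odd
    k (the half-normal median) but larger for even k (np.median averages
    the two central order statistics: 0.745 for k = 2); x_k(r) -> r once
    the aberration signal dominates the noise.  Tabulated by a
    fixed-seed Monte Carlo on a uniform r grid, linearly interpolated.
    """
    rng = np.random.default_rng(123456789)
    z = rng.normal(size=(n_mc, FOLD_K_MAX))
    rs = np.linspace(0.0, r_max, n)
    xs = np.empty((FOLD_K_MAX, n))
    for j, r in enumerate(rs):
        w = np.abs(z + r)
        for k in range(1, FOLD_K_MAX + 1):
            xs[k - 1, j] = np.median(np.median(w[:, :k], axis=1))
    slopes = np.gradient(xs, rs, axis=1)
    return rs, xs, slopes


_FOLD_R, _FOLD_X, _FOLD_XP = _build_fold_tables()


def _fold_interp(table, r, k):
    r = np.asarray(r, dtype=float)
    k = np.asarray(k)
    row = np.clip(k, 1, FOLD_K_MAX).astype(np.int64) - 1
    row = np.broadcast_to(row, r.shape)
    dr = _FOLD_R[1] - _FOLD_R[0]
    pos = np.clip(r / dr, 0.0, len(_FOLD_R) - 1.001)
    i0 = pos.astype(np.int64)
    frac = pos - i0
    return table[row, i0] * (1.0 - frac) + table[row, i0 + 1] * frac


def folded_median_shift(r, k=1):
    """x_k(r): folded-median location in units of the per-SNP BAF noise."""
    r = np.asarray(r, dtype=float)
    return np.where(r < _FOLD_R[-1], _fold_interp(_FOLD_X, r, k), r)


def folded_median_shift_slope(r, k=1):
    """d x_k(r) / d r, for chain-ruling emission-location gradients."""
    r = np.asarray(r, dtype=float)
    return np.where(r < _FOLD_R[-1], _fold_interp(_FOLD_XP, r, k), 1.0)


def folded_t_logdensity(m, mu, sigma, nu):
    """Log density of a folded (reflected at 0.5) Student's t.

    The per-exon MAF statistic is a fold of an underlying symmetric
    quantity: values that would fall below 0.5 are reflected above it.  The
    proper likelihood of the folded observation m >= 0.5 is therefore
    f(m; mu) + f(1-m; mu).  Without the reflection term a copy-neutral exon
    (mu = 0.5) systematically looks like a weak aberration, because folding
    shifts the observed mass above the center.
    """
    return np.logaddexp(
        t_logdensity(m, mu, sigma, nu),
        t_logdensity(1.0 - np.asarray(m, dtype=float), mu, sigma, nu),
    )
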