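"""Model parameters and the composite (aberration x cluster) state space.

The composite hidden-state space pins the copy-neutral heterozygous state
(NHET) to a single representative: its emission is independent of the
cluster, so keeping K copies would leave a K-fold label symmetry the EM
cannot resolve.  The space therefore has (C-1)*K + 1 states, laid out as

    index 0:              NHET (pinned)
    index 1 ..:           (state, cluster) for every non-neutral state,
                          state-major then cluster-minor order

which makes argmax tie-breaking (NHET first, then lower state id, then
lower cluster) a plain first-maximum scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .states import (
    LCR_FLOOR,
    N_STATES,
    NHET_STATE_ID,
    NORMAL_COPY,
    NORMAL_MAF,
    STATE_TABLE,
)

# Parameter bounds used by the M-step optimizer.
BETA_BOUNDS = (0.01, 1.0)
O_BOUNDS = (-2.5, 0.5)
SIGMA_L_BOUNDS = (0.01, 2.0)
SIGMA_M_BOUNDS = (0.005, 0.3)
NU_BOUNDS = (2.1, 30.0)
RHO_BOUNDS = (0.95, 1.0 - 1e-7)

#: Share of the aberration chain's switching mass that returns to the
#: copy-neutral state (the rest is uniform over the other states).
NHET_SWITCH_WEIGHT = 0.5


class CompositeSpace:
    """Index arrays describing the reduced (state, cluster) space for given K."""

    def __init__(self, K: int):
        if K < 1:
            raise ValueError("K must be >= 1")
        self.K = K
        state_ids = [NHET_STATE_ID]
        clusters = [0]
        for s in STATE_TABLE:
            if s.state_id == NHET_STATE_ID:
                continue
            for k in range(K):
                state_ids.append(s.state_id)
                clusters.append(k)
        self.state_id = np.array(state_ids, dtype=np.int64)
        self.cluster = np.array(clusters, dtype=np.int64)
        self.n_c = np.array(
            [STATE_TABLE[i - 1].total_cn for i in state_ids], dtype=float
        )
        self.nc_mu_c = np.array(
            [STATE_TABLE[i - 1].total_cn * STATE_TABLE[i - 1].mu_c for i in state_ids],
            dtype=float,
        )
        self.total_cn = self.n_c.astype(np.int64)
        self.is_nhet = self.state_id == NHET_STATE_ID
        self.size = len(state_ids)

    def permute_clusters(self, order: np.ndarray) -> np.ndarray:
        """Index permutation of the composite space when clusters are relabeled.

        ``order[j]`` is the old cluster index that becomes new cluster j.
        Returns ``perm`` with ``new_array = old_array[perm]``.
        """
        inv = np.empty(self.K, dtype=np.int64)
        inv[np.arange(self.K)] = order
        perm = np.empty(self.size, dtype=np.int64)
        perm[0] = 0
        idx = 1
        for s in STATE_TABLE:
            if s.state_id == NHET_STATE_ID:
                continue
            base = idx
            for k in range(self.K):
                perm[base + k] = base + inv[k]
            idx += self.K
        return perm


@dataclass
class ModelParams:
    """theta = (pi, A, beta_1:K, o, sigma_l, nu_l, sigma_m, nu_m).

    The transition matrix A is parameterized by two self-transition
    probabilities, ``rho_c`` for the aberration chain and ``rho_k`` for the
    cluster chain; off-diagonal mass is uniform within each chain and the
    composite transition is their product collapsed onto the pinned space.
    """

    K: int
    beta: np.ndarray                  # ascending cellularities, shape (K,)
    o: float = 0.0
    sigma_l: float = 0.3
    nu_l: float = 5.0
    sigma_m: float = 0.03
    nu_m: float = 5.0
    rho_c: float = 1.0 - 1e-4
    rho_k: float = 1.0 - 1e-4
    pi: np.ndarray | None = None      # over the composite space
    space: CompositeSpace = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.space is None:
            self.space = CompositeSpace(self.K)
        if self.pi is None:
            self.pi = default_pi(self.space)
        self.validate()

    def validate(self):
        if len(self.beta) != self.K:
            raise ValueError("beta must have length K")
        if np.any(self.beta <= 0) or np.any(self.beta > 1):
            raise ValueError("beta must lie in (0, 1]")
        if self.K > 1 and np.any(np.diff(self.beta) <= 0):
            raise ValueError("beta must be strictly increasing")
        if self.sigma_l <= 0 or self.sigma_m <= 0 or self.nu_l <= 0 or self.nu_m <= 0:
            raise ValueError("scale and dof parameters must be positive")
        if not (0 < self.rho_c < 1 and 0 < self.rho_k < 1):
            raise ValueError("rho_c and rho_k must be in (0, 1)")
        if abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must sum to 1")

    def copy(self) -> "ModelParams":
        return replace(self, beta=self.beta.copy(), pi=self.pi.copy())

    # ----- derived quantities ------------------------------------------

    def emission_mean_vectors(self) -> tuple[np.ndarray, np.ndarray]:
        """(mu_l, mu_m) over the composite space."""
        sp = self.space
        b = self.beta[sp.cluster]
        y = NORMAL_COPY * (1.0 - b) + sp.n_c * b
        z = NORMAL_COPY * NORMAL_MAF * (1.0 - b) + sp.nc_mu_c * b
        with np.errstate(divide="ignore"):
            mu_l = np.where(y > 0, np.log2(np.maximum(y, 1e-300) / 2.0) + self.o,
                            LCR_FLOOR)
        mu_l = np.maximum(mu_l, LCR_FLOOR)
        mu_m = np.where(y > 0, z / np.maximum(y, 1e-300), NORMAL_MAF)
        return mu_l, mu_m

    def transition_matrix(self) -> np.ndarray:
        """Composite transition over the pinned space; rows sum to 1.

        The aberration chain keeps probability ``rho_c`` of staying put; of
        the switching mass, a fixed share :data:`NHET_SWITCH_WEIGHT` goes
        back to copy-neutral and the rest spreads uniformly.  Favoring the
        return to neutral encodes that aberrant segments sit on a neutral
        background; it also breaks the ploidy aliasing in which a shifted
        baseline re-labels the whole neutral genome as a balanced gain.

        Entering NHET sums the factorial product over destination clusters
        exactly; leaving NHET re-enters the cluster chain uniformly (the
        pinned state retains no cluster label).
        """
        sp = self.space
        C, K = N_STATES, self.K
        w = NHET_SWITCH_WEIGHT

        def t_c(ci: int, cj: int) -> float:
            if ci == cj:
                return self.rho_c
            if ci == NHET_STATE_ID:          # from neutral: uniform switch
                return (1.0 - self.rho_c) / (C - 1)
            if cj == NHET_STATE_ID:          # back to neutral: favored
                return (1.0 - self.rho_c) * w
            return (1.0 - self.rho_c) * (1.0 - w) / (C - 2)

        if K == 1:
            t_k = lambda same: 1.0  # noqa: E731
        else:
            off_k = (1.0 - self.rho_k) / (K - 1)
            t_k = lambda same: self.rho_k if same else off_k  # noqa: E731

        S = sp.size
        A = np.empty((S, S))
        for i in range(S):
            ci, ki = sp.state_id[i], sp.cluster[i]
            from_nhet = sp.is_nhet[i]
            for j in range(S):
                cj, kj = sp.state_id[j], sp.cluster[j]
                pc = t_c(ci, cj)
                if sp.is_nhet[j]:
                    pk = 1.0  # summed over destination clusters
                elif from_nhet:
                    pk = 1.0 / K  # uniform cluster re-entry
                else:
                    pk = t_k(ki == kj)
                A[i, j] = pc * pk
        return A


def default_pi(space: CompositeSpace, nhet_mass: float = 0.9) -> np.ndarray:
    """Initial distribution: most mass on copy-neutral, remainder uniform."""
    pi = np.full(space.size, (1.0 - nhet_mass) / (space.size - 1))
    pi[0] = nhet_mass
    return pi
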