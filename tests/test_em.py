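import numpy as np
import pandas as pd
import pytest

from exoclone.em import (
    SignalArrays,
    emission_matrix,
    expected_loglik,
    fit_em,
    grid_search_fit,
    m_step,
    maf_emission_locations,
)
from exoclone.hmm import forward_backward
from exoclone.params import ModelParams
from exoclone.states import folded_t_logdensity, t_logdensity


def toy_signals(rng, n=50, maf_frac=0.8, depth=100.0):
    chrom = np.where(np.arange(n) < n // 2, "chr1", "chr2")
    maf = 0.5 + np.abs(rng.normal(0, 0.04, n))
    maf[rng.random(n) > maf_frac] = np.nan
    return SignalArrays(pd.DataFrame({
        "chrom": chrom,
        "lcr": rng.normal(0, 0.35, n),
        "maf": maf,
        "snp_depth": np.full(n, depth),
    }))


def simulate_at_params(rng, params, n=4000, snp_depth=120.0, segment=200):
    """Draw (lcr, maf) sequences directly from the model's own emission law.

    Hidden states follow segment-level switches between copy-neutral and
    aberrant states so all states get occupancy.
    """
    sp = params.space
    mu_l, mu_m = params.emission_mean_vectors()
    states = np.zeros(n, dtype=int)
    pos = 0
    aberrant = [s for s in range(sp.size) if not sp.is_nhet[s]]
    while pos < n:
        ln = int(rng.integers(segment // 2, segment * 2))
        states[pos:pos + ln] = 0 if rng.random() < 0.6 else rng.choice(aberrant)
        pos += ln
    lcr = mu_l[states] + params.sigma_l * rng.standard_t(df=params.nu_l, size=n)
    sd = 0.5 / np.sqrt(snp_depth)
    loc = 0.5 + sd * np.maximum(
        rng.normal((mu_m[states] - 0.5) / sd, 1.0), 0.0
    )  # crude folded draw
    maf = np.abs(loc - 0.5) + 0.5 + params.sigma_m * rng.normal(size=n) * 0.5
    maf = np.maximum(maf, 0.5)
    df = pd.DataFrame({
        "chrom": "chr1", "lcr": lcr, "maf": maf,
        "snp_depth": np.full(n, snp_depth),
    })
    return SignalArrays(df), states


class TestExpectedLoglik:
    def test_one_hot_posterior_is_single_density(self):
        rng = np.random.default_rng(0)
        sig = toy_signals(rng, n=1, maf_frac=1.0)
        params = ModelParams(K=2, beta=np.array([0.3, 0.7]))
        gamma = np.zeros((1, params.space.size))
        gamma[0, 5] = 1.0
        e_l, e_m = expected_loglik(gamma, sig, params)
        mu_l, mu_m = params.emission_mean_vectors()
        want_l = t_logdensity(sig.lcr[0], mu_l[5], params.sigma_l, params.nu_l)
        loc, _ = maf_emission_locations(sig, mu_m)
        want_m = folded_t_logdensity(sig.maf[0], loc[0, 5],
                                     params.sigma_m, params.nu_m)
        assert e_l == pytest.approx(float(want_l), abs=1e-10)
        assert e_m == pytest.approx(float(want_m), abs=1e-10)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        sig = toy_signals(rng, n=12)
        params = ModelParams(K=2, beta=np.array([0.25, 0.6]), o=-0.1)
        gamma = rng.dirichlet(np.ones(params.space.size), size=12)
        e_l, e_m = expected_loglik(gamma, sig, params)
        mu_l, mu_m = params.emission_mean_vectors()
        loc, _ = maf_emission_locations(sig, mu_m)
        ref_l = ref_m = 0.0
        for i in range(12):
            for s in range(params.space.size):
                ref_l += gamma[i, s] * float(
                    t_logdensity(sig.lcr[i], mu_l[s],
                                 params.sigma_l, params.nu_l)
                )
                if sig.maf_mask[i]:
                    ref_m += gamma[i, s] * float(
                        folded_t_logdensity(sig.maf[i], loc[i, s],
                                            params.sigma_m, params.nu_m)
                    )
        assert e_l == pytest.approx(ref_l, abs=1e-10)
        assert e_m == pytest.approx(ref_m, abs=1e-10)

    def test_missing_maf_contributes_nothing(self):
        rng = np.random.default_rng(2)
        sig = toy_signals(rng, n=20, maf_frac=0.0)
        params = ModelParams(K=1, beta=np.array([0.5]))
        gamma = rng.dirichlet(np.ones(params.space.size), size=20)
        _, e_m = expected_loglik(gamma, sig, params)
        assert e_m == 0.0


class TestEmissionMatrix:
    def test_missing_maf_equals_lcr_term_alone(self):
        rng = np.random.default_rng(3)
        sig = toy_signals(rng, n=10, maf_frac=0.0)
        params = ModelParams(K=1, beta=np.array([0.4]))
        loge = emission_matrix(sig, params)
        mu_l, _ = params.emission_mean_vectors()
        want = t_logdensity(sig.lcr[:, None], mu_l[None, :],
                            params.sigma_l, params.nu_l)
        assert np.allclose(loge, want, atol=1e-12)

    def test_neutral_state_identical_across_clusters(self):
        """Only one copy-neutral column exists: it is cluster-pinned."""
        params = ModelParams(K=3, beta=np.array([0.2, 0.5, 0.8]))
        assert int(params.space.is_nhet.sum()) == 1
        assert params.space.size == 11 * 3 + 1

    def test_strong_signal_decodes_to_generating_state(self):
        """Exons drawn at the NLOH/beta=0.7 means pick that composite state."""
        rng = np.random.default_rng(4)
        params = ModelParams(
            K=2, beta=np.array([0.3, 0.7]), sigma_l=0.1, sigma_m=0.02
        )
        sp = params.space
        target = int(np.flatnonzero((sp.state_id == 4) & (sp.cluster == 1))[0])
        mu_l, mu_m = params.emission_mean_vectors()
        n = 1000
        sig = SignalArrays(pd.DataFrame({
            "chrom": ["chr1"] * n,
            "lcr": rng.normal(mu_l[target], 0.1, n),
            "maf": rng.normal(mu_m[target], 0.02, n).clip(0.5, 1.0),
            "snp_depth": np.full(n, 10000.0),  # negligible folding shift
        }))
        loge = emission_matrix(sig, params)
        hits = (np.argmax(loge, axis=1) == target).mean()
        assert hits >= 0.95


class TestMStep:
    def test_sigma_l_matches_weighted_t_scale_fixed_point(self):
        """With only sigma_l free, the update solves the standard t-EM
        weighted-scale equation."""
        rng = np.random.default_rng(5)
        params = ModelParams(K=1, beta=np.array([0.6]), sigma_l=0.5, nu_l=6.0)
        sig, _ = simulate_at_params(rng, params, n=3000)
        loge = emission_matrix(sig, params)
        post = forward_backward(loge, params.pi, params.transition_matrix(),
                                sig.chain_offsets)
        new, _ = m_step(
            post, sig, params, inner_maxiter=200,
            update_mask={k: False for k in
                         ("beta", "o", "nu_l", "sigma_m", "nu_m", "pi", "rho")},
        )
        # independent fixed-point iteration of the weighted scale estimate
        mu_l, _ = params.emission_mean_vectors()
        resid = sig.lcr[:, None] - mu_l[None, :]
        w = post.gamma
        nu = params.nu_l
        sigma = params.sigma_l
        for _ in range(400):
            u = (nu + 1.0) / (nu + (resid / sigma) ** 2)
            sigma = np.sqrt((w * u * resid ** 2).sum() / w.sum())
        assert new.sigma_l == pytest.approx(sigma, abs=1e-4)

    def test_fixed_point_at_generative_params(self):
        """Data drawn at the current parameters leaves them nearly unmoved."""
        rng = np.random.default_rng(6)
        params = ModelParams(K=1, beta=np.array([0.7]), sigma_l=0.3,
                             sigma_m=0.02, nu_l=5.0, nu_m=5.0)
        sig, _ = simulate_at_params(rng, params, n=6000)
        loge = emission_matrix(sig, params)
        post = forward_backward(loge, params.pi, params.transition_matrix(),
                                sig.chain_offsets)
        new, _ = m_step(post, sig, params, inner_maxiter=50,
                        update_mask={"sigma_m": False, "nu_m": False})
        assert abs(new.beta[0] - params.beta[0]) < 0.01
        assert abs(new.o - params.o) < 0.01
        assert abs(new.sigma_l - params.sigma_l) < 0.01

    def test_auxiliary_never_decreases(self):
        rng = np.random.default_rng(7)
        params = ModelParams(K=2, beta=np.array([0.3, 0.7]))
        sig = toy_signals(rng, n=200)
        loge = emission_matrix(sig, params)
        post = forward_backward(loge, params.pi, params.transition_matrix(),
                                sig.chain_offsets)
        q0 = sum(expected_loglik(post.gamma, sig, params))
        new, _ = m_step(post, sig, params)
        q1 = sum(expected_loglik(post.gamma, sig, new))
        assert q1 >= q0 - 1e-9

    def test_betas_returned_sorted(self):
        rng = np.random.default_rng(8)
        params = ModelParams(K=2, beta=np.array([0.3, 0.7]))
        sig = toy_signals(rng, n=100)
        loge = emission_matrix(sig, params)
        post = forward_backward(loge, params.pi, params.transition_matrix(),
                                sig.chain_offsets)
        new, _ = m_step(post, sig, params)
        assert np.all(np.diff(new.beta) > 0)


class TestFitEm:
    def test_loglik_monotone_on_random_data(self):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sig = toy_signals(rng, n=150)
            init = ModelParams(K=2, beta=np.array([0.3, 0.7]))
            fr = fit_em(sig, 2, init, max_iter=15)
            hist = np.array(fr.loglik_history)
            assert np.all(np.diff(hist) > -1e-6), hist

    def test_infinite_tolerance_stops_after_one_iteration(self):
        rng = np.random.default_rng(11)
        sig = toy_signals(rng, n=80)
        fr = fit_em(sig, 1, ModelParams(K=1, beta=np.array([0.5])),
                    tol=np.inf)
        assert fr.n_iter == 1 and fr.converged

    def test_recovers_single_clone_cellularity(self):
        """Whole-pipeline parameter recovery at desk scale."""
        from exoclone.model import ExomeCNAModel
        from exoclone.simulate import (
            build_truth, homogeneous_mixture, simulate_counts,
        )

        spec = homogeneous_mixture(0.7, n_exons=5000, seed=9, n_segments=7,
                                   seg_exons=(25, 300))
        truth = build_truth(spec)
        exons, snps = simulate_counts(spec, truth)
        model = ExomeCNAModel.from_dataframes(exons, snps)
        res = model.fit(k=1, seed=17)
        assert res.cellularities[0] == pytest.approx(0.7, abs=0.03)

    def test_relabeling_invariance_of_initialization(self):
        rng = np.random.default_rng(12)
        true = ModelParams(K=2, beta=np.array([0.3, 0.8]), sigma_l=0.25,
                           sigma_m=0.02)
        sig, _ = simulate_at_params(rng, true, n=3000)
        fits = []
        for beta0 in ([0.2, 0.7], [0.45, 0.55]):
            fr = fit_em(sig, 2, ModelParams(K=2, beta=np.array(beta0)),
                        max_iter=60)
            fits.append(np.sort(fr.params.beta))
        assert np.allclose(fits[0], fits[1], atol=0.05)


class TestGridSearch:
    def test_singleton_grid_equals_fit_em(self):
        rng = np.random.default_rng(13)
        sig = toy_signals(rng, n=120)
        start = ModelParams(K=1, beta=np.array([0.4]))
        a = grid_search_fit(sig, 1, [start], max_iter=10)
        b = fit_em(sig, 1, start, max_iter=10)
        assert a.loglik == pytest.approx(b.loglik, abs=1e-9)
        assert np.allclose(a.params.beta, b.params.beta)

    def test_deterministic_given_starts(self):
        rng = np.random.default_rng(14)
        sig = toy_signals(rng, n=120)
        starts = [ModelParams(K=1, beta=np.array([b])) for b in (0.3, 0.6)]
        a = grid_search_fit(sig, 1, starts, max_iter=10)
        b = grid_search_fit(sig, 1, starts, max_iter=10)
        assert a.loglik == b.loglik
        assert np.array_equal(a.params.beta, b.params.beta)

    def test_shifted_baseline_start_wins_on_doubled_genome(self):
        """A genome-doubled sample is best explained from the o = -1 start.

        A purely balanced doubling (all AABB) is exactly aliased by an
        all-neutral diploid explanation, so the genome also carries
        triploid-LOH (AAA) stretches whose MAF of 1 has no diploid-baseline
        counterpart - that is what anchors the tetraploid solution.
        """
        rng = np.random.default_rng(15)
        true = ModelParams(K=1, beta=np.array([1.0]), o=-1.0, sigma_l=0.25,
                           sigma_m=0.02)
        sp = true.space
        s_aabb = int(np.flatnonzero(sp.state_id == 7)[0])   # (4,2)
        s_aaa = int(np.flatnonzero(sp.state_id == 6)[0])    # (3,3) ALOH
        n = 3000
        states = np.where(np.arange(n) < 600, s_aaa, s_aabb)  # contiguous LOH
        mu_l, mu_m = true.emission_mean_vectors()
        maf = np.clip(
            mu_m[states] + rng.normal(0, 0.02, n), 0.5, 1.0
        )
        sig = SignalArrays(pd.DataFrame({
            "chrom": "chr1",
            "lcr": rng.normal(mu_l[states], 0.25, n),
            "maf": maf,
            "snp_depth": np.full(n, 500.0),
        }))
        fits = {}
        for o0 in (0.0, -1.0):
            fr = fit_em(sig, 1, ModelParams(K=1, beta=np.array([0.9]), o=o0),
                        max_iter=30)
            fits[o0] = fr.loglik
        assert fits[-1.0] > fits[0.0]
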