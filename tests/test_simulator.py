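import numpy as np
import pandas as pd
import pytest

from exoclone.preprocess import compute_cr, gc_normalize, prepare_signals
from exoclone.simulate import (
    GenomeProfile,
    MixtureSpec,
    _normal_profile,
    build_truth,
    homogeneous_mixture,
    make_exome,
    multi_clone_mixture,
    preset_suite,
    simulate_counts,
    write_sample,
)


def _segment_profile(exome, name, events):
    """Profile with explicit aberrant exon-index runs [(i0, i1, cn, major)]."""
    base = _normal_profile(exome, name=name)
    starts = exome["start"].to_numpy()
    ends = exome["end"].to_numpy()
    chrom = exome["chrom"].to_numpy()
    segs = []
    covered = np.zeros(len(exome), dtype=bool)
    for i0, i1, cn, mj in events:
        assert len(set(chrom[i0:i1])) == 1
        segs.append((str(chrom[i0]), int(starts[i0]), int(ends[i1 - 1]), cn, mj))
        covered[i0:i1] = True
    # neutral filler for the rest, per chromosome run
    i = 0
    while i < len(exome):
        if covered[i]:
            i += 1
            continue
        j = i
        while (j + 1 < len(exome) and not covered[j + 1]
               and chrom[j + 1] == chrom[i]):
            j += 1
        segs.append((str(chrom[i]), int(starts[i]), int(ends[j]), 2, 1))
        i = j + 1
    return GenomeProfile(name=name, segments=segs)


class TestBuildTruth:
    def test_five_way_mixture_cluster_cellularities(self):
        """The t1..t4+n mixture at 0.3/0.15/0.1/0.15/0.3 gives the four
        clusters 0.15, 0.25, 0.4, 0.7 and purity 0.7."""
        spec = multi_clone_mixture(4, n_exons=2000, seed=5,
                                   segments_per_cluster=3, seg_exons=(10, 40))
        truth = build_truth(spec)
        assert np.allclose(truth.cluster_beta, [0.15, 0.25, 0.4, 0.7])
        assert truth.purity == pytest.approx(0.7)

    def test_clonal_event_cellularity_is_sum_of_carriers(self):
        exome = make_exome(200, n_chrom=2, rng=np.random.default_rng(0))
        t1 = _segment_profile(exome, "t1", [(10, 30, 3, 2)])
        t2 = _segment_profile(exome, "t2", [(10, 30, 3, 2)])
        spec = MixtureSpec(exons=exome, profiles=[t1, t2, _normal_profile(exome)],
                           proportions=[0.3, 0.25, 0.45])
        truth = build_truth(spec)
        assert truth.cluster_beta.tolist() == [pytest.approx(0.55)]
        assert truth.exons["cellularity"].max() == pytest.approx(0.55)

    def test_single_carrier_subclone(self):
        spec = multi_clone_mixture(4, n_exons=2000, seed=5,
                                   segments_per_cluster=3, seg_exons=(10, 40))
        truth = build_truth(spec)
        # the t4-only cluster sits at its proportion, 0.15
        assert truth.cluster_beta[0] == pytest.approx(0.15)

    def test_pure_normal_mixture(self):
        exome = make_exome(100, n_chrom=1, rng=np.random.default_rng(1))
        spec = MixtureSpec(exons=exome, profiles=[_normal_profile(exome)],
                           proportions=[1.0])
        truth = build_truth(spec)
        assert len(truth.cluster_beta) == 0
        assert truth.purity == 0.0
        assert (truth.exons["cluster"] == 0).all()

    def test_equal_cellularity_subsets_flagged(self):
        exome = make_exome(300, n_chrom=1, rng=np.random.default_rng(2))
        t1 = _segment_profile(exome, "t1", [(10, 40, 1, 1)])
        t2 = _segment_profile(exome, "t2", [(100, 140, 3, 2)])
        spec = MixtureSpec(exons=exome, profiles=[t1, t2, _normal_profile(exome)],
                           proportions=[0.3, 0.3, 0.4])
        truth = build_truth(spec)
        assert truth.ambiguous_cellularity
        assert len(truth.cluster_beta) == 2

    def test_conflicting_genotypes_rejected(self):
        exome = make_exome(100, n_chrom=1, rng=np.random.default_rng(3))
        t1 = _segment_profile(exome, "t1", [(10, 30, 1, 1)])
        t2 = _segment_profile(exome, "t2", [(20, 40, 3, 2)])
        spec = MixtureSpec(exons=exome, profiles=[t1, t2, _normal_profile(exome)],
                           proportions=[0.3, 0.3, 0.4])
        with pytest.raises(ValueError, match="genotype"):
            build_truth(spec)


class TestMixtureSpecValidation:
    def test_proportions_must_sum_to_one(self):
        exome = make_exome(50, n_chrom=1, rng=np.random.default_rng(0))
        with pytest.raises(ValueError, match="sum to 1"):
            MixtureSpec(exons=exome, profiles=[_normal_profile(exome)],
                        proportions=[0.7])


class TestSimulateCounts:
    def _balanced_spec(self, cell=0.5, n=6000, seed=11):
        """One HEMD and one equally sized one-copy-gain segment, so the
        genome-wide mean copy ratio stays 1 and the LCR baseline is clean."""
        exome = make_exome(n, n_chrom=6, rng=np.random.default_rng(seed))
        per = n // 6
        ev = [(10, 410, 1, 1), (per + 10, per + 410, 3, 2)]
        t1 = _segment_profile(exome, "t1", ev)
        return MixtureSpec(
            exons=exome, profiles=[t1, _normal_profile(exome)],
            proportions=[cell, 1 - cell], seed=seed,
            gc_bias_strength=0.0, gc_bias_strength_normal=0.0,
        ), ev

    def test_neutral_ratio_centers_at_one(self):
        # the ratio's *mean* carries a Jensen bias of +cv^2 from the noisy
        # denominator, so the centering check uses the median
        spec, ev = self._balanced_spec()
        truth = build_truth(spec)
        exons, _ = simulate_counts(spec, truth)
        cr, _ = compute_cr(exons)
        neutral = truth.exons["total_cn"].to_numpy() == 2
        assert 0.97 < np.nanmedian(cr[neutral]) < 1.03

    def test_hemizygous_deletion_mean_lcr(self):
        """HEMD at cellularity 0.5: segment mean LCR near log2(0.75)."""
        spec, ev = self._balanced_spec(cell=0.5)
        truth = build_truth(spec)
        exons, snps = simulate_counts(spec, truth)
        sig, _ = prepare_signals(exons, snps)
        idx = sig.index[(truth.exons.loc[sig.index, "total_cn"] == 1)]
        seg_mean = sig.loc[idx, "lcr"].mean()
        assert seg_mean == pytest.approx(np.log2(0.75), abs=0.03)

    def test_full_cellularity_nloh_maf(self):
        """Copy-neutral LOH in a pure tumor drives exon MAF toward 1."""
        exome = make_exome(2000, n_chrom=2, rng=np.random.default_rng(12))
        t1 = _segment_profile(exome, "t1", [(100, 400, 2, 2)])
        spec = MixtureSpec(exons=exome, profiles=[t1], proportions=[1.0],
                           seed=12)
        truth = build_truth(spec)
        exons, snps = simulate_counts(spec, truth)
        sig, _ = prepare_signals(exons, snps)
        in_seg = truth.exons.loc[sig.index, "major_cn"] == 2
        maf = sig.loc[in_seg[in_seg].index, "maf"].dropna()
        assert maf.mean() > 0.95

    def test_gc_bias_injected_then_removed_by_normalization(self):
        spec = homogeneous_mixture(0.5, n_exons=12000, seed=13, n_segments=8,
                                   seg_exons=(25, 200))
        truth = build_truth(spec)
        exons, _ = simulate_counts(spec, truth)
        cr, _ = compute_cr(exons)
        gc = exons["gc"].to_numpy()
        with np.errstate(divide="ignore"):
            lcr_raw = np.log2(np.maximum(cr, 1e-6))
        raw_corr = np.corrcoef(lcr_raw, gc)[0, 1]
        assert abs(raw_corr) > 0.2
        cr_norm = gc_normalize(cr, gc)
        lcr_norm = np.log2(np.maximum(cr_norm, 1e-6))
        assert abs(np.corrcoef(lcr_norm, gc)[0, 1]) < 0.1

    def test_seed_reproducibility_and_divergence(self):
        spec1 = homogeneous_mixture(0.4, n_exons=800, seed=7, n_segments=3,
                                    seg_exons=(10, 60))
        spec2 = homogeneous_mixture(0.4, n_exons=800, seed=7, n_segments=3,
                                    seg_exons=(10, 60))
        spec3 = homogeneous_mixture(0.4, n_exons=800, seed=8, n_segments=3,
                                    seg_exons=(10, 60))
        e1, s1 = simulate_counts(spec1, build_truth(spec1))
        e2, s2 = simulate_counts(spec2, build_truth(spec2))
        e3, s3 = simulate_counts(spec3, build_truth(spec3))
        pd.testing.assert_frame_equal(e1, e2)
        pd.testing.assert_frame_equal(s1, s2)
        assert not e1["tumor_count"].equals(e3["tumor_count"])

    def test_written_files_byte_identical_across_runs(self, tmp_path):
        spec = homogeneous_mixture(0.4, n_exons=500, seed=3, n_segments=2,
                                   seg_exons=(10, 40))
        for d in ("a", "b"):
            truth = build_truth(spec)
            exons, snps = simulate_counts(spec, truth)
            write_sample(tmp_path / d, spec, truth, exons, snps)
        for fname in ("exons.tsv", "snps.tsv", "truth_exons.tsv",
                      "truth_clusters.tsv", "mixture.yaml"):
            assert ((tmp_path / "a" / fname).read_bytes()
                    == (tmp_path / "b" / fname).read_bytes())


class TestPresets:
    def test_homogeneous_sweep_purities(self):
        specs = preset_suite("homogeneous_sweep", n_exons=600, seed=5)
        assert len(specs) == 9
        purities = [build_truth(s).purity for s in specs]
        assert np.allclose(purities, np.arange(0.1, 0.91, 0.1))

    def test_four_clone_default_clusters(self):
        (spec,) = preset_suite("four_clone", n_exons=2500, seed=5)
        truth = build_truth(spec)
        assert np.allclose(truth.cluster_beta, [0.15, 0.25, 0.4, 0.7])

    def test_cluster_separation_at_least_point_one(self):
        for name in ("two_clone", "three_clone", "four_clone"):
            (spec,) = preset_suite(name, n_exons=2500, seed=5)
            beta = build_truth(spec).cluster_beta
            assert np.min(np.diff(beta)) >= 0.1

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="homogeneous_sweep"):
            preset_suite("nope")
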