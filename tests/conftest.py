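import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def exon_frame():
    """A small, valid, coordinate-sorted exon count table."""
    return pd.DataFrame(
        {
            "chrom": ["chr1", "chr1", "chr2"],
            "start": [100, 500, 200],
            "end": [250, 700, 400],
            "gc": [0.4, 0.5, 0.6],
            "tumor_count": [120, 80, 100],
            "normal_count": [100, 100, 100],
        }
    )


def write_exon_tsv(path, df):
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tgc\ttumor_count\tnormal_count\n")
        df.to_csv(fh, sep="\t", index=False, header=False)
    return path


def write_snp_tsv(path, df):
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tb_depth\ttotal_depth\n")
        df.to_csv(fh, sep="\t", index=False, header=False)
    return path


@pytest.fixture(scope="session")
def small_two_clone_run():
    """A reduced-scale two-clone sample pushed through the full pipeline.

    Shared across tests that need a realistic fitted result; built once.
    """
    from exoclone.evaluate import evaluate_sample
    from exoclone.model import ExomeCNAModel
    from exoclone.simulate import build_truth, multi_clone_mixture, simulate_counts

    spec = multi_clone_mixture(
        2, n_exons=5000, seed=7, segments_per_cluster=5, seg_exons=(25, 300)
    )
    truth = build_truth(spec)
    exons, snps = simulate_counts(spec, truth)
    model = ExomeCNAModel.from_dataframes(exons, snps)
    results = model.fit(seed=17)
    metrics = evaluate_sample(
        results.exon_calls, truth.exons,
        est_betas=results.cellularities, truth_betas=truth.cluster_beta,
        est_purity=results.purity, truth_purity=truth.purity,
    )
    return {
        "spec": spec, "truth": truth, "exons": exons, "snps": snps,
        "model": model, "results": results, "metrics": metrics,
    }
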