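"""Model/Results front end tying preprocessing, fitting and output together.

`ExomeCNAModel` holds the prepared observation tracks; `fit()` runs the
BIC loop (or a fixed-K fit) and returns an `ExomeCNAResults` carrying the
estimates, segment calls and a printable summary.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .em import SignalArrays, build_grid, grid_search_fit
from .preprocess import (
    DEFAULT_GC_BIN_WIDTH,
    DEFAULT_MIN_BIN_COUNT,
    DEFAULT_MIN_NORMAL_DEPTH,
    prepare_signals,
    read_exon_table,
    read_snp_table,
)
from .segments import (
    SampleSummary,
    exon_calls_table,
    segment_table,
    segments_to_bed9,
    summarize,
)
from .selection import (
    MAX_CLUSTERS,
    bic_trace_frame,
    score_fit,
    select_k,
)


class ExomeCNAModel:
    """Joint segmentation model for tumor/normal WES copy-number signals.

    Parameters
    ----------
    signals : DataFrame from :func:`exoclone.preprocess.prepare_signals`
        (columns chrom, start, end, lcr, maf, n_snps, ...).
    dropped : exons excluded by the coverage filter, for reporting.
    """

    def __init__(self, signals: pd.DataFrame, dropped: pd.DataFrame | None = None):
        required = {"chrom", "start", "end", "lcr", "maf"}
        missing = required - set(signals.columns)
        if missing:
            raise ValueError(f"signals lack columns {sorted(missing)}")
        self.signals = signals.reset_index(drop=True)
        self.dropped = dropped if dropped is not None else signals.iloc[0:0]
        self._arrays = SignalArrays(self.signals)

    # -- constructors ---------------------------------------------------

    @classmethod
    def from_files(
        cls,
        exon_path,
        snp_path=None,
        *,
        gc_bin_width: float = DEFAULT_GC_BIN_WIDTH,
        min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
        min_normal_depth: int = DEFAULT_MIN_NORMAL_DEPTH,
    ) -> "ExomeCNAModel":
        exons = read_exon_table(exon_path)
        snps = read_snp_table(snp_path) if snp_path is not None else None
        return cls.from_dataframes(
            exons, snps, gc_bin_width=gc_bin_width,
            min_bin_count=min_bin_count, min_normal_depth=min_normal_depth,
        )

    @classmethod
    def from_dataframes(
        cls,
        exons: pd.DataFrame,
        snps: pd.DataFrame | None = None,
        *,
        gc_bin_width: float = DEFAULT_GC_BIN_WIDTH,
        min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
        min_normal_depth: int = DEFAULT_MIN_NORMAL_DEPTH,
    ) -> "ExomeCNAModel":
        signals, dropped = prepare_signals(
            exons, snps, gc_bin_width=gc_bin_width,
            min_bin_count=min_bin_count, min_normal_depth=min_normal_depth,
        )
        return cls(signals, dropped)

    # -- fitting --------------------------------------------------------

    def fit(
        self,
        k: int | None = None,
        *,
        k_max: int = MAX_CLUSTERS,
        seed: int = 17,
        tol: float = 1e-5,
        max_iter: int = 200,
        n_burn: int = 5,
        inner_maxiter: int = 6,
    ) -> "ExomeCNAResults":
        """Fit the model; ``k=None`` selects K by BIC up to ``k_max``."""
        if k is not None:
            starts = build_grid(self._arrays, k, seed=seed)
            fit = grid_search_fit(
                self._arrays, k, starts, n_burn=n_burn, max_iter=max_iter,
                tol=tol, inner_maxiter=inner_maxiter, seed=seed,
            )
            best = score_fit(fit, self._arrays.n_obs, self._arrays.n_chains)
            trace = [best]
        else:
            best, trace = select_k(
                self._arrays, k_max=k_max, seed=seed, tol=tol,
                max_iter=max_iter, n_burn=n_burn, inner_maxiter=inner_maxiter,
            )
        return ExomeCNAResults(self, best, trace, seed=seed)


class ExomeCNAResults:
    """Fitted estimates, segment calls and diagnostics."""

    def __init__(self, model: ExomeCNAModel, best, trace, *, seed: int = 17):
        self.model = model
        self.score = best
        self.trace = trace
        self.seed = seed
        self.fit_result = best.fit
        self.params = best.fit.params
        self.segments = segment_table(best.fit, model.signals)
        self.exon_calls = exon_calls_table(best.fit, model.signals)
        self.summary_data: SampleSummary = summarize(
            best.fit, self.segments, best.bic
        )

    # -- accessors ------------------------------------------------------

    @property
    def k(self) -> int:
        return self.params.K

    @property
    def cellularities(self) -> np.ndarray:
        return self.params.beta

    @property
    def purity(self) -> float | None:
        return self.summary_data.tumor_purity

    @property
    def loglik(self) -> float:
        return self.score.loglik

    @property
    def bic_trace(self) -> pd.DataFrame:
        return bic_trace_frame(self.trace)

    def summary(self) -> str:
        s = self.summary_data
        lines = [
            "Exome copy-number deconvolution",
            "=" * 47,
            f"exons analyzed      {len(self.model.signals):>10d}",
            f"exons dropped       {len(self.model.dropped):>10d}",
            f"clonal clusters K   {s.K:>10d}",
            f"log-likelihood      {s.loglik:>14.2f}",
            f"BIC                 {s.bic:>14.2f}",
            f"baseline shift o    {s.baseline_shift:>10.3f}",
            "",
            "cluster  cellularity",
        ]
        for i, b in enumerate(s.cellularities, start=1):
            tag = " (empty)" if i in s.empty_clusters else ""
            lines.append(f"{i:>7d}  {b:>10.3f}{tag}")
        purity = "undetermined" if s.tumor_purity is None else f"{s.tumor_purity:.3f}"
        lines.append("")
        lines.append(f"tumor purity        {purity:>12}")
        lines.append("")
        lines.append("genome fraction by aberration type")
        for t, f in sorted(s.genome_fraction.items()):
            lines.append(f"  {t:<6} {f:>8.4f}")
        lines.append("")
        lines.append(f"segments called     {len(self.segments):>10d}")
        return "\n".join(lines)

    # -- output ---------------------------------------------------------

    def save(self, outdir, config: dict | None = None, diagnostics: bool = False):
        """Write segments TSV/BED9, per-exon calls, summary JSON, BIC trace.

        With ``diagnostics=True`` also writes the selected fit's
        per-iteration log-likelihood and parameter snapshots.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        header = self._file_header(config)
        self._write_tsv(outdir / "segments.tsv", self.segments, header)
        self._write_tsv(outdir / "exon_calls.tsv", self.exon_calls, header)
        self._write_tsv(outdir / "bic_trace.tsv", self.bic_trace, header)
        if diagnostics:
            self._write_tsv(outdir / "fit_diagnostics.tsv",
                            self.fit_result.diagnostics_frame(), header)
        bed = segments_to_bed9(self.segments)
        with open(outdir / "segments.bed", "w") as fh:
            fh.write(header)
            bed.to_csv(fh, sep="\t", index=False, header=False)
        summary = self.summary_data.to_dict()
        summary["seed"] = self.seed
        summary["version"] = _version
        if config:
            summary["config"] = config
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
            fh.write("\n")

    def _file_header(self, config: dict | None) -> str:
        import hashlib

        cfg = json.dumps(config or {}, sort_keys=True)
        h = hashlib.sha1(cfg.encode()).hexdigest()[:12]
        return (
            f"# exoclone {_version} seed={self.seed} config_sha1={h}\n"
        )

    @staticmethod
    def _write_tsv(path: Path, df: pd.DataFrame, header: str):
        with open(path, "w") as fh:
            fh.write(header)
            df.to_csv(fh, sep="\t", index=False, float_format="%.6g")

    def plot_profile(self, ax=None):
        """LCR track colored by called aberration type (convenience plot)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(12, 3))
        sig = self.model.signals
        colors = {
            "HOMD": "#a50026", "HEMD": "#f46d43", "NHET": "#b0b0b0",
            "NLOH": "#74add1", "AHET": "#4575b4", "ALOH": "#313695",
        }
        x = np.arange(len(sig))
        state = self.exon_calls["state_id"].to_numpy()
        from .states import state_by_id

        types = np.array([state_by_id(int(s)).aberration_type for s in state])
        for t, col in colors.items():
            sel = types == t
            if sel.any():
                ax.scatter(x[sel], sig["lcr"].to_numpy()[sel], s=2, c=col,
                           label=t, rasterized=True)
        ax.set_xlabel("exon index")
        ax.set_ylabel("LCR")
        ax.legend(markerscale=4, ncol=6, fontsize=8)
        return ax
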