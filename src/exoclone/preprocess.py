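"""Input parsing and signal preprocessing.

Turns raw per-exon read counts and per-SNP allelic depths into the two
observation tracks the HMM consumes:

* **LCR** — log2 of the GC-corrected, sample-normalized tumor/normal
  read-count ratio per exon;
* **MAF** — per-exon median of the folded B-allele frequencies
  ``max(b, 1-b)`` of the germline heterozygous SNPs it contains (missing for
  SNP-free exons).

Input formats are plain tab-delimited tables (see :data:`EXON_COLUMNS` and
:data:`SNP_COLUMNS`); SNP depths may alternatively come from a minimal VCF
whose tumor sample carries an AD format field.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .states import LCR_FLOOR

logger = logging.getLogger(__name__)

EXON_COLUMNS = ["chrom", "start", "end", "gc", "tumor_count", "normal_count"]
SNP_COLUMNS = ["chrom", "pos", "b_depth", "total_depth"]

#: GC bins of 1% width; bins with fewer exons fall back to the global median.
DEFAULT_GC_BIN_WIDTH = 0.01
DEFAULT_MIN_BIN_COUNT = 20
DEFAULT_MIN_NORMAL_DEPTH = 10


class InputError(ValueError):
    """Malformed or inconsistent input data."""


def chrom_sort_key(chrom: str) -> tuple[int, str]:
    """Natural chromosome ordering: chr1 < chr2 < ... < chr10 < chrX < chrY."""
    name = chrom[3:] if chrom.lower().startswith("chr") else chrom
    if name.isdigit():
        return (int(name), "")
    special = {"X": 23, "Y": 24, "M": 25, "MT": 25}
    return (special.get(name.upper(), 99), name)


def _sort_genomic(df: pd.DataFrame, poscol: str) -> pd.DataFrame:
    key = df["chrom"].map(lambda c: chrom_sort_key(str(c)))
    order = sorted(range(len(df)), key=lambda i: (key.iat[i], df[poscol].iat[i]))
    if order != list(range(len(df))):
        logger.info("input not coordinate-sorted; sorting")
        df = df.iloc[order].reset_index(drop=True)
    return df


def read_exon_table(path: str | Path) -> pd.DataFrame:
    """Read a per-exon count table (TSV with a possibly '#'-prefixed header).

    Returns a DataFrame with :data:`EXON_COLUMNS`, coordinate-sorted.
    Overlapping or duplicated exons and out-of-range fields are rejected.
    """
    path = Path(path)
    df = _read_tsv(path, EXON_COLUMNS)
    df = _coerce(
        df,
        {"chrom": str, "start": np.int64, "end": np.int64,
         "gc": float, "tumor_count": np.int64, "normal_count": np.int64},
        str(path),
    )
    _validate_exons(df, str(path))
    df = _sort_genomic(df, "start")
    for chrom, grp in df.groupby("chrom", sort=False):
        s, e = grp["start"].to_numpy(), grp["end"].to_numpy()
        if np.any(s[1:] < e[:-1]):
            i = int(np.argmax(s[1:] < e[:-1]))
            raise InputError(
                f"{path}: overlapping or duplicate exons on {chrom} near "
                f"position {int(s[i + 1])}"
            )
    return df


def _read_tsv(path: Path, columns: list[str]) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
    header = first.lstrip("#").split()
    if header[: len(columns)] != columns:
        raise InputError(
            f"{path}: expected header columns {columns}, found {header}"
        )
    try:
        return pd.read_csv(
            path, sep="\t", comment=None, skiprows=1, names=columns,
            header=None, dtype=str, skip_blank_lines=True,
        ).dropna(how="all")
    except pd.errors.ParserError as exc:
        m = re.search(r"line (\d+)", str(exc))
        line = m.group(1) if m else "?"
        raise InputError(f"{path}: malformed line {line}: {exc}") from exc


def _coerce(df: pd.DataFrame, dtypes: dict, label: str) -> pd.DataFrame:
    """Column-wise dtype coercion; a failure names the offending line."""
    for col, dt in dtypes.items():
        try:
            df[col] = df[col].astype(dt)
        except (ValueError, TypeError) as exc:
            numeric = pd.to_numeric(df[col], errors="coerce")
            bad = numeric.index[numeric.isna()]
            line = int(bad[0]) + 2 if len(bad) else "?"
            raise InputError(
                f"{label}: malformed line {line}: bad value in column "
                f"{col!r}"
            ) from exc
    return df


def _validate_exons(df: pd.DataFrame, label: str):
    bad = df.index[df["end"] <= df["start"]]
    if len(bad):
        raise InputError(f"{label}: line {bad[0] + 2}: end must exceed start")
    bad = df.index[(df["gc"] < 0) | (df["gc"] > 1)]
    if len(bad):
        raise InputError(f"{label}: line {bad[0] + 2}: gc must be in [0, 1]")
    bad = df.index[(df["tumor_count"] < 0) | (df["normal_count"] < 0)]
    if len(bad):
        raise InputError(f"{label}: line {bad[0] + 2}: counts must be >= 0")


def read_snp_table(path: str | Path) -> pd.DataFrame:
    """Read SNP allelic depths from a TSV or a minimal VCF (.vcf).

    For VCF input, B-allele depth is the first ALT depth of the tumor
    sample's AD field and total depth is the sum of the AD entries.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf":
        df = _read_snp_vcf(path)
    else:
        df = _read_tsv(path, SNP_COLUMNS)
        df = _coerce(
            df,
            {"chrom": str, "pos": np.int64,
             "b_depth": np.int64, "total_depth": np.int64},
            str(path),
        )
    if np.any(df["total_depth"] < 1):
        raise InputError(f"{path}: total_depth must be >= 1")
    if np.any((df["b_depth"] < 0) | (df["b_depth"] > df["total_depth"])):
        raise InputError(f"{path}: b_depth must be in [0, total_depth]")
    return _sort_genomic(df, "pos")


def _read_snp_vcf(path: Path) -> pd.DataFrame:
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if not samples:
            raise InputError(f"{path}: VCF has no sample columns")
        tumor = samples[0]
        for rec in vcf:
            ad = rec.samples[tumor].get("AD")
            if ad is None or len(ad) < 2 or any(a is None for a in ad[:2]):
                continue
            total = int(sum(a for a in ad if a is not None))
            if total < 1:
                continue
            rows.append((rec.chrom, rec.pos, int(ad[1]), total))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def compute_cr(exons: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Sample-normalized tumor/normal read-count ratio per exon.

    cr_i = (tumor_i / T) / (normal_i / S) with T, S the sample totals.
    Returns ``(cr, excluded)`` where ``excluded`` flags exons with zero
    normal coverage (their cr is NaN).
    """
    t = exons["tumor_count"].to_numpy(dtype=float)
    n = exons["normal_count"].to_numpy(dtype=float)
    if len(t) == 0 or not np.any(n > 0):
        raise InputError("no exon has normal coverage")
    T, S = t.sum(), n.sum()
    excluded = n == 0
    cr = np.full(len(t), np.nan)
    cr[~excluded] = (t[~excluded] / T) / (n[~excluded] / S)
    return cr, excluded


def gc_normalize(
    cr: np.ndarray,
    gc: np.ndarray,
    gc_bin_width: float = DEFAULT_GC_BIN_WIDTH,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
) -> np.ndarray:
    """GC-correct read-count ratios: cr_i * (global median) / (GC-bin median).

    "Same GC content" is discretized into bins of ``gc_bin_width``; bins
    holding fewer than ``min_bin_count`` finite ratios keep factor 1.
    """
    cr = np.asarray(cr, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if cr.size == 0:
        raise InputError("empty input to gc_normalize")
    ok = np.isfinite(cr)
    m = np.median(cr[ok])
    bins = np.floor(gc / gc_bin_width).astype(np.int64)
    out = cr.copy()
    for b in np.unique(bins):
        sel = (bins == b) & ok
        if sel.sum() >= min_bin_count:
            m_x = np.median(cr[sel])
            if m_x > 0:
                out[sel] = cr[sel] * (m / m_x)
    return out


def _lcr_scale(tumor: np.ndarray, normal: np.ndarray,
               lcr: np.ndarray) -> np.ndarray:
    """Relative per-exon LCR noise scale from read depth.

    The counting part of the log-ratio variance is about 1/t + 1/n; the
    rest (overdispersion, capture noise) is a shared floor estimated
    robustly as the excess of the observed LCR variance over the median
    counting term.  Returns scales normalized to median 1, so the global
    sigma_l keeps its meaning for a typical exon.
    """
    v_count = 1.0 / (tumor + 1.0) + 1.0 / (normal + 1.0)
    ln2 = np.log(2.0)
    mad = np.median(np.abs(lcr - np.median(lcr)))
    total_var_ln = (1.4826 * mad * ln2) ** 2
    floor = max(total_var_ln - float(np.median(v_count)), 1e-4)
    v = v_count + floor
    scale = np.sqrt(v / np.median(v))
    return np.clip(scale, 0.5, 3.0)


def compute_maf(
    snps: pd.DataFrame, exons: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, int]:
    """Per-exon median folded B-allele frequency.

    SNPs (1-based positions) are assigned to the exon [start, end) with
    start < pos <= end.  Returns ``(maf, n_snps, snp_depth, n_unassigned)``;
    ``maf`` is NaN for exons without SNPs and ``snp_depth`` is the mean
    total depth of the exon's SNPs (used to size the folding-bias
    correction of the MAF emission).
    """
    n_ex = len(exons)
    maf = np.full(n_ex, np.nan)
    snp_depth = np.full(n_ex, np.nan)
    n_snps = np.zeros(n_ex, dtype=np.int64)
    if len(snps) == 0:
        return maf, n_snps, snp_depth, 0
    baf = snps["b_depth"].to_numpy(float) / snps["total_depth"].to_numpy(float)
    folded = np.maximum(baf, 1.0 - baf)
    depth = snps["total_depth"].to_numpy(float)
    unassigned = 0
    ex_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in exons.groupby("chrom", sort=False)
    }
    per_exon: dict[int, list[float]] = {}
    per_exon_depth: dict[int, list[float]] = {}
    snp_chrom = snps["chrom"].to_numpy()
    snp_pos = snps["pos"].to_numpy()
    for j in range(len(snps)):
        entry = ex_by_chrom.get(snp_chrom[j])
        if entry is None:
            unassigned += 1
            continue
        idx, starts, ends = entry
        # start < pos <= end  <=>  searchsorted over starts, then containment
        i = np.searchsorted(starts, snp_pos[j], side="left") - 1
        if i >= 0 and snp_pos[j] <= ends[i]:
            per_exon.setdefault(int(idx[i]), []).append(folded[j])
            per_exon_depth.setdefault(int(idx[i]), []).append(depth[j])
        else:
            unassigned += 1
    for i, vals in per_exon.items():
        maf[i] = float(np.median(vals))
        n_snps[i] = len(vals)
        snp_depth[i] = float(np.mean(per_exon_depth[i]))
    if unassigned:
        logger.info("%d SNPs fall outside every exon; ignored", unassigned)
    return maf, n_snps, snp_depth, unassigned


def prepare_signals(
    exons: pd.DataFrame,
    snps: pd.DataFrame | None = None,
    *,
    gc_bin_width: float = DEFAULT_GC_BIN_WIDTH,
    min_bin_count: int = DEFAULT_MIN_BIN_COUNT,
    min_normal_depth: int = DEFAULT_MIN_NORMAL_DEPTH,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full preprocessing: exclusion, CR, GC correction, LCR, MAF.

    Exons with normal coverage below ``min_normal_depth`` are dropped before
    analysis.  Returns ``(signals, dropped)``; ``signals`` adds columns
    cr, cr_norm, lcr, maf, n_snps to the retained exon rows.
    """
    keep = exons["normal_count"].to_numpy() >= min_normal_depth
    dropped = exons.loc[~keep].reset_index(drop=True)
    sig = exons.loc[keep].reset_index(drop=True)
    if len(sig) == 0:
        raise InputError("all exons dropped by the minimum normal-depth filter")
    cr, _ = compute_cr(sig)
    cr_norm = gc_normalize(
        cr, sig["gc"].to_numpy(), gc_bin_width=gc_bin_width,
        min_bin_count=min_bin_count,
    )
    with np.errstate(divide="ignore"):
        lcr = np.log2(np.maximum(cr_norm, 0.0))
    lcr = np.maximum(lcr, LCR_FLOOR)
    sig["cr"] = cr
    sig["cr_norm"] = cr_norm
    sig["lcr"] = lcr
    sig["lcr_scale"] = _lcr_scale(
        sig["tumor_count"].to_numpy(float),
        sig["normal_count"].to_numpy(float), lcr,
    )
    if snps is not None and len(snps):
        maf, n_snps, snp_depth, _ = compute_maf(snps, sig)
    else:
        maf = np.full(len(sig), np.nan)
        snp_depth = np.full(len(sig), np.nan)
        n_snps = np.zeros(len(sig), dtype=np.int64)
    sig["maf"] = maf
    sig["n_snps"] = n_snps
    sig["snp_depth"] = snp_depth
    if len(dropped):
        logger.info(
            "dropped %d/%d exons below normal depth %d",
            len(dropped), len(exons), min_normal_depth,
        )
    return sig, dropped
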