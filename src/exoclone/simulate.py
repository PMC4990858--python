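"""Synthetic heterogeneous tumor WES generator with ground truth.

Emulates, at the read-count level, the mixing construction used to test
subclonal copy-number callers: several tumor genomes (t1, t2, ...) each
carry segment-level integer copy-number aberrations, and the sequenced
sample is a mixture of those genomes plus a normal genome (n) at fixed
proportions.  Events carried by the same subset of tumor genomes share one
cellularity (the summed proportion of their carriers) and therefore form
one clonal cluster; tumor purity is 1 minus the normal proportion.

Instead of resampling reads from BAMs, counts are drawn directly:

* normal exon counts: negative binomial around a depth x exon-length mean
  with a multiplicative GC bias exp(a_n (gc - 0.5));
* tumor exon counts: the same mean scaled by y/2, where
  y = 2 (1 - cellularity) + total_cn * cellularity is the mixture-effective
  copy number, under its own GC bias strength a_t (a_t != a_n, so GC
  correction is non-trivial);
* SNP allelic depths: binomial around the mixture-effective B-allele
  fraction, the B allele assigned to the major or minor haplotype uniformly
  at random per SNP.

Everything is reproducible from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .preprocess import EXON_COLUMNS, SNP_COLUMNS

# Desk-scale defaults: minutes per sample, not hours.
DEFAULT_N_EXONS = 20_000
DEFAULT_N_CHROM = 22
DEFAULT_MEAN_DEPTH = 100.0
DEFAULT_OVERDISPERSION = 50.0     # negative-binomial size
DEFAULT_SNPS_PER_EXON = 2.0
DEFAULT_GC_BIAS_TUMOR = 1.5
DEFAULT_GC_BIAS_NORMAL = 0.75
MEAN_EXON_LEN = 150.0

PRESET_NAMES = ("homogeneous_sweep", "two_clone", "three_clone", "four_clone")

#: (total_cn, major_cn, weight) palette for aberrant segments.  Hemizygous
#: deletion and one-copy gains dominate, homozygous deletions are rare and
#: short, mirroring typical tumor genomes.
EVENT_PALETTE = (
    (1, 1, 0.30),
    (0, 0, 0.04),
    (2, 2, 0.18),
    (3, 2, 0.22),
    (3, 3, 0.06),
    (4, 2, 0.08),
    (4, 3, 0.05),
    (4, 4, 0.03),
    (5, 3, 0.04),
)


@dataclass
class GenomeProfile:
    """One genome of the mixture: segment-level (total, major) copy numbers."""

    name: str
    #: (chrom, start, end, total_cn, major_cn); tiles each chromosome.
    segments: list[tuple[str, int, int, int, int]]

    def is_normal(self) -> bool:
        return all(s[3] == 2 and s[4] == 1 for s in self.segments)


@dataclass
class MixtureSpec:
    """A stated mixture: exome grid, genome profiles, proportions, noise."""

    exons: pd.DataFrame                 # chrom, start, end, gc
    profiles: list[GenomeProfile]
    proportions: list[float]
    mean_depth: float = DEFAULT_MEAN_DEPTH
    overdispersion: float = DEFAULT_OVERDISPERSION
    snps_per_exon_mean: float = DEFAULT_SNPS_PER_EXON
    gc_bias_strength: float = DEFAULT_GC_BIAS_TUMOR
    gc_bias_strength_normal: float = DEFAULT_GC_BIAS_NORMAL
    seed: int = 17
    name: str = "mixture"

    def __post_init__(self):
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("proportions must sum to 1")
        if any(p <= 0 for p in self.proportions):
            raise ValueError("proportions must be positive")
        if len(self.proportions) != len(self.profiles):
            raise ValueError("one proportion per profile required")

    def to_yaml(self) -> str:
        doc = {
            "name": self.name,
            "seed": self.seed,
            "proportions": {
                p.name: float(w) for p, w in zip(self.profiles, self.proportions)
            },
            "mean_depth": self.mean_depth,
            "overdispersion": self.overdispersion,
            "snps_per_exon_mean": self.snps_per_exon_mean,
            "gc_bias_strength": self.gc_bias_strength,
            "gc_bias_strength_normal": self.gc_bias_strength_normal,
            "profiles": {
                p.name: [list(s) for s in p.segments] for p in self.profiles
            },
        }
        return yaml.safe_dump(doc, sort_keys=True)


@dataclass
class TruthTable:
    """Ground truth per exon and per clonal cluster."""

    exons: pd.DataFrame        # + total_cn, major_cn, cellularity, cluster
    cluster_beta: np.ndarray   # ascending cellularities, shape (K,)
    purity: float
    ambiguous_cellularity: bool = False
    carrier_sets: list[frozenset] = field(default_factory=list)


# ----------------------------------------------------------------------
# exome grid and profile construction


def make_exome(
    n_exons: int = DEFAULT_N_EXONS,
    n_chrom: int = DEFAULT_N_CHROM,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """An exon grid over ``n_chrom`` chromosomes with realistic GC content."""
    rng = rng or np.random.default_rng(0)
    per = np.full(n_chrom, n_exons // n_chrom)
    per[: n_exons % n_chrom] += 1
    rows = []
    for c in range(n_chrom):
        lengths = rng.integers(60, 300, size=per[c])
        gaps = rng.integers(200, 5000, size=per[c])
        pos = 10_000
        for ln, gp in zip(lengths, gaps):
            rows.append((f"chr{c + 1}", pos, pos + int(ln)))
            pos += int(ln) + int(gp)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    gc = np.clip(rng.normal(0.45, 0.1, size=len(df)), 0.2, 0.8)
    df["gc"] = np.round(gc, 4)
    return df


def _normal_profile(exons: pd.DataFrame, name: str = "n") -> GenomeProfile:
    segs = []
    for chrom, grp in exons.groupby("chrom", sort=False):
        segs.append((str(chrom), int(grp["start"].min()), int(grp["end"].max()),
                     2, 1))
    return GenomeProfile(name=name, segments=segs)


DEFAULT_SEG_EXONS = (25, 500)


def _place_events(
    exons: pd.DataFrame,
    cluster_plans: list[tuple[frozenset, int]],
    rng: np.random.Generator,
    seg_exons: tuple[int, int] = DEFAULT_SEG_EXONS,
) -> dict[frozenset, list[tuple[int, int, int, int]]]:
    """Assign non-overlapping aberrant runs (exon-index space) per cluster.

    Segment sizes are log-uniform between the ``seg_exons`` bounds, spanning
    focal events up to arm-scale ones (most tumor CNAs are broad);
    homozygous deletions are always focal.  Returns carriers -> list of
    (i0, i1, total_cn, major_cn).
    """
    n = len(exons)
    chrom = exons["chrom"].to_numpy()
    occupied = np.zeros(n, dtype=bool)
    kinds = np.array([(t, m) for t, m, _ in EVENT_PALETTE])
    weights = np.array([w for _, _, w in EVENT_PALETTE])
    weights = weights / weights.sum()
    out: dict[frozenset, list[tuple[int, int, int, int]]] = {}
    for carriers, n_seg in cluster_plans:
        placed = []
        attempts = 0
        while len(placed) < n_seg and attempts < 200 * n_seg:
            attempts += 1
            ki = rng.choice(len(kinds), p=weights)
            total, major = int(kinds[ki][0]), int(kinds[ki][1])
            if total == 0:
                ln = int(rng.integers(8, 25))    # homozygous deletions are short
            else:
                ln = int(round(np.exp(rng.uniform(
                    np.log(seg_exons[0]), np.log(seg_exons[1])
                ))))
            i0 = int(rng.integers(0, n - ln))
            i1 = i0 + ln
            if chrom[i0] != chrom[i1 - 1] or occupied[i0:i1].any():
                continue
            occupied[i0:i1] = True
            placed.append((i0, i1, total, major))
        if len(placed) < n_seg:
            raise RuntimeError("could not place all aberrant segments")
        out[carriers] = placed
    return out


def _profiles_from_events(
    exons: pd.DataFrame,
    tumor_names: list[str],
    events: dict[frozenset, list[tuple[int, int, int, int]]],
) -> list[GenomeProfile]:
    starts = exons["start"].to_numpy()
    ends = exons["end"].to_numpy()
    chrom = exons["chrom"].to_numpy()
    profiles = []
    for name in tumor_names:
        cn = np.full(len(exons), 2, dtype=int)
        mj = np.ones(len(exons), dtype=int)
        for carriers, segs in events.items():
            if name not in carriers:
                continue
            for i0, i1, total, major in segs:
                cn[i0:i1] = total
                mj[i0:i1] = major
        segs_out = []
        i = 0
        n = len(exons)
        while i < n:
            j = i
            while (
                j + 1 < n and chrom[j + 1] == chrom[i]
                and cn[j + 1] == cn[i] and mj[j + 1] == mj[i]
            ):
                j += 1
            segs_out.append(
                (str(chrom[i]), int(starts[i]), int(ends[j]), int(cn[i]), int(mj[i]))
            )
            i = j + 1
        profiles.append(GenomeProfile(name=name, segments=segs_out))
    return profiles


# ----------------------------------------------------------------------
# truth


def _exon_profile_cn(
    exons: pd.DataFrame, profile: GenomeProfile
) -> tuple[np.ndarray, np.ndarray]:
    """(total, major) per exon for one profile via coordinate containment."""
    total = np.full(len(exons), 2, dtype=int)
    major = np.ones(len(exons), dtype=int)
    by_chrom: dict[str, list[tuple[int, int, int, int]]] = {}
    for c, s, e, t, m in profile.segments:
        by_chrom.setdefault(c, []).append((s, e, t, m))
    for chrom, grp in exons.groupby("chrom", sort=False):
        segs = sorted(by_chrom.get(str(chrom), []))
        if not segs:
            continue
        s_arr = np.array([s[0] for s in segs])
        idx = np.searchsorted(s_arr, grp["start"].to_numpy(), side="right") - 1
        for row_pos, si in zip(grp.index, idx):
            if si >= 0:
                s, e, t, m = segs[si]
                if grp.at[row_pos, "start"] < e:
                    total[row_pos] = t
                    major[row_pos] = m
    return total, major


def build_truth(spec: MixtureSpec) -> TruthTable:
    """Derive per-exon truth and clonal-cluster cellularities from a mixture.

    Cluster cellularity is the summed proportion of the tumor genomes
    carrying the cluster's events; purity is 1 minus the normal proportion.
    Carrier subsets that coincide in cellularity are kept but flagged (such
    clones are not separable by any cellularity-based method).
    """
    n = len(spec.exons)
    props = {p.name: w for p, w in zip(spec.profiles, spec.proportions)}
    tumor_profiles = [p for p in spec.profiles if not p.is_normal()]
    purity = float(sum(props[p.name] for p in tumor_profiles))

    per = {p.name: _exon_profile_cn(spec.exons, p) for p in spec.profiles}
    total_cn = np.full(n, 2, dtype=int)
    major_cn = np.ones(n, dtype=int)
    cellularity = np.zeros(n)
    carrier_key = np.full(n, -1, dtype=int)
    carrier_sets: list[frozenset] = []

    for i in range(n):
        carriers = []
        geno = None
        for p in spec.profiles:
            t, m = per[p.name][0][i], per[p.name][1][i]
            if (t, m) != (2, 1):
                carriers.append(p.name)
                if geno is None:
                    geno = (t, m)
                elif geno != (t, m):
                    raise ValueError(
                        "multiple tumor genotypes at one locus are not supported"
                    )
        if not carriers:
            continue
        key = frozenset(carriers)
        if key not in carrier_sets:
            carrier_sets.append(key)
        carrier_key[i] = carrier_sets.index(key)
        total_cn[i], major_cn[i] = geno
        cellularity[i] = sum(props[c] for c in carriers)

    betas = np.array([sum(props[c] for c in cs) for cs in carrier_sets])
    order = np.argsort(betas, kind="stable")
    betas_sorted = betas[order]
    ambiguous = bool(
        len(betas_sorted) > 1 and np.any(np.diff(betas_sorted) < 1e-9)
    )
    relabel = {int(old): rank + 1 for rank, old in enumerate(order)}
    cluster = np.array(
        [0 if k < 0 else relabel[int(k)] for k in carrier_key], dtype=int
    )

    truth = spec.exons.copy()
    truth["total_cn"] = total_cn
    truth["major_cn"] = major_cn
    truth["cellularity"] = np.round(cellularity, 9)
    truth["cluster"] = cluster
    return TruthTable(
        exons=truth, cluster_beta=betas_sorted,
        purity=purity if tumor_profiles else 0.0,
        ambiguous_cellularity=ambiguous,
        carrier_sets=[carrier_sets[int(i)] for i in order],
    )


# ----------------------------------------------------------------------
# counts


def _neg_binomial(rng, mean, size_param):
    mean = np.maximum(mean, 1e-9)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_counts(
    spec: MixtureSpec, truth: TruthTable | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the exon count table and the SNP allelic-depth table."""
    truth = truth or build_truth(spec)
    rng = np.random.default_rng(spec.seed)
    ex = truth.exons
    n = len(ex)
    gc = ex["gc"].to_numpy()
    length = (ex["end"] - ex["start"]).to_numpy(dtype=float)
    cell = ex["cellularity"].to_numpy()
    cn = ex["total_cn"].to_numpy(dtype=float)
    mj = ex["major_cn"].to_numpy(dtype=float)

    y = 2.0 * (1.0 - cell) + cn * cell
    base = spec.mean_depth * length / MEAN_EXON_LEN
    mean_n = base * np.exp(spec.gc_bias_strength_normal * (gc - 0.5))
    mean_t = base * np.exp(spec.gc_bias_strength * (gc - 0.5)) * (y / 2.0)
    normal_count = _neg_binomial(rng, mean_n, spec.overdispersion)
    tumor_count = _neg_binomial(rng, mean_t, spec.overdispersion)

    exon_table = ex[["chrom", "start", "end", "gc"]].copy()
    exon_table["tumor_count"] = tumor_count
    exon_table["normal_count"] = normal_count

    # SNPs: mixture-effective major-allele fraction z/y, B-allele random side
    n_snps = rng.poisson(spec.snps_per_exon_mean, size=n)
    z = 1.0 * (1.0 - cell) + mj * cell
    rows = []
    chrom_arr = ex["chrom"].to_numpy()
    start_arr = ex["start"].to_numpy()
    end_arr = ex["end"].to_numpy()
    for i in range(n):
        if n_snps[i] == 0 or y[i] <= 1e-9:
            continue
        span = end_arr[i] - start_arr[i]
        k = min(int(n_snps[i]), int(span))
        offs = np.sort(rng.choice(span, size=k, replace=False))
        p_major = z[i] / y[i]
        for off in offs:
            depth = int(rng.poisson(spec.mean_depth * y[i] / 2.0))
            if depth < 1:
                continue
            p_b = p_major if rng.random() < 0.5 else 1.0 - p_major
            b = int(rng.binomial(depth, min(max(p_b, 0.0), 1.0)))
            rows.append((chrom_arr[i], int(start_arr[i] + off + 1), b, depth))
    snp_table = pd.DataFrame(rows, columns=SNP_COLUMNS)
    return exon_table, snp_table


# ----------------------------------------------------------------------
# presets


def _mixture(
    name: str,
    tumor_props: dict[str, float],
    cluster_plans: list[tuple[frozenset, int]],
    *,
    n_exons: int,
    seed: int,
    seg_exons: tuple[int, int] = DEFAULT_SEG_EXONS,
    **noise,
) -> MixtureSpec:
    rng = np.random.default_rng(seed)
    exome = make_exome(n_exons, rng=rng)
    events = _place_events(exome, cluster_plans, rng, seg_exons=seg_exons)
    profiles = _profiles_from_events(exome, sorted(tumor_props), events)
    profiles.append(_normal_profile(exome))
    names = [p.name for p in profiles]
    props = [tumor_props.get(nm, 1.0 - sum(tumor_props.values())) for nm in names]
    return MixtureSpec(
        exons=exome, profiles=profiles, proportions=props,
        seed=seed, name=name, **noise,
    )


def homogeneous_mixture(
    purity: float, *, n_exons: int = DEFAULT_N_EXONS, seed: int = 17,
    n_segments: int = 25, seg_exons: tuple[int, int] = DEFAULT_SEG_EXONS,
    **noise,
) -> MixtureSpec:
    """One tumor clone at the given purity mixed with normal cells."""
    plans = [(frozenset({"t1"}), n_segments)]
    return _mixture(
        f"homogeneous_p{purity:g}", {"t1": purity}, plans,
        n_exons=n_exons, seed=seed, seg_exons=seg_exons, **noise,
    )


def multi_clone_mixture(
    n_clones: int, *, n_exons: int = DEFAULT_N_EXONS, seed: int = 17,
    segments_per_cluster: int = 12,
    seg_exons: tuple[int, int] = DEFAULT_SEG_EXONS,
    **noise,
) -> MixtureSpec:
    """2-4 clonal clusters with cellularities separated by >= 0.1.

    The four-clone design follows the five-way mixture t1..t4 + n at
    proportions 0.3/0.15/0.1/0.15/0.3, whose carrier subsets yield clusters
    at cellularity 0.15, 0.25, 0.4 and 0.7.
    """
    if n_clones == 2:
        props = {"t1": 0.2, "t2": 0.5}                      # normal 0.3
        subsets = [frozenset({"t1", "t2"}), frozenset({"t2"})]   # 0.7, 0.5
    elif n_clones == 3:
        props = {"t1": 0.15, "t2": 0.25, "t3": 0.3}         # normal 0.3
        subsets = [
            frozenset({"t1", "t2", "t3"}),                  # 0.70
            frozenset({"t2", "t3"}),                        # 0.55
            frozenset({"t3"}),                              # 0.30
        ]
    elif n_clones == 4:
        props = {"t1": 0.3, "t2": 0.15, "t3": 0.1, "t4": 0.15}   # normal 0.3
        subsets = [
            frozenset({"t1", "t2", "t3", "t4"}),            # 0.70
            frozenset({"t1", "t3"}),                        # 0.40
            frozenset({"t2", "t3"}),                        # 0.25
            frozenset({"t4"}),                              # 0.15
        ]
    else:
        raise ValueError("n_clones must be 2, 3 or 4")
    plans = [(s, segments_per_cluster) for s in subsets]
    return _mixture(
        f"{n_clones}_clone", props, plans, n_exons=n_exons, seed=seed,
        seg_exons=seg_exons, **noise,
    )


def preset_suite(
    name: str, *, n_exons: int = DEFAULT_N_EXONS, seed: int = 17, **noise
) -> list[MixtureSpec]:
    """Named suites of mixtures used by the evaluation protocol.

    Segment counts scale with ``n_exons`` so reduced-scale runs keep
    roughly the same aberrant genome fraction as the 20k-exon default.
    """
    scale = n_exons / DEFAULT_N_EXONS
    n_seg = max(4, round(25 * scale))
    per_cluster = max(3, round(12 * scale))
    if name == "homogeneous_sweep":
        return [
            homogeneous_mixture(
                p, n_exons=n_exons, seed=seed + i, n_segments=n_seg, **noise
            )
            for i, p in enumerate(np.round(np.arange(0.1, 0.91, 0.1), 2))
        ]
    if name in ("two_clone", "three_clone", "four_clone"):
        k = {"two_clone": 2, "three_clone": 3, "four_clone": 4}[name]
        return [
            multi_clone_mixture(
                k, n_exons=n_exons, seed=seed,
                segments_per_cluster=per_cluster, **noise,
            )
        ]
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def write_sample(outdir, spec: MixtureSpec, truth: TruthTable,
                 exon_table: pd.DataFrame, snp_table: pd.DataFrame):
    """Write the caller inputs plus truth tables and the mixture YAML."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    exon_table.to_csv(outdir / "exons.tsv", sep="\t", index=False,
                      columns=EXON_COLUMNS)
    snp_table.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    truth.exons.to_csv(outdir / "truth_exons.tsv", sep="\t", index=False)
    clusters = pd.DataFrame(
        {
            "cluster": np.arange(1, len(truth.cluster_beta) + 1),
            "cellularity": truth.cluster_beta,
            "carriers": [",".join(sorted(cs)) for cs in truth.carrier_sets],
        }
    )
    clusters.to_csv(outdir / "truth_clusters.tsv", sep="\t", index=False)
    (outdir / "mixture.yaml").write_text(
        spec.to_yaml() + f"purity: {truth.purity}\n"
    )
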