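# Methods

`exoclone` calls clonal and subclonal somatic copy-number aberrations (CNAs)
from paired tumor/normal whole-exome sequencing, and estimates the
cellularity of each clonal cluster, the number of clusters, and tumor
purity. This note documents the model, the estimation procedure, the
synthetic-data generator, and the numerical and design choices a
maintainer would want to know about.

## Observations

Two per-exon tracks are derived from the inputs:

* **LCR** (log read-count ratio). Exon read counts are sample-normalized
  (divided by their sample totals), their ratio is GC-corrected by the
  median-ratio method — each exon's ratio is multiplied by
  (global median) / (median of its 1%-wide GC bin), bins with fewer than
  20 exons falling back to factor 1 — and the log2 of the corrected ratio
  is taken. Exons with normal coverage below `min_normal_depth`
  (default 10) are dropped before analysis and reported. LCR values and
  their model means are floored at −6 so that fully deleted segments stay
  finite.
* **MAF** (major-allele frequency). Per germline heterozygous SNP the
  B-allele frequency b = b_depth/total_depth is folded to max(b, 1−b);
  per exon the median over its SNPs is taken (1-based SNP position p
  belongs to 0-based half-open exon [s, e) iff s < p ≤ e). Exons without
  SNPs have missing MAF and contribute only the LCR factor to the
  likelihood — the standard missing-observation treatment in an HMM.

## Model

The hidden state of each exon is a pair (c, k): an aberration state c from
a fixed 12-row alphabet (total copy number 0–5 with every folded
major-allele configuration; mirrored genotypes such as AAB/ABB share one
state because folding makes them indistinguishable) and a clonal cluster
k ∈ {1..K} with cellularity β_k ∈ (0, 1]. With n_s = 2 and μ_s = 0.5 for
the normal genome, n_c the state's total copies and μ_c its major-allele
fraction (the n_c·μ_c product is 0 for the homozygous deletion):

    y_ck = n_s (1 − β_k) + n_c β_k
    z_ck = n_s μ_s (1 − β_k) + n_c μ_c β_k
    μ_l  = log2(y_ck / 2) + o          μ_m = z_ck / y_ck

where o is a global baseline shift absorbing tumor aneuploidy. Both
signals have Student's-t emission densities (scales σ_l, σ_m; degrees of
freedom ν_l, ν_m) so isolated outlier exons do not drag segment calls.

**Folded MAF emission.** The MAF statistic is folded at 0.5, so its
sampling density is not symmetric around μ_m. Three corrections are
applied:

1. the emission density is the *reflected* t, f(m; μ) + f(1−m; μ), the
   proper likelihood of a folded observation;
2. the emission location is the population median of |N(δ, s_i)| + 0.5
   with δ = μ_m − 0.5 and s_i = 0.5/√(mean SNP depth of the exon) — i.e.
   0.5 + s_i·x(δ/s_i), where x(r) solves Φ(x−r) + Φ(x+r) = 3/2
   (x(0) = 0.6745, x(r) → r). This accounts for the fact that folding
   pushes a copy-neutral exon's MAF above 0.5 by about 0.67 s_i;
3. the emission scale is per-exon, σ_m/√(n_snps): the exon MAF is a
   median over its SNPs, so multi-SNP exons carry proportionally sharper
   evidence. σ_m is thus the scale of a single-SNP exon.

Without the first two corrections the EM reproducibly preferred a
baseline-shifted solution that relabels the whole neutral genome as a weak
balanced gain (its μ_m matches the fold-biased data center better than an
uncorrected 0.5), collapsing specificity. With them the neutral state sits
exactly at the folded data's center and the aliasing dissolves.

**Depth-aware LCR scale.** Analogously, the LCR emission scale is
σ_l times a per-exon factor derived from read depth: the counting part of
the log-ratio variance is ≈ 1/t + 1/n; the shared remainder
(overdispersion, capture noise) is estimated robustly at preprocessing as
the excess of the observed LCR variance over the median counting term.
Factors are normalized to median 1 (clipped to [0.5, 3]), so σ_l keeps its
meaning for a typical exon.

**Composite space and transitions.** The copy-neutral state's emission
does not depend on k, so it is pinned to a single representative and the
composite space has (C−1)K + 1 states; this removes a K-fold label
symmetry. Transitions factorize into an aberration chain and a cluster
chain with self-transition probabilities ρ_c and ρ_k (both re-estimated).
Of the aberration chain's switching mass, a fixed share of 0.5 returns to
copy-neutral and the rest spreads uniformly: aberrant segments sit on a
neutral background, and this reversion preference also breaks the
ploidy-aliasing tie ("one copy gained in a pure tumor" vs "two copies
gained in a half-normal sample") in neutral-dominated genomes. Leaving the
pinned neutral state, the cluster chain re-enters uniformly (no cluster
memory across neutral stretches). Chromosomes are independent chains
restarting from the initial distribution π.

## Estimation

For fixed K, parameters θ = (π, ρ_c, ρ_k, β_1:K, o, σ_l, ν_l, σ_m, ν_m)
are fitted by EM:

* **E-step:** scaled forward–backward over the composite space (numba
  kernel, numpy fallback), yielding posteriors γ, expected transition
  counts, and the observed-data log-likelihood.
* **M-step:** the continuous block (β, o, σ_l, ν_l, σ_m, ν_m) is updated
  by bounded L-BFGS-B with analytic gradients of the expected complete-data
  log-likelihood (a few inner iterations per EM step — a generalized EM);
  any step that fails to improve the auxiliary is rejected, so the
  log-likelihood never decreases. π is the mean chain-start posterior;
  ρ_c, ρ_k are expected same-label transition fractions (the cluster chain
  counts only transitions between non-neutral states). β is kept sorted
  by relabeling clusters after each update.

Bounds: β ∈ [0.01, 1], o ∈ [−2.5, 0.5], σ_l ∈ [0.01, 2],
σ_m ∈ [0.005, 0.3], ν ∈ [2.1, 30] (initial 5; the upper bound avoids the
flat ridge toward the Gaussian limit), ρ ∈ [0.95, 1−1e−7]. Convergence:
relative log-likelihood change < 1e-5 (default), max 200 iterations.

**Grid search.** Starting points combine baseline shifts
o ∈ {0, −0.58, −1} (diploid, triploid, tetraploid) with cellularity seed
vectors (equispaced, plus a coarse one-cluster prescan seed at the diploid
baseline) and, for K > 1, warm starts extending the selected K−1 solution
by one new β inserted at each sufficiently wide gap. The baseline shift is
a global sample property, so it is settled at K = 1; higher K searches
only around the selected baseline. Every start is burned in for a few EM
iterations and the top two by log-likelihood are run to convergence (early
ranks are unreliable when basins converge at different speeds). This
short-run triage is what makes the multi-start search affordable at exome
scale.

**Model selection.** K starts at 1 and increases until the BIC stops
decreasing, a cluster comes back essentially unoccupied (< 50 expected
exons — treated as non-improving), or K = 10. The BIC penalty is
split-resolution: the 8 per-observation parameters (β_1:K collectively add
one each, plus o, σ_l, ν_l, σ_m, ν_m, ρ_c, ρ_k) are priced at
log(n_obs) with n_obs = #LCR + #non-missing MAF observations, while the
(C−1)K free initial-distribution entries are priced at log(#chromosome
chains): π is informed only by the 22 chain starts, and pricing it at
log(n_obs) (≈115 nats per added cluster) made the loop reject clearly
occupied true clusters while adding nothing to the rejection of vacuous
ones (which fail on occupancy or near-zero likelihood gain anyway). Under
the split penalty a new cluster must improve the log-likelihood by ≈22
nats at desk scale.

## Outputs

Per-exon maximum-posterior calls are merged into segments (runs of equal
(state, cluster) within a chromosome; ties in the argmax resolve toward
copy-neutral, then lower state id, then lower cluster). Each segment gets
a **reliability score**: the geometric mean over its exons of the
posterior mass on the called composite state — 1 exactly when every
posterior is one-hot, monotone decreasing in emission noise. (The score is
this package's own definition; it is a bounded [0, 1] summary of the same
posterior evidence a caller has available.) **Tumor purity** is the
cellularity of the largest occupied cluster: clonal events are carried by
every tumor cell, so max β is the tumor-cell fraction. If no aberrant
segment is called, purity is reported as undetermined rather than 0.

## Synthetic data

The generator emulates the genome-mixing construction used to benchmark
subclonal CNA callers, at the count level rather than by read resampling:
tumor genomes t1, t2, … carry segment-level (total, major) copy numbers;
the sample mixes them with a normal genome at fixed proportions; events
sharing a carrier subset form one cluster whose cellularity is the summed
carrier proportion; purity is 1 − normal proportion. Defaults (chosen
once, as the stated experimental world):

* 20,000 exons on 22 chromosomes, exon length 60–300 bp, GC ~ N(0.45, 0.1)
  clipped to [0.2, 0.8];
* mean depth 100× (scaled by exon length), negative-binomial counts with
  size 50 — WES depth is overdispersed relative to Poisson;
* multiplicative GC bias exp(a·(gc − 0.5)) with a = 1.5 for tumor and
  0.75 for normal — unequal strengths so the ratio retains a GC trend
  (raw |corr(LCR, GC)| ≈ 0.3) and the correction does real work;
* Poisson(2) heterozygous SNPs per exon; SNP depth Poisson(100·y/2);
  B-allele counts binomial with the mixture-effective B fraction, the B
  allele assigned to the major/minor haplotype uniformly per SNP;
* aberrant segment lengths log-uniform between 25 and 500 exons (focal to
  arm-scale, matching the broad-event character of real tumor genomes),
  homozygous deletions always focal (8–25 exons); the event palette is
  dominated by one-copy losses/gains with copy-neutral LOH and higher
  gains at lower weight.

Presets: `homogeneous_sweep` (one clone, purities 0.1–0.9),
`two_clone`/`three_clone`/`four_clone` (cluster cellularities separated by
≥ 0.1; the four-clone design mixes t1..t4 + n at 0.3/0.15/0.1/0.15/0.3,
giving clusters at 0.15/0.25/0.4/0.7 and purity 0.7). Segment counts scale
with the exon count so reduced-scale runs keep the same aberrant fraction.

**What the generator does not emulate:** capture-efficiency variation
beyond GC and length, mapping artifacts, germline CNVs, contamination of
the normal, position-dependent transition rates, or multiple tumor
genotypes at one locus (rejected with an error). A green test on this
generator establishes that the estimator recovers the generative model's
own world at realistic noise — not performance on real tumors.

## Numerical notes and degenerate inputs

* Forward–backward is per-position rescaled; emissions are max-shifted in
  log space before exponentiation, so any finite input yields finite
  posteriors (tested at emission log-densities near −800).
* The t log-density is computed via `gammaln`; the folded density via
  `logaddexp` of the two branches.
* The homozygous deletion at β = 1 has y = 0: its LCR mean is the −6
  floor and its MAF mean is defined as 0.5 (only normal-cell reads
  remain); gradients through the clipped/degenerate branches are zeroed.
* Zero-coverage and low-coverage exons are excluded up front; an all-zero
  normal sample is a fatal input error.
* Collided cluster cellularities after an M-step are separated by 1e-4
  (sorted order preserved); clusters that lose essentially all posterior
  occupancy are flagged and penalize model selection rather than being
  silently kept.
* Exact posterior ties decode toward copy-neutral — the conservative call.

## Known limitations

* One tumor genotype per locus; clones at equal cellularity are not
  separable (the generator flags such designs).
* Cellularities below ~0.1 produce signals comparable to the fold-bias
  scale and may be absorbed into neutral or a neighboring cluster.
* The reliability score is a posterior-concentration summary, not a
  calibrated probability.
* The two-scalar factorial transition model ignores genomic distance
  between exons.
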