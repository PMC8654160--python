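# Methods

This note documents the models, numerical choices and study conditions
behind `duosgs`, and what its synthetic-data experiments do and do not
demonstrate about real data.

## Sharing model

A case subset shares a SNP identity-by-state when the subset's non-missing
calls do not include both homozygote classes (equivalently, some allele is
carried by every member). Observed segments are maximal runs of shared
SNPs; runs never cross chromosome boundaries, and single-SNP runs are kept
(assessment renders them non-significant, and keeping them avoids an
arbitrary minimum-length cutoff). Missing genotypes are treated as
compatible with sharing by default — sparse array missingness is
non-informative and breaking runs on it would fragment real segments; a
strict mode (`missing_breaks=True`) is available.

All subsets of size ≥ 2 of the genotyped cases are assessed. The per-SNP
optimized profile takes the minimum empirical p over covering segments;
ties are broken toward the larger subset, then the longer bp span, then
lexicographic subset order, so the profile is deterministic and invariant
to segment input order.

## Null model: LD chain and gene dropping

Founder haplotypes follow a first-order Markov chain along each
chromosome: the alternate-allele frequency of the first SNP plus 2×2
transition probabilities per adjacent pair. First-order dependence is the
standard founder engine for gene-drop simulation; it captures the
adjacent-marker LD that inflates chance IBS runs while remaining exactly
samplable. Transitions are clamped to [1e-6, 1 − 1e-6]. The chain can be
fitted from a phased panel (direct pair counts) or from the study
genotypes via a composite-haplotype approximation (haplotype covariance
taken as half the genotype covariance); monomorphic conditioning SNPs fall
back to independence at the marginal frequency.

Transmission uses the Haldane (no-interference) model: crossovers are a
Poisson process on the genetic-map scale, realised as exponential
inter-event distances with haplotype-source toggling at each event. This
is distributionally identical to per-gap Bernoulli recombination at
r = 0.5(1 − exp(−2d/100)) while drawing O(events) rather than O(SNPs)
random numbers. SNP genetic positions come from linear interpolation of
the user map (constant beyond the anchors).

The pedigree is pruned to the ancestor closure of the genotyped cases
before simulation — individuals outside it cannot affect case genotypes.
The empirical p-value of an observed segment is the proportion of
replicates in which the *same subset's* sharing run contains the observed
SNP interval (a replicate counts once; containment for a larger subset
does not count, which is conservative and matches the per-subset
assessment). The production path never materialises null runs: a
replicate contains [a, b] iff the subset's indicator is true across all of
[a, b], so a single backward sweep per replicate suffices. The
`NullRunStore` path materialises runs for diagnostics and is seed-stream
identical to the fused kernel, which the tests exploit as an oracle.
Exact-zero p-values are floored at 1/n_sims so logarithms stay finite
(1e-6 at the publication-grade 1,000,000 replicates; 1e-4 at the desk
default of 10,000).

Randomness: one master seed feeds named substreams (gene-drop assessment,
perturbation, synthesis) through numpy `SeedSequence`; inside the numba
kernels an inline xoshiro256** generator (splitmix64-seeded, one stream
per founder haplotype lane) makes replicates reproducible from a single
uint64 and fast enough for millions of drops.

## Duo combination and thresholds

The duo statistic is Fisher's combination of the two profiles' p-values,
evaluated in closed form (chi-square with 4 df: p = q(1 − ln q) with
q = p1·p2) and minimised over partner pedigrees for each fixed pedigree;
ties go to the first partner in sorted id order.

Thresholds echo the observed optimization in null data. Each profile p is
replaced by a uniform draw from its Wilson 95% score interval (the Wilson
interval is used because its bounds are never negative; the draw
distribution within the interval is a modelling choice, fixed at
uniform). The duo optimization
is re-run on perturbed profiles, y = −log10 p_duo is fitted by gamma MLE
with location fixed at zero (scipy, shape k and rate σ; p ≥ 1 values are
dropped), and the Theory of Large Deviations gives the threshold: solve
μ(X) = [C + 2GX]·α(X) with α the chi-square(2k) survival function, by
doubling bracket plus Brent root-finding (the left side is eventually
strictly decreasing; relative tolerance 1e-12, residual verified ≤ 1e-8).
Back-transform: since 2σ·Y ~ chi-square(2k) when Y ~ Gamma(k, rate σ), the
solved X maps to T = 10^(−X/(2σ)). Treating σ as a *scale* instead gives
T = 10^(−Xσ/2); that reading is available via `back_transform="scale"` but
is not self-consistent with a rate parameterisation and is off by σ² in
the exponent whenever σ ≠ 1. C defaults to the number of chromosomes in
the genetic map and G is always computed from the map, never hard-coded.

μ = 0.05 defines genome-wide significant and μ = 1.0 suggestive.
Regions are maximal runs of SNPs with duo p ≤ threshold, summarised at
their most significant SNP; both contributing segments and their bp
intersection are reported (the intersection is non-empty because both
segments cover the summarising SNP). Post-hoc filters run in order:
duplicate unordered-pair findings keep the result with the smaller
p/threshold ratio (thresholds differ by fixed pedigree, so raw p would
mis-rank); regions whose two sharing subsets contain the same person
(after optional id aliasing across pedigrees) are removed; regions
overlapping a user-supplied centromere interval are removed.

## Synthetic data: what it emulates

`duosgs.synth` generates the study design end to end: a top founder
couple expanded into disjoint descent branches (spouses are new founders —
outbred), one genotyped affected case at the bottom of each branch, so
the meiosis count is the sum of branch depths and is placed inside the
requested band (default 8–23; the default configuration resolves to
4 cases × depth 4 = 16 meioses). Extra siblings pad internal couples for
file realism but are pruned before simulation.

Default study conditions, chosen once:

| quantity | value | rationale |
|---|---|---|
| desk genome | 4 chr × 2,000 SNPs | tractable Monte-Carlo at 10,000 replicates |
| chromosome length | 160 cM / 100 Mb | real autosomal mean genetic length |
| realistic genome | 22 chr × 1,000 SNPs | C = 22, G ≈ 35 Morgans as on a real array |
| marginal allele freq | U(0.1, 0.9) | common-variant array content |
| adjacent-haplotype LD | r = 0.5 (Fréchet-truncated) | dense-array adjacent correlation |
| n_sims | 10,000 (desk); 1,000,000 documented | p floor 1e-4 vs the publication-grade 1e-6 |
| planted segment | 10 Mb = 200 SNPs = 16 cM, 3 of 4 carriers | single-pedigree p at/near floor, comparable to reported segregating segments |

Planted segments copy a freshly drawn founder haplotype into one haplotype
of each carrier over the interval, so IBS sharing emerges exactly as the
detector expects, heterozygosity included, rather than forcing genotype
equality.

What passing the synthetic experiments shows: the detector, empirical
assessment, duo combination, threshold derivation and region reporting are
internally calibrated (rare significant regions under the null; planted
same-locus segments recovered as the top duo region) under the stated
generative model. What it does not show: robustness to genotyping error,
pedigree misspecification, strand/allele harmonisation, population
stratification, or array SNP-density variation — none of which the
generator emulates. Desk-scale thresholds are also granular: at
n_sims = 10,000 the profile p floor is 1e-4, which compresses the fitted
null tail relative to the million-replicate setting.

## Numerical and degenerate-input choices

* Empirical p floored at 1/n_sims; Fisher inputs must be in (0, 1].
* Gamma fitting refuses constant input (MLE diverges) and requires at
  least one p < 1.
* Wilson bounds are clipped to [0, 1]; perturbed draws to (0, 1].
* QC order is fixed: SNP call-rate filter (default ≥ 0.95) before
  individual call-rate filter (default ≥ 0.90, over surviving SNPs);
  removing every SNP or every individual is an error, and the filter is
  idempotent.
* Meioses between cases are counted as the edge weight of an exact Steiner
  tree (Dreyfus–Wagner) on a couple-contracted graph: child–couple edges
  cost 1, membership edges cost 0. Siblings → 2, first cousins → 4.
* PED allele labels are data-derived on read (at most two non-"0" labels,
  the lexicographically larger counted), so SNPs monomorphic for the
  alternate allele re-read as monomorphic reference — an inherent PED
  ambiguity, handled in round-trip tests by comparing allele letters.
* Chromosome order is numeric when labels are all integers, otherwise
  first-appearance order; bp must increase strictly within a chromosome.

## Known limitations

* First-order LD only; higher-order haplotype structure (and hence some
  long-range chance IBS) is not modelled.
* Same-subset containment is conservative when a superset's run covers the
  observed segment.
* Threshold fits pool all genome positions for a fixed pedigree (positions
  are correlated along segments; the gamma fit is a tail approximation,
  which is exactly why thresholds are derived by Large Deviations rather
  than by counting exceedances).
* Two-pedigree combination only; no meta-analysis weighting or 3+ pedigree
  combination.
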