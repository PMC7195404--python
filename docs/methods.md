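# Methods

This note documents the statistical models implemented in `hybridzone`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data generator does and does not emulate.

## Data model

All genotype data enter as genotype-likelihood triples `GL(g)` for
`g ∈ {0, 1, 2}` copies of a counted allele at a biallelic locus. Triples
are normalized to sum to one on input; every estimator is invariant to
per-triple rescaling, so nothing is lost. An all-equal triple encodes
missing data and is never dropped — estimators marginalize over it, which
means a missing observation simply contributes its prior expectation.
Loci use 1-based positions (VCF convention); feature annotations use
0-based half-open intervals (BED convention); the conversion happens in
exactly one place, the `near_feature` proximity test, whose rule is that a
locus lies "near" a feature when its 0-based position falls in
`[start − w, end + w)` with `w = 1000` bp by default.

## EM allele frequencies and AIMs

Per population and locus, the allele frequency maximizes the marginal
likelihood `Π_i Σ_g GL_i(g) HW_g(p)` with Hardy–Weinberg genotype
proportions. The EM update is the posterior-mean allele count averaged over
individuals. Defaults: tolerance 0.001 on the largest per-locus change, at
most 20 sweeps, initialization p = 0.5 for every locus (symmetric and
reproducible; at convergence the initialization is immaterial, which the
grid-search oracle test confirms). The observed-data log-likelihood is
monotone non-decreasing across sweeps and the test suite asserts this on
every run. A population whose data are entirely missing at a locus keeps
the initialization value and is flagged.

Ancestry-informative markers are the loci whose unweighted parental
mean-frequency difference is at least the threshold (default 0.3,
inclusive; 0.2 as a sensitivity setting). Means are unweighted across the
listed reference populations rather than sample-size weighted.

## Ancestry frequencies (ancient hybrids)

The target populations are past the hybrid-swarm stage: individuals have
similar genome-wide admixture proportions, but the frequency `q_l` of
parent-1-derived copies varies along the genome and is autocorrelated.
The model is a correlated beta process realized as a window-mean beta
prior: `q_l ~ Beta(ν μ_l, ν (1 − μ_l))` with `μ_l` the mean of the current
`q` over a `w`-locus window centered on `l` (truncated at chromosome
ends, `w = 3` by default). The precision ν (default 10) sets how strongly
neighbors pull on each other; ν → 0 recovers independent per-locus
beta-binomial estimation, a limit the test suite checks against the
closed-form conjugate posterior.

Gibbs sampling alternates (a) the per-individual latent count of parent-1
copies, sampled exactly by enumerating the ≤3 origin configurations with
the genotype marginalized over the GL triple, and (b) `q | z`, a beta draw
with `μ_l` held fixed within the sweep. Defaults: 10,000 iterations, 5,000
burn-in, thinning 10. Parental frequencies are treated as fixed point
estimates from the EM stage. Females contribute one allele copy at
Z-linked loci when sex is recorded; a male-only switch supports
robustness runs.

Polarity is canonicalized internally (the sampler always runs with the
higher-total-frequency pool as parent 1 and mirrors the output if the
caller's labels are reversed), which makes the label-swap symmetry
`q̂ → 1 − q̂` exact under a fixed seed rather than approximate.

Fixation summaries count loci with `q̂ ≥ 0.95` (parent-1) and
`q̂ ≤ 0.05` (parent-0), overall, per chromosome, and Z versus autosomes;
both thresholds are inclusive.

## Hybrid index and genomic clines (contemporary zone)

The hybrid index `h` of an individual maximizes
`Σ_l log Σ_g GL(g) Binom(g; 2, π_l)` with `π_l = h p1_l + (1−h) p0_l`,
solved by bounded scalar optimization on [0, 1] to 1e-6. Individuals with
no informative data are pinned at 0.5 and flagged.

Genomic clines use the quadratic-in-h form

    φ(h; α, β) = h + 2h(1−h)(α + β(2h−1)),  truncated to [0, 1],

which satisfies φ(0) = 0 and φ(1) = 1 for all parameter values, keeps
α interpretable as (twice) a shift of the cline center and β as a change
in cline width, and is exposed behind a single function so an alternative
form could be swapped in. Per AIM, each allele copy is parent-1-derived
with probability φ(h_i; α_l, β_l), the allele follows the origin's
parental frequency, and the genotype is observed through the GL triple.
Priors are independent Normal(0, 1) on α and β. Sampling is random-walk
Metropolis, alternating α and β updates, vectorized across loci (loci are
conditionally independent given h); proposal scales adapt during burn-in
toward 20–40% acceptance and are frozen afterwards. Defaults: 5 chains of
25,000 iterations, 5,000 burn-in, thinning 5; split-R̂ is reported per
locus, and loci with R̂ > 1.1 are flagged, never dropped.

Estimation is two-stage — h first, then (α, β) with h fixed — rather than
joint. This keeps the per-locus sampler exact and testable at desk scale.
The cost is that uncertainty in ĥ is not propagated: with a
genome-wide AIM panel the plug-in error is small (ĥ RMSE ≈ 0.02 in the
calibration experiments), and posterior interval coverage for (α, β) is
nominal when the generating h is supplied and stays near nominal with
estimated h when cline deviations are sparse. When a large fraction of
loci carry strong deviations, ĥ itself becomes biased and interval
coverage degrades — a known limitation of any two-stage fit.

Credible deviation classes come straight from the 95% equal-tail
intervals: directional toward parent 1 (CI(α) > 0), toward parent 0
(CI(α) < 0), restricted (CI(β) > 0). The same polarity canonicalization
as the ancestry sampler makes parent-label swaps negate α exactly under a
fixed seed.

## Permutation enrichment framework

Top-quantile sets contain `floor(qN)` loci ranked by score, ties broken
by locus order (stable sort) and logged when they cross the cutoff. The
x-fold enrichment of a statistic is observed / null-mean, with the null
built by relabeling the focal set uniformly at random over the N loci —
10,000 permutations for set-overlap tests, 1,000 for category
(Z-chromosome, near-feature) tests. P-values use the add-one estimator
`(1 + #{null ≥ obs}) / (n_perm + 1)` (lower tail for deficit tests), so
an empirical P is never exactly zero. The permutation null for a count
statistic coincides with the hypergeometric distribution, which the test
suite uses as a closed-form check on the null mean.

The consistency grid runs nine comparisons (high-α, low-α, high-β in the
zone, each against high-parent-1, high-parent-0, and near-fixation-either
ancestry in the ancient hybrids) across quantiles 10% down to 1% and
scopes all/autosomes/Z. For scoped runs the default rule rebuilds the
quantile sets within the scope and permutes within it
(`within_scope`); scoring genome-wide sets against a scope-restricted
null (`global_sets_scoped_null`) is available as a config switch, since
either reading of a scoped analysis is defensible and they answer
slightly different questions.

Chromosome-level trends are Pearson correlations of a per-chromosome
proportion against chromosome size, with the two-sided P from the t
transform on n − 2 degrees of freedom and an exclude-Z re-run supported.

## LD, F_ST, isolation by distance

LD is the Pearson correlation of posterior-mean genotype dosages between
AIM pairs within a population (inclusion rule: ≥ 20 individuals), with
each locus polarized so its counted allele is the one more common in
parent 1 — positive r then means coupling associations, the admixture
signature. Missing genotypes are excluded pairwise.

F_ST for a population pair is the ratio of averages
`mean(H_T − H_S) / mean(H_T)` with `H_S` the mean of the two
within-population expected heterozygosities `2p(1−p)` and `H_T` the
heterozygosity at the unweighted mean frequency (a sample-size-weighted
variant is available). Ratio-of-averages, not average-of-ratios.

The isolation-by-distance model is the pairwise mixed model
`logit(F_ST)_ij = b0 + b1 log d_ij + b2 τ_ij + u_i + u_j + e_ij` with
great-circle (haversine) distances, τ the same/different-taxon indicator,
and a random effect per population entering every pair it belongs to —
the device that absorbs the correlation structure of pairwise responses.
Priors: Normal(0, precision 0.001) on coefficients, Gamma(1, 0.01) on the
random-effect and residual precisions; all conditionals are conjugate, so
the fit is a plain Gibbs sampler (3 chains × 10,000, burn-in 2,000,
thinning 5 by default). Candidate models (full, geography-only,
taxon-only) are compared by `DIC = D̄ + p_D` with
`p_D = D̄ − D(posterior means)`. F_ST values are clipped to
`[1e-6, 1 − 1e-6]` before the logit.

## Window phylogenomics and f_d

Windows are consecutive runs of exactly `window_snps` loci (default
1,000) within a chromosome; trailing remainders are dropped and logged.
For five taxa there are exactly 15 unrooted binary topologies — few
enough that every window is scored against all of them, replacing
heuristic tree search with exhaustive, exact evaluation. The default
score is Fitch parsimony over biallelic sites with heterozygous calls
(0.5) treated as ambiguity sets {0, 1}; the alternative (`me_ls`) fits
nonnegative least-squares branch lengths to mean-difference distances and
scores by residual sum of squares. Ties are flagged and broken by the
lowest canonical topology id; an invariant window ties across all 15 and
is flagged uninformative. Externally inferred per-window trees can be
imported from Newick and mapped onto the same canonical ids.

Topology class tests (Z versus autosomes, candidate barrier windows)
permute topology labels across windows, 1,000 permutations, with excess or
deficit one-sided tails.

`f_d` uses within-taxon allele frequencies (0/0.5/1 for single diploid
genomes). Per site, `ABBA = (1−p1) p2 p3 (1−pO)` and
`BABA = p1 (1−p2) p3 (1−pO)`; the numerator sums ABBA − BABA and the
denominator recomputes the same sum with the donor frequency
`pD = max(p2, p3)` substituted for both p2 and p3 — the expectation under
complete introgression from the donor, making f_d an admixture
proportion. Sites missing any taxon are skipped; a zero denominator flags
the result undefined. The candidate-window test compares the mean f_d of
k candidate windows (k is a parameter; 49 by default) against random
k-window draws, lower tail, with undefined-f_d windows excluded from the
sampling pool. Taxon roles (P1, P2, P3, O) must be passed explicitly —
a quartet statement like "(P1 and P2)(H, O)" does not map uniquely onto
the role order, so guessing is refused by design.

## Synthetic data

The generator emulates, with study-like defaults: two parental gene pools
from a Balding–Nichols-style model (common ancestral frequency
π ~ U(0.05, 0.95), each parent Beta(π(1−F)/F, (1−π)(1−F)/F) with
divergence F, default 0.4); ancient hybrid populations whose two
haplotypes per individual carry two-state ancestry chains with local
stationary frequency matching a blockwise target profile `q_l` (mean
ancestry 0.65 toward parent 1, a fraction of segments pushed to q ≥ 0.95,
the Z biased further toward parent 1) and switch rates set so the mean
ancestry-block length equals the configured value (default 20 loci) at
q = 0.5; a contemporary zone with hybrid indexes Beta(0.5, 0.5) — the
U-shaped distribution of an active zone — and sparse nonzero cline
effects; GBS observation noise with Poisson read depth (default 4×, with
2–8× the realistic band) and per-read error 0.01, zero-read sites coded
missing; and five-taxon window matrices whose topology labels follow a
Markov chain along each chromosome with sites supporting the label's two
internal splits plus a configurable fraction of conflicting sites.

What it does not emulate: linked selection and realistic recombination
maps (a per-chromosome block-length parameter stands in), mutation
models or sequencing chemistry beyond a symmetric error rate, sex-ratio
and W-chromosome effects (simulated individuals are male by default,
matching male-only robustness analyses; female Z hemizygosity is modeled
in the inference, not the default simulation), and contiguous physical
coordinates (inter-locus spacings are arbitrary). Passing
parameter-recovery tests on these simulations therefore validates the
estimators under their own assumptions — it does not certify performance
under model violations real data may present (reference bias, paralogy,
batch effects).

Determinism: every stage draws from a generator seeded by the config seed
and a stage-name hash, so identical configs give byte-identical outputs
and stages are insensitive to each other's draw counts.

## Numerical choices

- GL triples are normalized on input; likelihood products are floored at
  1e-300 before logs; high-depth read likelihoods are computed in log
  space.
- The EM, hybrid-index and cline likelihoods share the same
  binomial-through-GL marginalization; no approximations beyond floating
  point.
- MCMC summary intervals are equal-tail quantiles of pooled post-burn-in
  thinned draws.
- Degenerate inputs fail loudly: all-equal scores for a quantile set,
  empty categories, zero-variance correlations and constant mixed-model
  responses raise errors rather than returning silent NaNs; undefined
  per-locus quantities (monomorphic LD pairs, zero-denominator f_d) are
  flagged and propagated as missing.

## Problem sizes used in the checks

The acceptance-level checks run at the sizes the analyses target: 1,164
AIMs with 225 Z-linked for the enrichment statistics; 200 focal cline loci
among ~700 AIMs and 200 hybrids for interval calibration; 25 individuals
at 8× for ancestry recovery; 200 windows of 1,000 sites for topology
recovery; and a 23-chromosome study preset (three parental, two ancient,
one zone population) for the end-to-end run. These sizes were chosen so
each check exercises the estimator in the regime it is designed for while
remaining a desk-scale computation.
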