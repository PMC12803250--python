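# Methods

This note documents the statistical models implemented in `admixsel`, the
choices made where the design was genuinely open, and what the synthetic
data used for validation does and does not emulate.

## 1. Per-variant selection test (`admixsel.scan`)

### Model

For one biallelic variant observed in A ancient and B present-day
populations, let x_i and N_i be the alternate-allele count and the total
number of called alleles in population i (pseudohaploid individuals
contribute one allele per site, diploid individuals two). Under the
alternative, each population has a free frequency and the maximized
log-likelihood is

    l1 = sum_i [ x_i log f_i + (N_i - x_i) log(1 - f_i) ],   f_i = x_i / N_i.

Under the null, the population frequencies are constrained by genome-wide
ancestry: f = M q, where M is the (A+B) x k row-stochastic admixture matrix
(consumed in ADMIXTURE .Q layout) and q in [0,1]^k holds the variant's
unknown frequencies in the k source populations. l0 is the same expression
maximized over q. The statistic 2(l1 - l0) is referred to chi-squared with
A+B-k degrees of freedom.

The null objective is concave in q (a concave function of f composed with a
linear map), so the box-constrained maximum is unique. It is found by
damped projected-Newton ascent with an active-set reduction at the box
faces, compiled with numba; the batch path uses a single pooled-frequency
start, while the scalar API additionally probes the box corners (useful
only when M is rank-deficient and the maximizer is a flat set). Convergence
is declared at projected-gradient norm < 1e-8 (1e-7 in the batch kernel);
frequencies inside the log are floored at 1e-12 only where a positive count
meets a boundary value, so monomorphic variants get exactly l = 0 and are
reported with statistic 0 and a `monomorphic` flag rather than dropped.

### Calibration

Binomial sampling ignores genetic drift since the populations diverged, so
raw statistics are inflated by a roughly constant factor. Two calibrations
are provided:

* genomic control (default): lambda = median(stat) / median(chi2_df);
  adjusted p-values come from chi2_df applied to stat/lambda;
* gamma fit: a maximum-likelihood gamma distribution on the statistics
  (fitted on the positive part), whose upper tail gives the p-values. This
  is the natural choice for regions that need a separately calibrated
  empirical null, such as the MHC; chi2_df is the special case
  shape = df/2, scale = 2.

Both are exposed because genome-wide rescaling and empirical-null fitting
answer slightly different questions; the pipeline defaults to genomic
control.

### Filtering, dense regions, replication

Technical artifacts private to one dataset produce isolated outliers. The
LD-companion filter therefore requires every variant at BH-FDR < 0.1 to
have at least `min_companions` (default 1) other variants within 200 kb at
r^2 > 0.5 that also pass the FDR threshold; pairs absent from the LD table
count as r^2 = 0 and are logged. Genome-wide significance is declared at
p < 5e-8 (configurable).

In SNP-dense regions each p-value is multiplied by the number of SNPs in
its tiling 50 kb window (clipped at 1), and the region-wide threshold is
0.05 divided by the number of non-empty windows.

Cross-region replication is tested at two levels: the lead variant's
p-value in the other region against 0.05/n_leads, and the minimum p within
1 Mb of the lead against 0.05/(SNPs in the window).

## 2. Polygenic test (`admixsel.polygenic`)

GWAS associations are reduced to approximately independent leads by greedy
clumping (smallest p first; absorb unclaimed variants within 200 kb at
r^2 > 0.4; inclusion threshold p < 1e-8, relaxable to 1e-6 for
under-powered GWAS). For each population, x_i sums the trait-increasing
allele over all leads (direction +1 contributes the effect-allele count,
-1 its complement) and N_i the non-missing called alleles; only effect
directions are used, never effect sizes, and variants missing at random
simply contribute nothing.

The pooled (x, N) go through the same admixture-constrained LRT, but the
chi-squared null does not apply to sums over correlated variants. Instead
each lead's direction is re-drawn as an independent Rademacher sign
(1,000,000 times by default) and x recounted with frequencies untouched;
p = (1 + #{null >= obs}) / (n_perm + 1), never exactly 0. Each lead's sign
stream is seeded from (seed, hash of the lead id), which makes the p-value
exactly invariant to lead order and to flipping every direction. An
alternative null that permutes the observed multiset of directions across
leads is available (`null_mode="permute"`); the independent-flip null is
the default.

Small p indicates directional selection (counts too far from the admixture
expectation), large p stabilizing selection (too close). With N traits the
two-sided Bonferroni calls are p < 0.025/N (directional) and
p > 1 - 0.025/N (stabilizing); the upper cutoff is deliberately the
symmetric mirror of the lower one.

## 3. Wright-Fisher machinery and power (`admixsel.wfsim`)

One generation of directional selection maps f to psel = f(1+s)/(1+fs);
the next generation's 2Ne alleles are Binomial(2Ne, psel). Defaults:
Ne = 10,000, with 2Ne as the binomial denominator.

The power grid plants, for each (s, generations) cell, n selected variants
(default 1000, MAF > 0.05 in the focal population) whose focal-population
frequency is replaced by a simulated endpoint, holds all other populations
at their baseline counts, and reruns the full scan with genomic control
estimated from an accompanying null background (5000 variants by default)
and the 5e-8 threshold. Two deliberate choices:

* lambda is estimated from the null background rather than the pooled set:
  at genome scale selected variants are a vanishing fraction of the median,
  but at validation scale they would contaminate it;
* all cells share their underlying uniform random numbers, with binomial
  transitions drawn by inverse CDF, so endpoints are pathwise monotone in s
  and horizons are nested prefixes of one trajectory per variant. Power
  estimates are therefore exactly coupled across the grid and monotonicity
  checks are not at the mercy of independent Monte-Carlo noise.

Initial frequencies come from a pluggable sampler, Uniform(0.05, 0.95) by
default; absolute power values therefore characterize the synthetic region,
not any particular real dataset.

### Synthetic data

`simulate_scan_dataset` draws source frequencies independently per source,
forms f = Mq, applies 10 generations of per-population drift at Ne = 10,000
(mild inflation, lambda ~ 1.05 at 100 alleles/population — the regime
genomic control is meant to absorb), and samples binomial counts.
`simulate_admixed_dataset` evolves K ancestry components independently
(optionally with a time- and ancestry-varying selection schedule), draws
individual loadings from a Dirichlet centred on each population's target
mixture (concentration 50, configurable), and samples each haploid allele
by ancestry-then-frequency; the realized mean loadings form the admixture
matrix, exactly as an ADMIXTURE run would be consumed.

What the generators do not emulate: linkage between variants (LD tables
for filter tests are constructed explicitly), ascertainment of the variant
panel, sequencing error, reference bias, and non-equilibrium demography
beyond the drift/admixture structure described. Passing validation on this
synthetic data shows the statistics are correct under their own model, not
that the model captures every feature of real ancient-DNA compilations.

## 4. Time-series inference (`admixsel.timeseries`)

### Model

Time t counts generations before present. K ancestry components evolve as
independent Wright-Fisher populations of constant haploid size 2N (N is a
single known config value):

    F_{t-1,k} | f_t, s_t ~ Binomial(2N, f'(f_{t,k}, s_{t,k})),

with f' the post-mating frequency f(1+s)/(1+fs) — the standard haploid
selection map; a different mating model (e.g. diploid with dominance) would
be a one-line swap of `post_mating_frequency`. Each dated haploid sample
carries ancestry loadings q_ti (its genome-wide mixture); its latent copy
ancestry is z_ti ~ Categorical(q_ti) and a_ti | z_ti = k ~ Bernoulli(f_tk).
Diploid individuals enter as two haploid samples sharing loadings.

### Particle filter

The posterior over frequency paths is approximated by P weighted atoms on
{0..2N}^K (default P = 1000). The filter sweeps from the oldest time T to
the present, starting from atoms uniform on the grid (a flat prior on the
oldest frequency), transitioning every atom through the binomial kernel and
multiplying weights by the data likelihood at each time. The emission used
by the standalone filter marginalizes the latent ancestry over the
loadings, sum_k q_tik f_tk^a (1-f_tk)^(1-a) — the only emission consistent
with the Bernoulli observation model; inside the Gibbs sampler the emission
conditions on the current z draw. Systematic resampling triggers when
ESS = 1/sum(w^2) falls below P/2; parent indices are stored at every step
so a full trajectory can be drawn by sampling a terminal particle by weight
and tracing its genealogy. The per-step normalizers accumulate an unbiased
marginal-likelihood estimate, used by the `profile_smoothing` utility.

### Gibbs sampler

Cycles f | a,Z,s (filter + backward trace), Z | a,f,Q (independent
categoricals), s | f (MALA), and optionally (alpha, beta) | s. The log
conditional for s_tk combines the binomial transition term (skipped where
f_tk is 0 or 1, where it carries no information) with the Gaussian
smoothing prior

    -alpha/2 sum_{t,k}(s_tk - s_{t-1,k})^2  -  beta/2 sum_t sum_{i!=j}(s_ti - s_tj)^2.

As alpha grows the surface shrinks to a time-constant value; as beta grows
the ancestries shrink to a common trajectory. Fixed-hyperparameter mode
uses alpha = 2.0 and beta = alpha/100; fully-Bayesian mode places
Gamma(a, b) hyperpriors (all hyperprior parameters default to 1) and uses
the conjugate updates

    alpha | s ~ Gamma(a_a + TK/2,        b_a + (1/2) sum (s_tk - s_{t-1,k})^2)
    beta  | s ~ Gamma(a_b + TK(K-1)/2,   b_b + (1/2) sum_{i!=j} (s_ti - s_tj)^2)

in the rate convention (with K = 1 the beta update is its prior).

MALA updates are per-coordinate with a red-black (even/odd time) schedule
per ancestry, so each block is evaluated against fixed neighbours and the
whole sweep vectorizes; the step size is adapted during burn-in toward an
acceptance rate of 0.57, and proposals below s = -0.999 are rejected to
keep 1 + fs positive. Because a filter pass is far more expensive than a
sweep, each Gibbs iteration performs 10 MALA sweeps (`s_sweeps`); with a
single sweep the s-chain's per-iteration innovation is much smaller than
its conditional width and mixing is needlessly slow.

Summaries are per-(t, k) posterior medians with 5-95% quantile bands of the
retained draws. Identical seeds give bit-identical draws.

### Numerical and design notes

* The frequency trajectories live on the 1/(2N) grid by construction;
  absorbing states stay absorbed under the prior dynamics.
* The backward-traced trajectory is a draw from the particle approximation
  of the smoothing distribution; no conditional reference trajectory is
  kept between iterations, so the sampler is exact only in the large-P
  limit. The filter-vs-exact-HMM check (total variation < 1e-2 at
  P = 1e5 on a 21-state chain) quantifies the approximation directly.
* With the default alpha = 2.0 the smoothing prior is weak (increment
  standard deviation ~0.7), so per-time marginals for s are wide wherever
  a single generation's transition is the only information, and the
  posterior inherits the right-skew of the likelihood in s (the map
  f(1+s)/(1+fs) approaches 1 slowly as s grows). Validation therefore
  checks band coverage and zero-exclusion rates, not point-estimate error.
* If all particle weights vanish at a time point (data impossible under
  every atom), the filter raises a diagnostic error; inside the Gibbs loop
  the pass is retried up to three times with fresh transitions before
  giving up.

### Validation scales

The parameter-recovery experiments run 20 replicate datasets per condition
at 2N = 2000, T = 50 generations, 25 haploid samples per generation,
P = 300 particles and 700 Gibbs iterations (260 burn-in, thinning 2) —
sizes chosen so the full suite completes on a single desktop core while
leaving the acceptance thresholds comfortable margins. The power grid runs
250 planted variants per cell over s in {0, 0.02, 0.05, 0.1} and
g in {0, 10, 20, 50, 100} against a 3000-variant null background.

## 5. Pipelines (`admixsel.pipeline`, CLI)

Every run is a pure function of (inputs, config, seeds); a JSON manifest
records the command, configuration, seeds, SHA-256 digests of all file
inputs, library versions and a timestamp. Output tables are deterministic,
so reruns under a fixed manifest are byte-identical. Each filter stage logs
the count of surviving variants at INFO. Exit codes: 0 success,
2 validation error, 3 numerical failure.
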