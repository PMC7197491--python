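# Methods

`tempopg` implements the statistical machinery for temporal
population-genomic surveys of a closed population: a panel of L
biallelic sites is genotyped in samples of n individuals taken at
successive time points, and the questions are (i) whether the observed
allele-frequency wander is consistent with pure genetic drift, (ii) how
strong directional and fluctuating selection are at a site, and (iii)
what the short-term effective population size N_e is. This note records
the models, the estimators, the numerical conventions, and the known
limits of each — including exactly what the bundled simulation studies
do and do not demonstrate.

## Model and sampling assumptions

All estimators assume a closed, unstructured population of constant
effective size, biallelic sites, equally spaced samples (a survey whose
samples are D generations apart is carried with D as metadata and the
results rescaled: s/D, sigma_s^2/D^2, N_e*D), genotypes called without
error (all sampling error comes from the n individuals genotyped), and
sites far enough apart to be treated as unlinked. When sites are
linked, L overstates the degrees of freedom, so every multi-site
standard error here is a lower bound; the drift test accepts an
`effective_L` override for that case. Missing cells are not supported:
a site must be observed at every time point it contributes to.

## Drift consistency tests

Under drift the true per-interval changes are uncorrelated, but
estimated changes sharing a sampling point are negatively correlated
(-p(1-p)/(2n)), so the pairings avoid adjacent intervals:

* **Scheme 1** pairs every change with the change two intervals later
  (m = T-2 pairs from T intervals). Sampling points are reused, which
  leaves a small negative expectation
  E = -p0(1-p0) (T-4) / [2 (T-3)(T-2) N_e]
  (exact form: the (T-4) factor becomes the sum of heterozygosity-decay
  powers lambda^i, lambda = 1 - 1/(2 N_e)). The result object reports
  this expectation when an N_e is supplied and standardizes against it.
* **Scheme 2** uses fully disjoint pairs (m = (T+1)/4), unbiased but
  needing ~4x longer surveys; its expected null SE at one site is
  p0(1-p0)/(n sqrt(m-1)), and sqrt(2) ~ 1.4x the scheme-1 SE at equal
  survey length. When T+1 is not divisible by 4 the maximal prefix is
  used with a warning rather than an error, so the statistic remains
  usable on real series.
* **Genome-wide test**: for two intervals sharing no sampling point,
  each site's change is standardized by its two-sample binomial SD
  evaluated at the interval-mean frequency; the across-site sample
  covariance of the two standardized changes has null expectation 0 and
  variance 1/L. The test compares |cov|*sqrt(L) with the standard
  normal; the 5% critical value is therefore 1.96/sqrt(L) (the SD of a
  variance-1/L statistic). For small L the package also provides the
  four-moment-exact heavy-tailed null density (variance L-1), evaluated
  in log space via log-gamma so it is stable at large L.

Sites whose standardization is undefined (interval mean frequency 0 or
1) are dropped and L reduced; the covariance uses the L-1 denominator
throughout.

## Selection: mean coefficient

Additive (genic) selection makes the logit zeta = ln[(1-p)/p] decline
linearly at rate mu_s, so s_hat is minus the OLS slope of zeta_hat on
generation (plain, unweighted least squares; positive s_hat means the
focal allele is favored). The closed-form sampling variance is

    var(s_hat) = [6/((T-1)(T+1))] [1/(T n p0 (1-p0)) + sigma_s^2].

Convention: this expression is the exact OLS slope variance under
binomial sampling noise when **T counts the equally spaced samples**
entering the regression (Sum (t - tbar)^2 = T(T^2-1)/12 for T points);
the package's validation studies and `fit_mu_s.se_pred` use that
convention. At T >= 30 the distinction from counting intervals is
within 5% on the SD scale.

Boundary frequencies (p_hat = 0 or 1) make zeta undefined; such sites
are dropped and reported, never smoothed with pseudo-counts, which
would bias the slope. The estimator is unbiased only while selection
dominates drift (N_e s p0 > 1); below that threshold the estimate is
systematically low — the leading term is the Jensen curvature of the
logit under drift noise, about zeta''(p0) p0(1-p0)/(4 N_e) per
generation — and no correction is attempted because it would require
the very N_e one is usually trying to estimate.

Design calculators built on the same formula: minimum detectable
coefficient (T^3 n = 24/[p0(1-p0) mu_s^2] at the two-sided 5% level,
i.e. 96/mu_s^2 at p0 = 0.5), the SE inflation of sparse surveys (T'
samples D generations apart: the leading variance term is evaluated at
T' and divided by D^2, since the slope is per true generation), and the
two-point (endpoints-only) estimator with variance
[1/(T^2 n)][1/(p0 q0) + 1/(pT qT)], whose SE is at least sqrt(T/6)
worse than the full survey.

## Selection: temporal variance

Single-generation estimates s_i = zeta_i - zeta_{i+1} decompose into
the true coefficient plus sampling error, so

    sigma_s^2_hat = Var(s_hat) - Var(e),

with Var(s_hat) the ddof-1 variance over the tau = T/2 non-overlapping
intervals (0,1),(2,3),... (no averaging over alternative phasings), and
Var(e) the closed-form average sampling variance using all T intervals
and the -phi covariance of adjacent estimates:

    Var(e) = (1/T) [phi_0 + phi_T + (2T/(T-1)) sum_{t=1}^{T-1} phi_t],
    phi_t = 1/(ploidy * n_t * p_hat_t (1 - p_hat_t)).

Negative differences are returned as-is with a flag — clipping would
bias pooled averages. Odd T drops the final sample with a warning. The
estimator's per-site sampling CV exceeds 1 even in favorable designs
(n = 1000, T = 100), the central practical limitation: averaging over
hundreds to millions of sites is required for a usable pooled estimate.

## Effective population size

The temporal F statistic F = (p_j - p_k)^2 / [pbar(1-pbar)], corrected
for the two binomial sampling terms 1/(2n) (1/n for haploids), has
expectation ~ t/(2 N_e) for t << 2 N_e. phi is averaged across sites
*before* the ratio N_e_hat = t/(2 phi_bar) — averaging per-site ratios
would inherit the wild sampling variation of individual F values, which
are chi-square-shaped (var/mean^2 ~ 2). Sites fixed at both samples are
excluded and counted. A non-positive phi_bar yields a flagged undefined
result, not a negative N_e.

Sampling variance: the full form
(8 N_e^4 / L)[1/(2N_e)^2 + 1/(t N n) + 1/(t n)^2] (N = census breeders)
collapses to (2/L)(2 N_e^2/(t n))^2 only when t*n << 2 N_e. The
bundled validation run (N_e = 10^3, t = 5, n = 500, L = 10^4) sits at
t*n ~ 2 N_e, where the reduced form underestimates the true sampling
variance about five-fold while the full form (with N = N_e, as
simulated) is accurate to within Monte-Carlo error; both are reported
so the comparison is explicit. Design inversions report both the exact
critical t*n = 2 N_e sqrt(2/L)/CV and the rounded rule of thumb
0.035 t n sqrt(L) > N_e.

Multi-interval schemes on six samples (endpoints; halves = two
two-generation analyses on samples (0,2),(3,5); thirds = three
single-generation analyses) are provided with the pooled mean of the
per-episode estimates. The idealized expectation that their sampling
SDs scale as 1:1.4:1.7 assumes gap-free subdivision of the span; with
the actual gapped layouts the simulated ratios are closer to
1:1.2:1.6 at the validation parameters, and the pooled means of the
shorter-episode schemes carry a small upward Jensen bias (each episode
estimate is a reciprocal of a noisier mean). Short-episode schemes
buy no precision; the endpoints contrast holds most of the information.

## Wright-Fisher simulator

Per generation: s_t is constant mu_s or Gaussian(mu_s, sigma_s2) with
no autocorrelation (the distribution of a fluctuating coefficient is
otherwise unconstrained; Gaussian is the assumption, truncated at
-0.99 to keep fitness positive, with truncations counted and warned
above a 1e-6 fraction); the deterministic update p* = p(1+s)/(1+ps)
(genic selection — the zeta decrement is then exactly ln(1+s), making
regression recovery exact on noiseless paths); then drift as binomial
sampling of ploidy*N_e gene copies (census N = N_e unless the variance
formulas are queried with a separate N). Individual sampling draws
binomial(ploidy*n) copies at each retained time point. Absorbing
states persist automatically. Panels draw all sites vectorized from a
single seeded PCG64 stream in (generation, site-block) order: a fixed
(config, seed) pair reproduces byte-identical output.

What the generator emulates: unlinked sites, constant N_e, constant or
white-noise selection, clean genotypes. What it does not: linkage and
hitchhiking, dominance, migration, spatial structure, sequencing
error, variable census size. Passing validation therefore shows the
estimators are correct under their own assumptions — not that those
assumptions hold in any particular real survey, where linkage alone
makes every multi-site SE here a lower bound.

## Validation studies and problem sizes

The canned studies in `run_experiment` re-create the calibration
analyses at replication counts sized for minutes on one CPU (the
original analyses used 10^6-10^7 replicates; Monte-Carlo tolerances in
the tests are widened accordingly):

* `cov_null` — 2,000 neutral four-sample panels (L = 10^4, N_e = 10^6,
  n = 100, p0 ~ U(0.1, 0.9)); the 5% test rejects 4-6% of the time and
  the statistic's null variance is 1/L within 10%.
* `fig2_sd` / `fig2_bias` — 10^4 replicate regressions per condition;
  MC SD within 10% of the closed form for s in {1e-3, 1e-2}, p0 in
  {0.1, 0.5}, T in {10, 30}; unbiased when N_e s p0 > 1, significantly
  low at (N_e = 1e4, s = 1e-4, p0 = 0.1, T = 41).
* `fig3_svar` — 10^4 quasi-neutral replicates (mu_s = 0, sigma_s^2 =
  1e-3, n = 1000, T = 100, N_e = 1e8): mean recovery within 15% with a
  small downward bias, sampling CV > 1.
* `ne_validation` / `ne_multi_interval` — 300/400 replicate panels at
  (N_e = 1e3, t = 5, n = 500, L = 1e4): mean N_e within 10%; MC
  variance matches the full variance form (see above) within 30%.

Numerical choices: covariances use the unbiased m/(m-1) form; all
closed-form SEs use the harmonic-mean sample size and warn when sizes
vary by more than 10%; rounded "design" outputs are reported at two
significant figures alongside raw values; JSON floats are serialized
at 10 significant digits.
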