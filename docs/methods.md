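# Methods

## The scientific setting

Monozygotic twins who share a placenta can exchange blood cells in utero. If
one twin's hematopoietic cells acquire a driver mutation before birth, the
malignant clone can engraft in the co-twin, and decades later both twins
present with the same clonal blood cancer. The computational question this
package answers: given tumor/germline whole-genome variant calls from both
adult twins, did the malignant clones share a common ancestor, and when did
that most recent common ancestor (MRCA) exist?

The logic has three steps. Somatic variants found in both twins' tumors but
in neither germline must predate the clone's split between the twins.
Cancer-cell-fraction (CCF) clustering plus the pigeonhole principle
identifies which mutations sit on the single cell lineage ancestral to the
malignant clone (as opposed to unrelated hematopoietic background). The size
of the shared set, compared with each twin's private set, then dates the
MRCA under a constant-rate mutation clock.

## Mutation clock and timing model

C>T substitutions at CpG dinucleotides (N[C>T]pG) arise largely from
spontaneous deamination of 5-methylcytosine and accumulate roughly linearly
with age, making them the preferred clock; an all-clonal-substitutions
variant of the model is also provided. Counts are modeled as Poisson with
rate = (mutations/genome/year) x (elapsed interval):

- shared count `s ~ Poisson(lambda * t_mrca)`;
- twin-unique counts `n_i ~ Poisson(lambda * E_i)`.

Two exposure conventions are implemented because the natural-language model
description (mutations accrue up to sampling) and the declared parameter
set (latent interval endpoints `t_1`, `t_2` with uniform priors) disagree:

- `latent_endpoint` (default): `E_i = t_i - t_mrca`,
  `t_i ~ Uniform(t_mrca, T_i)`. Matches the declared parameters; treats the
  observed bulk counts as having arisen over an unknown sub-interval (e.g.
  because the sampled clone expanded before sampling).
- `fixed_endpoint`: `E_i = T_i - t_mrca`. The generative convention of the
  synthetic-data module, and the exactly-specified model for recovery
  studies.

Both are exposed and can be compared by Bayes factor (`compare_models`).

Priors: `lambda ~ Exponential(mean mu)` with `mu = 1.71` clock mutations per
genome per year (or 10.6 for all clonal substitutions), both cohort-derived
constants; an optional hard upper truncation of the rate is supported but
its cohort-derived value is not built in — it must be supplied in config.
`t_mrca ~ Uniform(0, U)` with `U` = earliest presentation age (37 y) plus
gestation. All times are years from fertilization: calendar ages convert as
`years + months/12 + days/365.25`, and sampling/presentation ages add a
fixed 40-week gestation (40*7/365.25 = 0.7666 y). The two case sampling
times are T_A = 40.754 y and T_B = 39.221 y from fertilization.

### Inference and its oracle

The posterior is at most 4-dimensional, which permits an unusual luxury: a
deterministic quadrature oracle (`posterior_quadrature`). The latent
endpoints integrate in closed form,

    int_{t_m}^{T} Pois(n; lambda (t - t_m)) dt = P(n+1, lambda (T - t_m)) / lambda,

with `P` the regularized lower incomplete gamma, so only a 2-D grid over
`(lambda, t_mrca)` is needed. A coarse log-spaced scan locates the window
holding all density above `exp(-46)` of the peak; a dense trapezoid grid
(defaults 1200 x 1500, verified by Richardson refinement in the tests) then
gives means, equal-tailed intervals and the normalizing constant (= log
marginal likelihood). The heavy right tail of `lambda` in the
all-clonal/latent configuration is the resolution-limiting feature and set
the default grid size.

The production sampler is a partially collapsed Gibbs sampler — every full
conditional of this model is directly sampleable, so no step-size tuning is
needed and mixing is near-iid:

- `lambda | t_mrca` with the latent endpoints integrated out analytically
  (grid inversion in log-lambda; the collapse removes the strong
  lambda-exposure coupling that throttles uncollapsed sweeps);
- exposures `t_i - t_mrca | lambda, t_mrca`: Gamma(n_i+1, lambda) truncated
  to (0, T_i - t_mrca), completing an exact joint draw of
  (lambda, exposures) given t_mrca;
- `t_mrca | lambda, t_1, t_2`: a 1-D density sampled by grid inversion.

Grid draws use a midpoint-convention inverse CDF (a plain cumulative sum
carries a half-cell location bias that is visible at the 0.05-year
tolerance). Five chains with overdispersed starts and split-R-hat/ESS
diagnostics via arviz; R-hat >= 1.05 raises instead of returning. An
adaptive random-walk Metropolis was the first implementation but its
integrated autocorrelation times on the curved `lambda x t_i` ridge made
short runs fail diagnostics; the contract here is posterior correctness,
enforced by agreement with the quadrature oracle (2% relative on `lambda`,
0.05 y on `t_mrca` in the acceptance suite), not sampler identity.
Desk-scale defaults are 5 chains x 20,000 iterations (4,000 warmup), a 1/5
scale-down of the full setting (5 x 100,000 / 20,000), which remains
available by configuration.

Log marginal likelihoods use the iterative optimal-bridge estimator between
the posterior draws (on unconstrained parameters) and a moment-matched
Gaussian proposal, fitted on half the draws and evaluated on the other
half; iteration to relative tolerance 1e-10. The standard error uses the
asymptotic variance with an ESS correction on the posterior-side ratio
series to account for MCMC autocorrelation; the quadrature constant
provides an independent check.

## CCF clustering

A variant's cancer cell fraction is
`CCF = VAF * (rho*CN_t + 2*(1-rho)) / (rho*m)` with purity `rho`, local
total copy number `CN_t` and multiplicity
`m = clamp(round(VAF*(rho*CN_t + 2(1-rho))/rho), 1, CN_t)` (round half-up;
`CN_t = 0` is unmappable and excluded). CCF > 1 is retained and flagged
rather than capped — it signals multiplicity or copy-number misestimation.

Clustering uses a truncated stick-breaking Dirichlet-process mixture
(truncation 20, concentration 1.0) whose emission is binomial on read
counts: a record in a cluster at location `pi` (CCF) in sample `d` has
success probability `pi * rho_d * m / (rho_d*CN_t + 2(1-rho_d))`. The
binomial emission lets sequencing depth drive assignment uncertainty.
Records absent from one twin enter that dimension as 0 alt reads at the
local depth, which is what places twin-specific clusters on the axes of the
2-D fit. Gibbs sweeps alternate assignments (categorical), stick weights
(conjugate Beta) and locations (adaptive random-walk Metropolis, uniform
prior on [0, 1.3]); defaults are 1,000 iterations with 200 burn-in.

Point-estimate extraction is the delicate part. Three independent chains are
pooled into a posterior similarity (co-clustering) matrix; candidate
partitions are average-linkage dendrogram cuts scored by Binder loss. A
final greedy pass merges cluster pairs whenever the merge raises the
collapsed partition posterior (Chinese-restaurant prior times the
location-integrated binomial likelihood). The merge pass exists because the
blocked Gibbs sampler can park a small satellite component on the noise
tail of a large cluster and stay there; the collapsed posterior scores such
partitions tens of nats below the merged one, so the refinement removes
sampler artifacts without any tuned distance threshold and stops at
genuinely separated clusters. Cluster locations are then conditional
posterior draws at the consensus partition; clusters holding under 1% of
mutations are pruned with members reassigned by likelihood.

Pigeonhole labels: within a sample, clusters with CCF > 0.5 cannot occupy
disjoint cell populations, so they are co-lineage; a cluster above 0.5 in
both samples is the ancestral (pre-split) clone, above 0.5 in one sample it
is that twin's MPN lineage, never above 0.5 it is indeterminate.

## Consensus calling and filters

The high-confidence small-variant set is the exact `(chrom, pos, ref, alt)`
intersection of three callers after multi-allelic splitting and minimal-
representation normalization (shared suffix then prefix trimmed; reference-
aware left-alignment through repeats is out of scope, and a literal-match
mode is available). Exact-key matching is the strictest reading of
"overlap" and is configurable. Filters, in fixed order (order affects only
the removal log): no tumor coverage -> germline VAF > 0.05 -> tumor VAF
< 0.1 -> depth < 20 -> multiplicity 0. All thresholds are strict
inequalities, so a variant at tumor VAF exactly 0.10 and depth exactly 20
survives. Tumor VAF is `tumor_alt/tumor_depth` from the record's own counts
(the upstream realignment-based recomputation is an interface contract, not
reimplemented here).

Structural variants survive if both callers support them (same type, both
breakpoints within ±200 bp, transitive merging via union-find) or one
caller is corroborated by a copy-number changepoint within the same 200 bp
slop — reusing the inter-caller slop for changepoints is the simplest
consistent choice, as no separate value is published. Any alt-read evidence
in the matched normal vetoes the call before matching.

## Synthetic data: what it emulates and what it does not

The generator realizes exactly the model the pipeline assumes: Poisson
counts on the shared and private lineages (`fixed_endpoint` convention),
uniform-without-replacement placement on a reference with planted CpG
density, a configurable clock-context fraction (the genome-wide N[C>T]pG
opportunity is not a published constant, so it is a free parameter),
truncated-Poisson depths, binomial alt reads, per-caller Bernoulli
sensitivity and caller-private false calls at never-true positions. Twin
collisions are impossible by construction, which keeps the consensus oracle
exact. Defaults describe the case regime: rate 2.5/y, in utero split,
~40-year-old twins, 40x depth, purity 0.95.

It does not emulate: read-level artifacts (no FASTQ/BAM), mapping or
sequencing error, indel context realism, subclonal copy number, germline
contamination of the tumor sample, or inter-caller error correlation. A
green round-trip therefore establishes the pipeline's bookkeeping and
statistical calibration under the stated model, not robustness to real-data
artifacts.

## Known limitations and honest failures

- **Posterior-mean bias of `t_mrca` at small shared counts.** With a uniform
  prior, the conditional posterior of `t_mrca` is approximately
  `Gamma(s+1, lambda)`, so at fixed truth the posterior mean carries a
  `+1/lambda` pull (~0.4 y at rate 2.5/y, expected s = 1.5). The recovery
  study (200 replicates at rate 2.5, t_mrca 0.6 y) achieves 96% coverage of
  the 95% interval but a +0.42 y mean bias; the corresponding acceptance
  test asserts a |bias| < 0.15 y bound and fails honestly. The bias is a
  property of the Bayes estimator in this regime, not of the
  implementation; the interval, not the mean, is the meaningful summary
  when s is a handful of mutations.
- The published cohort-derived rate upper bound is not reproduced here;
  runs that need the truncation must supply it.
- Bulk N[C>T]pG counts need not equal single-lineage counts; the packaged
  count fixtures encode the published tallies and the assembly emits its
  filter trail for transparency.
- Bridge-sampling error bars assume the ESS-corrected iid approximation;
  the quadrature constant is the authoritative cross-check.
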