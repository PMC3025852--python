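# Methods

## Model and likelihood

The observation unit is the dam: her clutches are pooled into one binomial
record (`total_male` of `total_male + total_female` sexed adults), because
offspring are exchangeable within a dam given her linear predictor. The
per-offspring Bernoulli formulation and the dam-level binomial differ only
by the constant log binomial coefficient, so inference is identical and
the binomial is cheaper. Only adult offspring are sexed, so the response
is the tertiary sex ratio; unknown-sex individuals never enter the counts,
and dams with zero sexed adults are carried through aggregation with an
`excluded` flag but dropped from fits.

The maternally inherited effect `m` is one value per matriline: the
recursion "a mother's effect equals her daughters'" collapses it to a
constant on each maternal lineage, so the pedigree enters the likelihood
only through the partition of dams into matrilines (`resolve_matrilines`).
Males inherit a matriline label for bookkeeping but contribute nothing to
the likelihood. The residual effect `e` is dam-level (not clutch-level),
matching the dam indexing of the model; a per-clutch aggregation mode
exists solely for the clutch-size/sex-ratio correlation.

`mu` and the `m` effects are additively confounded in the likelihood; the
zero-centred priors resolve the ambiguity. Tests assert the invariant that
`mu + mean(m)` is stable when the vagueness of the intercept prior
changes, while `mu` alone may drift.

## Priors

* `mu`, `beta`: Normal(0, 10³).
* Precisions `tau_m = 1/σ²_m`, `tau_e = 1/σ²_e`: Gamma(shape 0.1,
  rate 0.1), the WinBUGS-style convention. Because "a gamma prior on σ"
  is ambiguous between precisions, variances and standard deviations,
  `MaternalModelSpec(prior_on="sd")` instead places the Gamma(0.1, 0.1)
  on the standard deviations (updated by Metropolis on log σ with the
  Jacobian term); the precision convention is the default and is what all
  reported experiments use.

## Sampler

Metropolis-within-Gibbs with a fixed block order per iteration:

1. all matriline effects `m` — because each dam record belongs to exactly
   one matriline, the full conditionals of the `m_j` are mutually
   independent given everything else, so all matrilines are proposed at
   once (independent normal random-walk steps) and accepted element-wise;
2. all dam effects `e` — same argument via the dam partition;
3. `mu`, then each `beta_j`, by scalar random walk;
4. `tau_m`, `tau_e` from their conjugate full conditionals
   Gamma(a + k/2, b + Σ effects²/2), with k the number of effects.

Proposal scales adapt every 50 iterations during burn-in toward ~30%
acceptance (multiplicative update `exp(0.66 (rate − 0.3))`, clipped to
[10⁻³, 10]) and are frozen at the end of burn-in, so the kernel used for
the retained draws is fixed and satisfies detailed balance. Within-block
update order is sorted by id; chains differ only in the substream spawned
from the master seed and in over-dispersed starting values (`mu` at the
empirical pooled logit plus N(0, 0.5) jitter, effects at N(0, 0.5),
precisions at 1). Identical data + config + seed reproduce the draws
bit-for-bit.

Numerical guards: the binomial log-likelihood is evaluated as
`k·η − n·log(1+e^η)` via `logaddexp`, so no probability is ever formed
near 0 or 1; pointwise `logit_sexratio` clips its return into
(10⁻¹², 1 − 10⁻¹²).

Defaults (2 chains × 12,000 iterations, 2,000 burn-in, equal-tailed 95%
intervals from pooled post-burn-in draws, variance components transformed
draw-wise from the precisions) match the original analysis settings.
Convergence is summarised by the classic Gelman–Rubin PSRF
(`sqrt(((n−1)/n·W + B/n)/W)`), a quantitative stand-in for visual chain
inspection.

## Quadrature oracle

`posterior_oracle_small` integrates the unnormalized posterior on a dense
tensor grid for up to three free location parameters with precisions fixed
and the dam level disabled. Each axis spans at least six prior standard
deviations; validation uses a deliberately tighter intercept prior
(variance 4) so the grid resolves the posterior — with the same spec fed
to both the oracle and the sampler, the comparison remains exact. Grid
refinement from 161 to 321 nodes moves the means by < 10⁻⁴ on the test
instances. The oracle is for testing only and never stands behind a fit.

## Synthetic data

The generator is the model read generatively, plus endosymbiont biology:

* founders draw `m ~ N(0, σ²_m)` once; daughters copy it unchanged (no
  segregation or mutation). Every breeding dam draws her own
  `e ~ N(0, σ²_e)`.
* offspring are male with probability `expit(mu + m + e)` (the primary
  sex ratio), then the mechanism acts on infected dams' broods:
  male killing removes each male with probability `strength` (hatched
  counts shrink accordingly); feminization relabels each male female with
  probability `rate` (hatched counts unchanged). Survival from hatching to
  adulthood is otherwise complete, so adult counts equal post-mechanism
  hatched counts — juvenile mortality in the real experiment was high
  (>85% survival) but is not sex-biased and is not modelled.
* infection is transmitted maternally with probability
  `transmission_efficiency` (default 1.0, consistent with infected
  mothers producing only infected offspring in PCR subsets); there is no
  paternal or horizontal transmission, no cytoplasmic incompatibility and
  no parthenogenesis.
* by default the sex-ratio effects are independent of infection status, so
  the generator matches the fitted model exactly;
  `infection_coupled_effects=True` restricts nonzero `m` to infected
  matrilines for causal-scenario studies.

Defaults are the study's conditions: 200 founding females, two breeding
generations with 2 daughters bred per dam, one clutch per dam,
Poisson(17) clutch sizes (the control-group mean hatched count was ~17;
the real clutch-size distribution is unknown beyond its mean and large
variance, so Poisson is a configurable stand-in — a negative-binomial
option covers over-dispersion), mean sex ratio 0.34 (`mu = logit(0.34)`),
σ²_m = 0.64, σ²_e = 0.27. Reproducibility uses one master seed with
substreams derived per (generation, dam).

What the generator does **not** emulate: paternal effects and nuclear
suppressors (real candidates for the residual variance), *Wolbachia*
titre variation, multi-endosymbiont interactions, overlapping
generations, and sex-biased juvenile mortality. Passing tests therefore
show the estimator recovers the variances of data generated under the
model's own assumptions — not that the real data satisfy them.

## Experiment sizes

The variance-recovery experiment (`variance_recovery_experiment`, also run
by `scripts/acceptance.py`) uses 10 replicates of the default study-scale
pedigree (~600 breeding dams, ~10,000 offspring per replicate) at the full
2 × 12,000 MCMC settings; one replicate fits in a few seconds thanks to
the vectorized block updates. The interval-coverage experiment uses 100
smaller replicates (30 matrilines × 2 dams × 15 offspring, 2 × 2,500
iterations), a size at which the 95% interval for σ²_m still covers the
generating value in well over 85% of replicates. The male-killing
diagnostic uses 10,000 single-clutch dams at 50% prevalence.

## Exact tests and correlation

`fisher_exact` and `exact_binomial_test` delegate to scipy, whose
two-sided convention is the minimum-likelihood rule (sum all outcomes with
point probability ≤ the observed); both are verified against exhaustive
hypergeometric/binomial enumeration for every table or outcome with total
≤ 30. The alternative "double the smaller tail" rule is provided
(`alternative="two-sided-doubled"`) because the two conventions disagree
in practice: testing 11 infected of 18 males against an expected
proportion of 0.37 gives p ≈ 0.048 under minimum likelihood but
p ≈ 0.065 (≈ 0.07) under doubling — the rule, not the data, decides
significance at 5% here, which is why both are exposed. A 2×2 table with
a zero margin returns p = 1 with a warning.

`weighted_pearson` uses weighted means, variances and covariance
throughout, with weights defaulting to clutch size so small clutches'
noisy ratios are down-weighted; it is invariant to positive weight
rescaling and sign-preserving affine transforms of either variable.

The group contrast re-expresses infection-status and treatment
comparisons as a fixed effect in the hierarchical model: reported are the
posterior of `beta` and each group's sex ratio computed draw-wise as
`expit(mu)` and `expit(mu + beta)`; a group "differs from 1:1" when its
95% interval excludes 0.5. This is a deliberate Bayesian replacement for
mixed-model F-tests with approximate denominator degrees of freedom —
those are not replicated numerically.

The brood-size diagnostic bootstraps clutches (not offspring) with
percentile intervals, 10,000 resamples, seeded.

## Known limitations

* A single variance scale per level: no population- or
  generation-specific variances.
* No additive-genetic (full animal-model) component — the obvious
  extension, but on binary sex data at this pedigree depth it is weakly
  identified and was not pursued.
* The sampler is single-machine and stores scalar draws densely; effect
  draws are only stored on request (`store_effect_draws=True`) to keep
  memory flat at study scale.
* Poisson clutch sizes understate the real clutch-size variance; the
  clutch-size/sex-ratio correlation magnitude is therefore
  data-dependent, and only its sign is treated as meaningful in tests.
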