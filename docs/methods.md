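# Methods

This note records the modelling conventions, defaults and numerical
choices behind `acwr_bayes`, and what the synthetic data generator does
and does not emulate.

## Load metrics

* **Session load** is duration (min) × Borg CR-10 rating, in arbitrary
  units (AU). RPE accepts the 0 and 10 endpoints and half-point
  ratings; the generator emits ratings rounded to 0.5 on [1, 10].
* **Acute load** is the weekly sum of session loads. **Cumulative
  loads** are trailing sums over 1–4 retained weeks.
* **Chronic load** is the 4-week rolling mean of weekly acute load,
  *coupled*: the current week is included, so a constant load series
  has ACWR exactly 1 at every defined week. The uncoupled convention
  (mean of the four weeks before the current one) is available via
  `coupled=False` / `--uncoupled`; it requires a fifth trailing week.
* **ACWRr**, the null comparator, divides acute load by a single draw
  per observation from Normal(1900, 730²) AU — team-level chronic-load
  location and spread. 730 AU is interpreted as a standard deviation;
  a variance of 730 AU² (sd ≈ 27 AU) would make the comparator nearly
  deterministic and is inconsistent with the intended team-level
  spread. Draws at or below a 50 AU floor are rejected and redrawn so
  the ratio stays positive and bounded; the floor is configurable and
  rejections are logged. With sd → 0 the metric converges to
  acute/1900 deterministically.
* **Monotony** is weekly mean daily load / SD of daily loads, with the
  sample SD (n−1). A constant week (SD = 0) is flagged undefined —
  maximal monotony — rather than given an arbitrary large value.
* **Quartile discretization** uses linear-interpolation empirical
  percentiles (25/50/75) of the pooled player-week values; assignment
  is upper-inclusive (value ≤ cut point → lower bin). On tie-free data
  the four groups are balanced to ±1 observation; heavy ties can make
  group sizes uneven, so equality of counts is never asserted on
  real-like data.

## Cohort assembly

One observation row per player-week with at least 4 trailing retained
weeks (5 for the uncoupled convention). The injury label marks the
completed week immediately preceding an onset (onset in week + 1); an
onset within a player's first weeks, before chronic load is defined,
produces no model row and is logged as a warning. Weeks a player spends
absent with a time-loss injury (the ceil(days_lost/7) weeks after the
onset week) are excluded entirely — they are neither zero-load rows nor
part of the trailing windows, which run over the retained sequence.
Stage-level logging records counts after each exclusion so the
reduction from nominal player-weeks to model rows is auditable.

## Synthetic team season

The generator emulates one professional squad monitored for a season:
12 players over 52 weeks and 23 over 26 weeks (1,222 nominal
player-weeks). Weekly training volume follows an AR(1) process (ρ =
0.6) on a player-week log multiplier (median 0.9, log-sd 0.3) applied
to session durations; sessions per week are uniform on {5, 6, 7},
durations Normal(75, 15²) min, RPE Normal(4.5, 1.5²) rounded to 0.5 and
clipped to [1, 10]. These defaults put the pooled weekly acute load at
a median near 1800 AU with IQR near (1400, 2300) AU. A weekly
availability probability of 0.79 (rotation, illness, travel — anything
other than recorded time-loss injury) plus injury absences reduce the
nominal 1,222 player-weeks to roughly 815 usable observation rows.

Injuries are drawn per player-week for the following week with
logit(p) = logit(0.037) + effect × (quartile − 2.5), where the quartile
is the acute-load or ACWR quartile under the respective dependent
models and the effect term is absent under the null model; 0.037 ≈
30/815 gives about 30 time-loss injuries per season. Days lost are
log-normal with median 10 days; at most one injury is open per player
at a time. The full dataset is generated in two passes: sessions →
preliminary metrics (whose quartiles drive the hazard) → injuries →
absence pruning → final observation table.

What the generator does **not** emulate: match congestion and fixture
calendars, positional or player-level injury-rate heterogeneity
(available as a config option, default off), seasonality in load
periodization beyond AR(1), within-player correlation of the injury
process, and reporting artifacts (missing RPEs, tied values from
rounded durations). Passing tests on synthetic data therefore validate
the pipeline's statistical machinery — not the epidemiological claims
one could make from real squad data.

## Posterior computation

All models are expressed as log unnormalized posterior densities over
unconstrained vectors (scales sampled on the log scale with the
Jacobian folded in) and sampled with multi-chain adaptive random-walk
Metropolis: chains advance in lockstep; during warmup the proposal
covariance is re-estimated every 100 iterations from the pooled,
per-chain-centered second half of the warmup history, and a per-chain
step scale follows a Robbins–Monro recursion toward ≈0.3 acceptance;
both are frozen before retained draws begin, so the retained chain is a
valid Markov chain. Defaults: 4 chains × 10,000 retained draws after
2,000 warmup iterations. Runs are deterministic given the seed.

Diagnostics: split-chain Gelman–Rubin PSRF (each chain halved) and
effective sample size by Geyer's initial-positive-sequence truncation
of the autocorrelation sum (per chain, summed over chains). Model fits
enforce PSRF < 1.01 and ESS > 400 for every reported parameter by
default and raise a diagnostics failure carrying the partial results
otherwise. HDIs use the narrowest-sorted-window method (the shortest
window over sorted draws containing ⌈0.95 n⌉ of them), not density
estimation; for multimodal posteriors this returns the narrowest single
interval.

## Robust comparison details

Priors follow the BEST defaults: μ_g ~ Normal(pooled mean,
(1000 × pooled SD)²), σ_g ~ Uniform(pooled SD/1000, pooled SD × 1000),
and a single ν shared by both groups with ν − 1 ~ Exponential(mean 29),
so small ν (heavy tails) is preferred only when the data demand it.
Data are standardized by the pooled location/scale before sampling
(the priors above are scale-equivariant, so this is a pure
reparameterization); as a consequence the effect size is exactly
invariant under a common affine rescaling of both groups. Groups are
ordered canonically before sampling, so swapping the two inputs reruns
the identical chain and negates the mean difference and effect size
draw-for-draw. The Shapiro–Wilk test is computed per group and reported
as the descriptive normality gate that motivates the t likelihood; it
never alters the model. Player-weeks are treated as exchangeable within
group — repeated measures on the same player are not modelled, a known
limitation shared with the analysis this package operationalizes.

## GLM details

The generative prior is the redundant "logistic ANOVA" form — intercept
a₀ ~ N(0, 2²) plus four exchangeable deviations a_q ~ N(0, σ_β²),
σ_β ~ HalfNormal(2) — reported after sweeping the category mean into
the intercept (β₀ = a₀ + ā, β_q = a_q − ā), which makes the deviations
sum to zero at machine precision for every draw. Internally the
unidentified mean direction is marginalized in closed form and the
sampler works in the identified coordinates (β₀, β₁..₃, log σ_β): the
implied priors are β₀ ~ N(0, 2² + σ_β²/4) independent of the
sum-to-zero deviation vector, whose density on the 3-dimensional
constraint subspace is ∝ σ_β⁻³ exp(−‖β‖²/2σ_β²). The posterior is
identical to the redundant form's; the ridge the redundant form asks a
random-walk sampler to traverse is gone.

HalfNormal(2) is weakly informative on the log-odds scale (quartile
deviations beyond ±4 log-odds are implausible for weekly injury risks)
and applies mild shrinkage to quartiles whose injury counts are small;
both prior scales are exposed as arguments. Bernoulli rows are
aggregated to the 4-row Binomial contingency internally (a sufficient
statistic), so the two input forms give bit-identical posteriors under
the same seed. Model comparison between two fitted metrics pairs the
fourth-quartile probability draws by index, truncating to the shorter
run, and declares the metrics similar when the 95% HDI of the
difference contains 0.

## Numerical and testing choices

* Degenerate inputs fail loudly: constant vectors for Shapiro–Wilk or
  monotony, chronic load ≤ 0, empty quartile cells, non-finite log
  densities at initialization.
* An HDI of constant draws collapses to a point; PSRF of identical
  duplicated chains is ≈1 (degenerate convergence), of disjoint chains
  ≫ 1.1.
* Replicate-based checks (HDI coverage at group sizes 30 vs 785;
  false-credible rate of the top-quartile deviation under the null
  injury model) use 50 seeded replicates with shortened chains
  (1,500–2,000 retained draws), sizes chosen so each check completes in
  well under a minute per replicate batch while keeping Monte-Carlo
  error far below the decision margins.
* Sampler correctness is anchored to closed forms: Beta-Binomial and
  Normal-known-σ conjugate posteriors, prior recovery on a zero-data
  model, AR(1) effective-sample-size theory, and cross-checks against
  arviz's R-hat/ESS on fixtures.

## Known limitations

Random-walk Metropolis is adequate for these low-dimensional posteriors
(≤ 6 coordinates) but would scale poorly to player-level hierarchical
extensions; the within-player correlation of both load and injury is
unmodelled; ACWRr draws one γ per observation (an alternative —
redrawing per recomputation — is not implemented); and the quartile GLM
conditions on the fitted quartile cut points rather than propagating
their sampling uncertainty.
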