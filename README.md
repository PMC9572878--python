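# acwr-bayes

Bayesian analysis of session-RPE training load and injury risk in team
sports, built around the acute:chronic workload ratio (ACWR) and a
random-denominator null comparator (ACWRr) designed to test whether the
ratio carries any information beyond the acute load itself.

## Who this is for

Sports scientists and biostatisticians monitoring squads with
session-RPE logs (session duration in minutes × Borg CR-10 intensity =
load in arbitrary units, AU) who want a fully Bayesian, reproducible
pipeline from raw session logs to posterior injury probabilities — and
a principled way to check whether a load metric "predicts" injury any
better than a randomized version of itself.

## The models

**Load metrics.** For player *p* in week *t*, acute load
`AL(p,t) = Σ sessions duration×RPE`; chronic load is the 4-week rolling
mean of AL (coupled convention, current week included);
`ACWR = AL / chronic`. The null comparator replaces the denominator
with a team-level random draw:

    ACWRr = AL / γ,   γ ~ Normal(1900, 730²)  [AU, redrawn while γ ≤ 50]

which destroys all individual chronic-load information while keeping
the scale comparable. Both ratios and AL are discretized into quartiles
of the pooled player-week sample.

**Robust group comparison (BEST).** Injured vs non-injured player-weeks
are compared with a Student-t likelihood,

    y_gi ~ StudentT(ν, μ_g, σ_g),    g ∈ {injured, not injured}

with a shared degrees-of-freedom parameter ν ~ 1 + Exp(29), diffuse
Normal priors on μ_g and wide Uniform priors on σ_g. Reported draw-wise:
the mean difference μ₁−μ₂ and the effect size
(μ₁−μ₂)/√((σ₁²+σ₂²)/2); a difference is *credible* when its 95%
highest-density interval (HDI) excludes 0.

**Injury GLM.** Injury onsets follow a Bernoulli/Binomial logistic
model over metric quartiles with sum-to-zero deviation coding:

    injured_i ~ Bernoulli(logit⁻¹(β₀ + β_q(i))),   Σ_q β_q = 0

with β₀ ~ N(0, 2²) and a hierarchical shrinkage prior
β_q ~ N(0, σ_β²), σ_β ~ HalfNormal(2). Conditional injury
probabilities per quartile are recovered draw-wise through the inverse
link.

All posteriors are sampled with a multi-chain adaptive random-walk
Metropolis sampler (4 chains × 10,000 retained draws by default) and
reported with mean, 95% HDI, effective sample size (ESS) and the
split-chain Gelman–Rubin PSRF.

## Worked example

Fit the quartile GLM to an observed injury contingency (one row per
ACWR quartile: injuries and injury-free player-weeks):

```bash
cat > contingency.csv <<EOF
quantile,injured,not_injured
1,3,202
2,6,213
3,5,182
4,16,188
EOF
acwr-bayes glm --contingency contingency.csv --out acwr_glm --seed 1
```

prints

```
              mean  hdi_low  hdi_high       ess   psrf
beta0       -3.425   -3.855    -3.019  1929.352  1.001
beta1       -0.551   -1.363     0.187  1967.434  1.003
beta2       -0.137   -0.791     0.474  1930.039  1.002
beta3       -0.148   -0.835     0.479  2393.888  1.002
beta4        0.836    0.168     1.405  1988.858  1.004
p_quantile1  0.021    0.004     0.040  2392.161  1.002
p_quantile2  0.029    0.011     0.050  2140.018  1.001
p_quantile3  0.029    0.009     0.051  2686.425  1.001
p_quantile4  0.072    0.039     0.109  2048.672  1.002
sigma_beta   1.044    0.128     2.379  2155.764  1.002
```

Read: baseline injury log-odds β₀ ≈ −3.43 (≈ 3% weekly risk); only the
fourth quartile's deviation β₄ is credible (its 95% HDI excludes 0),
and a player-week in the top ACWR quartile carries a posterior injury
probability of about 0.07 (95% HDI 0.04–0.11) — roughly double the
baseline, but with wide uncertainty.

A full synthetic team season (35 players, session logs → metrics →
comparisons → GLMs → report tables) runs with:

```bash
acwr-bayes run --out-dir results/ --seed 1
```

which writes `table1_descriptives.csv` … `table5_glm.csv`, posterior
draw files, a diagnostics summary and a manifest with the config hash.
The same seed reproduces every file byte-for-byte. Individual stages
are available as `simulate`, `metrics`, `compare` and `glm`
subcommands; the same functionality is importable from `acwr_bayes`.

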