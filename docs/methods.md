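# Methods

This note documents the models, the sampler, the synthetic-data generator,
the numerical choices, and the limitations of `seedtrend`. Everything stated
quantitatively here is computed by the test suite or `scripts/acceptance.py`.

## Fecundity model

State variables per tree `i` at site `j` in year `t`:

- **Maturation** `z` is an absorbing binary state. The probability that a
  tree of diameter `G` (cm) is mature is a probit,
  `rho = Phi(alpha0 + alphaG * G)`, `alphaG >= 0`. Note `rho` is a *state*
  probability, not a transition hazard; internally each tree carries a
  maturation *changepoint* (the first mature year), which makes monotone
  trajectories true by construction rather than by rejection. A tree
  observed bearing seed — a positive crop count, or a recorded
  `first_seed_year` — is constrained mature from that year on, in every
  MCMC iteration.
- **Conditional fecundity** `psi` (seeds/yr of a mature tree) is lognormal:
  `log psi = x'beta + kappa_[e,t] + b_i + eps`, `eps ~ N(0, sigma^2)`,
  `b_i ~ N(0, sigma_re^2)`.

The canonical design `x` (fixed ordering, shared with the growth model):
intercept; `G`; `G^2`; shade class (ordinal 1–5, entered numerically —
users who prefer dummy coding can pre-expand); spring-minimum-T norm;
spring-T anomaly (year `t`); summer-T norm; summer-T norm²; summer-T
anomalies (`t`, `t-1`); moisture-deficit norm; deficit anomalies (`t`,
`t-1`); deficit-norm × `G`. Splitting each climate variable into a site
norm (window mean) and yearly anomalies separates geographic from
interannual responses; anomalies use the current and previous year because
seed development spans seasons. For spring-dispersing species a
per-species flag substitutes previous-year anomalies only.

Moisture deficit is defined as PET − P accumulated over months 1–8
(mm·month), so that **positive = drier**; sources that print P − PET must be
negated on import.

**Observation layers.** Crop counts are `Poisson(theta * z * psi)` with
`theta` the recorded fraction of crop observed. Trap counts are
`Poisson(area * sum_i z_i psi_i K(r_i; u))` over candidate source trees on
the trap's plot, with the isotropic 2-D Student-t kernel
`K(r; u) = u / (pi (u + r^2)^2)` (unit integral over the plane; `u` in m²).
These are deliberately simple forms: they support partial observation and
inverse dispersal modelling, and they are the swappable points of the
package if richer detection/identification error models are wanted.

**Year effects.** `kappa_[e,t]` is fixed within ecoregion `e` and
hierarchical between ecoregions: `kappa_[e,t] ~ N(kbar_t, tau^2)` with
`kbar_t ~ N(0, 10^2)` and `tau^2` estimated. The intercept and the grand
mean of year effects are not separately identified by the likelihood; the
sampler runs unconstrained and *records* the identified functionals (kappa
centered to zero grand mean per draw, the removed mean folded into the
intercept). The synthetic generator centers its year effects the same way,
so recovery comparisons are like-for-like.

**Size-class weighting.** Coefficient sampling is a weighted regression:
each tree-year carries weight inversely proportional to the occupancy of
its 5-cm diameter bin, so abundant size classes cannot drown out the rare
large (or small) trees that identify the declining limb of the
size–fecundity curve. Raw inverse-occupancy weights are winsorized at 10×
the median raw weight before mean-1 normalization: an almost-empty bin
would otherwise claim hundreds-fold precision for a handful of points,
which measurably distorts both point estimates and interval calibration
(we verified this in coverage experiments). Weights enter all conjugate
updates coherently as inverse relative variances, so the sampler targets a
well-defined posterior.

**Priors** (weakly informative defaults, all configurable):
`beta, kbar ~ N(0, 10^2)`; `alpha0 ~ N(-3, 2^2)`;
`alphaG ~ N(0.05, 0.05^2)` truncated at 0; variances
(`sigma^2, sigma_re^2, tau^2`) ~ inverse-gamma(2, 1). The kernel parameter
`u` is fixed at its configured value by default or sampled under a
lognormal prior (sd 0.5 on the log scale) when `sample_kernel_u=True`.

## Posterior simulation

One iteration of the Gibbs/Metropolis composite:

1. **Latent log psi** — single-site Metropolis sweep over mature tree-years
   (log-scale Gaussian random walk; one shared step size adapted during
   burn-in toward ~0.3 acceptance). Trap intensities are updated
   incrementally and rebuilt from scratch each iteration to prevent
   floating-point drift.
2. **Maturation changepoints** — per tree, a Metropolis–Hastings move that
   proposes the changepoint from its (data-constrained) prior — the prior
   mass of "first mature at position p" is `rho_p - rho_{p-1}` on the
   running-max diameter path — and proposes fecundities for newly mature
   years from their conditional prior. Prior and proposal cancel, so the
   acceptance ratio is the observation-likelihood ratio alone.
3. **Maturation probit (alpha0, alphaG)** — joint random-walk Metropolis on
   the changepoint prior likelihood, adapted during burn-in; proposals with
   `alphaG < 0` are rejected (prior truncation).
4. **Kernel u** (optional) — random-walk Metropolis on `log u`.
5. **Conjugate block** — `beta` (weighted Gaussian update), `kappa`, `kbar`,
   `tau^2`, `b`, `sigma^2`, `sigma_re^2`, all in closed form.

Defaults: 4000 iterations, 2000 burn-in, thinning 2. Acceptance rates and
split-chain R-hat per coefficient are *emitted* in `diagnostics.json`, not
enforced. All randomness flows from one `numpy` Generator seeded by the run
seed; latent sweeps (numba kernels) consume pre-drawn arrays, so a run is
bit-reproducible. The latent updates are compiled with numba; a full fit of
the default synthetic network (1000 trees × 15 years, ~6600 crop counts,
1200 trap counts, 1500 iterations) takes ~6 s on one CPU after compilation.

**Prediction.** `E[F] = Phi(mu) * exp(x'beta + kappa + sigma_pred^2 / 2)`
with `sigma_pred^2 = sigma^2 + sigma_re^2` (random individual effects
marginalized). The lognormal *mean* is the default report; the median
(no variance correction) is available via `use_mean=False`. Requests for a
year with no fitted year effect fall back to the ecoregion mean with a
warning.

**DIC.** Deviance is recorded per retained iteration at the "complete"
focus — observation log-likelihoods given the latent states *plus* the
latent log-fecundity density given the regression — because an
observation-only deviance is insensitive to covariates when flexible
tree-year latents absorb the fit. `p_D` is mean deviance minus deviance at
the posterior means (latents and regression), with maturation states fixed
at their posterior mode. This is the standard conditional-DIC compromise
for latent-variable models; it correctly prefers the generating covariates
over a null model on synthetic fixtures.

## Growth model

Annual increments `max(0, G_{t+1} - G_t)` regress on the same design by a
Tobit: latent `y* = x'beta_g + N(0, sigma_g^2)`, observed `max(0, y*)` —
remeasurement can shrink, so negative growth is censoring, not signal.
Estimation maximizes the likelihood in the Olsen parameterization
(`delta = beta/sigma`, `h = 1/sigma`), in which the log-likelihood is
globally concave; standard errors come from the numerically differentiated
observed information on the natural scale. A dataset with no positive
increment is rejected as non-identifiable. For trend attribution the growth
rate `dG/dt` is the **latent predictor** `x'beta_g`, not the censored mean:
the decomposition is linear in coefficients and the latent scale is where
the partial derivatives live (the censored mean
`m Phi(m/sigma) + sigma phi(m/sigma)` is available as `predict_increment`
for simulation and reporting).

## Trend attribution

Per tree-year, with `mu = alpha0 + alphaG G` and `Delta = trend × 1 yr`:

| term | expression |
|---|---|
| direct spring T | `beta_Tsp * dTsp` |
| direct summer T | `(beta_T + 2 beta_T2 T) * dT` |
| direct deficit  | `(beta_D + beta_GD G) * dD` |
| growth          | `(alphaG phi(mu)/Phi(mu) + beta_G + 2 beta_G2 G + beta_GD D) * dG` |
| residual gamma  | OLS slope of the ecoregion's year effects + anomaly coefficients × climate trends |

The inverse Mills ratio is computed as `exp(log phi - log Phi)` using
`log_ndtr`, so deeply immature trees cannot produce NaN. The total is the
exact arithmetic sum of the terms (additivity at machine precision), and
because each partial is the exact derivative of `log(rho psi)`, the
deterministic total agrees with an exact recomputation of
`Delta log(rho psi)` to second order in the perturbation (empirical
log–log slope 2.0). The stochastic residual has variance `2 sigma^2`
(difference of two year residuals), reported as `nu_var`, and is added as
predictive noise only on request.

**Routing.** `dG/dt` is expanded on the growth model's climate partials:
`routed_c = (df/dG) * (dg/dc) * dc/dt`, with the remainder
`(df/dG) * (dG/dt - sum_c ...)` reported as the unexplained growth share;
the routed shares and the unexplained share sum to the growth term exactly.
The full effect of a climate variable is its direct term plus its routed
growth share; the deficit×diameter interaction's `G * dC/dt` part is
assigned to the deficit's full effect (an explicit convention — aggregation
rules for interaction terms are inherently conventional).

**Aggregation.** Plot summaries are unweighted means of the per-tree
proportionate changes (using each tree's latest decomposed year, the
current-state decomposition), with per-species breakdowns; absolute stand
change is `sum_i F_i * df_i` (seeds/yr), which weights trees by their
expected fecundity. Species without a confident fit can borrow the
element-wise mean coefficients of fitted congeners (`genus_fallback`).
Term-wise uncertainty comes from re-evaluating the decomposition at every
posterior draw (5/50/95% quantiles; ≥100 draws required).

## Synthetic generator

The generator *is* the study design for all validation experiments.
Defaults: 10 sites in 4 ecoregions, 4 plots/site × 25 trees (40 plots,
1000 trees), a 16-year climate series whose last 15 years are the analysis
window. Climate: norms uniform on spring-min T ∈ (−4, 8) °C, summer T ∈
(14, 24) °C, deficit ∈ (0, 120) mm·month; linear trends uniform on
(−0.02, 0.06), (0, 0.05) °C/yr and (−0.5, 1.5) mm·month/yr; iid Gaussian
anomalies (sd 1.0, 0.7, 12.0) with an optional AR(1) switch. Trees start
uniform on 5–45 cm with FIA-style shade classes; growth uses the Tobit
generating process (sigma_g = 0.25 cm/yr, ~10% censoring); maturation is
simulated by monotone coupling — one uniform per tree, `z_t = 1` iff
`Phi(mu_t) >= u_i` — so the state probability matches the probit exactly
while trajectories are absorbing. Fecundity coefficients are chosen so that
conditional fecundity peaks near 50 cm and ~17.5 °C summer T, with
sigma² = 0.64 (masting-scale volatility), sigma_re² = 0.16, year-effect
sds 0.4 (yearly) and 0.15 (between ecoregions). Observations: 60% of trees
carry crop counts in 75% of years with theta ~ U(0.4, 1); two 0.5-m² traps
per plot under `u = 80 m²`.

What the generator does **not** emulate — hence what passing recovery tests
do not show about real data: resource-depletion masting dynamics beyond
year effects (no bespoke interannual synchrony mechanism), seed
identification error between species, spatially correlated climate error,
canopy-class measurement error, irregular remeasurement intervals, and
species-specific covariate subsets. Recovery experiments therefore validate
the estimator under its own assumptions (plus the homoscedastic-truth vs
weighted-fit mismatch, which the winsorized weights keep benign), not
robustness to all field realities.

## Numerical and design choices

- Climate trends: OLS slope over the configured window (≥3 years required);
  trend estimation is invariant to level shifts and equivariant to scaling.
- `split_norm_anomaly` is an exact decomposition (reconstruction is the
  identity; window anomalies mean to ~0 at 1e-9 relative tolerance).
- Poisson log-likelihoods use a `rate = 0` convention: probability 1 for a
  zero count, −inf otherwise; intensities are floored at 1e-300 inside the
  sampler to avoid log(0).
- Changepoint prior mass uses the running maximum of the diameter series so
  that a (real-data) shrinking remeasurement cannot produce a negative
  prior mass; zero-mass positions are floored at 1e-300.
- Degenerate inputs fail loudly: all-censored Tobit, empty plots in
  aggregation, unknown genus in fallback, missing climate trends by name,
  traps referencing unknown plots, fractions outside (0, 1].
- Pipeline stage seeds are small fixed offsets of the run seed; artifacts
  (`attribution.csv` etc.) are byte-identical across reruns of the same
  configuration and seed.
- Validation reports shrinking diameters at "info" severity (real
  remeasurements shrink); everything else is an error.

## Problem sizes used in validation

The default test suite runs in ~2 minutes on one CPU: the recovery
experiment fits the full default network (≈15,000 tree-years) once with
1500 iterations and twenty times with 700 iterations for the coverage
check; arithmetic identity checks (additivity, routing conservation,
first-order fidelity, finite-difference partials) use hundreds of
randomized draws each. `scripts/acceptance.py` repeats all of this from
scratch, seeded, in ~2 minutes.

## Known limitations

- The crop-count and seed-trap likelihoods are simple Poisson layers; field
  data have extra-Poisson dispersion and identification error that would
  need richer observation models.
- The kernel parameter `u` is shared across species and either fixed or
  weakly identified from trap data alone; joint dispersal estimation across
  species is out of scope.
- Year-effect/anomaly confounding leaves anomaly coefficients the least
  well-identified part of the model at small numbers of sites per
  ecoregion; their credible intervals are honest but wide, and mild
  undercoverage is visible in replicate experiments at the default design
  (site-level norms are identified only across sites, so designs with few
  sites leave them prior-dominated).
- The AR(p) lag form of the year-effect term and automated covariate-subset
  selection are not implemented (year-effects variant only, subsets by
  explicit configuration).
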