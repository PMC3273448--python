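# Methods

`arealvar` implements a three-layer analysis of geographic variation in
paired-outcome hospital-admission counts: classical small-area variation
statistics, the Besag–York–Mollié (BYM) convolution model fitted to each
outcome separately, and a two-outcome shared component model (SCM) with
variance partitioning. This note records the models, the estimation
machinery, the synthetic-data design and the numerical choices, together
with their limitations.

## Data model

The unit of analysis is a set of `n` small geographic areas (healthcare
areas) with, per area and per gender, an observed admission count `o_i`, a
population at risk `N_i` and an expected count `e_i`. Expected counts are
single-stratum indirect standardization per gender: `e_i = r·N_i` with `r =
Σo/ΣN` the whole-region rate, so `Σe = Σo` exactly. No age stratification is
performed (the intended population is a single age band, 75+), and areas
with zero population or zero expected count in a stratum are rejected.

Neighborhood structure is an undirected graph (areas sharing a boundary);
it is supplied as an adjacency-list or edge-list file, or generated as a
rook lattice. Geometry (GeoJSON) is carried through only for choropleth
export and never affects computation. Disconnected graphs are accepted with
a warning; intrinsic-CAR computations then use per-component centering and
an effective rank of `n − #components`, with isolated areas falling back to
an exchangeable conditional.

## Classical small-area statistics

Per-area indirect utilization ratios `IUR_i = o_i/e_i` carry exact
Poisson–gamma intervals: at level `1−α` the bounds are
`Gamma(o_i, 1)` quantile at `α/2` and `Gamma(o_i+1, 1)` quantile at
`1−α/2`, divided by `e_i` (lower bound 0 when `o_i = 0`). The interval
excludes 1 exactly when the exact Poisson test rejects.

Five statistics of variation are reported:

- **EQ** — ratio of the 95th to the 5th percentile of crude area rates
  (linear interpolation between order statistics; the most common
  percentile convention, adopted because no other is standard for this
  statistic).
- **CV** — sample sd / mean of area rates (`n−1` denominator).
- **CVw** — population-weighted sd about the population-weighted mean,
  weights normalized to sum 1.
- **SCV** — `(1/n)·Σ[((o_i−e_i)/e_i)² − 1/e_i]` on the natural scale; the
  `1/e_i` term removes the expected Poisson contribution, so SCV can be
  slightly negative under the null of constant risk.
- **EB** — a Marshall-type method-of-moments estimate of the between-area
  variance of relative risks,
  `max(0, Σe_i(r_i−r̄)²/Σe − r̄·n/Σe)` with `r_i = o_i/e_i`, `r̄ = Σo/Σe`.
  Several EB variants circulate in the small-area literature; this is the
  standard moment estimator, and it is tested against its own literal
  transcription, not against any published table.

Confidence intervals for all five use a parametric bootstrap: each
replicate redraws `o_i* ~ Poisson(o_i)` (the saturated-model fitted mean)
and recomputes the statistic; percentile intervals are expanded, when
necessary, to contain the point estimate — relevant for boundary statistics
such as EQ, whose resampled values are strictly above 1 even when the
observed EQ equals 1. Default 1,000 replicates, seeded.

## The BYM model

`o_i ~ Poisson(e_i ρ_i)`, `log ρ_i = α + u_i + v_i`, with `u` an intrinsic
CAR (ICAR) field — each `u_i` conditionally normal about the mean of its
neighbors with precision `τ_u·d_i` — and `v_i ~ N(0, 1/τ_v)` exchangeable.
`α` has a flat prior; both precisions have the diffuse conjugate
`Gamma(0.5, 0.0005)` hyperprior (shape/rate). The share of between-area
variability attributable to spatial structure is computed per posterior
draw as `s_u²/(s_u² + σ_v²)` where `s_u² = Σ(u_i−ū)²/(n−1)` is the
*empirical marginal* variance of the spatial field (not the conditional
variance `1/τ_u`) and `σ_v² = 1/τ_v`. The unstructured variance is reported
as the posterior of `σ_v²` (rather than the empirical variance of `v`
draws); the two differ only by a chi-square fluctuation of order `1/n`.
Per-area exceedance probabilities `Pr(ρ_i > 1 | data)` are fractions of
kept draws, with a 0.95 highlighting threshold.

## The shared component model

Two outcomes (men = 1, women = 2) are modelled jointly:

```
o_1i ~ Poisson(m_1i),  log m_1i = log e_1i + α₁ + δ·λ_i + φ_1i
o_2i ~ Poisson(m_2i),  log m_2i = log e_2i + α₂ + λ_i/δ + β_i + φ_2i
```

`λ` is the shared spatial (ICAR) field, scaled by `δ` for men and `1/δ`
for women; `β` is a women-specific ICAR field; `φ₁, φ₂` are exchangeable
residuals. Which gender carries `β` and the direction of the `δ` scaling
are fixed conventions of the model, not options. Priors: `α`'s flat,
`log δ ~ N(0, precision 0.2)` (variance 5), all precisions
`Gamma(0.5, 0.0005)`. The `δ` prior precision is configurable because the
two common conventions for writing normal dispersions (precision vs
variance) are easily conflated in this literature.

Variance partitioning uses the empirical across-area variances of the
additive log-risk terms within each posterior draw: men `V(δλ)` vs
`V(φ₁)`; women `V(λ/δ)`, `V(β)`, `V(φ₂)`. Per gender the fractions sum to
one within every draw by construction. The women-specific share is
reported both in total (`β + φ₂`) and split into its spatial and
unstructured parts. "Common spatial variance" is reported as the posterior
of the empirical variance of `λ` (consistent with partitioning on
empirical variances), not as `1/τ_λ`.

Prior-sensitivity alternatives, selectable per fit or via the standard
grid: exchangeable (independent normal) priors for `λ` and/or `β`;
hyperpriors `Gamma(0.01, 0.01)` (on the precision — equivalently an
inverse-gamma on the variance, implemented as written on the variance
scale), `Uniform(0, 100)` on the sd, half-normal (precision 0.01) on the
sd; and `Uniform(0.5, 2)` for `δ` with hard rejection at the bounds.
When both spatial fields are exchangeable alongside the `φ` terms the model
is weakly identified and a warning is issued.

## Estimation

All models are fitted by Metropolis-within-Gibbs with a **hierarchically
centered** parameterization. The total log-relative-risk field (`b = u + v`
for BYM; `b₁ = δλ + φ₁`, `b₂ = λ/δ + β + φ₂` for the SCM) carries the
Poisson likelihood and is updated by vectorized single-site random-walk
Metropolis (sites are conditionally independent given the latent fields).
The structured fields are then drawn **exactly** from their Gaussian full
conditionals given the totals — e.g. for BYM, `u_i | b, rest` is normal
with precision `τ_u d_i + τ_v` and mean `(τ_u·Σ_{j~i}u_j + τ_v b_i)/(τ_u
d_i + τ_v)` — using graph-coloring blocks so that a whole color class is
updated in one vectorized draw while preserving exactness (no two areas in
a class are adjacent). Intercepts are drawn exactly: with a flat prior,
`exp(α) | rest ~ Gamma(Σo, Σe·exp(b))`. Precisions use conjugate gamma
Gibbs updates (`Gamma(a + n_eff/2, b + Q/2)`, with `Q` the ICAR pairwise
difference form and `n_eff = n − #components` its rank, or the plain sum of
squares with `n_eff = n` for exchangeable components); the non-conjugate
sd-scale hyperpriors use adaptive random-walk Metropolis on `log τ`.
`log δ` is updated by random-walk Metropolis; given the totals its
conditional involves only the Gaussian residual terms, which keeps the
update cheap and well-behaved.

The centered parameterization was chosen after the textbook uncentered
sampler (fields updated against the likelihood directly, with sum-to-zero
recentering) proved unable to mix between spatial/unstructured variance
attributions at this data scale (expected counts ~10³ make the total field
nearly observed, the classic regime where centering is required). The
ICAR impropriety leaves an exact flat direction `(u+c, b+c, α−c)`; it is
removed by re-centering the structured field (per connected component)
after every sweep and folding the constant into the intercept — a move
along the invariant ridge, not an approximation, on connected graphs.

Proposal scales adapt per site by Robbins–Monro during burn-in only
(target acceptance 0.4, inside the usual 0.3–0.5 band) and are frozen
afterwards, so kept draws come from a fixed transition kernel. All
randomness flows from a single integer seed through `numpy.SeedSequence`
spawning, one stream per chain: results are bit-for-bit reproducible for a
fixed seed, chain count and schedule.

**Schedules.** The default desk-scale schedule is 2 chains × (2,000
burn-in + 2,000 sampling) thinned by 4 (1,000 kept draws total); all
shipped tests and the acceptance script use it. The long WinBUGS-era
schedule (50,000 burn-in + 100,000 sampling, keep every 10th) is available
as `MCMCConfig.long_schedule()` / `--long-schedule`. The reduced default
was validated against long runs (8× the default) on the same data: posterior
medians and intervals agree to within Monte-Carlo noise.

**Diagnostics.** Split-chain potential scale reduction factors (each chain
halved; ≥ 2 chains required) are computed for the monitored scalars;
parameters with R̂ > 1.1 flag the fit with a warning. The deviance is
`−2Σ log PoissonPMF(o; m)` without the saturated term (constant in the
parameters), `pD = mean(D) − D(posterior parameter means)`, `DIC = mean(D)
+ pD`; negative `pD` is returned with a warning. BYM totals for the
two-gender comparison are the sum of the per-gender DICs.

## Synthetic data

The generator emulates the study conditions: a 12×15 rook lattice (180
areas, matching the number of healthcare units), lognormal per-area
populations with means 5,500 (men) and 8,700 (women) and log-sd 0.55
(matching the reported medians and interquartile spread of area
populations), baseline rates 21.44 and 13.98 per 100, shared spatial
variance 0.08, women-specific spatial variance 0.004, unstructured
variances 0.0005 (men) and 0.0015 (women), and δ = 1. With these defaults
the realized women shared fraction is ≈ 0.94 and the extremal quotient of
simulated rates is ≈ 2.5, reproducing the scale of the motivating
application.

ICAR fields are forward-sampled in the eigenbasis of the graph Laplacian
restricted to the sum-to-zero subspace, then rescaled so their empirical
across-area variance equals the target *exactly* — the empirical variance
is precisely the quantity the fitted models partition, so simulations
control exactly what the models estimate. Component fields are made
pairwise empirically orthogonal (each later field has its projection on the
earlier ones removed before rescaling). This makes the stored "realized
fraction" identities exact rather than contaminated by chance cross-terms:
spatial fields on a lattice have few effective degrees of freedom, so a raw
independent draw of `β` typically carries a non-negligible λ-shaped
component, which shifts the realized shared loading away from the nominal
`δ` and would make the generative `δ` unrecoverable in principle.

What the generator does **not** emulate: irregular real-world adjacency
(real healthcare geographies average more neighbors per area than a rook
lattice and contain islands), age structure within the 75+ band,
over-dispersion beyond the Poisson level, data anomalies (late
registrations, coding changes), or spatial structure in populations.
Passing tests therefore demonstrate correctness of the machinery and
recoverability under the model's own assumptions, not robustness to real
data pathologies.

## Known limitations

- **The BYM spatial fraction is weakly identified.** With expected counts
  ~10³ the total log-risk field is nearly observed, and the data inform
  the split into ICAR and exchangeable parts only through spatial
  smoothness — which the ICAR prior constrains weakly (its draws contain
  substantial high-frequency content). Under the `Gamma(0.5, 0.0005)`
  hyperpriors the posterior median of the spatial fraction scatters widely
  (roughly 0.35–0.97 across replicate datasets whose realized fraction is
  0.71). This is a property of the posterior itself, verified by two
  independent routes: an ensemble-sampler fit of the full posterior on a
  small lattice and a Laplace (INLA-style) marginalization over the two
  precisions on the full 180-area lattice, both of which reproduce the
  package's posterior medians seed by seed. Fixing the precisions at their
  true values recovers the realized fraction closely for every replicate,
  which localizes the dispersion in the hyperprior learning, not in the
  likelihood or the sampler. Point estimates of the spatial fraction from
  a single dataset should therefore be read together with their (wide)
  credible intervals.
- **δ uncertainty under gender asymmetry.** When a women-specific spatial
  field is present, the trade-off between `β` and the shared loading adds
  realization-level dispersion to the `δ` estimate that the posterior does
  not fully capture: in simulations at the default asymmetric settings the
  95% interval covers the generative δ = 1 in about 85% of replicates
  (at symmetric-gender settings coverage is nominal).
- Per-component recentering on disconnected graphs imposes the sum-to-zero
  constraint per component without per-component intercepts; area-level
  contrasts within components are unaffected, but levels of small isolated
  components are shrunk toward the global intercept.
- DIC is computed with parameter-mean plug-in, matching common MCMC
  practice; it shares the known sensitivity of DIC to the plug-in choice
  in strongly skewed posteriors.
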