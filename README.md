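# arealvar

Small-area variation analysis and Bayesian disease mapping for paired
areal count data — built for health-services researchers studying
geographic variation in healthcare utilization (hospital admissions,
procedures) across small areas, and in particular for asking whether two
related outcomes (here: men's and women's admissions) share one
geographic pattern or diverge.

The package provides three analysis layers over the same per-area inputs
(observed counts `o_i`, populations at risk `N_i`, indirectly standardized
expected counts `e_i = N_i·Σo/ΣN`, and a neighborhood graph `W`):

1. **Classical small-area variation analysis (SAVA).** Per-area indirect
   utilization ratios `IUR_i = o_i/e_i` with exact Poisson intervals, and
   the statistics of variation EQ₅₋₉₅, CV, CVw, SCV and EB with
   parametric-bootstrap confidence intervals.

2. **The Besag–York–Mollié (BYM) model**, fitted per outcome:
   `o_i ~ Poisson(e_i ρ_i)`, `log ρ_i = α + u_i + v_i`, with `u ~
   ICAR(W, τ_u)` spatially structured and `v_i ~ N(0, σ_v²)` exchangeable.
   It reports the spatial fraction `s_u²/(s_u² + σ_v²)` (with `s_u²` the
   empirical marginal variance of `u`) and exceedance maps
   `Pr(ρ_i > 1 | data)`.

3. **The shared component model (SCM)**, fitted jointly to both outcomes:

   ```
   log m_1i = log e_1i + α₁ + δ·λ_i + φ_1i          (men)
   log m_2i = log e_2i + α₂ + λ_i/δ + β_i + φ_2i    (women)
   ```

   with a shared spatial field `λ`, a scaling parameter `δ`, a
   women-specific spatial field `β` and exchangeable residuals `φ`. The
   posterior partitions each gender's across-area log-risk variance into
   shared and specific components, and maps `e^λ` (common pattern) and
   `e^β` (discrepant pattern) with exceedance probabilities.

Inference is Metropolis-within-Gibbs (hierarchically centered, vectorized
over graph-coloring blocks), with split-chain R̂ convergence diagnostics
and DIC for model comparison. A synthetic-data generator reproduces the
study conditions (180 areas, populations and admission rates at the scale
of a national 75+ hospital-admission atlas) with known latent structure,
so every estimator can be validated against recorded truth. See
`docs/methods.md` for the full model and sampler documentation.

## Worked example

```python
from arealvar import (SimulationParams, MCMCConfig, simulate_scm, fit_scm,
                      fit_bym, compare_dic, variation_statistics)

params = SimulationParams(seed=42)          # 180-area lattice, study-scale data
ds, truth = simulate_scm(params)

vs = variation_statistics(ds.men, n_boot=500, seed=42)
print(f"men EQ5-95 = {vs.estimates['eq']:.2f} "
      f"({vs.ci_low['eq']:.2f} to {vs.ci_high['eq']:.2f})")

config = MCMCConfig(seed=42)                # 2 chains, reduced schedule
scm = fit_scm(ds, config=config)
f = scm.fractions
print(f"women shared fraction = {100*f['women.shared']['median']:.2f}% "
      f"({100*f['women.shared']['ci_low']:.2f} to {100*f['women.shared']['ci_high']:.2f})")
print(f"  realized in simulation: {100*truth['women_shared_fraction_realized']:.2f}%")
d = scm.delta_summary()
print(f"delta = {d['median']:.3f} ({d['ci_low']:.3f} to {d['ci_high']:.3f})")

bym_m = fit_bym(ds.men, ds.adjacency, config)
bym_w = fit_bym(ds.women, ds.adjacency, config.with_seed(43))
rec = compare_dic(bym_m, bym_w, scm)
print(f"DIC: BYM total {rec.dic_bym_total:.1f}, SCM {rec.dic_scm:.1f}, "
      f"difference {rec.delta_dic:.1f}")
```

Output:

```
men EQ5-95 = 2.49 (2.43 to 2.67)
women shared fraction = 94.13% (91.44 to 96.70)
  realized in simulation: 93.57%
delta = 1.017 (0.989 to 1.044)
DIC: BYM total 3853.0, SCM 3793.8, difference 59.2
```

Reading: area rates vary 2.5-fold between the 5th and 95th percentile; the
joint model attributes ~94% of the women's between-area log-risk variance
to the pattern shared with men (the credible interval brackets the
simulation's realized value); `δ ≈ 1` says the shared gradient loads
symmetrically on the two genders; and the joint model fits better than two
independent BYM fits (lower DIC), because it borrows strength across
outcomes.

## Command line

The same pipeline is available as subcommands, each writing seeded,
config-fingerprinted delimited tables:

```sh
arealvar simulate --out-dir demo --seed 5
arealvar sava    --counts demo/counts.csv --adjacency demo/adjacency.csv --out-dir demo --seed 5
arealvar bym     --counts demo/counts.csv --adjacency demo/adjacency.csv --out-dir demo --seed 5
arealvar scm     --counts demo/counts.csv --adjacency demo/adjacency.csv --out-dir demo --seed 5
arealvar compare --counts demo/counts.csv --adjacency demo/adjacency.csv --out-dir demo --seed 5
arealvar sensitivity --counts demo/counts.csv --adjacency demo/adjacency.csv --out-dir demo --seed 5
```

`--long-schedule` switches from the reduced desk-scale MCMC schedule to
the long 50,000 + 100,000-iteration schedule. Counts files are CSV/TSV
with columns `area_id, observed, population[, expected]` and a `gender`
column; adjacency is an edge list or an adjacency list.

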