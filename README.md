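# bstmap

Bayesian space-time hierarchical modelling of area-level age-standardized
mortality rates — structured random effects, model comparison, risk-factor
association mapping, and exceedance-probability hotspot detection.

## The problem

Country-level mortality surveillance (for example the WHO Global Health
Observatory's age-standardized suicide-rate panel: ~183 countries, yearly
rates per 100,000 over 2000–2019) asks three linked questions:

1. **Trends** — how have rates moved globally, by region, and by sex?
2. **Clusters** — which areas are persistently above the worldwide norm?
3. **Associations** — which area-level risk factors track the rates, and
   where?

Raw area-by-year rates are noisy, especially for small areas, so the package
fits a Bayesian hierarchical model that borrows strength across neighbouring
areas and adjacent years, and answers questions 2–3 from the posterior.

## The model

Rates are treated as log-normal. With `y_it` the rate for area `i` in year
`t` and `z_it = ln(y_it)`,

```
z_it ~ Normal(mu_z_it, sigma_z^2)
mu_z_it = beta_0 + sum_m (beta_m + b_im) * X_itm + u_i + v_i + phi_t + delta_it
```

* `beta_m + b_im` — a global coefficient per risk factor plus exchangeable
  area-level deviations (an area-varying, time-constant coefficient);
* `u_i` — intrinsic CAR (Besag) spatial effect on the contiguity graph;
  `v_i` — exchangeable spatial effect; together the BYM convolution;
* `phi_t` — temporal effect (exchangeable, RW1 or RW2);
* `delta_it` — Knorr-Held space-time interaction of type I–IV, built as a
  Kronecker combination of the spatial and temporal structures.

Everything is conjugate, so the model is fitted by a blocked Gibbs sampler
(structured blocks are updated in the eigenbasis of their precision
structure). The arithmetic-scale expected rate is `exp(mu_z + sigma_z^2/2)`;
a coefficient `beta` means a `100·(exp(beta) − 1)` percent change in the
geometric-mean rate per standardized unit of the risk factor, flagged
significant when the equal-tailed 95% credible interval excludes zero.

Model choice follows a two-step procedure: risk factors are screened by
correlation with the log rate (collinear pairs pruned, keeping the member
more strongly correlated with the outcome), then all 3 spatial × 3 temporal
× 4 interaction = 36 random-effect structures are fitted and scored by WAIC
(primary), DIC, LPML/CPO, bias, RMSE and fitted-observed correlation.

Hotspots are area-years whose posterior probability of exceeding the yearly
cross-area median rate `q_t` — `P(mu_z_it > ln q_t)` — is above `1 − alpha`
(default `alpha = 0.05`).

## Worked example

```python
import numpy as np
from bstmap import (
    ModelSpec, MCMCSettings, generate_area_graph, simulate_panel, fit_gibbs,
    detect_hotspots, two_step_select, coefficient_significance,
    coefficient_percent_effect, yearly_group_means,
)

graph, polygons = generate_area_graph(30, layout="grid", seed=0)
spec = ModelSpec(covariate_names=("ncd_mortality_rate", "tb_incidence"),
                 spatial_family="bym", temporal_family="rw2", interaction_type="I")
panel, covariates, truth = simulate_panel(
    graph, n_years=10, spec=spec, effect_sizes=np.array([0.5, -0.3]), seed=0)

(summary,) = yearly_group_means(panel, "global")
print(f"mean rate {summary.yearly_means[0]:.2f} -> {summary.yearly_means[-1]:.2f} "
      f"per 100,000 ({summary.percent_change:+.2f}%)")

candidates = [ModelSpec(covariate_names=spec.covariate_names, spatial_family="bym",
                        temporal_family="rw2", interaction_type=t) for t in ("I", "IV")]
mcmc = MCMCSettings(iterations=2000, burn_in=800, chains=2, seed=0)
table, best = two_step_select(panel, covariates, graph, candidates, mcmc)
print("best structure:", best.label)

draws = fit_gibbs(panel, covariates, graph, best, mcmc)
for name in best.covariate_names:
    beta = draws.coefficient_draws(name)
    sig, _ = coefficient_significance(beta)
    pct = np.median(coefficient_percent_effect(beta))
    print(f"{name}: median effect {pct:+.1f}% per sd"
          f" ({'significant' if sig else 'not significant'})")
result = detect_hotspots(panel, draws.mu_z, alpha=0.05)
print("hotspot area-years:", int(result.hotspot.sum()), "of", result.hotspot.size)
```

Output:

```
mean rate 24.09 -> 19.82 per 100,000 (-17.74%)
best structure: bym+rw2+I
ncd_mortality_rate: median effect +72.6% per sd (significant)
tb_incidence: median effect -26.6% per sd (significant)
hotspot area-years: 112 of 300
```

The selection table put WAIC at −13.1 for the generating type-I structure
against 111.5 for the type-IV rival, so the search recovers the structure
the data were simulated from; both simulated coefficient effects are
recovered with the right signs (`exp(0.5) − 1 ≈ +65%`,
`exp(−0.3) − 1 ≈ −26%`), and roughly a third of area-years sit confidently
above the yearly medians, as expected when a minority of areas carries
elevated rates.

There is also a CLI for file-based runs:

```bash
bstmap simulate --n-areas 183 --n-years 20 --seed 1 --out data/
bstmap describe data/rates.csv
bstmap run-all --synthetic-preset small --candidates bym+rw2+I --out run/
```

Real panels are read from CSV (`area_id, region, year, stratum, rate` /
`area_id, year, name, value`), adjacency from a neighbor-list file or
derived from GeoJSON boundaries by queen contiguity.

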