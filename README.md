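# scalediv

**Scale-explicit, detection-corrected taxonomic and functional diversity
change for repeated community surveys.**

Apparent biodiversity change depends on the spatial scale at which it is
measured and on whether imperfect detection is corrected. `scalediv` is a
pipeline for community monitoring data of the breeding-bird-survey type —
routes with a handful of within-route segments acting as repeat samples —
that estimates, per year and per spatial scale:

- **ψ**, detection-corrected occupancy probabilities per species × site,
  from a hierarchical multispecies occupancy model with data augmentation;
- **TD**, taxonomic diversity, `TD = Σᵢ ψᵢ` per assemblage;
- **FD**, functional diversity, the ψ-weighted branch length of a master
  Gower/UPGMA trait dendrogram: each branch contributes
  `ℓ · (1 − Πᵢ∈I(1 − ψᵢ))` over its descendant leaves *I*;
- **temporal β diversity** between a later year *m* and baseline, via the
  probabilistic calculus `a = Σ ψₘψ_base` (persistence),
  `b = Σₜ ψₜ(1−ψₜ₋₁)` (first colonizations, ψ ≤ 0.8 before *m*),
  `c = Σₜ ψₜ₋₁(1−ψₜ)` (unrecovered losses, ψ ≤ 0.8 after *m*), partitioned as

      DIS = (b+c)/(2a+b+c),  TUR = min(b,c)/(a+min(b,c)),  NES = DIS − TUR

  with functional analogues (d, e, f) on the same formulas;
- **trend slopes** (Δ quantities) of any metric against year, from a linear
  mixed model with a grid-cell random intercept and AR(1) residuals;
- **TD-constrained null models** for FD change (within-year ψ reshuffling,
  rank p values with 0.975/0.025 cutoffs).

Sites aggregate across a nested hierarchy of equal-area square grids (50 to
1600 km side, plus a continental and a symbolic global scale) by taking the
maximum ψ over member routes, with constant-effort cell retention. A fully
synthetic data generator with known ground truth makes every stage testable
without any real survey download.

## Worked example

Simulate a small community, fit the occupancy model for one year, and trace
diversity change over eight years:

```python
import numpy as np, pandas as pd, scalediv as sd

routes = sd.generate_routes(n_routes=60, n_bcrs=2, extent_km=900, seed=1,
                            years=range(1995, 2003))
params = sd.generate_species_params(
    20, {"mu_beta0": -0.5, "sd_beta0": 1.0, "mu_trend": 0.05, "sd_trend": 0.0},
    seed=2)
dets = sd.simulate_detection_histories(params, routes, range(1995, 2003), seed=3)

res = sd.fit_multispecies_occupancy(
    dets[0], routes, sd.OccupancyConfig(chains=2, draws=1000, warmup=600), seed=4)
print(res.summary().round(3))
```

```
             mean     sd  hdi_2.5%  hdi_97.5%   rhat  ess_bulk
mu_beta0   -0.450  0.254    -0.960      0.044  1.001   525.002
sd_beta0    1.033  0.223     0.686      1.559  1.007   222.782
mu_beta1    0.102  0.149    -0.179      0.391  1.003   386.577
sd_beta1    0.520  0.116     0.336      0.774  1.005   239.348
mu_alpha0   0.133  0.221    -0.329      0.567  1.002   567.432
sd_alpha0   0.925  0.190     0.645      1.373  1.007   211.648
Omega       0.810  0.077     0.642      0.931  1.000  1929.028
richness   20.052  0.228    20.000     21.000  1.002   346.403
```

The community hyperparameters used to simulate (`mu_beta0 = -0.5`,
`sd_beta0 = 1.0`, ...) sit inside their 95% posterior intervals, R-hat is
< 1.01 throughout, and the posterior predictive check confirms calibration
(`res.posterior_predictive_check()` → p = 0.185, discrepancy ratio 0.941;
for a well-specified fit p should be unexceptional and the ratio near 1).

Build the functional dendrogram and follow TD and FD at the continental
scale (one cell; ψ aggregated by maximum over routes):

```python
traits = sd.generate_trait_table(20, seed=5, species_ids=params.species_ids)
tree = sd.upgma_tree(sd.gower_distance(traits))

elev = routes["elevation_z"].to_numpy()
psi_by_year = {}
for t in range(1995, 2003):
    logit = (params.beta0[:, None] + params.trend[:, None] * (t - 1995)
             + params.beta1[:, None] * elev[None, :])
    psi_by_year[t] = (1 / (1 + np.exp(-logit))).max(axis=1)

div = sd.diversity_series(psi_by_year, tree=tree, traits=traits)
print(div[["year", "TD", "FD", "TD_rel", "FD_rel"]].round(3).head(3))
#  year     TD    FD  TD_rel  FD_rel
#  1995 12.447 1.648   1.000   1.000
#  1996 12.626 1.668   1.014   1.012
#  1997 12.803 1.688   1.029   1.024

tab = pd.DataFrame({"cell": "continent", "year": div["year"], "value": div["TD"]})
print(sd.fit_trend(tab).slope)          # 0.1745  (TD units per year)

dis = sd.dissimilarity_series(psi_by_year, tree=tree)
print(dis[["year", "TD_DIS", "TD_NES", "TD_TUR"]].round(3).tail(1))
#  year  TD_DIS  TD_NES  TD_TUR
#  2002   0.700   0.016   0.683

nd = sd.null_fd_slope_distribution(tree, psi_by_year, n_reps=100, seed=6)
print(nd.observed_slope, nd.p_value)    # 0.0194  0.44
```

With a positive simulated occupancy trend (0.05 logit units/yr for every
species), TD rises ~0.17 species-equivalents per year; dissimilarity to the
baseline year grows and is turnover-dominated (TD_TUR ≫ TD_NES, since gains
and losses are balanced); and the FD slope is unremarkable against its
TD-constrained null (p = 0.44), as it must be when traits are assigned
independently of the dynamics.

The same pipeline is scriptable from the shell — see `scalediv --help`
(`simulate`, `fit`, `dendrogram`, `aggregate`, `diversity`, `trends`,
`null`), each stage reading and writing plain CSV/JSON/newick.

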