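# Methods

`scalediv` estimates temporal change in detection-corrected taxonomic (TD)
and functional (FD) diversity from repeated community surveys, across a
nested hierarchy of spatial scales. This note documents the models, the
numerical choices, and what the synthetic-data generator does and does not
emulate.

## Occupancy model

One hierarchical multispecies occupancy model is fitted per survey year.
Detection histories `y[i, j, k]` (species *i*, route *j*, segment *k* = 1..5;
the five within-route segments act as spatially substituted "repeat visits")
are modelled as

    y_ijk ~ Bernoulli(p_i * z_ij)          logit(p_i)    = alpha0_i
    z_ij  ~ Bernoulli(psi_ij)              logit(psi_ij) = beta0_i + beta1_i * ELEV_j

where `ELEV_j` is standardised route elevation (mean 0, SD 1; standardisation
keeps the hyperpriors interpretable and the sampler well scaled). Species
coefficients are pooled through Normal community hyperdistributions, e.g.
`beta0_i ~ N(mu_beta0, sd_beta0^2)`. Hyperpriors: each community mean gets
`N(0, 5^2)`; each community variance gets `InverseGamma(0.5, 0.5)` (a
heavy-tailed, weakly informative choice equivalent to a scaled inverse
chi-squared with one degree of freedom). Detection is intercept-only because
segment-level detection covariates are not part of the data model.

Data augmentation (Kéry–Royle style) appends all-zero pseudo-species up to a
superpopulation of `ceil(1.2 * observed richness)` (configurable), each with
an inclusion indicator `w_i ~ Bernoulli(Omega)` and `Omega ~ Beta(1, 1)`, so
community hyperparameters and richness are not conditioned on the observed
list alone. Species supplied in the input detection array are treated as
known community members (`w = 1`); only appended pseudo-species have free
inclusion indicators.

### Sampler

Inference is a blocked Metropolis-within-Gibbs sampler (default 3 chains,
1000 warmup + 2000 retained draws):

- `z`, `w`, `Omega`, and all hyperparameters have closed-form full
  conditionals (Bernoulli, Bernoulli with the zero-history likelihood
  marginalised over `z`, Beta, Normal/InverseGamma).
- `beta0`, `beta1`, `alpha0` are updated with Gaussian random-walk Metropolis
  steps vectorised across species; proposal scales adapt every 50 warmup
  iterations toward a 0.44 acceptance rate and are frozen afterwards.
- Species with `w = 0` at an iteration are redrawn from the community prior,
  which is their exact conditional.

Convergence is summarised by rank-normalised split R-hat and bulk ESS (ArviZ)
on the monitored hyperparameters; fits with max R-hat >= 1.1 are flagged with
a logged warning when their occupancy matrix is extracted.

### Reported occupancy

`psi_ij` is reported as the posterior mean of `z_ij` — the *conditional*
probability of presence given the detection history — rather than the
marginal logit-linear occupancy. Any species-route pair with a detection
therefore has `psi = 1` exactly, and a zero history shrinks toward the
Bayes-rule value `psi (1-p)^5 / (psi (1-p)^5 + 1 - psi)`. A post-hoc regional
constraint zeroes `psi` for species never detected in a given conservation
region (BCR) that year, preventing spurious occurrence far outside a
species' observed range.

### Posterior predictive check

The discrepancy is the sum of squared Pearson residuals of segment-level
detection counts over occupied (`z = 1`) species-route cells, computed for
the observed data and for a replicate simulated from `Binomial(5, p_i)` at
each retained draw. The Bayesian p value `Pr(D_rep >= D_obs)` and the ratio
`mean(D_rep)/mean(D_obs)` are both reported; a well-calibrated fit gives p
near 0.5 and ratio near 1. On self-simulated data at the package's reference
size (15 species x 100 routes) the p value is conservative but variable
across data realisations (roughly 0.2–0.8); it concentrates toward 0.5 as
the data grow.

## Spatial scales

Square grids of side 50–1600 km are built in a hand-coded Lambert
cylindrical equal-area projection (spherical Earth), all anchored at one
origin so each cell of side 2L is exactly the union of four cells of side L.
Two sentinel scales complete the hierarchy: `continental` (one cell covering
the extent) and `global` (a symbolic cell where every non-extinct species is
present, stepping down at each recorded extinction year).

Routes are assigned to the cell containing their median coordinate (routes
are summarised by their median latitude/longitude; true length-majority
assignment would require route geometries). Exact boundary ties go to the
lower-indexed cell. Survey effort is held constant two ways: only routes
surveyed in both endpoint years enter the analysis, and a cell is retained
in a year only if *every* route initially assigned to it was surveyed that
year. Over-dense regions can be thinned to a per-BCR cap (default 30) by
repeatedly removing the route with the smallest nearest-neighbour distance.
Cell-level occupancy is the maximum over member routes, so cell TD is
non-decreasing along the nesting chain.

## Functional space

Trait space combines body mass, a 7-axis diet simplex, and a 7-axis
foraging-niche simplex. Pairwise dissimilarity is a weighted Gower distance
(per-axis range-normalised absolute differences): mass carries weight 1 and
each simplex axis 1/7, so the three categories contribute equally. Mass
enters on the log scale by default — its heavy right tail would otherwise
dominate the axis — and this is configurable off. Axes with zero range are
dropped with a warning. The master dendrogram is built once from the full
species pool with UPGMA (average linkage, species sorted lexicographically
first so tie-breaking is platform-stable) and reused for every assemblage;
cophenetic correlation against the input distances is the fidelity
diagnostic.

FD of an assemblage is the occupancy-weighted total branch length: each
branch contributes `length * (1 - prod_{i in I}(1 - psi_i))` over the leaves
*I* below it. For terminal branches this is `length * psi_i`; branches with
no occupied descendants contribute 0, which makes explicit pruning (with
branch-length-summing collapse of degree-2 nodes) arithmetically redundant —
the uniform formula is what the implementation evaluates.

## Temporal beta diversity

Between the baseline year and a later year *m*, per species:

- persistence `a_i = psi_m * psi_base`,
- colonization `b_i = sum_{t} psi_t (1 - psi_{t-1})` over `t = base+1..m`,
  counted only for species whose psi never exceeded 0.8 in `[base, m-1]`
  (first colonizations only),
- loss `c_i = sum_{t} psi_{t-1} (1 - psi_t)` over the same `t`, counted only
  for species whose psi never exceeded 0.8 in `[m+1, last year]` (no
  recolonization).

Eligibility is a species-level filter over the whole window, not per term.
A fluctuating species can contribute to both `b` and `c`; the calculus does
not force exclusivity. Sørensen dissimilarity and its partition:

    DIS = (b + c) / (2a + b + c)
    TUR = min(b, c) / (a + min(b, c))
    NES = [(max(b,c) - min(b,c)) / (2a + b + c)] * [a / (a + min(b,c))]

with `NES + TUR = DIS` and contributions `NESc = NES/DIS`, `TURc = TUR/DIS`.
Degenerate conventions: all-zero components give missing values (excluded
from trend fits); `a + min(b,c) = 0` gives `TUR = 0` and the nestedness
factor `a/(a + min)` is taken as 1 so the partition identity survives the
corner. With binary psi and the threshold disabled the whole calculus
reduces to integer set counts and classic Sørensen.

Functional analogues `d, e, f` are the FD of the persisting / colonizing /
lost sets, obtained by feeding the per-species component magnitudes (clipped
into [0, 1]; multi-year sums can exceed 1 and clipping is logged) into the
weighted-FD machinery, then reusing the same partition formulas.

Trait-space change uses occupancy-weighted summaries: mean body mass
`sum(psi_i m_i)/sum(psi_i)` and guild prevalence
`sum(psi_i trait_ik)/sum(psi_i)` per diet and foraging axis.

## Trend estimation

Every "change" quantity is the fixed-effect slope of a metric against
calendar year in a linear mixed model with a grid-cell random intercept and
AR(1)-correlated residuals (the minimal structure for serially revisited
sites; the order is configurable down to independent errors). The fit is
restricted maximum likelihood by default (ML available), with the fixed
effects profiled out and the three variance parameters optimised by L-BFGS-B
on unconstrained transforms. Unbalanced panels enter through the actual year
gaps in the AR(1) correlation; a single-cell series reduces to GLS. All
metrics use a normal response, including bounded ones — adequate away from
the 0/1 boundaries, and flagged as a limitation near them. Per-cell OLS
slopes are retained for the distributional summaries (2.5/25/50/75/97.5
percentiles across cells). The fitter is cross-checked in the test suite
against R's `nlme` (`gls`/`lme` with `corAR1`) on identical data.

## Null model

To ask whether FD change exceeds what TD change alone implies, occupancy
values are reshuffled across the species of each assemblage independently
within each year — preserving each year's TD exactly — and the FD-vs-year
slope is refitted per replicate (default 100). The observed slope's rank
gives `p = (#{null < obs} + 0.5 #{null = obs}) / n`; p > 0.975 (or < 0.025)
flags significantly higher (lower) FD change than the TD-constrained
expectation. When traits are unrelated to occupancy dynamics the p values
are approximately uniform, which the suite checks with a coarse
Kolmogorov–Smirnov test.

## Synthetic data

The generator emulates the structure the estimators rely on: Bernoulli
detection of a latent occupancy state over 5 i.i.d. within-route segments,
logit-linear occupancy in standardised elevation, species coefficients drawn
from Normal community hyperdistributions (defaults: `mu_beta0 = -1`,
`sd_beta0 = 1`, `mu_beta1 = 0`, `sd_beta1 = 0.5`, `mu_alpha0 = 0`,
`sd_alpha0 = 0.7` — moderate occupancy, moderate detectability communities),
an optional per-species linear logit-scale occupancy trend (the yearly
models assume no generative temporal process; the trend gives
trend-recovery tests a known truth), routes scattered uniformly over a
square equal-area extent with region membership by spatial blocks, lognormal
elevations and body masses, Dirichlet-distributed diet/foraging simplices
with an optional guild-concentration parameter (default off: mixed diets),
and a small extinction record with uniform years.

It does not emulate observer effects, weather, abundance, route geometry,
spatially autocorrelated occupancy, or non-stationary detection — so passing
tests demonstrate correctness of the estimators under the stated model, not
robustness to those real-data complications.

## Problem sizes and determinism

Reference problem sizes used throughout the examples and checks: 15 species
x 100 routes x 5 segments for occupancy fits (3 chains, 1000 + 2000
iterations, a few seconds vectorised); 50 cells x 45 years for trend
recovery; 100 replicates for null distributions. Every stochastic component
takes an explicit seed (NumPy `SeedSequence` spawning per chain), and all
generators are exactly reproducible under a fixed seed.

## Known limitations

- The sampler is random-walk Metropolis within Gibbs; very large communities
  would mix slowly compared to gradient-based samplers.
- The conditional-occupancy convention makes `psi` depend on the realised
  detections (it is 1 wherever a species was seen); analyses that need the
  marginal occupancy should use the coefficient draws directly.
- `beta1` for species detected at very few routes is informed mostly by the
  community prior; its per-species interval can be wide.
- The AR(1)-only residual structure is a deliberate floor; seasonal or
  higher-order dependence is out of scope.
- One null model is implemented (within-year psi reshuffling); alternative
  richness-preserving binary swaps are not.
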