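# Methods

## Terrain-resistance accessibility

Roads are an undirected graph; each segment's travel cost is its free-flow
time (length / design speed of its class) multiplied by a comprehensive
resistance coefficient, the weighted overlay

```
R = 0.4·R_slope + 0.3·R_elevation + 0.3·R_road
```

Slope is extracted from the DEM with Horn's 3×3 finite-difference method
(edge replication at borders) and classified 0–5° → 1.0, 5–15° → 1.2,
15–25° → 1.5, 25–35° → 2.0, >35° → 3.0; elevation <1500 m → 1.0,
1500–2500 m → 1.2, 2500–3500 m → 1.5, >3500 m → 2.0; road classes
highway/national/provincial/county/rural carry speeds 120/80/60/40/20 km/h
and resistances 0.8/1.0/1.2/1.5/2.0. Given these tables the overlay is
bounded in [0.94, 2.4]. Classification intervals are right-closed (a value
exactly on a boundary takes the lower class), a deterministic tie rule.
Slope and elevation for a segment are the means of ≥5 evenly spaced raster
samples along it. Multiplying time by resistance is the only combination
that uses both the speeds and the dimensionless coefficients; costs are
therefore "terrain-equivalent hours".

Per-unit accessibility S_i needs a scalar summary, for which two
conventions are provided: **service_area** (default for mapping workflows) —
total beds of facilities whose least-cost path (Dijkstra) to the unit's
nearest network node is within a cost budget, per 1000 residents 65+ — and
**gravity** (pipeline default) — `Σ_f beds_f · exp(−cost_if/β)` per 1000
elderly, which avoids the all-or-nothing budget cliff on coarse synthetic
networks. Units and facilities snap to the nearest network node by
Euclidean distance. Unreachable facilities contribute zero; units with no
elderly population get S = NaN, are logged, and are excluded downstream.
Both directions of the service-area computation coincide on an undirected
graph, so seeding at facilities vs at units is immaterial.

## Aging typology and growth mismatch

`PA` is the percentage of population 65+ at period end; `V_PA` the annual
growth rate of the 65+ **count** (counts, not proportions — the typology's
growth dimension describes the population, and using proportions would
conflate it with total-population change). Three growth-rate conventions
are exposed because reported figures in this literature mix them: geometric
(CAGR, the default), arithmetic (ratio minus one over years), and
period-total (total percent change, the convention behind headline "grew
X%" figures). The eight-type classification crosses PA bands ≤7 / (7,10] /
(10,14] / >14 with rapid (V_PA > 4) vs slow (V_PA ≤ 4); both boundary
conventions follow the printed table (bands right-closed, V_PA = 4 slow).
Growth gaps are rounded half-up to one decimal **after** subtraction of
unrounded rates; passing already-printed rates reproduces published
arithmetic exactly.

## Lorenz/Gini equity

Units are sorted ascending by accessibility per elderly resident; the
Lorenz curve accumulates elderly-population shares (x) against
accessibility-mass shares S_i·elderly_i (y), and
`G = 1 − Σ (x_i − x_{i−1})(y_i + y_{i−1})` (trapezoid rule). This equals the
weighted pairwise mean-absolute-difference Gini (verified to 1e−12 in
tests) and is invariant to unit order and to uniform rescaling of either
margin. A literal covariance-style reading sometimes seen in applied work is kept
behind `method="covariance_form"` for comparison only; it is not
range-guaranteed and is never used by the pipeline. If every unit has zero
accessibility the curve is degenerate and G = 1 is reported with a warning.
UNDP bands: ≤0.2 high equality, (0.2,0.3] moderate, (0.3,0.4] relatively
reasonable, (0.4,0.6) significant disparity, ≥0.6 extreme inequality (0.6
assigned to the extreme band — the printed bands overlap there).

## Coupling coordination

`C = 2√(ES)/(E+S)`, `T = αE + βS` with α = β = 0.5 (the two subsystems are
treated as equally important), `D = √(CT)`. E is the range-normalized
elderly **count** (a proportion variant is available), S the
range-normalized accessibility; normalization is per census year by default
(cross-sectional comparison), pooled optionally. A constant normalization
group maps to 0.5 with a warning. C is computed as 2√E·√S/(E+S) to avoid
subnormal underflow of the product, and clamped at 1 against last-bit
round-off. The ten D bands are half-open [a, a+0.1) with [0.9, 1.0] closed.
Level-distribution percentages are 100·count/n_units rounded half-up to one
decimal, so a 14-unit region yields the characteristic 7.1/14.3/21.4…
sequence.

## Geographical detector

Factors are min-max normalized and discretized with **exact Fisher–Jenks
natural breaks** (O(k·n²) dynamic programming over prefix sums; ties at
boundaries go to the lower class), default k = 5 in the pipeline, matching
the 1–5 integer convention of this literature; the recovery experiment uses
k = 3 because with 14 observations five classes leave ~3 units per stratum
and all factors overfit. The q-statistic uses population variances
(divide by N, N_h) so q = 1 − SSW/SST telescopes exactly. Significance
defaults to a seeded permutation test, p = (1 + #{q* ≥ q}) / (1 + n_perm) —
assumption-free and reproducible; the transformed noncentral-F test of the
geodetector literature is available as an option. Interaction detection
computes q on the overlay of two stratifications (occupied cells only; with
14 units overlay cells are small, a known small-N caveat) and classifies
against the single-factor values with the five standard classes;
"independent" (q_ab = q_a + q_b) uses absolute tolerance 1e−9 since exact
equality is measure-zero in floating point. VIF regressions (each factor on
all others, intercept included, via OLS) run on all unit-years pooled
rather than a single 14-row cross-section; even so, 10 factors on 42 rows
make VIF estimates heavy-tailed, which the screen reports honestly rather
than smoothing away.

## Synthetic province

The generator defines the study conditions; its defaults are fixed, not
tuning knobs:

- **Geometry** — 14 units as a bounded Voronoi tessellation (mirrored-points
  construction) of well-separated uniform seeds on a 500×400 km rectangle.
  Real administrative geometry is not imitated; the polygons only need to
  support area, centroids and point-in-polygon.
- **Panel** — censuses 2000/2010/2020. Base populations lognormal around
  1.2 M; 65+ share starts at 5.5–7.5% and grows at
  `4.0 ± gradient_strength %/yr` (north +, south −; default strength 1.5),
  so northern units are "rapid" (>4 %/yr) and southern "slow", PA rises
  everywhere, and the province-wide rate is ≈4.2 %/yr.
- **Covariates** — ten factors (R1–R3, J1, J2, S1, S2, Z1–Z3) drawn from a
  Gaussian copula with affine marginals (affine maps preserve Pearson
  correlations exactly). The default target keeps density–aging-base at
  0.726 and expenditure–facilities at 0.6272; the remaining two documented
  pairs are shrunk by 0.8 because the four raw values are jointly
  infeasible (the matrix has a negative eigenvalue). S1/S2 are indicator
  covariates, deliberately not derived from the generated facility list.
- **Facilities** — 120 by the final census; the capital unit (nearest the
  region centre) holds ≥ `capital_share` (default 0.3); remaining counts
  follow negative-binomial weights (over-dispersed registry profile, a
  modelling convenience). Establishment years are drawn so the cumulative
  count grows at exactly `facility_growth` (default 2.7 %/yr): a point mass
  of pre-period stock plus a geometric pdf. Facility growth therefore lags
  aging growth by ≈1–2 pp — the supply–demand mismatch regime. Beds
  lognormal around 50.
- **DEM / roads** — a southern plateau (~3200 m) sloping to a northern basin
  (~1000 m) with 12 random Gaussian peaks, on a 100×100 ASCII grid; roads
  are the Delaunay adjacency of unit centres, trunk classes radiating from
  the capital, lengths with a 1.15–1.35 winding factor.
- **Randomness** — one master seed, named CRC-keyed substreams per component
  (geometry/panel/covariates/facilities/dem/roads), so partial re-runs
  reproduce exactly.
- **Outcome generator** — for detector-recovery experiments: each factor's
  k = 3 jenks stratum index contributes `weight × index`, dominant weight
  1.0, all others 0.1, plus N(0, noise_sd); "low noise" is sd = 0.1. Effect
  sizes are returned as ground truth.

What the generator does **not** emulate: spatial autocorrelation of
covariates between neighbouring units, migration flows, within-unit
heterogeneity, facility capacity growth over time, or real census
magnitudes. Passing tests therefore demonstrate correctness of the
statistical machinery and recoverability of designed structure — not that
any real region matches real-world observed values.

## Problem sizes and numerical choices

The default pipeline uses 14 units × 3 years, 120 facilities, a 100×100
DEM, k = 5 detector classes and 999 permutations; the recovery experiment
uses 100 provinces and the type-I-error suite 500 null simulations at
n = 40, n_perm = 199 — sizes chosen so the complete suite exercises every
claim in seconds. Degenerate inputs are defined, not crashed: C(0,0) = 0,
constant normalization groups → 0.5, zero-variance outcomes → q = NaN,
all-zero accessibility → G = 1, zero elderly population → S = NaN, all with
logged warnings.

## Known limitations

- With 14 observations, q values for 5-class stratifications are strongly
  upward-biased and permutation p-values are coarse; interpret the q table
  comparatively, not absolutely.
- The service-area statistic is discontinuous in the budget; the gravity
  mode is smoother and is the pipeline default.
- Accessibility uses the road network only (no raster least-cost paths);
  off-network travel is not modelled.
- VIF on 10 factors at panel scale (42 rows) remains noisy; the screen
  flags, it does not drop.
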