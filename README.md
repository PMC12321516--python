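# eldermatch

Spatial-matching analysis between an aging population and older-adult care
facilities, for health-geography and public-health researchers studying
service equity in topographically complex, resource-constrained regions.
The package chains five stages over a panel of spatial units (e.g.
prefecture-level cities observed at successive censuses):

1. **Terrain-corrected network accessibility.** Travel cost on each road
   segment is free-flow time multiplied by a comprehensive resistance
   coefficient, a weighted overlay of slope, elevation and road-class
   resistances: `R = R_slope·0.4 + R_elev·0.3 + R_road·0.3`, with slope
   classes 0–5° (1.0) … >35° (3.0), elevation classes <1500 m (1.0) …
   >3500 m (2.0), and road classes from highway (120 km/h, 0.8) down to
   rural (20 km/h, 2.0). Per-unit accessibility `S_i` is then either the
   beds reachable within a least-cost budget per 1000 residents aged 65+
   (service-area mode) or an exponentially cost-discounted bed sum
   (gravity mode).
2. **Aging-evolution typology.** Each unit is classified by crossing the
   aging level at period end (`PA`, % of population aged 65+; bands ≤7,
   7–10, 10–14, >14) with the annual growth rate of the 65+ population
   (`V_PA`; rapid if >4 %/yr), giving eight types, plus the growth gap
   `V_PA − facility growth rate` in percentage points.
3. **Lorenz/Gini matching equity.** Units sorted by accessibility per
   elderly resident; `G = 1 − Σ (P_i − P_{i−1})(S_i + S_{i−1})` over
   cumulative shares, banded with the UNDP five-level classification.
4. **Coupling coordination.** With range-normalized subsystems `E`
   (elderly population) and `S` (accessibility):
   `C = 2√(ES)/(E+S)`, `T = αE + βS` (α = β = 0.5), `D = √(CT)`,
   classified into ten bands from extreme imbalance to high-quality
   coordination.
5. **Geographical-detector attribution.** Factors discretized by exact
   Fisher–Jenks natural breaks; factor power
   `q = 1 − Σ_h N_h σ_h² / (N σ²)` with a seeded permutation test (a
   noncentral-F variant is available), pairwise interaction detection on
   stratification overlays, and a VIF screen (`VIF = 1/(1−R²)`) for
   collinearity.

A synthetic-province generator (`eldermatch.synthetic_province`) produces a
complete study region — Voronoi unit polygons, census panel, facility
registry, mountainous DEM, road network — with the statistical structure the
analysis assumes (north/south aging gradient, capital facility
concentration, Gaussian-copula covariates with a density–aging-base
correlation of 0.726), so the whole pipeline runs without any external data.

## Worked example

```bash
eldermatch run-all --seed 1 --outdir out
```

or equivalently from Python:

```python
from eldermatch.pipeline import RunConfig, run_pipeline
paths = run_pipeline(RunConfig(seed=1, outdir="out"))
```

This synthesizes the default 14-unit province (censuses 2000/2010/2020),
writes every stage's table into `out/`, and produces, among others
(`out/gini.csv`):

```
year  G         method            undp_class
2000  0.466897  lorenz_trapezoid  significant disparity
2010  0.411085  lorenz_trapezoid  significant disparity
2020  0.352304  lorenz_trapezoid  relatively reasonable
```

i.e. accessibility is initially distributed very unequally relative to where
the elderly live (G in the 0.4–0.6 "significant disparity" band) and becomes
more balanced as later-established facilities spread beyond the capital.
The detector table (`out/q_table.csv`) ranks the ten covariates by their
power `q` to explain the spatial pattern of the coordination degree `D`, and
`out/interactions.csv` classifies all 45 factor pairs (on this synthetic
region every overlay is enhancing — `q_ab ≥ max(q_a, q_b)` always holds when
overlay cell means fit the outcome at least as well as either margin).

Other verbs expose single stages (`synth`, `access`, `typology`, `gini`,
`coupling`, `detect`, `validate`); `eldermatch validate DIR` schema-checks
an input directory and exits 2 on violations.

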