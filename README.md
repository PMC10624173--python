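# sqimap

Soil-quality-index (SQI) mapping for agricultural land-suitability
assessment, built for soil scientists and land-use planners evaluating a
study area from a gridded point soil survey. The package implements the
full multi-criteria workflow used in GIS-based land evaluation for a
wheat–barley cropping system — from raw soil analyses to a classified
suitability map and its yield-based validation — plus a seeded synthetic
survey generator so every stage is testable without field data.

## The method

Given a survey of *n* soil parameters (texture fractions, bulk density,
hydraulic conductivity, available water capacity, slope, depth, pH, EC,
CaCO₃, organic matter, CEC, ESP and the major/micro nutrients), each
measurement *x* is scored by a **standard scoring function** between a
lower threshold *L* and an upper threshold *U*:

* more is better: `f(x) = 0.1` for `x ≤ L`, `0.1 + 0.9 (x−L)/(U−L)`
  between, `1` for `x ≥ U`;
* less is better: the mirror image (`f(x) = 1` below `L`, `0.1` above `U`).

Criterion weights `Wᵢ` come from the **analytic hierarchy process**:
reciprocal pairwise-comparison matrices on the Saaty 1–9 scale, one per
hierarchy level (physical / chemical / productivity groups, then the
indicators within each group), weights as the normalized principal
eigenvector, consistency certified by `CI = (λmax − n)/(n − 1)` and
`CR = CI/RI ≤ 0.10`. Global indicator weights are the products of the
group and within-group weights.

The index is the weighted linear combination

```
SQI = Σᵢ Wᵢ · Xᵢ        (Xᵢ ∈ [0.1, 1],  Σ Wᵢ = 1)
```

mapped to a 0–100 scale and cut into FAO-style suitability classes
S1 [80, 100], S2 [60, 80), S3 [50, 60), N1 [20, 50), N2 [0, 20).

Surfaces are produced by the best of **15 candidate interpolators**
(IDW powers 1–3; thin-plate, completely regularized and tension splines;
ordinary/simple/universal kriging × gaussian/spherical/exponential
variograms), selected per parameter by leave-one-out cross-validated RMSE.
Non-agricultural areas (settlements, stream beds, ponds, canals) are
masked by polygon, class areas tabulated in hectares, and the map is
validated by ordinary least squares of observed yield (kg ha⁻¹) on SQI
with the conventional `R² = 1 − SS_res/SS_tot`.

## Worked example

Simulate a survey with the default geometry (6.48 × 6.48 km ≈ 4,200 ha,
256 points on a 400 m grid, 24 parameters with realistic means, spreads,
skewness and 800 m spatial correlation), run the whole pipeline, and
validate against simulated yields:

```bash
sqimap run --seed 1 --candidates IDW-power2,RBF-CRS --simulate-yields --out demo
```

prints

```
class  code  area_ha  share_pct
   S2     2   823.77  22.655380
   S3     3  2549.88  70.126977
   N1     4   262.44   7.217643
yield regression R^2 = 0.714
outputs in demo
```

Most of the simulated area lands in the medium class (S3) with good (S2)
and weak (N1) fringes — the profile a semi-arid wheat–barley area
typically shows — and the yield regression recovers the R² ≈ 0.67
association the generator encodes. `demo/` holds the per-point SQI table,
the interpolation leaderboard, the SQI and class rasters (ESRI ASCII), the
area table and a JSON manifest (seed + every method choice) that makes the
run bit-reproducible.

The same stages are available individually (`sqimap simulate / score /
weights / interpolate / classify / validate`) and as library functions:

```python
from sqimap import ahp

weights, reports = ahp.default_hierarchy_weights()
weights["Slope"]            # 0.1232 — the most influential indicator
reports["physical"].cr      # 0.096, consistent (CR <= 0.10)
```

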