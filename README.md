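# lagclust

Spatial-temporal cluster detection for case-control studies with residential
histories.

Disease clusters are usually sought at the residence at diagnosis, which
silently assumes that people never move and that exposure acts with zero
latency. `lagclust` implements a cluster-detection pipeline that takes
residential histories seriously: each subject is represented by the home they
occupied at a *lag* of 0, 5, 10, 15 or 20 years before their diagnosis (or
reference) date, disease risk is modelled as a smooth spatial surface at each
lag, and the lag whose surface best explains case status is chosen by a
formal model-selection step. It is aimed at spatial epidemiologists analysing
population-based case-control studies, and ships a fully seeded synthetic-data
generator so the entire pipeline can be exercised and validated without
confidential subject data.

## The model

For subject *i* with binary case status *Yᵢ*, covariates *Xᵢ* and planar
residential location *s_t* at lag *t* years,

```
logit P(Yᵢ = 1) = α + Xᵢ β + Z_t(s_t)
```

a logistic generalized additive model in which *Z_t* is a bivariate **loess**
smooth (tri-cube weights, nearest-neighbour span, local degree-1 polynomials)
of the lagged locations, fitted by local scoring with backfitting. Dropping
*Z_t* gives ordinary logistic regression; dropping *Xᵢ* gives a crude spatial
model; dropping both gives the intercept-only null model. The moving parts:

- **Span selection** — the loess span (fraction of the data in each local
  fit) is profiled over a grid by AIC = deviance + 2·edf; among local-minimum
  spans within ΔAIC = 3 of the global minimum, the *smallest* span is chosen,
  emphasising local variation in risk.
- **Risk mapping** — model log odds are predicted on a 50 × 50 grid (2,500
  cells) spanning the study area and divided by the null-model odds, so each
  cell reads as a local odds ratio relative to the whole study population
  (OR 1.8 = risk elevated 80%).
- **Cluster inference** — case labels are permuted over the fixed locations
  (999 times by default), the model is refitted at the same span, and cells
  whose observed OR falls in the upper/lower 2.5% of the pointwise
  permutation distribution are classified hot/cold and contoured. This is
  pointwise inference only; it identifies areas of significantly elevated or
  lowered risk, not a family-wise "most likely cluster".
- **Lag selection** — for each lag the smooth is tested by analysis of
  deviance (ANODEV) against the no-smooth reduction, with chi-square df equal
  to the effective-df difference; the lag with the smallest p-value best
  explains risk. These p-values are known to be anti-conservative for smooth
  terms and are reported with that caveat.
- **Inclusion filters** — residences geocoded only to a populated place,
  county or state centroid are dropped; subjects must have usable residences
  continuously covering the full lag window inside the study area plus a
  boundary buffer.

## Worked example

Simulate a single-center study of 300 cases and 300 frequency-matched
controls with a known Gaussian log-odds bump (amplitude 1.0, radius 15 on a
100-unit domain) acting on the residence occupied **20 years** before the
reference date, then run the full pipeline:

```python
import lagclust as lc
from lagclust.simulate import ScenarioConfig, GaussianBump, CovariateEffects

cfg = ScenarioConfig(
    n_cases=300, n_controls=300, centers=("c1",),
    bumps=(GaussianBump(35.0, 35.0, 15.0, 1.0),), active_lag_years=20,
    covariate_effects=CovariateEffects.null(),
    matching_strata=("age_group", "sex"),
    match_level_probs={"exact": 1.0, "intersection": 0.0, "zip_centroid": 0.0,
                       "place": 0.0, "county_centroid": 0.0, "state_centroid": 0.0},
    seed=4,
)
subjects, residences = lc.generate_study(cfg)

report = lc.run_center_analysis(
    subjects, residences,
    lc.AnalysisConfig(lags=(0, 5, 10, 15, 20), covariates=(), adjusted=False,
                      grid_nx=30, grid_ny=30, n_perm=199, seed=5))
print(report.anodev_table().round(4).to_string(index=False))
```

```
 lag model  deviance_with  deviance_without     df  p_value
   0 crude       859.6313          861.4968 3.0443   0.6090
   5 crude       856.5986          861.4968 4.8477   0.4084
  10 crude       848.9829          861.4968 8.1137   0.1355
  15 crude       840.5117          861.4968 7.7428   0.0061
  20 crude       836.4374          861.4968 7.4349   0.0010
```

The ANODEV p-value falls monotonically toward the lag at which the surface
truly acts, and `report.selected_lag` is `20`. At that lag the AIC profile
selects span 0.5, and the 199-permutation map classifies 119 of 900 cells hot
— a hot contour sitting over the true bump — and 117 cold:

```
selected lag: 20
selected span at that lag: 0.5 (global-min)
hot cells: 119  cold cells: 117  of 900
```

The same pipeline is available from the shell:

```bash
lagclust simulate --config scenario.json --seed 3 --out sim/
lagclust run --subjects sim/subjects.csv --residences sim/residences.csv \
             --config analysis.json --out results/
```

which writes per-center span and ANODEV tables (CSV), the OR grid (CSV),
cluster contours (GeoJSON), a rendered map (PNG) and a JSON run report.

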