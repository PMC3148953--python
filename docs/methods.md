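# Methods

This note documents the statistical model, the algorithmic and numerical
choices behind `lagclust`, what the synthetic-data generator does and does
not emulate, and the known limitations. It is the package's own account of
its science; every empirical figure referenced here is computed by the test
suite or by `scripts/acceptance.py`, never asserted.

## Model and fitting

The core model is a logistic GAM for case status,

logit P(Yᵢ = 1) = α + Xᵢβ + Z_t(sᵢ,t),

with one bivariate loess smooth Z_t of the planar residential location at lag
t. The smooth is a surrogate for unmeasured, spatially varying exposures at
that time; the covariates carry the measured individual-level risk factors.

**Loess (`lagclust.loess`).** At each evaluation point a degree-1 polynomial
(intercept + both coordinates) is fitted by weighted least squares to the
k = max(3, ⌈span·n⌉) nearest observations under Euclidean distance, with
tri-cube weights w = (1 − (d/d_k)³)³ for d < d_k and 0 beyond, d_k being the
distance to the k-th nearest point. Conventions:

- Distance ties at d_k include all tied points; their tri-cube weight is
  exactly 0, so the rule is deterministic and order-independent.
- The local normal equations are solved on globally standardized coordinates
  purely for conditioning (the polynomial basis is affine-closed, so fitted
  values are unchanged). A singular local design falls back to the local
  weighted mean with a logged warning; a neighbourhood whose combined
  weights vanish entirely falls back to uniform weights over the
  neighbourhood; d_k = 0 (all neighbours coincident) gives the coincident
  points weight 1.
- Every evaluation is an exact local solve — no surface interpolation — so
  fitted values and grid predictions can be checked against a brute-force
  per-point WLS oracle (the suite requires agreement to 1e−10). A caution
  for test design: at evaluation points where a distance tie plus near-zero
  weights leave fewer than three effective neighbours the local problem is
  genuinely rank-deficient and any two parameterizations may disagree; such
  configurations are measure-zero for continuous coordinates.
- The smoother is linear in the response; the full smoother matrix and its
  trace (effective df of the smooth) are available. At span 1 the local fit
  at every point is the tri-cube-weighted global regression (d_k = the
  largest distance), matching the usual loess convention rather than an
  unweighted OLS.
- Coordinates are assumed planar/projected with commensurate units; no
  standardization is applied before distance computation. A small
  azimuthal-equidistant helper (`histories.project_lonlat`) converts
  longitude/latitude to local planar km for study areas up to a few hundred
  km across; the statistical core never sees spherical coordinates.
- Degree 2 (full quadratic, q_min = 6) is available; degree 1 is the default
  and the standard choice for disease mapping.

**Local scoring (`lagclust.gam`).** Fitting alternates the working response
z = η + (y − p)/(p(1−p)) and weights w = p(1−p) with backfitting between the
parametric part (WLS) and the loess smooth, until the relative deviance
change is < 1e−8 (max 25 outer iterations; inner backfit tolerance 1e−10).
Probabilities are clipped to [1e−10, 1 − 1e−10] to guard the working
quantities at small spans; if more than 10% of fitted probabilities pin at
the bounds a separation warning is emitted. The smooth is identified by
centering to mean zero over the subjects (exactly, at every iteration); the
removed constant is absorbed by the intercept. Effective df of the smooth is
trace(S) at the converged weights minus 1 for the centering constraint — an
approximation in the usual GAM-software sense — and
AIC = deviance + 2·(1 + #covariate columns + edf_smooth). With the smooth
disabled the loop reduces to IRLS logistic regression (verified against an
independent implementation to 1e−6); with everything disabled it reproduces
the closed-form intercept-only null model. Prediction at new locations
re-applies the identical local-fit recipe to the converged partial residuals
and weights, so predicting at a training point reproduces the training
fitted value.

Categorical covariates are one-hot encoded against the first level in sorted
order; the default grid-prediction profile holds continuous covariates at the
analysis-population mean and categoricals at the reference level, and is
recorded in the output.

## Span selection (`lagclust.span`)

AIC is profiled over spans 0.05–1.00 in steps of 0.025 (configurable). The
selection rule: among spans at local minima of the profile whose AIC is
within Δ = 3 (a conventional "meaningful difference") of the global minimum,
take the smallest; otherwise take the global minimizer. On a discrete grid a
local minimum is defined strictly against both neighbouring values (one
neighbour at the boundary); plateaus are compressed and represented by their
smallest span. The rule is invariant to shifting all AICs by a constant, and
the selected span's AIC never exceeds the global minimum by more than Δ.
Small spans are deliberately favoured because they emphasise local structure
in the risk surface; a sensitivity rerun with the global-minimum span is
supported (`SpanProfile.global_min_span`, CLI `--span`).

## Risk mapping and permutation inference (`lagclust.cluster`)

Log odds are predicted at the centers of an nx × ny grid (default 50 × 50 =
2,500 cells) spanning the min/max subject coordinates, optionally masked by a
boundary polygon (masked cells are flagged, never dropped). Each cell's odds
are divided by the intercept-only null model's odds, giving a local OR
relative to the whole analysis population; OR 1.8 reads as an 80% elevation.

Significance is pointwise: conditioning on the locations (covariates stay
attached to their subject), case labels are permuted n_perm times (default
999), the model is refitted *at the fixed selected span* and the OR grid
re-predicted. Tail probabilities use the add-one rank rule (r + 1)/(n_perm +
1) with ties counted toward exceedance (conservative); hot/cold means the
upper/lower 2.5% tail. Failed permutation fits are resampled; more than 5%
failures aborts. Re-selecting the span inside each permutation is not done —
the null conditions on the chosen amount of smoothing and the fixed-span
refit is two orders of magnitude cheaper; neighbourhoods and tri-cube
weights are precomputed once per dataset and reused across refits, which is
an exact reformulation because the locations do not change under the null.
Whether the permutation should respect frequency-matching strata is an open
design question; the default permutes labels unstratified.

Hot/cold regions are contoured by marching squares on the classification
grid and exported in cell-center data coordinates (GeoJSON). Every rendered
or serialized classification carries a pointwise-inference label, because
per-cell error control says nothing family-wise: neighbouring cells share
data through the smoother and 2.5% of null cells are expected hot by
construction.

## Lag evaluation (`lagclust.pipeline`)

For each lag in {0, 5, 10, 15, 20} (configurable) the subject's residence
containing the target calendar year is selected; the span is re-selected per
lag; the smooth is tested by ANODEV against the no-smooth reduction — the
intercept-only null for crude models and, by default, the covariates-only
logistic fit for adjusted models (a config switch allows the null instead).
The deviance difference is referred to a chi-square whose df is the
effective-df difference, non-integer df handled by the continuous (gamma)
form. The smallest p-value selects the lag; ties go to the smallest lag.
Two caveats are attached to every report: these chi-square p-values are
anti-conservative for smooth terms, and the ANODEV is a *global* test of
spatial pattern — a localized cluster can be strongly significant pointwise
while the global test stays unremarkable, and single-realization lag
selection is correspondingly noisy (visible in the acceptance script's
replicate rates).

The selection-bias comparison (`compare_subpopulations`) reruns the lag-0,
age+sex-adjusted analysis on two populations over one shared grid and
reports the Jaccard overlap of their hot cells plus the fraction of the
first population's hot cells reproduced in the second.

### Residence-selection tie rules (`lagclust.histories`)

Calendar years are the data's resolution; "continuous residence" means the
union of [move-in, move-out] year intervals covers every year of the window.
When two residences claim the lag target year: abutting intervals (one ends
the year the other begins) resolve to the later move-in — the home the
subject moved *to* that year; properly overlapping intervals (temporary or
summer homes) resolve to the longest-duration (primary) residence, then
later move-in; an exact tie after both keys is a data-integrity error, not a
silent choice.

## Synthetic-data generator (`lagclust.simulate`)

The generator emulates the statistical structure the analysis assumes, with
defaults chosen once as the package's study conditions:

- 840 cases / 680 controls across four named centers, reference year 2000,
  a 20-year window, a 100 × 100 planar study area.
- Mobility: 1/2/3 residences per subject with probabilities 0.25/0.50/0.25
  (median 2 addresses); the window is cut at distinct random years (each
  interval ≥ 1 whole year, consecutive homes sharing the boundary year) and
  each residence is placed uniformly in the study area.
- Geocoding match levels per residence: exact 80%, intersection 8.8%, ZIP
  centroid 5%, populated place 4%, county centroid 1.5%, state centroid
  0.7% — so the inclusion filters are exercised with realistic attrition.
- Covariates: age ≈ round N(60, 10) clipped to [20, 74]; sex (52% male);
  race (85% white); three education levels (0.20/0.45/0.35); termite
  treatment flag (15%). Default log-odds effects are modest and
  direction-realistic (age +0.15/decade, male +0.20, white +0.30, education
  −0.10/−0.20, termite +0.30); `CovariateEffects.null()` zeroes them.
- Risk surface: a sum of Gaussian bumps amp·exp(−d²/(2·radius²)) — smooth,
  matching loess's assumptions, closed-form for oracles — acting on the
  residence occupied at the configured active lag.
- Labels: a pool of n_cases + n_controls subjects is drawn and labelled
  Bernoulli(expit(b₀ + Xβ + Z)), b₀ = logit(n_cases/(n_cases + n_controls)),
  so the realized case fraction is the requested fraction in expectation and
  the in/out-bump log odds of case status equals the generating amplitude.
- Controls: the requested count is apportioned over the realized case
  margins of the matching strata (age 5-year group, sex, race, center by
  default) by largest remainder — deterministic, exactly reproducible — and
  filled by drawing candidates with the stratum variables fixed, accepted
  with probability 1 − p (population members verified disease-free). This
  preserves the case/control spatial density ratio exactly and keeps an
  explicit failure path: a stratum that cannot fill its quota within the
  sampling budget raises `MatchingError` naming the stratum.

Everything is driven by one `numpy` generator seeded from the config;
identical config ⇒ byte-identical tables.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: real population density (controls and
residences are spatially uniform, so there is no density confounding);
street-level geocoding error; spatially structured covariates (so
confounding of the smooth by covariates is absent by construction);
multi-year diagnosis periods (all subjects share one reference year);
center-specific geographies (centers share one study area and differ only by
label); non-participation mechanisms. The real-data phenomena the pipeline is
designed around — inclusion-filter attrition, frequency matching, mobility
dilution of lagged signals — are represented.

## Problem sizes in the tests and acceptance script

Simulation-backed checks run at reduced scale chosen as the package's own
test conditions: permutation calibration uses 50 null datasets of n = 400
with 199 permutations on 30 × 30 grids (mean per-cell hot rate required in
[1%, 4%] against the nominal 2.5%); signal recovery uses 25 replicates of
n = 600 with a single amplitude-1.0 bump (radius 15% of the domain) active at
lag 20, requiring majority lag-20 selection, ≥ 80% hot-contour overlap with
the true bump at lag 20 and < 50% at lag 0, with the per-lag ANODEV at a
fixed span of 0.4 (span re-selection is exercised separately by the AIC
profile checks). The lag-recovery tests use scenario configs whose geocoding
is all-exact so the analysis n equals the nominal n. The acceptance script
runs the same computations at slightly smaller replicate counts and prints
each quantity with the problem size it used.

## Known limitations

- Pointwise inference only; no family-wise or FDR-corrected cluster claims.
- One residence per subject per model: cumulative/multi-residence exposure
  is out of scope.
- ANODEV p-values for smooth terms are anti-conservative; lag selection from
  a single dataset is noisy and should be read alongside the permutation
  maps.
- edf via smoother-matrix trace is an approximation, and AIC/df conventions
  differ across GAM software; agreement is claimed only to the conventions
  documented here.
- β standard errors are not provided (not needed by the pipeline).
- Centers are analysed separately; no pooled multi-center model.
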