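# Methods

`sdmuq` is a closed-loop simulation laboratory for asking how far statistical
species distribution models (SDMs) can be trusted when projected into a
changing ocean, and where their uncertainty comes from.  Because the "true"
species–environment relationship is simulated, projections can be scored
against a known answer for ninety years into the future — something no field
data set permits.

## 1. Synthetic environmental forcing

The domain is an idealised California Current-like box (30–48 °N, 134–116 °W,
0.5° cells by default, annual spring means 1985–2100).  The coastline is the
eastern boundary; bathymetry deepens strictly westward through a shelf
(~10 m), a slope reaching ~1250 m about 8.5° offshore, and an abyssal plain
(~4.5 km), with a ±4 % along-shore modulation.  Inshore habitat is defined by
depth ≤ 1200 m (≈ 45 % of the box, 586 cells at 0.5°), standing in for shelf
and slope waters.

Seven covariates are generated per pseudo earth-system model (ESM): SST, BT
(bottom temperature, °C), BO (bottom oxygen, mmol m⁻³), MLD (mixed layer
depth, m), CHL (chlorophyll-a, mg m⁻³) and zooplankton integrated over 50 m
and 200 m (mmol N m⁻²).  Each field is

    base(x, y) + trend · amp(x) · (t − 1985) + decadal sinusoid + AR(1) noise,

clipped to physical bounds (BO, CHL, ZOO ≥ 0; MLD ≥ 1 m).  Base fields carry
plausible structure: SST decreases poleward, BT and BO follow bathymetry
(with an oxygen minimum near 700 m depth), MLD deepens offshore, and the
productivity variables concentrate in the coastal band.  Interannual noise is
white in time innovation-wise, AR(1) with φ = 0.5, and spatially smoothed
(Gaussian kernel, 3-cell e-folding).  A 30-year sinusoid is applied to MLD,
CHL and the zooplankton fields, with a different phase per pseudo-ESM, to
emulate decadal ocean variability.

Three default pseudo-ESM "styles" share the base climatology but diverge in
trend: warming of 0.22 / 0.33 / 0.45 °C per decade in SST (mild / middle /
strong futures) with correspondingly scaled declines of MLD, BO and the
productivity variables.  Bottom-variable trends are deliberately small
(≤ 0.1 °C per decade BT) — bottom habitats change far less than the surface,
which is what makes the groundfish archetype the least exposed to
environmental novelty.  Declines of BO and zooplankton by 2100 amount to
roughly 10–30 % of the climatological mean, a realistic strong-scenario
magnitude; an earlier draft with larger declines drove the whole domain novel
and collapsed every population by mid-century, which is not the regime of
interest.  Trends are amplified by up to 1.6× at the coast (decaying
offshore with a 4° e-folding), so the futures disagree most nearshore.

Real forcing can be ingested from NetCDF (classic format via the scipy
engine); monthly files are reduced to March–May means per year.

## 2. Virtual species (operating models)

Three archetypes emulate broad functional types: a highly migratory pelagic
(HMS, driven by SST, MLD, ZOO200; whole domain), a coastal pelagic (CPS;
SST, ZOO50, bathymetry; inshore only) and a groundfish (GFS; BT, BO,
bathymetry; inshore only).  Habitat suitability is the product of per-driver
response curves (Gaussian, logistic or linear-ramp), rescaled by the field
maximum so the best cell-year scores 1.  Suitability converts to presence
through a sharp logistic, p = 1/(1 + exp((s − β)/α)) with β = 0.3,
α = −0.05; presence is a Bernoulli draw.  Where present, biomass is
LogNormal(μ = 2, σ = 0.3) × suitability × M_t, and exactly zero elsewhere
(hurdle structure).  M_t is an annual population-level multiplier: none for
HMS, a two-state boom–bust Markov regime for CPS (stay probabilities 0.8,
levels 2.0/0.25, lognormal jitter σ = 0.2) and a smoothed 20-year low/high
recruitment alternation for GFS (levels 0.5/1.5, 4-year ramps).

Response-curve defaults were calibrated once against the *oracle predictor*
(the exact suitability field with the closed-form hurdle mean), with three
goals: strong historical spatial structure; an oracle pooled training-period
Spearman comfortably above the 0.77 floor that well-specified SDMs are
expected to reach; and end-of-century environmental novelty of roughly
20–40 % for the pelagic archetypes but much less for the groundfish.  The
SDMs themselves were never consulted during calibration.

## 3. Observation design and the chlorophyll proxy

Estimation models never see the full grid: 500 random cells per year (no
replacement within a year) over 1985–2010 for training (n = 13,000) and
2011–2100 for testing (n = 45,000).  The test draw is shared by every
ensemble member of an archetype — including across pseudo-ESMs — so model
comparisons and the variance partition are fully paired.  SDMs are denied
the true prey fields: chlorophyll-a substitutes for zooplankton in their
covariate sets (HMS: SST, MLD, CHL; CPS: SST, CHL, bathymetry; GFS: BT, BO,
bathymetry), mimicking the imperfect prey information available in practice.

## 4. The hurdle-SDM ensemble

Every member is a delta/hurdle model: a binary occurrence submodel fitted to
presence/absence on all training rows, and a Gaussian submodel for
log-biomass on presence rows only.  Combined prediction is
p̂ · exp(μ̂ + s²/2), the bias-corrected lognormal mean, with s² the training
residual variance.  Covariates are never clipped to the training range —
models extrapolate natively, and extrapolation is *measured*, not prevented
(only the log-scale mean is capped at ±300 to keep exp() finite).

Four families:

- **GAM** — penalized cubic B-spline bases (df 8, knots at inverted-CDF
  quantiles) per covariate, a tensor-product lat×lon surface for the spatial
  term, and an unconstrained spline in year for the temporal term.  The
  bases extrapolate polynomially outside the training range; for an
  always-increasing covariate such as year this runs away over a 90-year
  projection, which reproduces the known spatiotemporal-GAM hazard.
- **GLMM surrogate** — standardized linear + quadratic environmental fixed
  effects (the usual way GLM-type SDMs accommodate unimodal niches), a
  low-rank Gaussian radial-basis surface (6×6 knots, bandwidth 1.5× the knot
  spacing) standing in for a spatial random effect, and a linear year term.
- **BRT** — stochastic gradient-boosted trees (LightGBM; 500 trees, depth 3,
  8 leaves, learning rate 0.05, 50 % subsampling, single-threaded for
  reproducibility).
- **MLP** — one hidden layer of 16 units on standardized inputs (L-BFGS).

The GLM-type penalties are expressed per training row (logistic C ∝ 1/n,
ridge α ∝ n, matching how each library scales its objective), which makes
the fits invariant to duplicated data and corresponds to a light penalty
(C ≈ 13) at the 13,000-row design.  Occurrence submodels always output
probabilities; nothing in the pipeline thresholds them.

Covariate parameterizations: E (environmental), S (lat, lon), T (year), their
combinations, and a deliberately under-specified temperature-only variant
(SST, or BT for the groundfish).  The full roster holds 15 family×
parameterization types (the spare slot is BRT_ST, a machine-learning
spatiotemporal variant); the retained ensemble drops GAM_S, GAM_EST and
GLMM_ST for poor projection behaviour, leaving 12 types × 3 archetypes × 3
pseudo-ESMs = 108 members, plus 36 temperature-only members for the
degraded-information experiment.

## 5. Evaluation, novelty, and uncertainty partition

**Skill.** Pooled Spearman rank correlation between true and predicted
biomass per year on the shared 500-cell test draw (ties — the many true
zeros — take average ranks; years with a constant side are undefined and
recorded missing).  Occurrence skill is the Mann–Whitney AUC.  Eleven-year
centered running means (edge windows shrink) smooth displayed series.  Note
that pooled Spearman against a continuous predictor has a tie ceiling below
1 whenever absences receive small but ordered predictions; with ~50 %
absences even the oracle cannot exceed ≈ 0.85.

**Novelty.** ExDet-style: NT1 sums per-covariate range exceedance relative
to the 1985–2010 reference (all domain cells, not just sampled ones); NT2,
computed inside the univariate envelope, is Mahalanobis distance to the
reference mean scaled by the most extreme reference point, with the
reference covariance ridge-regularized by 1e-8 × trace.  A cell-year is
novel if NT1 < 0 or NT2 > 1.  Novelty uses each archetype's SDM covariate
set on its own domain.

**Variance partition.** For each (archetype, region, year) — regions north
(> 40°), central (34.5–40°, boundaries inclusive), south (< 34.5°) and the
whole domain — the regional sum of predicted biomass of each ensemble member
is regressed on three categorical factors: pseudo-ESM (3 levels), family
(4), parameterization (up to 6).  General dominance assigns each factor its
average incremental R² over all subsets of the other factors (the 2³ subsets
are enumerated exhaustively and verified in tests against an independent
normal-equations implementation; the weights sum to the full-model R² by
construction).  Relative shares renormalize the three weights to 1 —
residual variance is excluded, matching a three-component stacked
presentation — and are smoothed with the 11-year running mean.  The
temperature-only experiment re-partitions with the full-E members replaced
by their Temp counterparts.

## 6. Reproducibility and problem sizes

One master seed drives everything; every stochastic component (per variable
and pseudo-ESM in the generator, per truth draw, per sample role, per
ensemble member) gets a SHA-256-derived child seed, so adding a component
never perturbs the others.  The default experiment — 1296 cells, 116 years,
3 pseudo-ESMs, 144 fitted hurdle models, 45,000-row projections, novelty and
the full dominance partition — runs in under 5 minutes on one CPU; stages
are memoized on disk by configuration hash, and per-cell prediction tables
are reduced to annual metrics and regional aggregates immediately rather
than persisted.

## 7. What the synthetic world does and does not show

The generator reproduces the statistical skeleton real downscaled forcing
would provide — divergent trends, decadal cycles, coastal amplification,
spatially coherent anomalies — but not ocean dynamics: no fronts, eddies,
advection or coastline geometry, and the truth contains no density
dependence, movement, age structure or species interactions.  Passing tests
therefore demonstrate properties of the *method chain* (fitting, projecting,
novelty accounting, variance partitioning) under a controlled
data-generating process, not claims about any real species.  Two quirks of
the synthetic world are worth naming: the groundfish's early-century
inter-ESM forcing spread is very small (bottom variables barely diverge
early), so its ESM uncertainty share is low from the start; and the
strongest-warming future collapses the pelagic populations late in the
century, which drags skill down by presence starvation as well as by
covariate novelty.

Known limitations: the GLMM surrogate has no true spatio-temporal random
effect (a low-rank basis with a linear year term instead); dominance shares
exclude residual variance, so "share of uncertainty" means share of the
explained between-member variance; NT2's ridge regularization breaks exact
affine invariance at the 1e-4 level; and the lognormal bias correction
assumes homoscedastic log-scale residuals, which tree and network
submodels only approximate.
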