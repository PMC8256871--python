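# Methods

## Scope and units

One "plant" record is one pot: three seedlings are maintained per pot, but
replication, imaging, watering and harvest all operate per pot, so the pot
is the experimental unit. Days are integers (DAT, days after treatment),
with day 0 the day stress was imposed. Water mass and volume are
interchangeable at 1 g = 1 ml. Image features stay in pixel units: with a
fixed camera geometry and little variation in plant height, no
pixel-to-millimetre calibration is applied.

## Synthetic experiments

The generator emulates a greenhouse phenotyping run at the study's scale:
24 genotypes × 2 water treatments × 3 replicate pots observed daily for 26
days. Latent shoot biomass follows logistic growth

    B(d) = K / (1 + ((K − B0)/B0) e^(−r d)),

with per-pot rate r = base_rate · exp(g) · m, where g ~ N(0,
genotype_rate_sd²) is a genotype log-rate effect and m the stressed-growth
multiplier. Defaults: B0 = 0.5 g, K = 40 g, base_rate = 0.12 d⁻¹, m = 0.5,
genotype_rate_sd = 0.15. These give roughly a four-fold contrast between
well-watered and stressed final biomass — the qualitative pattern of a
saturating stressed trajectory under a continuing well-watered one. An
exponential mode (B = B0·e^{rd}) exists because its RGR is exactly r on
every window, which makes growth-rate recovery an analytic test.
Observation noise is multiplicative lognormal (residual_sd = 0.05).

Genotypes also differ in transpiration per unit biomass
(genotype_wue_sd = 0.10, lognormal on the transpiration coefficient).
Without this, the only genetic signal is the growth rate, whose effect on
RGR-per-water changes sign over the experiment (≈ ε(1 − r·d)) and averages
to no genotype main effect — water-use-index heritability would be
degenerate by construction. A day-stable water-use efficiency effect is
exactly the genetic signal a water-use screening protocol presumes.

Watering follows the platform's target-weight scheme: each day the pot is
weighed, then refilled to tare + dry soil + f·FC, with f = 0.8
(well-watered) or 0.5 (stressed) and FC = 3500 g on 14 kg of soil. Daily
loss is transpiration_coeff (40 ml g⁻¹ d⁻¹) × biomass + 10 ml soil
evaporation, with 3% lognormal noise. The ledger records pre/post weights,
so the analysis recovers water use purely from weights, as on the real
platform.

Image features are noisy monotone functions of latent biomass with
allometric powers: projected areas ∝ B^0.9, linear extents ∝ B^0.35,
perimeter ∝ √area; shape descriptors (compactness, eccentricity, solidity)
are approximately constant. The near-proportional area power reflects
leaf-dominated shoots with roughly constant specific leaf area (mild
self-shading keeps it sublinear); markedly sublinear powers such as the
2/3 of compact bodies would make young-plant biomass inaccessible to any
linear-family model — a line fitted through the harvest-day range then
maps seedlings to negative mass. Powers are configurable per experiment. NIR mean gray is inversely affine in tissue
water fraction (dry plants reflect more). Powers and scales are
configurable; the defaults only claim monotonicity, not photorealism. The
renderer draws elliptical silhouettes whose rasterized pixel count matches
the requested projected area within ~2%; it exists to exercise the
segmentation code, not to imitate plant morphology.

What passing recovery tests on these data do *not* show: robustness to
segmentation failures from occlusion or color drift, allometry mis-match
between genotypes, non-monotone feature responses (wilting), or
autocorrelated watering errors. Real-data behaviour of the model-selection
stage in particular depends on feature quality, not just collinearity
structure.

## Imaging

Segmentation assigns each ROI pixel to the class of its nearest reference
color (plant vs background) in raw RGB Euclidean distance, then erodes and
dilates by configurable radii, drops components below a minimum area, and
composes the survivors into one object. An empty result is a *missing
observation*, not an error. The per-view registry holds 14 geometric
descriptors — projected area, convex hull area, perimeter, bounding-box
width/height/area, maximum caliper (Feret) length, equivalent diameter,
compactness 4πA/P², eccentricity, centroid height, hull solidity, extent,
aspect ratio — so the geometry-only predictor set across the three views
has 42 columns; NIR mean gray under the RGB-derived mask is carried
separately. Whether a real rig's two side rotations should be averaged
rather than kept as separate views is configuration-dependent; they are
kept separate here.

## Biomass models

All eight families consume the same standardized (train-split mean/SD)
geometry predictors; missing cells are mean-imputed inside each training
split, so no statistic leaks across a resample boundary. Tuning grids:
PLS/PC components 1..min(20, p, n−2); elastic-net mixing 0.1..1.0 ×
10 log-spaced penalties; RF 500 trees with mtry ∈ {√p, p/3}; GBM depth
1–3 × 100–500 trees at shrinkage 0.1 (scored via staged predictions from
one 500-tree fit per depth); MARS max 21 terms. Stepwise (SM) is
forward-backward selection by AIC on the linear model. MARS is implemented
here directly — paired hinge bases max(0, x−t)/max(0, t−x) grown greedily,
then pruned backward by generalized cross-validation with the classic
penalty (c = 3 per knot pair).

Per-resample R² is recorded as the squared Pearson correlation of held-out
observed vs predicted values (bounded [0, 1]; the 1 − SSres/SStot form is
stored alongside and is what `compute_metrics` returns). The printed
definition of MAE as a bare difference is implemented as mean absolute
error — the only reading under which it is a positive scalar comparable
across models.

Selection ranks families by (mean RMSE, mean MAE, −mean R²) and then, among
families whose mean RMSE is within one resample standard error of the best,
takes the one with the fewest components/parameters (complexity = component
count for PLS/PC, selected-term count for SM/MARS, nonzero coefficients for
the elastic net; ensembles are never preferred on parsimony). A single
pooled model is fitted across both treatments; fitting per treatment is a
caller choice (filter the tables first).

Predictions below the floor ε = 0.01 g are clipped and flagged; the floor
also guards the RGR logarithm downstream.

The final daily-prediction model is fitted on harvest-day plants but must
predict far smaller plants on earlier days — an extrapolation below the
training response range. Tree ensembles (RF, GBM) predict constants outside
their training hull, so a day-0 seedling would be assigned roughly the
smallest harvest-day biomass and every early trajectory would flatten onto
the same censored value. They therefore remain in the comparison table but
are not eligible as the pipeline's final model; the linear, component,
penalized and hinge families all extend monotonically beyond the training
range.

## Growth rates

Smoothing uses a cubic smoothing spline with the penalty solved to match a
target equivalent degrees of freedom, default min(5, distinct days − 1).
The df→penalty map is found by bisection on the smoother-matrix trace and
cached per day-grid, so a whole experiment costs one calibration. Fewer
than four distinct days cannot support the spline: the series' smoothed
values and derivatives are set to missing with a warning. Interval AGR/RGR
always evaluate the *smoothed* PFB at window endpoints; extrapolation
beyond the fitted day range is refused rather than clamped. Window choices
(2–6, 5–12, 2–12 DAT by default) are parameters, never hard-coded.

## Water use

WU(d) = weight_after(d−1) − weight_before(d) includes transpiration and
soil evaporation, uncorrected — no bare-pot subtraction. Ledger gaps spread
the observed loss uniformly over the missing days (flagged); negative
computed losses (balance drift) are floored at zero and flagged. %FC is
(weight_before − tare − dry soil)/FC × 100. WUI_BM is reported in mg ml⁻¹
(×1000 from g ml⁻¹). Indices are per pot; divide by 3 for per-plant
reporting if needed.

## Variance components and heritability

REML is computed by the profiled penalized-least-squares formulation of the
mixed-model equations: with variance ratios λ_i = σ_i²/σ_e², the REML
deviance is log|A'A + I| + log|X'H⁻¹X| + (n−p)(1 + log 2π r²/(n−p)) with
A = ZΛ and r² the penalized residual sum of squares; λ is optimized on the
log scale (golden-section for one term, Nelder-Mead otherwise, bounds
e±30). Negative components are handled by the boundary (λ → 0) and flagged.
BLUP prediction-error covariances and BLUE sampling covariances come from
the inverse coefficient matrix, giving v̄ΔBLUP and v̄ΔBLUE as means over all
genotype pairs of the variance of a difference. The engine is cross-checked
against R lme4 on a fixture in the test suite.

The default trait model takes genotype random with treatment and DAT fixed;
replicate and G×T, G×DAT, G×T×DAT random (terms with fewer than two levels
are dropped automatically). Treating treatment as random instead is a
one-argument change. For the standard estimator, σp² composes on the mean
basis: each genotype-interaction variance is divided by the number of
levels of its non-genotype factors and the residual by the full
replication multiplier (nT·nDAT·nRep); this is the convention under which
a balanced one-way design gives H² = σg²/(σg² + σe²/r). Cullis is clamped
to [0, 1] and defined as 0 at σg² = 0; Piepho is undefined only when both
σg² and v̄ΔBLUE vanish.

In the pipeline, the heritability trait (default WUI_RGR) is computed over
cumulative windows within the H² window (default 0–21 DAT, thinned to
every 3rd day): RGR(t0→d)/WU(t0→d) per thinned level d. Cumulative windows
keep the rates positive and stable; consecutive short windows pick up
spline-derivative noise and can dip negative at the end of a plateaued
stressed trajectory. The anchor t0 is the first thinned level at which at
least 90% of plants sit clear of the prediction clipping floor, and
floor-level endpoint values are treated as censored (dropped), since a
clipped prediction carries no information about the plant. If the trait is everywhere positive and a
Shapiro-Wilk test on fixed-effects residuals rejects normality at α, the
trait is log-transformed before the REML fit (recorded in the report).

## ANOVA and Duncan's test

ANOVA uses type-II sums of squares on an OLS fit; Shapiro-Wilk on residuals
below α triggers a log(x + offset) refit, with the offset chosen to make
the minimum positive. Duncan's multiple range test uses protected
significance levels 1 − (1−α)^(r−1) for a span of r means, studentized-
range quantiles computed numerically (no tables), and the harmonic mean of
group sizes under imbalance (flagged via the reported n_harmonic). Letters
are maximal runs of mutually nonsignificant sorted means, so letter sharing
is order-consistent by construction. Note the null behaviour implied by the
protection levels: all k groups share one letter with probability
(1−α)^(k−1) under H0 — about 0.90 at k = 3 but 0.81 at k = 5 — which is the
yardstick any null-calibration check must use.

## Numerical choices and problem sizes

Determinism: every stochastic step (simulation, resampling, fold
assignment, forests/boosting) is seeded from the caller's seed; running the
pipeline twice with one seed reproduces the report payload byte-for-byte.
Ties in genotype ranking break by genotype id. Test and acceptance runs use
deliberately compact problem sizes — the default 24×2×3×26 experiment for
the end-to-end and model-comparison checks; 8-genotype, 13-day experiments
for the repeated planted-genotype recovery runs; balanced 24×3 designs for
heritability recovery; n = 60–100, p = 10–42 matrices for the regression
oracles — chosen so the full suite exercises every stage at realistic
shapes while each repeated study stays at seconds per run.

## Known limitations

No thermal-IR analysis, no 3D reconstruction, no leaf-level segmentation.
No narrow-sense heritability or marker-based prediction. The REML solver
uses dense algebra: thousands of random-effect levels are fine, hundreds of
thousands are not. AIC/BIC model comparison is deliberately absent from the
model-selection stage (resampled error is the criterion); AIC appears only
inside the stepwise family. The day-gap spreading policy assumes losses are
roughly uniform across a gap, which understates hot-day variation.
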