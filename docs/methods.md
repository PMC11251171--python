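# Methods

`mycoforest` implements a plot-level pipeline linking the dominance of
ectomycorrhizal (EcM) trees to tree, soil and whole-forest carbon stocks in
high-latitude forest inventories, together with a synthetic-inventory
generator that makes every inferential step testable against known ground
truth. This note records the models, the defaults that matter, and the
choices made where the design was genuinely open.

## Plot-level quantities

**Inventory structure.** A plot is 30 m x 30 m (0.09 ha) of nine 10 m x
10 m subplots; every stem with DBH >= 3 cm is recorded with species, DBH
(cm) and height (m). Plots belong to one of ten ecoregions.

**Tree carbon.** One allometric equation is shared by all species to avoid
species-specific artifacts: ln(biomass kg) = c0 + c1·ln(DBH² · height),
defaults c0 = −2.5, c1 = 0.95 (configurable; the generator and the
estimator use the same form, so carbon recovery is exact by construction).
Biomass converts to carbon with the factor 0.5; plot tree carbon is the
stem sum expressed in Mg C/ha.

**Soil carbon.** Per depth layer i (0–10, 10–20, 20–30, 30–50, 50–100 cm),
SOCD_i = (1 − V_i)·B_i·C_i·T_i/10 with V the gravel (>2 mm) volume
fraction, B bulk density (g/cm³), C organic-C content (g/kg), T thickness
(cm); the /10 makes the product Mg C/ha. V is a fraction in [0, 1]; the
(1 − V) structure forces that reading even where field tables print
percentages, so a percent switch divides by 100 on input. Plot soil carbon
sums the available layers (shallow profiles sum fewer); missing soil data
propagate as missing, never as zero, which is also why soil/forest-carbon
models run on fewer plots than tree-carbon models. Forest carbon = tree +
soil carbon.

**Mycorrhizal dominance.** EcMD = (basal area of EcM species + half the
basal area of dual EcM/AM species) / total EcM+AM+dual basal area; AMD =
1 − EcMD. Species with other strategies (ericoid, non-mycorrhizal; ~1.25%
of a realistic pool) are excluded from numerator and denominator only:
their stems still count toward tree carbon and richness, preserving carbon
mass balance (a config switch extends the exclusion to all quantities for
users who prefer the stricter reading).

**Richness and functional diversity.** Richness is the count of species in
the 900 m² plot. Functional diversity is Rao's quadratic entropy
Q = Σ p_i p_j d_ij over eight leaf traits (Cmass, Nmass, Pmass, Kmass, LA,
SLA, LMA, LDMC). Open choices fixed here: d_ij is the Gower distance
(range-normalized; the traits span heterogeneous units), with
Euclidean-on-z-scores available; p_i are basal-area shares, consistent
with the dominance metric, with stem-count weights available. Trait gaps
are imputed: species-level means where replicate records exist, then the
cross-species trait mean; a trait with no values at all is an error.

**Climate score.** Temperature and precipitation seasonality are z-scored
and summarized by the first principal component of their 2x2 correlation
matrix, sign-fixed so the TS loading is positive: a higher score means
stronger joint seasonality, i.e. a less favorable growing climate. The
axis-1 variance share is reported (it is bounded in [50%, 100%] for two
standardized variables).

## Successional ordination

Importance Values per species and plot: IV = (relative density + relative
cover + relative frequency)/3, each component normalized to sum to one
over the plot's species; measured canopy cover is used when present,
otherwise the basal-area share proxies cover. Relative frequency is the
share of the nine subplots occupied, renormalized across species.

Climax Adaptation Values: designated pioneers are pinned at 1, designated
climax species at 10 (designation comes from the species table's
seral_status column). Every other species is interpolated as
CAV = (10·S_c + S_p)/(S_c + S_p), where S_c and S_p are Czekanowski
percentage similarities 2·Σmin(a,b)/(Σa+Σb) between the species' plot-wise
IV profile and the aggregated profile of the climax resp. pioneer group.
The similarity index is an open choice; Czekanowski on IV profiles is used
because it is the standard percentage-similarity coefficient for
abundance profiles. A species similar to neither group (it never co-occurs
with designated species) receives the neutral midpoint 5.5 with a warning
rather than failing the run (configurable).

The compositional index of a plot is Σ IV·CAV ∈ [1, 10]; sorting it
ascending orders plots along the successional sequence, and an equal-count
tertile cut labels them early/middle/late (qualitative stage concepts give
no numeric thresholds; tertiles are deterministic and balanced, with ties
broken by plot id).

## Inference

**Boundary transform.** Dominance proportions enter models as
y' = (y·(N−1) + 0.5)/N with N the number of plots in the model, keeping
pure-AM and pure-EcM plots off the boundary; 0.5 is a fixed point and the
map is exactly invertible.

**Mixed models.** Each carbon stock is modelled on the natural-log scale
with a Gaussian linear mixed model — "generalized" only in the sense that
the response was log-transformed — with fixed effects EcMD', richness,
stage, climate score, slope, altitude, the two-way interactions
EcMD' x richness, EcMD' x stage, EcMD' x climate, and an ecoregion random
intercept. Continuous covariates and moderators are z-scored within the
sample; EcMD' stays on its natural (0, 1) scale so its coefficient is
directly comparable with the generator's true effect, and standardized
coefficients are reported post hoc as b·sd(x)/sd(y) (stage dummies are
left unstandardized). Wald z inference throughout; models are fitted by
maximum likelihood so AIC is well defined; marginal/conditional variance
explained follows the fixed/(fixed+random+residual) decomposition.
Collinearity is screened with VIFs computed column-by-column from the
design matrix; aliased columns are reported as infinite.

The random intercept is retained only when the likelihood-ratio statistic
for its variance exceeds 3.84 (the chi-square(1) 5% point); a smaller or
non-converged fit is flagged and falls back to OLS. With ~10 ecoregions a
tiny intercept variance is not estimable, and this rule also makes
zero-heterogeneity fits agree with OLS exactly.

**Moderation.** Simple slopes of EcMD' are reported at tertile midpoints of
continuous moderators (three lines: low/middle/high) and at the three
stages, with standard errors from the coefficient covariance.

**Driver screening.** A random forest (200 trees, fixed seed) with
permutation importances ranks {EcMD, richness, stage, climate, slope,
altitude} per response; this is a screen, not an estimator.

**Stability.** The ecoregion-stratified subsampling check redraws
floor(0.5·n_e) plots per ecoregion without replacement (ecoregions have
very unequal plot counts, hence the stratification), refits the model B
times (default 200) and reports per-term sign consistency and replicate
quantiles. Subsampling without replacement is used deliberately, rather
than a classical with-replacement bootstrap, to match the described
half-per-ecoregion resampling.

## Piecewise SEM

The a priori DAG has nodes climate, succession (numeric compositional
index, so standardization is well defined), ln richness, EcMD'
(transformed), functional diversity (Rao's Q) and one ln carbon stock,
with the twelve edges from the three exogenous drivers into EcMD, FD and
carbon, EcMD -> FD, and EcMD/FD -> carbon; the same skeleton is fitted to
each carbon response. Each endogenous node gets its own linear mixed model
(parents as fixed effects, ecoregion random intercept, same
singular-fallback rule), standardized path = b·sd(parent)/sd(child), and
indirect effects multiply standardized coefficients along a route.

Global fit: for every non-adjacent pair, one conditional-independence
claim given the union of the pair's parents, tested on the causally later
node by adding the earlier one to its parent model (Shipley's basis set);
Fisher's C = −2 Σ ln p is chi-square with 2k df under the model, and an
empty basis set is the saturated model (C = 0, p = 1). Pairs of exogenous
nodes are excluded by default — their covariance is free, the
piecewise-SEM convention — but the full construction (whose basis-set size
is exactly node pairs − edges) is available with a flag.

## Fungal community summaries

A guild-annotated OTU table (rows OTUs, columns plots, guild in
{EcM, SAP, other}) is filtered by total abundance (strictly greater than
10 reads across all plots survives), then summarized per plot: guild
relative abundances (they close to 1) and Shannon diversity −Σ p ln p
(natural log, no rarefaction) for all fungi, EcM fungi and SAP fungi.
Each summary is regressed on EcM tree dominance by OLS.

## The synthetic generator

The generator emulates: ten ecoregions of equal plot counts; per plot a
candidate pool of 3–25 species from a 240-species pool (lognormal base
abundances), ~40 stems with DBH 3 + lognormal(1.8, 0.7) cm and heights
from a power law with noise; five soil layers with plausible depth
profiles of bulk density and organic C; TS/PS generated from one latent
climate factor with loading sqrt(0.236), so the climate PCA axis 1
explains ~62% of their variance, a typical axis-1 share for these two
seasonality measures over a large temperate survey region. Strategies are
drawn with P(EcM) = 0.40, P(dual) = 0.05, P(other) = 0.0125 (other
strategies are rare among temperate trees — on the order of one percent
of a regional pool), remainder AM. Traits are lognormal with strategy-linked
shifts (EcM: lower Nmass, higher LDMC); 5% of trait cells are blanked to
exercise imputation. Designated pioneers (15%) are enriched among
high-SLA draws and climax species (15%) among low-SLA draws; every other
species carries a continuous successional affinity in [−0.7, 0.7].
Composition responds to a latent standard-normal succession score via
exp(2.5 · latent · affinity) weights — strong sorting, matching the
near-complete early-to-late turnover (larch/birch/poplar to
conifer-broadleaf mixtures) that the staging concept describes — and to a
per-plot EcM tilt, exp(tilt · strategy weight) with tilt ~ N(0, 1.2),
which spreads realized basal-area dominance over (0, 1).

Ground truth enters in two steps. First the realized predictors are
computed exactly as the metrics module will see them (basal-area EcMD with
the dual split and boundary transform, realized richness z-scored, the
realized climate PCA score z-scored). Then per-plot targets
ln C = intercept + beta_ecm·EcMD' + interactions + nuisance terms +
ecoregion intercept + N(0, sigma_resid) are imposed exactly: stem heights
are rescaled by (target/current)^(1/c1) biomass (biomass scales as
height^c1 under the shared allometry) and layer organic-C contents are
rescaled to the target SOCD. Defaults: beta_ecm_tree = 0.4,
beta_ecm_soil = 0.3, EcMD x climate = +0.15 (stronger effect in harsher
climate), EcMD x richness = −0.15 (stronger effect in species-poor
stands), sigma_ecoregion = 0.3, sigma_resid = 0.3, small nuisance effects
of richness, climate, stage, slope and altitude. One seeded generator per
dataset; identical config and seed reproduce every output byte for byte.

What the generator does *not* emulate — and hence what passing tests do
not show about real data: no spatial autocorrelation within or between
plots, no climate rasters or real seasonality fields, no real taxonomy or
trait covariance beyond the built-in shifts, no measurement error in DBH
or height, equal plot counts per ecoregion, and a generating model that
shares its functional form with the estimator (recovery tests validate
the estimation machinery, not the allometry or the linear-model
assumption themselves). The stage effect is generated from latent-gradient
tertiles while the fitted models use compositional-index tertiles, so
stage misclassification behaves like extra residual noise — independent of
EcMD by construction.

## Problem sizes and numerical choices

Simulation-based checks run at the sizes the recovery properties are
stated for: 2000 plots x 100 replicates for effect recovery (95% CI
coverage and interaction sign), 500 plots x 100 replicates for the
null-effect calibration, 500 simulations of n = 400 for the d-separation
test size, 1000 plots for the succession-gradient recovery. Tolerances:
abundance vectors must sum to 1 within 1e-8; dominance shares satisfy
EcMD + AMD = 1 to 1e-12; the boundary transform inverts to 1e-12; oracle
equivalences hold to relative 1e-12. Ties in stage assignment break by
plot id; degenerate inputs (zero-variance covariates, empty plots,
all-'other' plots, zero-read plots) raise typed errors or propagate as
flagged missing values, never as silent zeros.

## Known limitations

Wald z p-values (rather than Satterthwaite/Kenward-Roger t) are mildly
liberal with few ecoregions; the d-sep calibration shows the practical
size stays near nominal at the sizes used here. The CAV similarity is
computed from the same IV table it later weights, so compositional indices
are not independent across plots. The random-forest screen uses
permutation importance with correlated predictors and should not be read
causally. The fungal generator encodes the expected qualitative guild
shifts; it is a synthetic stand-in, not a fitted model of any real
community.
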