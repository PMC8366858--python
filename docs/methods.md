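# Methods

## Survey geometry

Transects are planar polylines in a metric coordinate system; geographic
inputs are projected with a local equirectangular transform
(x = R·cos(lat0)·Δlon, y = R·Δlat), which is meter-true to well under a
percent over a study area a few degrees across and exactly invertible.
Each transect is tiled into consecutive half-open along-track intervals
[a, b) of nominal length 1,000 m; a sighting is assigned to the cell
containing its along-track projection provided its perpendicular offset is
within the 275 m strip half-width (the surveyed 250 m plus a 25 m GPS
buffer per side, 550 m total width). Boundary ties go to the later cell —
deterministic and order-independent. A trailing remainder shorter than one
cell is kept and flagged partial by default (dropping shoreline-adjacent
habitat would bias covariates); `remainder="drop"` and `"merge"` are
available. Off-strip or past-the-end sightings are logged and counted, never
silently discarded. Count summaries use lower-nearest (type-1) order
statistics so quantiles of integer counts are integers.

## Covariates

Seven linear covariates: yearly NAO index, bathymetry (ETOPO-style
elevation, negative below sea level — this sign convention is what makes a
*positive* NAO×bathymetry coefficient mean "deep water in negative-NAO
years"), sea-floor slope, distance to shore, latitude, and survey-window
averages of wind speed and time between waves.

- **Slope** (degrees): central differences over the 4 rook neighbours
  (one-sided at edges), g = √(gx² + gy²), slope = atan(g). This is the
  simplest faithful reading of "difference of the values between neighboring
  cells" and is checkable against an analytic plane.
- **Distance to shore** (km): planar minimum from the cell center to the
  shoreline polyline.
- **Buoy interpolation**: inverse distance weighting with power 2 (the
  conventional default; configurable), distances on the projected plane. IDW
  is exact at buoy sites and bounded by the observed range. Daily surfaces
  are averaged over the year's survey dates.
- **NAO**: the February value of the survey year (surveys are flown in
  February); a monthly CSV reader supports other choices.
- **Standardization**: z = (x − mean)/sd with sample sd (n−1), constants
  stored for prediction on new data; quadratics and interactions are
  products of standardized linear columns and are *not* re-standardized.
- **Collinearity screen**: |Pearson r| among the linear covariates, warning
  (not error) at ≥ 0.6.

The design matrix has 14 fixed-order columns: intercept, nao, bathy,
bathy², slope, dist, dist², wind, wind², wave, wave², latitude, nao×bathy,
nao×dist.

## Model and sampler

Counts are NB with size r and mean mu, log mu linear in the 13 terms;
p = r/(r + mu). Selection is Kuo–Mallick: beta_k = gamma_adj_k · delta_k,
gamma_k ~ Bernoulli(0.5), delta_k ~ Normal(0, sigma),
sigma ~ InvGamma(1, 1), r ~ Uniform(0, 10), beta0 ~ Normal(0, 0.01).
Strong heredity multiplies indicators: gamma_adj for a quadratic or
interaction is its own gamma times its parents' gammas.

The Normal(0, 0.01) prior is ambiguous between precision and variance
conventions. Default is `bugs-precision`: beta0 sd 10, and sigma is the slab
*variance* (conjugate with the InvGamma prior). The `moment` convention
(variance 0.01) is a switch, and every fit records which was used.

One Metropolis-within-Gibbs sweep updates:

1. beta0 — random-walk MH;
2. each delta_k — RW-MH when the term acts (gamma_adj = 1); otherwise the
   full conditional is the slab prior and delta_k is refreshed from
   Normal(0, sigma) (the Kuo–Mallick scheme);
3. each gamma_k — its exact two-point full conditional via the likelihood
   ratio with gamma_adj recomputed (flipping k also toggles its children);
   when a term is gated out by an absent parent the likelihood is flat and
   the conditional reduces to the prior;
4. sigma — conjugate InvGamma(1 + 13/2, 1 + Σdelta²/2);
5. r — RW-MH on log r with the uniform bound enforced;
6. (zero-inflated families) the intercept-only inflation weight
   w ~ Uniform(0, 1) by RW-MH on logit w.

Proposal scales adapt toward 44% acceptance (the 1-D RW optimum, inside the
conventional 20–50% band) during a discarded adaptation phase and are frozen
afterwards to preserve detailed balance. Chains start from dispersed points;
all randomness flows from one `SeedSequence`, so runs are bit-reproducible.
Convergence is monitored with classic split-chain Gelman–Rubin R-hat on
beta0, sigma, r and every beta with inclusion > 0.2; failures are flagged in
the output metadata, never ignored.

ZIP/ZINB variants put the same covariate structure on log mu and an
intercept-only mixture weight at zero — the minimal structure consistent
with the comparison being made.

Reported summaries: inclusion probability per term is the posterior mean of
gamma_adj (the probability the term *acts*, respecting heredity; raw gamma
is also available), and P[beta > 0] counts spike draws (beta exactly 0) as
not positive, with a slab-conditional alternative.

### Behaviour worth knowing

- With every indicator frozen at 0 the (delta, sigma) subchain targets its
  joint prior exactly — the basis of the conjugacy test — but mixes slowly
  (lag-1 autocorrelation ≈ 0.9, because sigma feeds the refreshed deltas and
  back), so distributional checks thin to near-independence first.
- Under informative null data the inclusion probability of a *linear* term
  is well below the 0.5 prior: the Bernoulli conditional compares the
  likelihood at a prior-drawn slab value against zero, and the data penalize
  spurious effects (Occam/Lindley shrinkage). Only terms that carry no
  information — higher-order terms gated out by absent parents — sit at the
  prior. This is correct behaviour of the method, not a sampler artifact,
  and it is what makes null-term exclusion sharp.

## Model checking

Freeman–Tukey discrepancy T(y, mu) = Σ(√y − √mu)². For each retained draw,
mu is computed, a replicate is simulated from the fitted family, and
p = mean(T_rep ≥ T_obs) (ties inclusive — conservative). Lack of fit is
flagged two-sided at 0.1/0.9. The check is seeded independently of the fit
and may evenly subsample draws for speed.

## Prediction

"Relative abundance" is the posterior expected count per 1,000 m × 550 m
cell — the model's native unit, no density rescaling. Summaries are the
posterior mean and equal-tailed 95% interval of mu over draws. Interaction
curves standardize a raw bathymetry grid and raw NAO levels (default −3.9,
−1.4, 2.8, spanning the observed index range) with the *fitted* constants,
hold all other covariates at their means, and evaluate per draw. Requests
outside the fitted covariate range warn (extrapolation) but proceed; a
constants checksum guards against predicting with mismatched
standardization. Coarse presentation maps average cell-level posterior means
within 0.3° blocks.

## Synthetic studies

The generator emulates the survey's statistical structure, not its
oceanography:

- **Seascape**: a north–south coastline with a gentle sinusoidal wiggle;
  depth = −(shelf gradient)·(offshore km) + smoothed seeded noise (repeated
  box-blur of white noise — simple and oracle-friendly), clipped to ≤ 0
  offshore. The shelf gradient varies smoothly alongshore so depth is not a
  pure function of offshore distance; without this, bathymetry and distance
  to shore would be collinear at |r| ≈ 0.95, violating the < 0.6 condition
  the analysis assumes.
- **Transects**: east–west, spaced 5 nm in latitude (2.5 nm in 2012),
  length the longer of 14.8 km or the run to the 16 m depth contour.
- **Buoys**: 20 wind / 9 wave-period stations spread along the coastal
  strip (stratified latitudes — real networks are deliberately dispersed),
  with low-order oscillatory mean fields in latitude, persistent site
  offsets, and AR(1) day-to-day noise, truncated to physical ranges. The
  oscillatory (non-monotone) structure keeps the interpolated fields from
  collapsing onto the latitude covariate, and the small daily noise keeps
  chance year-level correlation with NAO low. With these defaults the
  maximum pairwise collinearity is typically 0.3–0.5.
- **NAO**: one value per year, Uniform[−4, 3] (bracketing the observed
  index range) unless given explicitly.
- **Counts**: drawn from the model's own generative process; flock sizes
  arise purely from NB overdispersion (no explicit flocking process), which
  suffices for the zero-heavy/huge-max pattern. Counts are then scattered
  into point sightings inside their cells and re-gridded through the real
  survey module, so the response has passed through the same geometry code
  as real data.

Presets: `null` (no effects, baseline 2.3 birds/cell), `paper_like` (the
three strongly-supported effects: bathy +0.5, slope −0.8, wave +0.6, with
r = 0.2), `paper_like_interaction` (adds NAO +0.3 and NAO×bathy +0.5,
heredity-consistent), `dense` (all 13 terms at ±0.3). At r = 0.2 the
baseline gives ≈ 60% zeros, median 0 and maxima in the hundreds at desk
scale. An r as small as the ~0.005 reported for the real four-year dataset
makes single observations nearly uninformative; recovering effects under it
requires the full ~17,000-cell dataset, so the desk-scale preset uses a
value that keeps strong overdispersion while leaving the ~2,000-cell study
informative. What passing tests show, therefore, is that the *method* is
correct and well calibrated under the assumed structure — not that real
surveys carry equivalent information, and not anything about detection
probability, spatial autocorrelation, or bird movement, none of which the
generator emulates.

## Problem sizes

The standard synthetic study spans 1.4° × 2.3° at 500 m raster resolution,
yielding ≈ 2,700 cell-years (≈ 2,000 are used where a fixed size is wanted).
Routine fits use 3 chains × 1,200 retained draws after 400 adaptation + 400
burn-in; distributional checks and replicate experiments use single chains
or longer thinned runs as noted in the tests. A full fit takes a few seconds
on one CPU.

## Known limitations

- Detection probability is not modelled (the survey could not estimate it);
  counts are relative, not absolute, abundance.
- No spatial random effects or temporal autocorrelation; cells are
  conditionally independent given covariates.
- The equirectangular projection is for regional extents; a continental
  analysis would substitute a proper projected CRS.
- IDW is the only interpolator (no kriging), matching the original
  analysis choice.
- The ZIP/ZINB inflation component is intercept-only; covariate-dependent
  inflation is out of scope.
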