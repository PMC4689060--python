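# Methods

This note documents the models, the synthetic data-generating process,
the numerical choices, and the limits of what the test suite can show.
All coordinates are planar metres; intensities are reported per km².

## Problem setting

Built-environment studies relate children's physical activity to the
availability of urban point characteristics — street intersections,
public transit stations, public open spaces — around the home. Two
methodological choices dominate the results: how point availability is
measured (a count per area versus a smoothed kernel intensity, and with
what bandwidth), and at what spatial scale the neighborhood is drawn
(the modifiable-areal-unit / uncertain-geographic-context problem). The
package implements both axes jointly: seven intensity measures × six
network-distance neighborhoods, linked to accelerometer-derived
moderate-to-vigorous physical activity (MVPA) through gamma log-link
regression, so the pattern of effect estimates across measures and
scales can be studied on synthetic data with known truth.

## Intensity measures

Point layers are modelled as planar point processes on the study window
W. The seven per-neighborhood exposures are:

1. **simple** — #{s_i ∈ A}/ν(A), the point count per km² of the
   neighborhood polygon A (boundary-inclusive).
2. **fixed** — mean over A of the Gaussian-kernel intensity surface with
   σ_f = 500 m.
3. **mse_cv** — as 2, with σ chosen by Berman–Diggle style MSE
   cross-validation.
4. **lscv** — as 2, with a full 2×2 bandwidth matrix Σ chosen by
   least-squares cross-validation (elliptical kernel).
5.–7. **\*_adaptive** — each kernel measure with its bandwidth rescaled
   by the factor (2000 / R_A), where R_A is the residential density
   (residents/km²) of that child's neighborhood at that distance and
   2000/km² is the pilot density at which the bandwidth is unchanged.
   Denser neighborhoods get narrower kernels, sparser ones wider. R_A is
   floored at 100/km² so near-empty fringes cannot blow the bandwidth up
   without bound. Anisotropic bandwidths scale their covariance by the
   squared factor so the *linear* spread scales exactly like the
   isotropic case, keeping the three adaptive measures commensurate.

### Edge correction

The kernel mass that a point near the window boundary loses outside W
must be compensated. `edge_correction()` returns the classical weight
w(s) = 1/m(s), m(s) = ∫_W K_Σ(u−s) du. For surfaces, the default is the
per-data-point (Diggle 1985) form λ̂(s) = Σ_i K_Σ(s−s_i)/m(s_i), which
conserves mass exactly (∫_W λ̂ = n up to grid discretization, which for
Gaussian kernels and midpoint sums is spectrally small). The
evaluation-point ("uniform") form w(s)·Σ_i K_Σ(s−s_i) is available via
`correction="uniform"`; it is pointwise unbiased for an inhomogeneous
Poisson intensity but only approximately mass-conserving — for
bandwidths comparable to the window size its integral can be several
percent off n, which is why it is not the default. The two coincide as
the bandwidth becomes small relative to the window.

Masses on rectangular windows use the closed-form Gaussian rectangle
probability (Φ-products for diagonal Σ, the bivariate normal CDF
otherwise, with a 6-SD interior short-circuit); general polygonal
windows fall back to midpoint summation on the surface grid.

### Bandwidth selection

**MSE-CV.** The criterion is
M(σ) = ∫_W λ̂_σ(s)² ds − 2 Σ_i λ̂_σ,−i(s_i),
with λ̂ the edge-corrected surface, the integral a midpoint sum on the
surface grid, and λ̂_−i leave-one-out values at the data points — the
standard least-squares/MSE cross-validation identity for intensity
estimation. The search grid is 32 geometric steps from the cell size to
a quarter of the window diameter; ties break toward the smaller σ. The
criterion is translation-invariant and scale-equivariant (σ_CV scales
linearly with coordinates), which the tests verify. A caveat verified in
testing: with exactly duplicated points every leave-one-out criterion
degenerates (the duplicate contributes K_σ(0) → ∞), and the arg-min
collapses to the smallest grid value; duplicated layers should be
deduplicated or jittered before selection if that is not wanted.

**LSCV.** LSCV(Σ) = ∫ f̂² − (2/n) Σ_i f̂_−i(s_i) has a closed form for
Gaussian kernels (Gaussian convolution identity), minimized over SPD
matrices via a 3-parameter log-Cholesky parametrization with
Nelder–Mead from six deterministic starts (isotropic pilot ± octave
scalings, one sheared start). LSCV surfaces routinely carry several
local minima whose objectives differ by a fraction of a percent but
whose shapes differ substantially; among converged minima within 2 %
(relative) of the best objective the most-smoothing one — largest
|Σ| — is selected, the standard guard against spurious small-bandwidth
LSCV minima. Even so, LSCV bandwidths are noisy (the relative error of
cross-validated bandwidths decays like n^(−1/10)): on isotropic
Gaussian samples of n = 200 the selected axis ratio has median ≈ 1.2
but a heavy right tail, so single-sample axis ratios are not a reliable
isotropy test. What is reliable, and what the tests assert, is the
*ordering*: a 4:1 anisotropic sample virtually always yields a larger
selected axis ratio than an isotropic one of the same size.

Two guards keep the selector usable on awkward layers: tie-break
candidates whose kernel spread exceeds half the window diameter are
dropped when an alternative exists (plateau minima equivalent to "no
structure"), and a degenerate selection — spread beyond half the window
or below 1 m, the classic LSCV failure on exactly gridded point sets
such as lattice intersections — falls back to the isotropic pilot
bandwidth, flagged in the result's diagnostics and provenance.

## Network neighborhoods

Residences are snapped to the nearest street edge (deterministic
lowest-edge-id tie-break; snap distances > 250 m are warned about as
outside the urban fabric). Single-source shortest paths from the snapped
origin delimit the reachable sub-network at each of the six distances
(500, 750, 1000, 1250, 1500, 2000 m); partial edges are cut at the exact
residual distance, including both-end and through-origin reaches merged
per edge. The neighborhood polygon is the union of reached fragments
buffered by 25 m (configurable; a documented sensitivity axis), and
ν(A) its area. Reached edge sets and polygons are nested across
distances by construction. R_A is the area-weighted raster mean over the
polygon with exact cell clipping.

**Privacy blurring.** Homes are displaced by bivariate Gaussian noise
with SD = c/density(home), c = 1.7·10⁵ m·residents/km², so the median
shift is ≈ 57 m at the default city's peak density (inside the 50–100 m
band appropriate for dense areas) and the displacement SD is capped at
100 m via a 2000/km² floor on the density used — blurring protects
privacy without invalidating the exposure assessment. Draws leaving the
window are rejected and redrawn (bounded). Kernel-based exposures at
≥ 1 km are nearly unaffected (ρ > 0.9 with/without blurring); the
count-based simple intensity is the blur-sensitive one, consistent with
its general instability.

## Accelerometry

15-s epoch counts per child. Non-wear is any maximal within-day run of
≥ 120 consecutive zero epochs (30 min); runs never merge across a
non-zero epoch, and days are processed independently (a documented,
configurable simplification — runs do not span midnight). An epoch is
MVPA if its count reaches 2298 cpm when scaled to counts per minute:
≥ 575 counts per 15-s epoch (2298/4 = 574.5, ceiled because counts are
integers). A 60-s re-integration mode (sum four epochs, classify the
block) is available behind a flag. A day is valid with ≥ 8 h weartime
after non-wear exclusion; a child is included with some run of ≥ 3
consecutive valid calendar days containing a weekend day; habitual MVPA
is the mean over *all* valid days (window-only averaging is a config
option).

## Gamma log-link regression

MVPA is positive and right-skewed, so Y ~ Gamma(shape ν, mean μ) with
log μ = Xβ. For this family and link the score for β does not involve
ν, so the IRLS solution (statsmodels GLM) is the full MLE of β; ν̂ is
then the 1-D ML solution of log ν + 1 − ψ(ν) = mean(log μ̂ − log y +
y/μ̂) (full ML, not the Pearson moment estimator, so AIC is a true
likelihood quantity — this deliberately differs from some software
defaults). Wald p-values use cov(β̂) = (XᵀX)⁻¹/ν̂. AIC counts the shape
parameter, AIC = −2ℓ + 2(k+1); the convention without it is reported
alongside (`aic_excl_shape`). Reference levels: medium ISCED, no safety
concerns, autumn/winter season. Strata: school (6–9.9 y) / pre-school
(2–<6 y) × all / boys / girls; sex is never a covariate inside sex
strata, and exposures enter the basic model one at a time. Raw p-values
are reported across the measure × distance grid without multiplicity
adjustment, matching the descriptive use of the pattern tables. MVPA
values of exactly 0 (possible under synthetic nulls) are dropped with a
warning since the gamma likelihood requires positivity.

## Synthetic city and cohort

The generator provides the statistical structure the analysis assumes,
with every default chosen once:

* **Street network**: a lattice at 100-m spacing with 15 % random edge
  dropout (retried, bounded, until the largest component holds ≥ 90 %
  of nodes). Intersections are nodes of degree ≥ 3, the standard GIS
  convention.
* **Residential density**: a truncated anisotropic Gaussian gradient —
  the simplest shape that exercises both the adaptive bandwidth and the
  anisotropic kernel — peaking at 3500/km² in the center, floored at
  300/km², with 2:1 elliptical elongation; the default 3.2 × 2.5 km
  window then holds ≈ 8500 residents (≈ 1100/km² city-wide, the ballpark
  of a mid-sized north-German town).
* **Point layers**: transit 4.0 and open space 3.5 points per 1000
  residents (giving city-wide intensities of a few points/km², the
  right order for these characteristics), placed by an inhomogeneous
  Poisson draw with intensity ∝ residential density; optional
  Neyman–Scott (Thomas) clustering with configurable cluster SD. This
  placement creates the exposure–density confounding the adaptive
  bandwidth is designed to address.
* **Cohort**: 75 % school-age, 51.5 % girls, per-age-group ISCED shares
  (school 23/56/21 %, pre-school 13/72/15 %), safety-concern
  probability 35.3 % (school) / 47 % (pre-school), 29 % spring/summer,
  weartime ~ N(11.5, 1.2²) h clipped to [8, 16]. Category counts are
  allocated exactly (largest-remainder) and randomly paired with
  children, so printed shares match the configuration while assignments
  stay random. Homes are sampled ∝ residential density.
* **Outcome**: MVPA ~ Gamma(ν = 8) — matching a ≈ 60 (23) min/day
  mean (SD) — with log-linear mean in centered age (−6 y), BMI z-score,
  centered weartime (−11.5 h), season, safety concerns, ISCED dummies
  and the built-environment exposure; default multiplicative effects
  mirror a school-age basic model (season 1.17, safety 0.86, BMI 0.95,
  weartime 1.04, exposure 1.10 per intensity unit).
* **Screening**: the worked sample-accounting example generates the
  400-child analysis sample with exact marginals and adds 24
  rural-peripheral plus 24 missing-questionnaire children on top of it,
  because marginals are reported for the analysis sample, not the
  baseline.
* **Epochs**: a 07:00–21:00 wear window, configurable injected non-wear
  bouts placed mid-window, and MVPA-level counts on exactly
  (noise="none") or binomially on average (noise="poisson") habitual×4
  worn epochs per day. The deterministic mode exists so the
  accelerometry chain can be round-trip tested to the epoch.

What the generator does **not** emulate: realistic road topology,
intra-personal day-to-day MVPA structure beyond wear/non-wear, spatial
autocorrelation of covariates, self-selection into walkable areas, or
seasonal confounding between geography and assessment time. Passing
tests therefore certify the estimators and their interplay, not the
epidemiology of any real town.

## Replication designs used in testing

Two simulation harnesses deliberately hold the spatial design fixed and
redraw only the gamma outcomes: the end-to-end recovery check (exposure
effect 1.10, n = 400, 50 replicates, CI coverage ≥ 90 %) and the
measure-stability property (below). Fixing the design isolates the
inference machinery from spatial re-randomization and keeps the suite
fast; coverage is then over noise realizations at a fixed design, the
standard conditional-simulation reading. The recovery harness plants
the effect on the quantity the pipeline itself measures (mean
fixed-kernel open-space intensity in the 1-km neighborhood, unblurred),
so there is no errors-in-variables gap between truth and measurement.

The stability property — with a distance-constant true effect, the
across-distance range of exp(β̂) under LSCV-kernel exposure is at most
that under simple-intensity exposure — is evaluated on a fixed 6.4 ×
5 km city (32 km²), with cohorts and outcomes redrawn. Two findings of
the testing process are worth stating plainly. First, the scale
relation matters: in a city where 2-km neighborhoods cover a large
share of the window, between-child exposure variance collapses at the
top distances and slope rescaling dominates every measure, destroying
the contrast — neighborhoods must be local to the window, as in any
real study region. Second, the property is a statement about one study
region at a time, not about cities on average: across random city
realizations the win fraction varies widely (individual realizations
can fail through a small Poisson layer draw, a degenerate LSCV
bandwidth selection, or an unusual exposure-variance profile), while
within a given region it is stable across cohorts. The tests therefore
fix the demo region — mirroring a single-site study design — and vary
the cohort; single-region results about measure stability should not
be read as universal.

## Numerical choices

* Surface grid: 25-m cells by default (50 m in the fast demo paths);
  all window integrals are midpoint sums on that grid.
* Gaussian grid sums are spectrally accurate for σ ≳ the cell size, so
  mass-conservation and quadrature checks hold to ~10⁻⁶ or better.
* Adaptive factors within 10⁻¹² of 1 are snapped to exactly 1 so the
  constant-density coherence property (adaptive ≡ parent at R_A = 2000)
  holds record for record in floating point.
* Service-area fragments merge overlapping intervals per edge with a
  1-nm tolerance; full edges reuse their geometry without substring
  extraction.
* The pipeline fans one root seed into named per-stage streams
  (CRC32-keyed), so changing one stage's seed leaves the others
  untouched; after each stage the in-memory cache is dropped and
  downstream stages read the written files, making an interrupted and
  resumed run byte-identical to an uninterrupted one.
* GeoJSON is read and written directly (plain JSON features, CRS-free
  planar metres); importing data whose coordinates all fit in the
  lon/lat box is rejected with a pointer to external reprojection.
  Surfaces and density rasters round-trip as ESRI ASCII grids with a
  JSON sidecar for bandwidth provenance.

## Known limitations

* Kernel densities are planar; network-constrained kernels and
  per-point (Abramson-style) adaptive bandwidths are out of scope.
* The simple intensity's polygon-based count (rather than counting on
  raw network fragments) is a convention choice; it is configurable and
  cannot be verified against the original workflow.
* LSCV bandwidth selection remains high-variance at realistic layer
  sizes; the pipeline reports its diagnostics (all local minima and the
  tie-break) so degenerate selections are visible.
* The multi-level daily-MVPA model and finer age stratifications are
  intentionally not implemented.
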