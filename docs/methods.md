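# Methods

This note documents the models, conventions and numerical choices the
package implements, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Forest-history reconstruction

A pixel's annual land-cover series (forest = 1, anthropic = 0) is
classified in the final year:

* **old-growth** — forest in every observed year. Forests cleared and
  regrown entirely before the observation window cannot be detected;
  they are mislabelled old-growth, an unavoidable left-censoring of the
  age distribution.
* **secondary** — forest in the final year after at least one anthropic
  year. Age = length of the uninterrupted trailing forest run (age 1 =
  regrew in the final year); with n annual layers ages span 1..n−1.
* **anthropic** — non-forest in the final year. Any earlier secondary
  episode is discarded; age accounting restarts at the next
  anthropic→forest conversion.

The **deforestation count** is the number of forest→anthropic
conversions before the current regrowth onset. A pixel that is already
anthropic in the first layer was converted before the window; its count
is floored at 1 so that "1" always means "only the original conversion"
and counts ≥ 2 mean repeated clearing. Any nodata year makes the pixel
nodata — age is undefined across gaps (the real annual products are
gap-free, so this is conservative).

Secondary pixels are grouped into connected components (8-neighbour by
default, configurable) and components under **9000 m²** (10 Landsat
pixels, about one cell of the coarse biomass product) are dropped; the
threshold is inclusive (≥). A patch's representative age and
deforestation count are the modal values over its member pixels with
ties broken toward the smaller value; a patch is *burnt* if any member
pixel intersects any annual burned-area mask, and *repeated* if its
representative count is ≥ 2. Patches are contiguous secondary areas
that may span ages; per-age sub-polygons would be an alternative
delineation and the mode is the aggregation chosen here.

## Drivers

**MCWD.** Within a year the cumulative water deficit follows
CWD₁ = min(0, P₁ − E), CWDₙ = min(0, CWDₙ₋₁ + Pₙ − E) with a fixed
evapotranspiration demand E = 100 mm month⁻¹; the year's MCWD is the
most negative monthly CWD and the driver is the mean over years
(mm yr⁻¹, always ≤ 0). Windows reset each January by default; an
``anchor_month`` option supports hydrological-year windows, since the
windowing convention is genuinely open — the calendar default
understates deficits that straddle December/January.

**Resampling** between grids is nearest-neighbour (cell-centre rule):
values are replicated or subset, never interpolated, which is safe for
categorical layers and invents no smoothing.

**Binning** of continuous drivers uses half-open intervals
[bᵢ, bᵢ₊₁) with breaks either explicit or at the 25/50/75th
percentiles (linear interpolation) of patch-level values — the patch,
not the pixel, is the analysis unit throughout.

## Space-for-time substitution and the growth model

Biomass is converted to carbon at AGB = 2·AGC. Patch AGC is the
**zonal mode**: values are binned to 1 Mg C ha⁻¹ (a raw mode on
near-continuous rasters is degenerate; the bin width is configurable),
ties go to the smaller bin, and the reported value is the median of the
raw values in the modal bin, so constant surfaces are returned exactly.

Per group (driver category, or climate region × disturbance class),
patch AGC is aggregated to the **median per stand age**, and a **bias
correction** subtracts the smallest per-age median so the curve starts
at or near zero for the youngest stands. The same offset is subtracted
from the group's old-growth median AGC, which becomes the fixed
asymptote A. The offset equals the youngest observed age's median, not
exactly Y(0) = 0; for sigmoidal curves (c > 1) the distortion is a few
tenths of a Mg C ha⁻¹, but in groups whose youngest stands are old the
offset can be large — parameter estimates from such groups should be
treated with caution (the noise-free end-to-end tests quantify this:
a few percent on (k, c) for age-1-anchored groups).

The **Chapman–Richards** curve Y(t) = A(1 − e^(−kt))^c is fitted to the
corrected medians by bounded nonlinear least squares (scipy
``curve_fit``, trust-region reflective), one point per age, unweighted
(optional per-age-n weighting is available). Initialisation is
k₀ = 0.1 yr⁻¹, c₀ = 1; on failure a 4×4 restart grid
(k ∈ {0.01, 0.05, 0.1, 0.3} × c ∈ {0.5, 1, 2, 4}) is tried and the best
objective kept; if no start converges the group is flagged and excluded
rather than forced — this happens in thin disturbed groups whose tables
are degenerate (e.g. three rows, two of them zero). Confidence
intervals are asymptotic t-intervals from the curvature by default;
a residual-resampling bootstrap (default 1000 refits, seeded) is
available where the extra cost is warranted. Fits live in
bias-corrected AGC space; comparisons with raw AGC must re-add the
group offset.

Derived statistics: the mean accumulation rate over the first n years
is Y(n)/n (n = 20 by default); the time to reach a fraction f of the
asymptote is the smallest integer t with Y(t) ≥ f·A, with the closed
form t* = −ln(1 − f^(1/c))/k reported alongside. The curve never
attains A, so "reaching old-growth carbon" needs a threshold; the
default is f = 0.9, a choice this package makes explicitly
(configurable) rather than a convention inherited from elsewhere.

## Driver importance

Stand age plus the six drivers are ranked by **marginal permutation
importance** on a random-forest regressor: each of 30 iterations draws
a stratified subsample (n = 2500 biome-wide, 1500 for per-region runs;
proportional allocation over the stratum column), trains 500 trees on
80%, and measures permutation importance on the held-out 20%
(5 permutations). Importances are converted to within-iteration ranks
(1 = least … 7 = most important; ties broken alphabetically for
determinism) and only the mean rank ± 95% CI across iterations is
interpreted — absolute importances are not comparable across runs.
Tree controls are the classical regression-forest settings (p/3
candidate features per split, minimum leaf size 5). This is not the
conditional permutation importance of conditional-inference forests:
correlated drivers share credit here, so rankings among strongly
correlated climate variables should be read loosely. The per-iteration
raw importances are kept in the result for audit, so a conditional
backend can be swapped in without changing the aggregation contract.

## Regionalization

K-means (k = 4 by default, 10 seeded restarts, best objective kept) on
z-scored MCWD, shortwave radiation and precipitation; z-scoring is
required because the three drivers have incomparable units. Centroids
are fitted on pixels carrying secondary forest; every pixel of the
domain is then assigned to its nearest centroid, so old-growth pixels
also carry a region id (needed for regional asymptotes) and a pixel's
region depends only on its own driver vector. Labels are canonicalized
by ascending mean shortwave radiation: "region 1" is reproducibly the
wettest, lowest-radiation cluster. Crossing regions with the four
disturbance classes (single/repeated × burnt/not burnt) yields up to 16
regional models; combinations with fewer than three distinct stand ages
cannot identify (k, c) and are skipped.

## Carbon accounting and projection

The accounting unit is the **pixel**: each secondary pixel contributes
Y(age)·area (0.09 ha at 30 m), with the growth model of its patch's
(region, class) — this makes the ledger identity exact. The annual
ledger between consecutive years books growth of persisting pixels
(Y(age+1) − Y(age)), recruitment at Y(1) (a one-year-old stand has one
year of growth, not zero), and losses as the modelled stock of
deforested pixels — model-predicted rather than raster-observed, for
consistency with the gains side (an observed-AGC loss option would mix
scales). stock_end = stock_start + gains − losses holds to machine
precision and is validated on construction. Pixels whose patch first
crosses the minimum mapping unit enter the accounted set at their
current age; pixels of patches that shrink below it leave it — a
scale artifact of the mapping unit, negligible when clearing operates
on whole polygons.

The **no-disturbance counterfactual** rescores every secondary pixel
with its region's single-deforestation/not-burnt curve at its observed
age. Observed ages are kept — the counterfactual does not rewind
repeated clearing to make stands older — so the disturbance reduction
it implies is conservative. Coarse-grid maps sum pixel values with a
centre-point rule: every pixel lands in exactly one cell, so cell sums
re-add to the total.

**Projection**: preserved pixels (stand age ≥ scenario threshold in the
reference year) accrue Y(age + Δ) for Δ = 0..13 (2017→2030);
non-preserved pixels are removed with their stock excluded, not booked
as an emission (an optional emission booking exists at the ledger
level). The headline number is the mean annual accumulation
(stock₂₀₃₀ − stock₂₀₁₇)/13 — a single summary of a declining series,
which the per-year table also reports. The CI band propagates (k, c)
uncertainty by evaluating the projection at parameter draws (bootstrap
draws when available, otherwise Gaussian draws from the asymptotic
covariance). NDC arithmetic converts pledge fractions of the
2.1 GtCO₂e yr⁻¹ baseline to Tg C yr⁻¹ via ×1000 × 12/44.

## The synthetic landscape

The generator emulates the statistical structure of the real inputs at
desk scale (default 100×100 pixels of 30 m, 33 annual layers,
1985–2017):

* **Events.** The landscape is tiled with management units — clearable
  cores of 2×5 pixels (exactly 9000 m²) inside tiles with a 1-pixel
  permanent-forest margin. Each unit runs a Markov chain: old-growth →
  anthropic at 0.03 /yr, anthropic → secondary at 0.15 /yr (mean fallow
  ~7 years, matching the observed 5–10-year clear/abandon cycling),
  secondary → anthropic at 0.04 /yr; secondary units burn at 0.02 /yr
  from 2001 (≈29% ever burnt by 2017, matching the observed share of
  burnt secondary forest). Unit-level events mimic clearing polygons:
  each regrowing unit is an isolated even-aged patch that passes the
  minimum mapping unit, and margins prevent neighbouring patches from
  percolating into mega-patches. Every event is recorded in a truth
  ledger whose independent replay reproduces final class, age and
  deforestation count exactly — the oracle for the history stage.
  Event uniforms are drawn from rate-independent streams, so raising a
  rate under the same seed only adds events.
* **Regions.** The four grid quadrants carry planted climatologies
  ordered by shortwave radiation (163.6 → 190 W m⁻²; annual
  precipitation 2049 → 1850 mm; MCWD −64.4 → −390 mm yr⁻¹) with small
  within-region gradients and noise, so K-means can recover them.
  Monthly precipitation is built from a seasonal profile whose annual
  MCWD equals the planted value exactly (dry-season months below the
  100 mm demand; wet-month jitter only). Old-growth asymptotes are
  120/128/112/135.5 Mg C ha⁻¹, and the 16 planted (A, k, c) curves are
  solved so the undisturbed 20-year accumulation is 3.0/2.4/1.8/1.3
  Mg C ha⁻¹ yr⁻¹ by region, scaled by 1.0/0.8/0.7/0.5 for the
  disturbance classes (regrowth reductions of 20–50%), with shape
  c = 1.6–1.8.
* **Carbon.** Secondary pixels carry 2·(Y(age) + ε); old-growth pixels
  2·(A + ε); anthropic pixels Uniform(0, 10) Mg ha⁻¹ background
  clutter; values clip at zero. The noise ε is drawn once per
  management unit (sd 5 Mg C ha⁻¹) plus a small per-pixel jitter
  (sd 0.5): the coarse biomass product's error is spatially correlated
  at the patch scale, and unit-level noise is also what keeps the
  1-Mg-binned zonal mode meaningful. The sd is chosen so that the
  per-age median curve at desk scale (1–3 patches per age row) has a
  signal-to-noise ratio comparable to the full-scale analysis, whose
  medians pool orders of magnitude more polygons.

What the generator does **not** emulate: real geography and spatially
organised deforestation frontiers, sensor/cloud artefacts, sub-annual
dynamics, misclassified plantations (exclusion masks are exercised with
synthetic masks instead), age-dependent fire susceptibility, and any
correlation between soil fertility and growth (the soil field is pure
nuisance). Passing tests therefore demonstrate that the pipeline's
logic and statistics are correct under a faithful data-generating
model, not that the full-scale published magnitudes are reproduced —
those depend on the real rasters, and only their printed arithmetic
(NDC targets, ledger identities, percentage reductions) is
desk-recomputable.

## Problem sizes used in validation

Parameter recovery runs the complete pipeline on 100 seeded 100×100
landscapes (~400 curve fits) and checks ≤10% median absolute relative
error on the no-disturbance (k, c) with ≥90% CI coverage; ledger
conservation is checked on a further 100 random 42×42 landscapes;
importance recovery uses the full study protocol (30 × 500 trees,
n = 2500) on 20 000 synthetic patch records. The whole suite runs in
under ten minutes on one CPU.

## Known limitations

* Space-for-time substitution equates today's age gradient with a
  stand's future trajectory; directional climate change breaks this.
* One biomass epoch means ages beyond the window (>32 yr) and
  old-growth dynamics are unconstrained; extrapolation beyond the
  observed age range inherits the fixed-asymptote assumption.
* The fixed asymptote transfers old-growth heterogeneity into residual
  error of (k, c); groups without young stands are additionally
  distorted by the bias correction (see above).
* Marginal permutation importance shares credit among correlated
  drivers; region-level rankings mitigate but do not remove this.
* Losses are instantaneous stock removals; committed decay emissions,
  belowground and soil carbon are out of scope.
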