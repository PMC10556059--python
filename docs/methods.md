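# Methods

This note records the models implemented in `gulfweed`, the parameter
choices that matter, what the synthetic generators do and do not emulate,
and the numerical decisions taken where the design was genuinely open.

## Uptake kinetics and the As:P prediction

Uptake of dissolved phosphate and arsenate is modelled in Michaelis–Menten
form, ρ = μC/(k + C), with independent maximal rates (μ_P, μ_As) and
half-saturation constants (k_P, k_As). At concentrations well below k the
rates are first-order, and with arsenate held fixed the As:P uptake ratio
is proportional to 1/[PO₄³⁻]. Mapping dissolved phosphate to tissue
phosphorus content (tissue composition assumed to mirror proportionate
uptake), the testable prediction is log₁₀(As:P) affine in log₁₀(%P) with
slope −1.

`predicted_asp_curve` enforces a linear-regime guard (grid maximum ≤
k_P/10): the first-order approximation errs by ~C/k, so at C = k/10 the
curve is within ~10% of the saturating form and the log-log slope is −1 to
machine precision; beyond the guard a warning is recorded in the output
table rather than raising, since exploring the saturating bend is a
legitimate use.

## Power-law fitting and inference

The exponent is estimated by ordinary least squares of log₁₀(y) on
log₁₀(x). Non-positive or non-finite pairs are excluded and counted; the
fit refuses fewer than 3 valid pairs. Inference is reported two ways and
labelled in every output:

* a conventional t-test on the slope, against H₀: b = 0 and against
  H₀: b = −1 (two-sided; −1 is the theory value, so "supra-hyperbolic"
  means the −1 test rejects with b < −1);
* a nonparametric pair bootstrap (default 10,000 resamples, percentile
  95% CI), vectorized and chunked to bound memory, bit-reproducible under
  its seed.

Multiplicative (lognormal) error is the working noise model throughout —
the natural scale for composition ratios, and the scale on which OLS in log
space is the maximum-likelihood fit.

The spurious-ratio caveat is implemented, not narrated: for independent
positive a, b, Cov(log a − log b, log b)/Var(log b) = −1, so
`spurious_ratio_null` draws lognormal pairs (optionally correlated, where
the population slope becomes ρσ_a/σ_b − 1) and returns the fitted-slope
distribution. `correlation_summary` pairs each Pearson correlation (Fisher-z
CI) with the companion ratio-vs-denominator fit for As:P, As:N and As:C, so
the hyperbolic / non-hyperbolic contrast across denominators is a computed
output.

## Isotope dilution

Two end-member mass balance: after growth by factor F, δ_final =
δ_init/F + (1 − 1/F)·δ_new, inverted as F = (δ_init − δ_new)/(δ_final −
δ_new), with doublings = log₂F. Targets outside the open interval between
the end members, or coincident end members, are domain errors — no finite
growth produces them.

## Tissue tables, regions, group statistics

The canonical tissue schema is a flat CSV (one row per replicate) with
dry-weight percentages, δ¹⁵N (‰), arsenic in µg g⁻¹, species, and a
collection-era code. Missing chemistry is NaN, never imputed, and every
summary and fit reports its effective n. Longitudes are normalized to
[−180, 180) on read; rows with unparseable/out-of-range coordinates or with
all chemistry missing are rejected with logged reasons and counted.

Elemental ratios are computed on a weight basis (direct percent ratios,
As converted µg g⁻¹ → % by /10⁴) or a molar basis (percent divided by
atomic mass: C 12.011, N 14.007, P 30.974, As 74.922); the two interconvert
exactly through mass ratios. Weight is the default for As:P.

Regional grouping uses an ordered list of polygons (first containing
polygon wins, boundary inclusive; fallback "other"). The default scheme is
four lon/lat boxes — northern Sargasso Sea (30–40°N), Sargasso Sea
(22–30°N), Caribbean interior (12–22°N west of 64°W), western tropical
Atlantic (south of 12°N), all within 75–45°W — chosen so grouping is
reproducible and user-overridable (YAML) in the absence of published
boundary coordinates.

Group comparisons use a Welch one-way ANOVA plus pairwise Welch t-tests
under Holm correction with Cohen's d, and the method label travels with
every result: the appropriate test is a modelling choice, so it is recorded
rather than implied. Degenerate (zero-variance) groups yield a defined
zero effect size instead of an exception.

## Lagrangian tracking

Velocity at a particle is the trilinear (lon × lat × time) interpolation of
the current field plus windage × the wind field. A stencil touching masked
(land) nodes renormalizes over the unmasked nodes and flags the point
near-land; a fully-masked stencil is undefined and deactivates the particle.
Fields with a single time level are treated as steady.

* **Random walk.** σ² = 4DΔt is interpreted as the total 2-D displacement
  variance (per-component SD √(2DΔt)), the standard 2-D Fickian convention,
  so ensemble MSD grows as 4Dt and `estimate_diffusivity` (MSD/(4t),
  averaged over saved steps, with an increment-based cross-estimator)
  recovers the configured D. The per-component reading (4DΔt) is available
  as `sigma_convention="per_component"` for comparison.
* **Defaults.** D = 4000 m² s⁻¹ (regional Argo-derived estimate),
  windage 0.02 (mid-point of the 0.5–3% range that best reproduces observed
  *Sargassum* drift), Δt = 6 h, 60 days, 100 particles per station.
* **Integrators.** Fixed-step forward Euler by default — it matches the
  random walk's own time discretization — with RK4 on the advective part as
  an option for accuracy-critical work. On a solid-body orbit with
  ωΔt ≈ 0.05 per step, Euler grows the orbit radius by the well-known
  factor (1 + (ωΔt)²)^(n/2) (~18% over 30 days) while tracking the angular
  rate to <0.1%; RK4 stays on the circle to <0.05% of the radius.
* **Backward mode** negates the advective velocity and steps earlier in
  time; the diffusion step keeps the same magnitude in both directions
  (random walks are not time-reversible — backtracking is statistical).
* **Geometry.** Meters convert to degrees on a per-step local tangent
  plane (R = 6,371,000 m; dlon = dx/(R cos φ)), with a hard error near the
  poles (|cos φ| < 10⁻⁶). Longitude arithmetic is dateline-safe; ensemble
  centroids average longitude circularly so ensembles straddling ±180°
  average to ~180°, and exclude particles after deactivation, truncating
  when none remain.
* **Land and domain.** Landing on a masked cell beaches the particle at the
  landing point (no reflection — conservative and logged); leaving the grid
  freezes it at its last in-domain position. Deactivated particles never
  move again and the particle count is conserved.
* **Determinism.** One master seed; each station's stream derives from
  (seed, station index) via `SeedSequence`, and the Gaussian perturbation is
  drawn for every particle each step regardless of active status, so
  identical (config, seed) reruns are bit-identical.

Trajectories round-trip losslessly (positions, flags, config, seed) through
netCDF and long-format CSV; GeoJSON output carries one LineString per
particle plus a centroid LineString per station. All netCDF I/O uses the
NETCDF3-classic backend.

## Synthetic generators

`gen_tissue_dataset` emulates the deposit schema with era group sizes
200 / 20 / 21 (the 2021 survey and the two archive eras), %P log-uniform
over 0.01–0.3% dry weight, arsenic built from As:P = 10^a(%P)^b with
b = −1.3, a = −2.4 and lognormal noise SD 0.15 (log₁₀ units) — the
intercept places As at ~20–200 µg g⁻¹, the observed order of magnitude —
plus regional offsets giving the qualitative field contrasts: N and P
enriched in the Caribbean / western tropical Atlantic, P-poor Sargasso Sea,
δ¹⁵N ≈ +2‰ in the northern Sargasso Sea against slightly negative values
elsewhere. Archive-era samples are placed in the Sargasso Sea. What it does
*not* emulate: along-track spatial autocorrelation, station-level replicate
clustering, species effects (none are generated — the field finding is that
species compositions are similar), measurement censoring at detection
limits, or any real circulation. Passing tests therefore demonstrate
estimator correctness and calibration under the assumed error model, not
the field result itself.

`gen_field` builds uniform, solid-body and single-cell gyre fields. The
uniform evaluator solves the spherical kinematics exactly (the meridional
case integrates sec φ, i.e. the inverse Gudermannian). The solid-body field
and its closed-form orbit are defined on the tangent plane at the rotation
center with fixed metric cos(lat_c); the tracker uses the per-particle
cos(lat), so closed-form and integrated orbits differ by O((φ−φ_c)·tan φ_c)
— negligible for the low-latitude, ~100 km test geometry and a property of
the test construction, not a tracker defect. Gyre grids must resolve the
cell (≥ 8 nodes per wavelength) or generation is refused.

## Problem sizes and tolerances

Test and verification runs use 1000 particles × 120 steps for diffusivity
recovery (tolerance ±10%, the Monte-Carlo scatter of MSD/(4t) at that
ensemble size), 100 seeds × n = 200 for exponent recovery (±0.05, ≈ 5× the
SE of the mean fitted slope), 500 datasets × 1000 bootstrap resamples for
CI coverage (95% ± 3%), and exact or 10⁻¹⁰–10⁻¹² tolerances wherever the
quantity is deterministic (windage ratio, noiseless fits, conversions,
interpolation against the brute-force stencil oracle).

## Known limitations

Interpolation does not wrap longitude across the grid's edges (fields are
regional); no Stokes drift, vertical motion, growth/mortality along
trajectories, or leeway angle on the windage vector (a scalar factor only);
the statistical tests behind regional contrasts are a configurable,
labelled choice, not a claim about how any particular published table was
computed; and dissolved arsenate speciation is outside scope — arsenate
uniformity enters only as the assumption that collapses the uptake ratio to
1/[PO₄³⁻].
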