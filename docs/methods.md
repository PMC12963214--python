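# Methods

`spectherm` implements spectral-CT thermometry for thermal-ablation
monitoring: the relation between dual-energy electron density and tissue
temperature, the image-processing steps that make it usable next to a metal
probe, and the statistics that quantify how well it predicts temperature.
This note documents the models, the defaults and the numerical choices, in
enough detail to re-derive every number the package produces.

## The physical model

Warming tissue expands; its electron density per unit volume falls. With
EDW(T) the electron density as a percent of water's and α(T) the volumetric
thermal-expansion coefficient,

    EDW(T) = EDW(T₀) / (1 + ∫_{T₀}^{T} α(T′) dT′),       α(T) = b·T² + c·T + d,

so the integral evaluates to b/3·(T³−T₀³) + c/2·(T²−T₀²) + d·(T−T₀).
Units: temperatures in °C throughout; b, c, d carry °C⁻³, °C⁻², °C⁻¹. For
soft tissue near body temperature EDW(T₀) ≈ 104 % and α ≈ 4–9·10⁻⁴ °C⁻¹
over the ablation range, giving a 3–4 % EDW drop between 37 and 99 °C —
small but measurable, and strictly monotone wherever α > 0, which is what
makes EDW a temperature surrogate.

An `as_printed` audit flag reproduces a variant of the formula in which the
c term also carries (T³−T₀³); it exists only so the implemented integral can
be compared against that (dimensionally inconsistent) rendering and is not
used anywhere in the pipeline.

`fit_expansion` estimates (EDW(T₀), b, c, d) by nonlinear least squares in
EDW units (`scipy.optimize.least_squares`, tight tolerances, explicit
parameter scales of 100 / 10⁻⁷ / 10⁻⁵ / 10⁻⁴). Starting values: EDW(T₀)
from the mean EDW of the coolest temperature decile; d from the slope of a
linear EDW-vs-T fit divided by −EDW(T₀) (the small-expansion linear
regime); b = c = 0. `fix_b=True` (the default used by the pipeline) pins
b = 0, making α linear in T. A smooth floor on the denominator keeps the
optimiser out of the unphysical region 1 + ∫α ≤ 0; the forward model raises
there instead.

**Identifiability.** Over a 29–99 °C span the regressors (T²−T₀²)/2 and
(T−T₀) are ~99 % collinear, so ĉ and d̂ trade off almost one-for-one. At
EDW noise SD 0.2 with n = 192 the linearised covariance gives ~9 % relative
SD for ĉ but ~50 % for d̂ — the curve α(T) and its slope are well
determined, the intercept d individually is not. The acceptance script
reports per-coefficient recovery rates separately for this reason; users
should interpret fitted d (and α extrapolated below the sampled range) with
that uncertainty in mind.

## Temperature calibration and statistics

* **Polynomial calibration** (orders 1–4): least squares of temperature on
  powers of EDW. Powers of raw EDW ≈ 100 are severely ill-conditioned at
  orders 3–4, so fitting and prediction run in numpy's centred/scaled
  polynomial basis; coefficients are back-converted to the raw basis only
  for reporting. Each fit records its training EDW span for later range
  checking.
* **RMSE** is √(Σ(xᵢ−x̂ᵢ)²/N) over measured/estimated temperature pairs.
* **Cross-validation**: 5 folds from a seeded shuffle (`sklearn.KFold`),
  squared errors pooled over all held-out predictions before the square
  root. No stratification.
* **Spearman correlation**: average-rank ρ with the t-approximation p-value
  (scipy); the 95 % CI uses the Fisher z transform with the Bonett–Wright
  rank-based standard error √((1+ρ²/2)/(n−3)). Constant inputs are
  rejected (ρ undefined), |ρ| = 1 returns the degenerate one-sided
  interval.
* **Breusch–Pagan**: auxiliary regression of squared residuals on distance
  to the probe emitting point (statsmodels). Both flavours are reported —
  LM = n·R² against χ²₁ and the auxiliary F against F(1, n−2); F is the
  headline because ablation-thermometry reports print it. The sign of the
  auxiliary slope says whether error variance grows or shrinks with
  distance. Residuals enter from the active-heating phase only (scan times
  within the ablation-on window, default 0–300 s).

## The synthetic phantom

No imaging data ship with the package; the phantom generates studies with
the statistical structure the analysis assumes, as first-class tested code.

* **Temperature field**: anisotropic Gaussian around the emitting point
  (15 mm proximal to the probe tip), stretched ×1.6 along the shaft,
  T(x,t) = T_body + ΔT(t)·exp(−ρ²/2σ(t)²). ΔT ramps linearly to
  T_peak−T_body over the 300 s heating and decays exponentially
  (τ = 240 s) afterwards; σ grows from 4 mm by 0.01 mm/s while power is
  on. This is deliberately not a bioheat PDE: it is the simplest field with
  the right qualitative shape (hot core, monotone radial falloff, ramp then
  decay) and a closed form that doubles as its own oracle. Defaults
  T_body = 37 °C, T_peak = 99 °C reproduce the intended 29–99 °C study
  span from the hot side; baseline liver a few degrees below core
  temperature is not modelled.
* **Study design**: 3 subjects × 16 scans at 1-min intervals × 4
  thermocouples = 192 candidate (sample, temperature) pairs. Default
  sensor placements sit 3 / 6 / ~12 / 24 mm from the shaft near the
  emitting plane (matching a realistic 2.5–24 mm placement spread), with
  ±1.5 mm per-subject jitter. Grid 96×96×64 voxels at 0.75×0.75×1.0 mm —
  coarser than a clinical 512² reconstruction but fine enough that a 3 mm
  ROI holds ~200 voxels; chosen so a full study generates in well under a
  minute.
* **Spectral channels**: EDW comes voxelwise from the expansion forward
  model at the local temperature (liver-like parameters EDW₀ = 104,
  c = 7.9·10⁻⁶, d = 9.6·10⁻⁵, b = 0); conventional HU falls at
  −0.25 HU/°C from 55 HU; Z-eff rises at +0.002/°C from 7.8. Each channel
  carries white voxel noise (SD 1.5 % EDW / 12 HU / 0.3 Z-eff / 8 HU VMI)
  plus a smooth correlated field (Gaussian-filtered noise, σ = 6 voxels,
  SD 0.5 % / 10 HU / 0.15) — the smooth component is what survives ROI
  averaging, and its scales are set so the rank-correlation ordering
  |ρ(EDW)| > |ρ(HU)| > ρ(Z-eff) > 0 emerges from the generated data rather
  than being asserted. Sensor noise SD 1 °C reflects a ±2 °C calibration
  tolerance.
* **Artifacts**: metal-level HU (900) in 1.5 mm-radius tubes along the
  probe shaft and each thermocouple wire; gas bubbles (−400 HU, 1.5 mm)
  seeded only where T > 90 °C, where vaporisation happens in practice.
  Artifact voxels also corrupt EDW/HU/Z-eff, so masking genuinely changes
  downstream numbers.
* What the phantom does **not** emulate: perfusion heat sinks, respiratory
  motion, streak (as opposed to blob) artifacts, beam-hardening gradients,
  partial-volume blur at the probe, inter-subject tissue variability.
  Passing tests therefore demonstrate the pipeline's correctness and its
  behaviour under the assumed noise structure, not clinical accuracy.

All randomness flows through one explicitly passed `numpy` generator;
subject- and stage-level seeds are spawned from the top-level seed via
`SeedSequence`, so identical (config, seed) runs are byte-identical.

## Masking, ROIs, pairing

A voxel is valid iff its 70 keV VMI attenuation lies in the **closed**
interval [0, 80] HU — the exclusion rules are strict (> 80 metal, < 0
gas), so boundary values are valid; this is fixed explicitly because it
changes counts on exact-boundary data. Masks are recomputed per scan
(artifacts evolve as gas forms).

Spherical ROIs (default radius 3 mm) collect voxels whose centres lie
within the radius of the sensor tip in world mm (anisotropic spacing
respected; centre-in-sphere, not any-overlap, for determinism). The
artifact mask is intersected; an ROI left empty is flagged excluded rather
than silently dropped — the "tip obscured by metal" case. Each sample is
paired with the 1 Hz log reading nearest the scan's nominal time (gantry
rotation is sub-second, so averaging over the scan would change nothing).
Sensor tip coordinates come from the study manifest; per-scan
re-localisation is out of scope since sequential scans are assumed
co-registered.

## Thermometry maps and zone metrics

Polynomial calibrations map EDW to temperature voxelwise. Voxels outside
the calibration's training EDW span (±5 % of the span) are withheld as
invalid rather than extrapolated. Optional mask-aware Gaussian smoothing
(normalised convolution over the valid support; pipeline default σ = 2 mm)
precedes mapping: voxel-level EDW noise converts to tens of °C through the
~ −11 °C/% calibration slope, so unsmoothed isotherms are noise. The
expansion model predicts EDW from temperature; mapping it the other way
goes through `invert_edw`, a brentq bisection on the strictly monotone
forward curve.

The treatment zone is the 26-connected component containing the seed point
at/beyond the threshold (≥ 60 °C, the irreversible-damage isotherm). The
pipeline segments on smoothed EDW at the EDW level its linear calibration
maps to 60 °C, for two reasons: the hottest voxels read *below* the
calibration span (the temperature map withholds them, but low EDW means
hot, so they certainly belong in the zone), and the emitting point itself
sits inside the metal artifact (the segmentation seed is therefore placed
4 mm off-shaft). Zone metrics: volume = voxel count × voxel volume (cm³);
long axis = extent of zone voxel centres projected on the probe direction;
short axis = maximal pairwise extent perpendicular to the probe within the
one-voxel slab through the emitting point (convex-hull diameter). These are
probe-aligned extents, the convention of ablation-zone reporting, not PCA
axes; the two are reported sorted so long ≥ short always holds.

## Degenerate inputs and tie-breaks

Constant vectors are rejected by `spearman` and by the auxiliary BP
regression; empty inputs by `rmse`; rank-deficient designs by
`fit_polynomial`; temperature spans < 10 °C by `fit_expansion` (α is
unconstrained without span). An ROI centre outside the grid's physical
bounding box returns an empty set with a warning. `segment_zone` with a
seed below threshold warns and returns an empty mask; `zone_metrics` on an
empty mask raises. NaNs in a map are never part of a zone.

## Problem sizes

Defaults were sized for a laptop-class single core: the full synthetic
study (3 × 16 × 4 channels at 96×96×64) generates, extracts, calibrates
and maps in about a minute; the Monte-Carlo recovery study (100 replicates
of n = 192) and the Breusch–Pagan null calibration (2000 replicates of
n = 100) each run in seconds.
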