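# Methods

This note records the physical model, the numerical choices and the defaults
behind `fluorodose`, and what the synthetic fixtures do and do not emulate.

## Photon transport model

Photons in the 5–150 keV range are transported with three interaction
channels: photoelectric absorption, incoherent (Compton) scattering, and —
off by default — coherent (Rayleigh) scattering. Compton energies and angles
are sampled from the Klein–Nishina differential cross section with Kahn's
two-branch rejection method; the scattered energy satisfies
E′ = E / (1 + (E/m_ec²)(1 − cos θ)) exactly. Rayleigh angles, when enabled,
use the Thomson form (1 + cos²θ). Electron transport is omitted: in this
energy range secondary-electron CSDA ranges (≲0.03 mm in tissue at 150 keV)
are far below the 1–10 mm voxel sizes, so transferred energy is scored
locally (kerma approximation). Characteristic x-rays and fluorescence are
not modeled.

Cross sections come from a packaged CSV (see `src/fluorodose/data/README.md`
for provenance): mass attenuation and mass energy-transfer coefficients for
air, lung, soft tissue, bone, water and copper, log-log interpolated, with
per-energy channel fractions that sum to 1 to within 10⁻⁹. The transport
kernel uses these resampled onto a 0.25 keV grid with nearest-bin lookup.

### Voxel tracking

Heterogeneous voxel grids are traversed by Woodcock (delta) tracking: free
paths are drawn against an energy-dependent majorant
Σ̂(E) = max over materials present of (μ/ρ)(E)·ρ_max, and collisions are
accepted with probability μ/Σ̂ (rejections are "virtual" collisions). Steps
that would leave the grid are truncated at the boundary, which is valid by
the memorylessness of the exponential free path. Homogeneous regions of the
room (air, the table slab, the walls) use direct analytic free-path
sampling instead.

### Estimators

* **Skin dose** (default): collision-density kerma estimator. Every Woodcock
  collision — real or virtual — in a voxel contributes
  E·(μ_tr/ρ)(E)/Σ̂(E) to that voxel; divided by the voxel volume this is an
  unbiased estimate of Φ·E·(μ_tr/ρ), the kerma. It uses every traversing
  photon rather than only the ~7% that interact per 3 mm voxel, which is
  what makes the peak-voxel precision target reachable at 10⁷ photons
  (measured ≈1.8% relative SE, vs ≈6% for analog scoring at the same count).
  Analog scoring (deposit E at photoelectric events, E−E′ at Compton events)
  remains available via `MCConfig(estimator="analog")` and backs the
  energy-conservation ledger — emitted = deposited + escaped to ≲10⁻¹⁵
  relative — and the cross-check against an independent plain ray-marching
  reference in the test suite.
* **Air kerma**: track-length estimator on a coarse room lattice; each air
  path segment adds ℓ·E·(μ_tr/ρ)_air to the cells it crosses
  (Amanatides–Woo traversal). Because this estimates *mass* kerma it is
  independent of the air density, which the tests exploit: a near-vacuum air
  density turns the point-source benchmark into an exact 1/r² law, removing
  the ~5–10%/2 m bias that real-air attenuation and scatter build-up
  otherwise introduce at these energies.
* **Primary transmission**: the skin kernel histograms the path length from
  phantom entry to each photon's first real collision (1 mm bins), so the
  uncollided fraction can be compared directly with exp(−μt).

### Uncertainty

Runs are split into `n_batches` (default 10) independently seeded batches;
the per-voxel relative standard error is the standard deviation of the batch
means over √n_batches. The headline precision statistic is the relative SE
at the voxel of maximum mean skin dose; the statistic's reference figure of
3.5% does not pin down which voxel population it refers to, and the peak
voxel is the conservative, clinically relevant choice.

Seeds: a single integer seed expands through `numpy.random.SeedSequence`
into per-batch (and, for table builds, per-node) streams, so every output is
bit-reproducible from (inputs, seed, config).

## Beam and geometry

* **Spectrum**: Kramers' law with copper filtration, no tungsten
  characteristic lines and no heel effect. The spectral shape only needs to
  carry the correct beam-quality trend for dose-pattern work; the absolute
  output lives in the separate tube calibration (photons per mA·s).
  Spectra are discretized at 1 keV (configurable) bin centers; the top
  nonzero bin is within one bin width of kVp.
* **Room frame**: right-handed, origin at the isocenter, +x patient-left,
  +y patient-anterior (up, supine), +z cranial. PA (0°, 0°) places the
  source under the table at (0, −s_iso, 0). Lateral rotation (RAO−/LAO+) is
  about +z applied after the cranio-caudal rotation about +x. These sign and
  order conventions are frozen and tested; vendor conventions may differ.
* **Defaults**: SID 100 cm, source-to-isocenter 72 cm (typical isocentric
  C-arm; configurable). The default synthetic torso's posterior surface is
  120 mm behind the isocenter, making the PA source-to-skin distance 60 cm.
* **Table motion** is modeled by translating the phantom in the room frame —
  equivalent to moving the table, and simpler.
* **Beam sampling**: source directions are drawn uniformly over the
  collimated square on the detector plane (what a collimator defines), not
  uniformly in solid angle; at the ~5.7° half-angles involved the difference
  is cosine-order. Aperture shaping beyond the square field is unsupported.
* **Room**: a concrete-walled box (default 6×3×6 m, 20 cm walls, floor
  1.2 m below the isocenter) with a low-density carbon-fiber-like table
  slab. The material enumeration has no concrete entry, so walls use the
  cortical-bone coefficient set at 2.3 g/cm³ — effective atomic numbers of
  bone and concrete are close throughout 5–150 keV, which is what wall
  backscatter depends on. Photons scatter in walls like in any other
  region (multiple bounces allowed); no fluorescence.

## Phantoms

`hu_to_material` segments CT numbers into air (< −900 HU), lung (−900…−200),
soft tissue (−200…150) and bone (≥ 150), with a continuous piecewise-linear
density calibration through (−1000, 0.0012), (0, 1.000), (1000, 1.80) g/cm³.
Real scanners' calibrations differ; both the thresholds and the anchors are
the package's choice and are documented rather than claimed universal.

The synthetic torso (default 128×128×64 at 3 mm, seed 0) is an elliptical
soft-tissue cylinder with two lung ellipsoids, a posterior spine column and
seeded HU texture noise. It emulates the gross attenuation structure of a
chest/abdomen body phantom — entrance-surface geometry, lung low-density
volumes, a bony column — but none of the fine anatomy, so passing tests
demonstrate correct physics and plumbing on realistic length scales, not
dosimetric accuracy for any particular patient. The skin layer is the
air-adjacent tissue shell grown to 3 mm (default) with a Euclidean distance
transform.

## Air-dose lookup table

Air-kerma grids are precomputed at angular nodes covering lateral −90°…90°
and cranio-caudal −30°…30°. The angular step defaults to 15° (13×5 = 65
nodes), a desk-scale compromise; per-node photon counts default to 10⁶,
whereas a production build would use orders of magnitude more — the table
stores per-photon values, so scaling affects statistical noise, not
normalization. Node seeds derive from (build seed, node indices), making
builds resumable (checkpointed HDF5) and each node bit-identical to a
standalone run. Queries interpolate multilinearly (bilinear in the two
angles, trilinear in position), never extrapolate, and are bound to the
(kVp, filter, FOV, SID) fingerprint the table was built for; tube current
and pulse duty scale linearly at query time. One table per fingerprint.

The eye-lens dose rate is the interpolated air-kerma rate times the scalar
conversion factor 1.550 Gy/Gy; no angular (Hp(3)) dependence is applied.

## Acquisition

The synthetic console renderer draws fixed-slot seven-segment digits (with a
reserved sign slot for the gantry angles and implicit decimal points
recorded in the layout) plus a beam-on indicator lamp; noise is additive
Gaussian with a uniform brightness jitter. The recognizer scores each slot
against the 0–9/minus templates by normalized cross-correlation and accepts
the best match at score ≥ 0.6 with ≥ 0.05 margin; the blank template has
zero variance, where NCC is undefined, so blanks score 1 − 2·RMS of the
crop instead. Thresholds are exposed configuration, chosen so zero-noise
recognition is exact. A failed slot raises an error naming the field, and
the streaming layer then re-emits the last good record flagged stale
(emitting a gap marker if none exists yet). The synthetic display stands in
for a real console camera: perspective, keystone, glare and font differences
of real screens are *not* modeled, so recognizer accuracy figures here do
not transfer to camera captures.

Ultrasonic positioning uses v(T) = 331.3 + 0.606·T m/s (standard linear
approximation of the speed of sound in air), d = v·ToF/2 per axis, and
offsets relative to calibrated reference distances. A validation harness
sweeps ±10 cm in 2 cm steps per axis; noiselessly the chain is exact to
numerical precision, and a Gaussian ToF-noise model exists only for
degradation studies — real transducer beam width, echo detection and
electronics are not modeled.

## Session semantics

Condition records cover the interval to the next record; skin-dose MC runs
are cached per (beam fingerprint, pose, table offset) so repeated records
accumulate linearly and replays are bit-identical. Cumulative dose is
per-voxel monotone non-decreasing and invariant to stream chunking; a
`latest_only` mode shows only the most recent interval instead. During
beam-off intervals nothing accumulates, but payloads still carry the
eye-lens rate the latest conditions would produce, flagged `predicted`, so
risk is visible before the beam turns on. Colors are presentation only
(linear colormap over [0, session max] by default, log opt-in); dose values
in Gy travel alongside them in every payload.

## Problem sizes in the test suite

The bundled tests run the full 10⁷-photon peak-precision check once and keep
every other Monte Carlo at 10⁴–10⁶ photons (coarser phantoms, smaller
lattices), which resolves each property's pass band while keeping the whole
suite in single-digit minutes. Statistical assertions use 3σ bands with
fixed seeds; replicate-run variance is used where track-length correlations
would invalidate per-cell error propagation.

## Known limitations

* No electron transport, characteristic radiation, or fluorescence; kerma ≈
  dose assumed throughout 5–150 keV.
* Spectrum is an analytic continuum; no tungsten lines, no heel effect.
* Rigid anatomy: no respiratory motion, deformation or movable shields.
* Single square field; collimator aperture shaping unsupported.
* The acquisition fixtures are synthetic stand-ins; hardware-specific error
  figures (camera optics, transducer accuracy) are out of scope.
* Wall scatter uses a bone-as-concrete surrogate and a single wall material.
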