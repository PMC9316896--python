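# Methods

## Scope

rcvkit models the statistics of cleaning verification with a hand-held
specular-reflectance FTIR: how many ~1.76 mm² spot readings justify a
surface mean, what the method's capability is against the residue
acceptance limit (RAL), and what the limit of quantification (LOQ) of
the whole measurement chain is. A droplet-level coupon simulator
supplies test data with the statistical structure the analysis assumes,
so every stage is testable without instrument data.

## Coupon and deposition model

A coupon is a flat plate (default 25 × 25 mm) carrying up to 5200
microdroplets of API solution, 4–10 nL each, at a default solution
concentration of 2 × 10⁻⁴ µg/nL (≈ 2700 droplets for 0.6 µg/cm²).
Each droplet spreads into a uniform disc of fixed diameter (default
0.4 mm) — the simplest footprint that conserves mass and produces
spot-scale variance. Droplet volumes are drawn uniformly in range and
then shifted by a common clipped offset so the area-averaged density
equals the target exactly; mass conservation (Σ droplet masses =
area integral of the density field) therefore holds identically.

Placement has two regimes, controlled by the `inhomogeneity` dial:

- **0 — printed grid.** Regular pitch chosen from the 0.5–1 mm range
  (coarsest feasible), equal volumes. Emulates a microdot printer;
  spot %RSD is a few percent, though moiré between the grid pitch and
  the spot footprint makes individual spots vary by ±15–20 %.
- **> 0 — clustered hand deposition.** Two-level process: uniform
  cluster centres, Gaussian scatter (SD 1 mm) around them, ~40·dial
  droplets per cluster. The default dial 0.1 (clusters of ~4) puts the
  spot-sampled %RSD of a 0.6 µg/cm² coupon near 40 %, the middle of
  the 27–53 % band observed on hand-deposited coupons; the dial was
  fixed once from that band and is not tuned elsewhere.

Droplets may sit anywhere on the coupon; a disc overhanging the edge
has its overhanging mass folded back across the edge (liquid stays on
the plate). Sampling implements the fold by adding mirror-image
droplets, which keeps the expected density field uniform up to the
edge — without the fold, confining droplets to an inset region
inflates interior densities by several percent and spot sampling would
be biased. Spot sampling itself is deterministic: the exact
circle–circle overlap of the footprint with every droplet disc,
divided by the footprint area. Spot footprints must lie fully on the
coupon.

## Spectrum model

Spectra live on a 650–4000 cm⁻¹ grid at 2 cm⁻¹ steps (a typical
hand-held sampling interval; the step is configurable). A synthetic
API signature is a sum of Gaussian bands with absorbance strictly
proportional to surface density; the default has its strong band at
1230 cm⁻¹ inside the default calibration window plus two weaker bands.
Each measurement adds:

- one baseline realisation per measurement — a random offset
  (SD 0.01 AU default) plus a mild tilt — modelling coupon-to-coupon
  surface roughness;
- channel noise with SD `noise_sd_per_scan/√scans` (default
  0.004/√16 = 0.001 AU). "16 scans" is modelled as averaging 16
  i.i.d. noise realisations of one spectrum; interferogram-level
  co-addition is not modelled.

Pseudo-blank replicates share a single baseline realisation (fixed
instrument and sample, stable detector) while noise stays independent;
this is what makes the replicate SD a property of the detector chain
rather than of coupon roughness.

What the simulator does **not** emulate: real API band shapes and
overlaps, detector drift, non-linear absorbance, specular-reflectance
optics (no Kramers–Kronig correction), or operator handling. Passing
tests therefore demonstrate the statistical machinery on data obeying
the model's assumptions, not instrument performance on real residues.

## Preprocessing and PLS calibration

Models are built on narrow windows around strong bands (default
1200.20–1259.84 cm⁻¹; two windows are supported for two-band APIs).
Window membership uses closed intervals. Within each window the
straight line through the first and last channel is subtracted, which
removes additive offsets and tilts exactly — predictions are invariant
to a constant shift of the spectrum. Linear correction needs ≥ 3
channels per window.

The regression is univariate-response PLS (PLS1) via the NIPALS
recursion on mean-centred data: per component, weight w ∝ Xᵀy, score
t = Xw, loadings p = Xᵀt/tᵀt, q = yᵀt/tᵀt, then deflation of both
blocks. The inner iteration converges in one pass for a single
response; the loop still checks relative weight change (< 1e-10, max
500 iterations). Covariance below 1e-10 × ‖X‖‖y‖ is treated as
exhausted rank and raises a degenerate-data error rather than fitting
noise. With full-rank data and all components, the regression vector
equals the ordinary least-squares solution — used as a test oracle
(and cross-checked against scikit-learn, which is never the
implementation).

Component count is chosen by level-blocked cross-validation:
replicates of a calibration level always share a fold (contiguous
blocks of sorted levels), preventing replicate leakage; the smallest
count within 5 % of the minimum CV RMSE wins (parsimony). Models
serialise to a self-describing JSON document; floats use shortest-repr
encoding, so the round trip is lossless.

## Margin of error and capability

For n spot measurements, MOE(n) = t₁₋α/₂,ₙ₋₁ · SD/√n. Student's t
with df = n − 1 (not the normal 3.0 multiplier) is used throughout:
at the defaults (mean 0.6, SD 0.3, CI 99.73 %) it gives the 10-point
interval 0.212–0.988 µg/cm², whereas z would give 0.315–0.885. The
reported interval floors its lower bound at zero (residue cannot be
negative) while keeping the raw value for diagnostics. n starts at 2
(an SD needs two points).

Capability: CpK = (USL − mean)/(3σ) with σ = MOE(n), classified as
Poor < 1.33 ≤ Acceptable ≤ 1.67 < Good ≤ 2.00 < Excellent; the band
edges 1.33 and 1.67 are assigned to Acceptable and 2.00 to Good (the
published band table is ambiguous at its edges). CpK(n) is strictly
increasing, so the minimum n for a target is the first hit.

**Documented discrepancy.** Published guidance for this procedure
quotes 7 samples for CpK ≥ 1.33 and 10 for ≥ 1.67. Composing the CpK
formula with σ = MOE(n) under the stated defaults yields 86 and 133;
no quantile convention (t or z) reproduces the quoted counts.
`capability.discrepancy_note()` prints both; computation never uses
the quoted values.

## LOQ and the calibration floor

LOD = 3.3·SD and LOQ = 10·SD of ≥ 10 fixed-point replicate
*predictions* (the ICH Q2-style multipliers; configurable). Working in
prediction space makes the LOQ a property of the full chain. Fewer
than 10 replicates is allowed only in exploratory mode and flagged;
constant replicates give a flagged degenerate result. The LOQ becomes
the model's calibration floor: a training range dipping below it
invalidates the model, and later predictions under it carry a
below-LOQ flag (the value is still returned).

## Verification verdicts

Visual inspection gates everything: a visually failed surface is never
measured, so its report is `not-evaluated-visual-fail` with no
statistics. A wrong measurement count yields `inconclusive` (with
reason) rather than an exception. Otherwise the location's mean is
compared with the RAL (`pass`/`fail`) and, as a plausibility flag,
with the expected n-point interval. The four-way verdict taxonomy and
the uniform-random (possibly overlapping) measurement locations in
simulation are this package's choices; reporting uses 3 decimals for
densities. A configuration with RAL below the visual limit is rejected
outright.

## Problem sizes and determinism

Default study conditions: 3 coupons, 10 spots each; calibration at 5–6
levels × 5 replicates; 10 pseudo-blank replicates; Monte-Carlo checks
use 10³ spots and a few thousand spectrum replicates. All generators
take explicit seeds; identical seeds give bit-identical coupons,
spectra, bundles and report files. The acceptance script derives every
stream from its single `--seed` via `numpy.random.SeedSequence`.

## Known limitations

- The simulator's Gaussian-band, linear-response spectra are far
  cleaner than real specular-reflectance spectra; real calibrations
  will need more components and show higher LOQs.
- The grid (printer) mode's moiré with the spot footprint is a model
  artefact of perfectly regular pitch.
- The LOQ depends on the simulated noise floor, so its absolute value
  is a property of the chosen noise defaults, not a claim about any
  instrument.
- Tolerance intervals or non-parametric alternatives to the MOE bound
  are out of scope, as are instrument drivers and vendor file formats.
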