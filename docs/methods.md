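# Methods

This note documents the models behind `lungsbrt`: what is simulated, which
parameters matter, the numerical conventions, and what the synthetic study
can and cannot say about real patients.

## Coordinate conventions

Voxel indices are 0-based; the world coordinate of the center of voxel
(i, j, k) is `origin + index * spacing` (mm). Axes are (LR, AP, CC):
+x patient-left, +y posterior (toward the couch), +z cranial. A positive
craniocaudal offset is a cranial shift. All masks use voxel-center
membership; no partial-volume weighting enters any dose statistic.

## Synthetic phantom

The generator emulates the anatomy *statistics* of a lung SBRT cohort, not
patient geometry. On a default 64³ grid at 2.5 mm isotropic spacing
(160 mm cube — a thorax section scaled to desk size) it paints:

| tissue | ρ<sub>w</sub> mean ± SD | shape |
| --- | --- | --- |
| body (soft tissue) | 1.00 ± 0.05 | elliptic cylinder |
| lungs | 0.30 ± 0.18 | two ellipsoids |
| GTV | 1.00 ± 0.12 | sphere (optionally ellipsoid) in the left lung |
| heart | 1.10 ± 0.03 | ellipsoid |
| spinal cord | 1.00 ± 0.02 | posterior cylinder |
| esophagus | 1.00 ± 0.15 | cylinder |

Density noise is i.i.d. Gaussian per voxel, truncated at zero (this shifts
the realized lung mean from 0.300 to ≈0.303; tests account for it). The
soft-tissue figures are the generator's own choice where the study
conditions specify none.

The GTV radius is *calibrated*: a bisection on the voxelized volume makes
the realized mask volume match the request (supported range up to tens of
cc, covering 1.7–33.9 cc tumors) to well under 5%. The PTV is the GTV
dilated by a Euclidean 3 mm margin (exact distance transform honoring
anisotropic spacing). The GTV boundary is blended into lung over a
~2 mm partial-volume ramp confined to the PTV shell, so the PTV periphery
realizes an intermediate density (≈0.4 ± 0.18) without being painted as an
independent region; lung outside the PTV is pure lung. The lungs mask
excludes the GTV.

Grids and masks are exchanged as NIfTI with a diagonal affine; rotated or
sheared affines are rejected.

## Beam model

Beams are circular-collimated cones from a point source at SAD = 800 mm.
Source points sit on a Fibonacci lattice over a spherical cap centered on
the anterior axis with a configurable polar bound (default 100°), which
excludes through-couch directions while approximating the quasi-uniform
non-coplanar node set of a robotic SBRT unit. Collimator diameters come
from the fixed list {5, 7.5, 10, 12.5, 15, 20, 25, 30, 35, 40, 50, 60} mm
and are assigned round-robin; an iris-style variable collimator is treated
as equivalent to its per-beam fixed diameters. Every beam axis passes
through the target point exactly; initial MU weights are equal.

## EPL engine

The path-length engine computes, per beam and voxel,

    D = MU · cal · OF(ϕ) · (SAD/z)² · PDD(d_eff) · OAR(r)

* `d_eff` — radiological depth ∫ρ<sub>w</sub> dl from source to voxel by exact
  Amanatides–Woo/Siddon traversal (piecewise-constant voxels; outside the
  grid ρ<sub>w</sub> = 0). No interpolation, so line integrals are exactly
  additive over concatenated segments — a deliberate testability choice.
* `PDD(d) = (1 − e^{−βd}) e^{−μd}`, normalized to its maximum.
  Defaults: μ = 0.005 /mm (≈6 MV effective attenuation in water),
  β = 0.25 /mm (depth of maximum ≈ 15.7 mm).
* `OAR(r)` — a Gaussian-blurred circular field edge,
  0.5·erfc((r − R<sub>proj</sub>)/√2σ), exactly 0.5 at the projected field
  radius; R and the penumbra width scale with z/SAD along the ray fan.
  Default 80–20% penumbra: 4.5 mm — derived as the quadrature sum of the
  stochastic engine's electron kernel (2.5 mm) and source blur (1 mm), so
  the two engines share one water penumbra by construction.
* `OF(ϕ)` — field-size output factor: the fraction of a two-component
  (1−p, p = 0.15) kernel with broad-component σ = 10 mm captured inside a
  field of diameter ϕ, normalized at the 60 mm reference field. This is
  the same closed form the stochastic engine's broad kernel implies, so
  water agreement is structural rather than fitted.
* Contour correction is subsumed by tracing through the true body
  outline; there is no separate step.

The defining contract — dose depends on densities only through primary-ray
line integrals — is asserted in tests (lateral density blindness, shift
covariance in uniform media).

## Heterogeneity-aware ("MC-class") engine

A stochastic kerma-spread surrogate rather than full Klein–Nishina
transport, keeping the two effects a path-length engine misses:

1. Rays are sampled per history through the collimator aperture (uniform
   disk at the target plane, Gaussian source blur σ = 1 mm). Beam energy
   scales as MU × aperture area, making MU a fluence weight as in the EPL
   engine.
2. The ray marches in 2 mm steps with a random start phase (the phase
   jitter removes aliasing between the step comb and the voxel lattice).
   Per step the ray releases ΔE = E·(1 − e^{−μρΔs}), μ = 0.005 /mm.
3. Each released quantum is displaced *in radiological length*: forward by
   an exponential range (mean 4 mm·ρ<sub>w</sub>, which reproduces the β = 0.25 /mm
   build-up in water) and laterally by a Gaussian (σ = 2.5 mm·ρ<sub>w</sub>
   electron-like component; with probability 0.15 a broad σ = 10 mm·ρ<sub>w</sub>
   scatter component). The displacement is marched through the actual
   density grid, so electrons stop quickly in dense tissue and travel far
   in lung. This yields lateral scatter disequilibrium (central-axis dose
   loss and penumbra broadening in lung for small fields) and energy
   accretion on the dense side of interfaces — the density/targeting
   coupling mechanism itself.
4. Dose = deposited energy / voxel mass (mass ∝ ρ<sub>w</sub>). Voxels at or below
   ρ<sub>w</sub> = 0.02 are treated as massless: energy arriving there is dropped
   with a warning and the dose is 0.
5. Statistical uncertainty uses the batch method (≥10 batches): per-voxel
   relative SD of the mean of the *smoothed* batch doses; the engine adds
   batches until the mean relative SD over voxels above 50% of the maximum
   meets the target (default 1%) or the histories cap (default 2×10⁶) is
   reached, in which case the result is flagged, not discarded. Batch
   doses are smoothed with a unit-sum Gaussian of 0.6 *voxels* (the width
   is a kernel parameter; voxels are its unit here).
6. Energy bookkeeping (launched ≥ deposited + dropped) is tallied and
   asserted in tests; unsmoothed, uncalibrated dose × mass reproduces the
   deposited-energy tally exactly.

**Cross-calibration.** Both engines are normalized to the same axis dose
at reference conditions — an all-water phantom, the 60 mm reference field,
a small on-axis region at 50 mm depth — via one cached calibration run
with a fixed internal seed (the calibration is part of the engine
definition, not of any experiment's random state). Inter-engine
differences everywhere else therefore reflect heterogeneity handling, not
unit conventions. In water the engines agree within ~2–3% for fields
≥ 20 mm; agreement degrades for ≤10 mm fields where the electron kernel
itself breaks lateral equilibrium, which is the intended physics.

## Plan optimization and normalization

Optimization runs only on the EPL engine (mirroring the clinical two-step
workflow). Per-beam unit-MU dose matrices are precomputed over the PTV, a
20 mm conformity shell and sampled OAR voxels — dose linearity makes these
exact. A projected-gradient scheme on non-negative MUs minimizes a
quadratic pull of PTV voxels to 1.05·Rx with one-sided penalties on shell
(above 0.8·Rx) and OAR voxels, followed by a linear rescale that pins PTV
coverage at the requirement (V<sub>Rx</sub> = 95%) and guarantees full GTV
coverage. Feasibility is then checked on the full-grid dose; a violated
criterion is named in the result, never silently relaxed. With the default
geometry the prescription lands naturally near the 80% isodose line.

D<sub>q</sub> uses sorted-voxel counting: the largest dose d with
(volume ≥ d)/total ≥ q/100; no histogram bins. The conformity index is
prescription-isodose volume / PTV volume (the orientation that makes the
usual ≤1.2 limit meaningful). Renormalization to coverage is
s = Rx / D<sub>coverage</sub>(PTV), exact to the counting convention (a 10⁻⁹
relative bump keeps the pinned quantile voxel on the ≥Rx side of float
rounding).

## Geometric errors

Systematic errors translate every beam rigidly (source and target), the
model of a tracking system following a consistently wrong target estimate;
beam directions and SAD are preserved. Random errors give each beam its own
rigid offset: uniform [0,1] draws per axis, centered by their sample mean
(uncentered draws would smuggle in a systematic component), rescaled per
axis to σ<sub>tot</sub>/√3 so the realized root-square-sum of per-axis SDs equals
the requested σ<sub>tot</sub> exactly. σ<sub>tot</sub> = 0 is the explicit all-zero case.

## Study conditions and problem sizes

The standard desk-scale experiment (shared by the test suite and
`scripts/acceptance.py`) uses: 64³ voxels at 2.5 mm; a 20 cc GTV
(mid-range of 1.7–33.9 cc); 3 mm PTV margin; 100 beams with diameters
{20, 25, 30, 35, 40} mm; Rx = 60 Gy in 3 fractions; three replicate
phantom/plan seeds; ±3 mm craniocaudal offsets; stochastic doses at the 1%
batch-uncertainty target with a 2×10⁶-history cap. Sweep-style analyses
(random-error magnitudes, offset curves) use reduced statistics
(6×10⁵ histories, 2% target) — quantile metrics over ~10³-voxel structures
are robust at that level. These sizes are the package's chosen study
conditions; configurations are not tuned per run.

## What the phantom study does and does not show

The generator reproduces density statistics, target sizes, margins, beam
counts and prescription practice — not lobar anatomy, chest-wall curvature,
breathing deformation (4D effects are out of scope), or vendor beam data.
Consequently the *structural* findings transfer: EPL shift-equivalence
(offset GTV dose ≈ planned PTV dose within ~2 points of Rx), the
heterogeneity engine's coverage deficit at fixed MUs, renormalization
factors > 1, the positive offset-coupling excess, and random errors being
less damaging than equal-magnitude systematic ones. The *absolute*
patient-cohort numbers (e.g. cohort-mean D99 tables) do not transfer and
are not targets: they depend on the eight real CT anatomies. On this
phantom the coupling excess is larger than typical clinical values because
the synthetic PTV periphery is uniformly lung-like, a conservative
worst-case for the periphery deficit.

## Known limitations

* The stochastic engine is a surrogate: no energy spectrum, no explicit
  secondary-particle transport, no backscatter; its validity is bounded by
  the water benchmarks and the qualitative lung physics asserted in tests.
* The optimizer handles MU weights only (no fluence maps), matching
  circular-collimator planning but not MLC systems.
* OAR tolerance limits are configurable placeholders, not a clinical
  protocol table.
* Only rigid translational errors are modeled; no rotations, no
  time-resolved (breathing-phase-correlated) error structure.
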