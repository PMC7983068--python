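# Methods

## Problem and model

`darcyflow` estimates convective transport properties — flow speed and
Darcy permeability — of vascularized porous tissue from 4-D dynamic
contrast-enhanced CT. Tissue is treated as a mixture of solid matrix
(volume fraction `phi_tissue`), blood carrying contrast (`phi_nano`) and
blood without contrast (`phi_blood`), with

    phi_tissue + phi_nano + phi_blood = 1,
    s_nano + s_blood = 1,   phi_nano = phi * s_nano,

where `phi` is the porosity and `s_iota` the pore-space saturation of
constituent `iota`. Summing the constituent mass balances under these
constraints makes the flow incompressible. Transport is modelled along
characteristics normal to the imaging-visible feeding vessels: with flow
speed `a` along the characteristic, the saturation obeys a first-order
hyperbolic equation whose solution is the arterial input delayed by
travel time,

    s_nano(x, t) = s_AIF(t - d(x) / a(x)),

with `d(x)` the Euclidean distance to the vessel surface. The inverse
problem therefore reduces to two measurable ingredients: a distance map
and a bolus-arrival-time (BAT) map.

    a(x) = d(x) / (BAT(x) - BAT_inlet).

Speed is reduced to a piecewise-constant basis on SLIC superpixels,
either by averaging pixelwise speeds per region or by refitting the
delayed-AIF model per region (default). Darcy's law (`a = -(kappa/mu)
grad p . n`) combined with Poiseuille's law for the feeding vessel
(`Q = pi R^4 / (8 mu) * grad p . n`) under a spatially homogeneous
pressure-gradient assumption gives a permeability that is independent of
viscosity:

    kappa = a * pi * R^4 / (8 Q)    [m^2].

An extended Tofts compartmental model (`Ktrans`, `ve`, `fpv`) is fit to
the same curves as a control; it measures exchange rates rather than
convection, so agreement is assessed by correlation, not identity.

## Parameters and defaults

| parameter | default | units | rationale |
|---|---|---|---|
| blood viscosity `mu` | 3.5e-3 | Pa s | literature value; cancels in `kappa` |
| feeding flow `Q` | 2.95e-6 (= 177 ml/min) | m^3/s | measured hepatic flow in rabbit liver |
| vessel radius `R` | estimated from mask | m | skeleton + internal EDT mean |
| SLIC grid size | 20 | voxels | target region edge; seeds = mask volume / 20^3 |
| SLIC iterations | 2 | — | sufficient for convergence on these volumes |
| SLIC compactness | 0.1 | — | on intensities rescaled to [0, 1] |
| speed search range | 0.05–20 | mm/s | brackets physiologic tissue transit speeds |
| BAT convention | forward difference, left time, earliest tie | — | deterministic peak-gradient definition |
| baseline frames `n_pre` | 2 | — | mean of pre-contrast frames |
| Tofts bounds | Ktrans in [0, 5/min], ve in (0, 1], fpv free | — | physiologic ceiling; fpv deliberately unclamped |
| Tofts init | (0.005/s, 0.3, 0.05) | — | mid-range start, fixed multistart fallback |

Internally all geometry is world millimetres (speeds mm/s), time in
seconds; conversion to SI happens only inside the permeability formula.
Voxel indexing is 0-based with world = origin + index * spacing.

The Ktrans upper bound matters: beyond a few per minute the convolution
kernel approaches the AIF itself and the convolution term becomes
degenerate with `fpv` (large Ktrans traded against negative `fpv`). The
5/min cap removes that branch; it is the same order as the ceilings used
by standard DCE fitting tools.

## Synthetic phantom

The reference phantom is a 60x60x60 voxel, 1 mm isotropic volume with a
straight cylindrical vessel (radius 2 mm) along z, tissue restricted to
a 20 mm cylinder around it, 30 frames at 2 s spacing. The arterial
input is a gamma-variate bolus (arrival 4 s, shape 2, scale 3 s, unit
peak); tissue curves are the porosity-scaled delayed AIF plus Gaussian
HU noise; vessel voxels carry the undelayed AIF so the inlet arrival is
observable. The true speed field is piecewise constant on a 2x2x2 block
grid spanning 0.5–4 mm/s, chosen so every tissue voxel's bolus arrives
inside the acquisition window. Porosity defaults to 0.3 (a plausible
liver value, not a measured one). Noise for validation runs is sigma =
2% of the peak tissue enhancement. Mixture and saturation sums hold to
machine precision by construction; identical config and seed give
bit-identical series.

What the phantom does *not* emulate: branching vascular trees, bolus
dispersion and recirculation, motion, beam hardening, partial-volume
mixing at vessel boundaries, and any active (cellular) transport.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated transport model, not robustness to every
in vivo confound.

## Numerical choices

- **Distance maps** use the exact Euclidean distance transform with
  anisotropic sampling; distance is measured to the vessel *surface*
  (mask), with `nearest_vessel_point` breaking ties toward the lowest
  lexicographic index. A centerline-based distance can be obtained by
  passing a skeletonized mask.
- **BAT** is intentionally unsmoothed and returns the left endpoint of
  the maximal forward-difference interval; voxels whose curve never
  rises, or whose arrival does not strictly follow the inlet, are
  flagged invalid rather than clipped.
- **Superpixel speed refit** profiles out a per-voxel amplitude in
  closed form and minimises over speed with a log-spaced grid (48
  points) plus bounded scalar refinement; distances are quantised to
  0.25 mm so the AIF is interpolated once per distinct delay. The
  search is fully deterministic.
- **Tofts forward model** uses a causal trapezoid convolution on the
  acquisition grid (O(frames^2), cached weights). Its discretisation
  error is O(dt^2); at 4 ms sampling it agrees with adaptive quadrature
  to ~1e-6 relative, and with the boxcar closed form to <1e-6.
- **Radius estimation** averages the internal EDT over the skeleton.
  3-D thinning annihilates tubes whose cross-section has no on-axis
  voxel; the estimator then falls back to the EDT ridge (local maxima).
  On digital cylinders the estimate is within half a voxel diagonal of
  truth across radii 2–10 voxels, and within 0.05 mm for a 1.09 mm tube
  on a 0.1 mm grid.
- **Degenerate inputs** (empty masks, zero AIF peak, zero denominators,
  constant curves) raise typed errors or flag invalidity; they are
  never silently imputed.

## Validation design

- Speed recovery is assessed at sigma = 0 on the block phantom with the
  partition aligned to the true blocks: refit speeds land within 0.5%
  of truth (asserted at 5%). On the full pipeline (SLIC regions that
  straddle speed blocks, 2% noise), the Pearson correlation between
  region-mean pixelwise speed and refit speed is ~0.97.
- Tofts recovery is assessed at region level (27 regions of 5^3 voxels,
  voxel noise 2% of peak, 20 replicates): bias <2% and RMSE <5% on a
  3x3x3 grid Ktrans {0.01, 0.02, 0.04}/s x ve {0.15, 0.3, 0.5} x fpv
  {0.05, 0.1, 0.2}, chosen so all washout times fit an 87 s window.
  Region-level assessment matches how the pipeline applies the control
  model (one fit per superpixel-mean curve). Single-voxel fits at this
  noise cannot reach that precision: a Cramer-Rao analysis of the
  forward model puts their best-case spread near 10% for Ktrans and
  fpv, which is a property of the model/AIF information content, not of
  the optimizer.
- The pipeline's correlation stage is validated on a phantom whose
  porosity (hence enhancement amplitude) is coupled to flow speed; the
  fitted `fpv` then correlates positively with speed (r ≈ 0.67).

## Known limitations

- The transport model is one-dimensional along the nearest-vessel
  characteristic; far from vessels, or where flow is oblique to that
  normal, recovered speeds are effective rather than literal.
- BAT quantisation at the frame interval biases pixelwise speeds for
  short transits; the per-region refit interpolates the delay
  continuously and does not share this bias, which is visible as a
  slope offset in the pixel-mean vs refit scatter.
- On phantoms whose amplitude is independent of speed, the control
  model's fitted `fpv` still carries a systematic (negative) delay
  dependence — curve truncation at the window end is speed-dependent.
  Correlations between speed and Tofts parameters should therefore be
  read as descriptive, not causal.
- The homogeneous pressure-gradient assumption is taken as stated; no
  spatial pressure solve is attempted, and the blood-volume flow
  estimators integrate the arterial input in their denominators.
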