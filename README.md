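# darcyflow

Recovery of convective transport properties — flow speed and Darcy
permeability — of porous, vascularized tissue from 4-D dynamic
contrast-enhanced CT, with an extended Tofts compartmental model as a
control and a fully synthetic perfusion phantom for validation.

Classical pharmacokinetic (compartmental) analysis yields rate
constants with no direct meaning in the governing equations of
convective flow. `darcyflow` instead treats the contrast bolus as a
tracer carried through a porous medium: along the characteristic normal
to a feeding vessel the pore saturation is the arterial input function
delayed by travel time,

    s_nano(x, t) = s_AIF(t - d(x)/a(x)),

so the flow speed at a voxel is simply the distance to the nearest
vessel surface, `d(x)` (from a Euclidean distance transform of the
vessel segmentation), divided by the bolus transit time (peak-gradient
bolus arrival time minus arrival at the inlet). Speed is reduced to a
piecewise-constant field on SLIC superpixels (grid 20 voxels, 2
iterations) and converted to a Darcy permeability through Poiseuille's
law for the feeding vessel,

    kappa = a * pi * R^4 / (8 Q)   [m^2],

with `R` the mean vessel radius (skeleton + internal distance
transform) and `Q` the feeding flow rate (default 177 ml/min, measured
in rabbit liver); the blood viscosity cancels. The extended Tofts model

    s(t) = Ktrans * int_0^t s_AIF(u) e^{-(Ktrans/ve)(t-u)} du + fpv * s_AIF(t)

is fit to the same curves (voxelwise or per superpixel) as the
compartmental control, and per-region Pearson correlations between flow
speed and (Ktrans, ve, fpv) are reported.

Intended users: quantitative imaging and tumor-transport researchers
who want permeability in the Darcy sense (m^2, directly usable in
porous-media flow simulations for drug or nanoparticle delivery
planning) rather than compartmental rate constants.

## Worked example

Run the full pipeline on the built-in validation phantom (a 60 mm cube
with a cylindrical feeding vessel, eight constant-speed tissue blocks
spanning 0.5–4 mm/s, and 2% additive noise):

```python
import darcyflow as df

cfg = df.RunConfig(out_dir="out", seed=12345)
cfg.phantom.noise_sigma = 0.02 * cfg.phantom.contrast_scale * cfg.phantom.porosity
bundle = df.run_pipeline(cfg)
for c in bundle.correlations:
    print(f"r({c.pair}) = {c.r:+.3f} (p={c.p:.2g}, n={c.n})")
print(f"inlet BAT = {bundle.inlet_bat:.1f} s, "
      f"vessel radius = {bundle.vessel_radius_m*1e3:.2f} mm")
print(f"mean permeability = {bundle.mean_permeability:.3e} m^2")
```

prints

    r(speed_vs_ktrans) = +0.919 (p=0.00045, n=9)
    r(speed_vs_ve) = -0.580 (p=0.1, n=9)
    r(speed_vs_fpv) = -0.015 (p=0.97, n=9)
    r(pixel_mean_speed_vs_fit_speed) = +0.972 (p=1.2e-05, n=9)
    inlet BAT = 6.0 s, vessel radius = 1.41 mm
    mean permeability = 9.273e-10 m^2

The phantom's tissue mask decomposes into 9 superpixels. The key
number is `r(pixel_mean_speed_vs_fit_speed) = +0.972`: the flow speed
obtained by refitting the delayed-AIF transport model per superpixel
agrees with the superpixel average of the voxelwise distance/transit
speeds, i.e. the superpixel decomposition is a faithful
piecewise-constant reduction of the heterogeneous speed field. The
permeability is the mean Darcy `kappa` over tissue, from the fitted
region speeds, the estimated vessel radius and the configured feeding
flow rate. The Tofts correlations illustrate the control comparison;
see `docs/methods.md` for how to read them.

The same run is available from the shell:

    darcyflow run --seed 12345 --out out/
    darcyflow phantom --seed 3 --out phantom_dir/   # series + ground truth
    darcyflow report --in out/                      # re-print correlations

`out/` contains `regions.csv` (per-superpixel distances, speeds,
permeability, Tofts parameters), `correlations.csv` and a
`manifest.json` recording stages, constants, seed and input hashes.

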