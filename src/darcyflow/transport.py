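"""Convective transport estimators: flow speed, superpixel reduction,
Darcy permeability, flow-rate and blood-volume relations.

The flow speed at a voxel is the distance to the feeding-vessel surface
divided by the bolus transit time (arrival at the voxel minus arrival at
the inlet). Speed is reduced to a piecewise-constant field on SLIC
superpixels, either by averaging the pixelwise speeds or by refitting
the delayed-AIF transport solution per region (the default). Darcy's
law combined with Poiseuille's law turns speed into a permeability:

    grad p . n = 8 mu Q / (pi R^4)          (Poiseuille)
    kappa      = a pi R^4 / (8 Q)           (Darcy; viscosity cancels)

with Q the feeding flow rate (m^3/s), R the mean vessel radius (m) and
a the flow speed in m/s. Speeds are carried in mm/s and converted only
here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from skimage.segmentation import slic as _slic

from .core import AIFCurve, DynamicImage, Image3D, LabelMap
from .errors import ArgumentError, DegenerateInputError
from .kinetics import BATMap

#: 177 ml/min, hepatic arterial + portal flow measured in rabbit liver
RABBIT_LIVER_FLOW_M3S = 177e-6 / 60.0
#: blood viscosity, Pa s
BLOOD_VISCOSITY = 3.5e-3
MM_PER_S_TO_M_PER_S = 1e-3


# ---------------------------------------------------------------------------
# pixelwise speed


@dataclass
class SpeedField:
    """Voxelwise flow speed a(x) in mm/s with a validity mask."""

    speed: Image3D
    valid: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.speed.values


def pixelwise_speed(distance: Image3D, bat: BATMap, inlet_bat: float) -> SpeedField:
    """a(x) = d(x) / (BAT(x) - inlet_bat), mm/s.

    Voxels whose arrival does not strictly follow the inlet arrival have
    an undefined transit time and are flagged invalid (not clipped).
    """
    if distance.values.shape != bat.values.shape:
        raise ArgumentError("distance and BAT maps must share one grid")
    transit = bat.values - inlet_bat
    valid = bat.valid & np.isfinite(transit) & (transit > 0) & (distance.values > 0)
    a = np.full(distance.values.shape, np.nan)
    a[valid] = distance.values[valid] / transit[valid]
    if not valid.any():
        import warnings

        warnings.warn("no voxel has a positive transit time; speed field is empty")
    return SpeedField(Image3D(a, distance.spacing, distance.origin), valid)


# ---------------------------------------------------------------------------
# superpixels


@dataclass
class SuperpixelPartition:
    """Compact piecewise-constant decomposition of the tissue mask.

    ``labels`` holds region ids 1..n inside the mask and 0 outside.
    """

    labels: np.ndarray
    mask: np.ndarray
    spacing: tuple[float, float, float]
    region_ids: np.ndarray = field(init=False)
    voxel_counts: np.ndarray = field(init=False)

    def __post_init__(self):
        inside = self.labels[self.mask]
        self.region_ids, self.voxel_counts = np.unique(inside[inside > 0], return_counts=True)

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    @property
    def mean_region_volume_mm3(self) -> float:
        return float(self.voxel_counts.mean() * np.prod(self.spacing))

    def region_mean(self, values: np.ndarray) -> np.ndarray:
        """Mean of ``values`` over each region, ignoring NaNs; NaN when empty."""
        out = np.full(self.n_regions, np.nan)
        for i, rid in enumerate(self.region_ids):
            v = values[self.labels == rid]
            v = v[np.isfinite(v)]
            if len(v):
                out[i] = v.mean()
        return out

    def paint(self, region_values: np.ndarray) -> np.ndarray:
        """Voxel field with each region filled by its scalar value."""
        out = np.full(self.labels.shape, np.nan)
        for rid, val in zip(self.region_ids, region_values):
            out[self.labels == rid] = val
        return out


def slic_superpixels(reference: Image3D, mask: LabelMap | np.ndarray,
                     grid_size: int = 20, iterations: int = 2,
                     compactness: float = 0.1,
                     labels=("parenchyma", "tumor")) -> SuperpixelPartition:
    """SLIC clustering of the reference volume restricted to a mask.

    ``grid_size`` sets the target region edge length in voxels (the
    number of seeds is the mask volume divided by grid_size^3). The
    reference intensities are rescaled to [0, 1] so ``compactness``
    keeps one meaning across inputs; clustering distance is measured in
    world coordinates via the voxel spacing.
    """
    m = mask.mask(*labels) if isinstance(mask, LabelMap) else np.asarray(mask, bool)
    if not m.any():
        raise DegenerateInputError("superpixel mask is empty")
    vals = reference.values.astype(float)
    lo, hi = vals[m].min(), vals[m].max()
    if hi > lo:
        vals = (vals - lo) / (hi - lo)
    else:
        vals = np.zeros_like(vals)
    n_segments = max(1, int(round(m.sum() / grid_size**3)))
    if n_segments == 1:
        lab = m.astype(np.int64)
    else:
        lab = _slic(
            vals,
            n_segments=n_segments,
            compactness=compactness,
            max_num_iter=iterations,
            spacing=reference.spacing,
            mask=m,
            channel_axis=None,
            start_label=1,
            enforce_connectivity=True,
        )
        lab = np.where(m, lab, 0)
    return SuperpixelPartition(lab.astype(np.int64), m, reference.spacing)


# ---------------------------------------------------------------------------
# per-region speed fit


@dataclass
class RegionSpeeds:
    """Per-superpixel flow speeds alpha_i (mm/s)."""

    region_ids: np.ndarray
    alpha: np.ndarray           # mm/s, NaN where invalid
    valid: np.ndarray
    sse: np.ndarray             # residual sum of squares per region


def superpixel_speed_fit(sat: DynamicImage, aif: AIFCurve, distance: Image3D,
                         partition: SuperpixelPartition,
                         a_min: float = 0.05, a_max: float = 20.0,
                         n_grid: int = 48, d_quant: float = 0.25,
                         min_energy: float = 1e-12) -> RegionSpeeds:
    """Fit one flow speed per superpixel to the delayed-AIF transport model.

    For region i the speed alpha_i minimises

        sum_{x in region} sum_t ( sat(x,t) - c_x * s_AIF(t - d(x)/alpha_i) )^2

    with the per-voxel amplitude c_x profiled out by linear least
    squares (the HU proportionality constant and local porosity are
    unknown, so only the delay carries speed information). The search is
    a deterministic log-spaced grid over [a_min, a_max] mm/s followed by
    bounded scalar refinement. Distances are quantised to ``d_quant`` mm
    so the AIF is interpolated once per distinct delay.
    """
    times = sat.times
    grid = np.geomspace(a_min, a_max, n_grid)
    n = partition.n_regions
    alpha = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    sse = np.full(n, np.nan)

    for i, rid in enumerate(partition.region_ids):
        sel = partition.labels == rid
        sm = sat.values[sel]                      # (V, T)
        d = distance.values[sel]
        fin = np.all(np.isfinite(sm), axis=1) & np.isfinite(d) & (d > 0)
        sm, d = sm[fin], d[fin]
        if len(d) == 0:
            continue
        ss_x = (sm**2).sum(axis=1)
        if ss_x.sum() <= min_energy * max(len(d), 1):
            continue
        dq = np.round(d / d_quant) * d_quant
        uniq, inv = np.unique(dq, return_inverse=True)

        def ssr(a):
            g = aif.sample(times[None, :] - uniq[:, None] / a)   # (U, T)
            den = (g * g).sum(axis=1)[inv]                        # (V,)
            num = (sm * g[inv]).sum(axis=1)
            proj = np.zeros_like(num)
            ok = den > 1e-30
            proj[ok] = num[ok] ** 2 / den[ok]
            return float(ss_x.sum() - proj.sum())

        vals = np.array([ssr(a) for a in grid])
        j = int(np.argmin(vals))
        if not np.isfinite(vals[j]) or vals[j] >= ss_x.sum() - min_energy:
            # no delay explains any signal (e.g. bolus never arrives)
            continue
        lo = grid[max(j - 1, 0)]
        hi = grid[min(j + 1, n_grid - 1)]
        if lo < hi:
            res = minimize_scalar(ssr, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-5})
            alpha[i], sse[i] = float(res.x), float(res.fun)
        else:
            alpha[i], sse[i] = float(grid[j]), float(vals[j])
        valid[i] = True
    return RegionSpeeds(partition.region_ids.copy(), alpha, valid, sse)


def region_mean_speeds(speed: SpeedField, partition: SuperpixelPartition) -> np.ndarray:
    """Alternative reduction: superpixel mean of the pixelwise speeds."""
    vals = np.where(speed.valid, speed.values, np.nan)
    return partition.region_mean(vals)


# ---------------------------------------------------------------------------
# Darcy / Poiseuille


def pressure_gradient_poiseuille(Q: float, R: float, mu: float = BLOOD_VISCOSITY) -> float:
    """Pressure gradient (Pa/m) sustaining laminar flow Q through a tube of radius R."""
    if Q <= 0 or R <= 0 or mu <= 0:
        raise ArgumentError(f"Q, R, mu must be positive, got {Q}, {R}, {mu}")
    return 8.0 * mu * Q / (np.pi * R**4)


def permeability(speed_m_s, R: float, Q: float):
    """Darcy permeability kappa = a pi R^4 / (8 Q), in m^2.

    ``speed_m_s`` may be a scalar or an array of speeds in m/s; the
    blood viscosity cancels between Darcy's and Poiseuille's laws.
    """
    if R <= 0 or Q <= 0:
        raise ArgumentError(f"R and Q must be positive, got {R}, {Q}")
    return np.asarray(speed_m_s, dtype=float) * np.pi * R**4 / (8.0 * Q)


def permeability_map(speed: SpeedField, R_m: float, Q_m3s: float) -> Image3D:
    """Voxelwise kappa (m^2) from a speed field carried in mm/s."""
    kappa = np.full(speed.values.shape, np.nan)
    kappa[speed.valid] = permeability(
        speed.values[speed.valid] * MM_PER_S_TO_M_PER_S, R_m, Q_m3s
    )
    return Image3D(kappa, speed.speed.spacing, speed.speed.origin)


# ---------------------------------------------------------------------------
# indicator-dilution style flow estimates


def flow_rate_from_mass(phi_nano: DynamicImage, roi: LabelMap | np.ndarray,
                        inlet_curve: np.ndarray, T_index: int = -1,
                        density: float = 1000.0, labels=("parenchyma", "tumor")) -> float:
    """Inflow rate Q (m^3/s) from mass conservation over an inflow-only window.

    Q = m(T) / int_0^T rho phi_in dt, with m(T) the contrast mass
    accumulated in the ROI at the window end and ``inlet_curve`` the
    porosity-scaled saturation history at the feeding vessel. The mass
    density cancels; it is kept explicit for unit transparency.
    """
    m = roi.mask(*labels) if isinstance(roi, LabelMap) else np.asarray(roi, bool)
    if not m.any():
        raise DegenerateInputError("flow ROI is empty")
    times = phi_nano.times
    T_index = int(np.arange(len(times))[T_index])
    voxel_m3 = float(np.prod(phi_nano.spacing)) * 1e-9
    mass_T = density * float(phi_nano.values[m, T_index].sum()) * voxel_m3
    inlet = np.asarray(inlet_curve, dtype=float)[: T_index + 1]
    denom = density * float(np.trapezoid(inlet, times[: T_index + 1]))
    if denom <= 0:
        raise DegenerateInputError("inlet curve integrates to zero over the window")
    return mass_T / denom


def blood_volume_map(phi_nano: DynamicImage, aif: AIFCurve) -> Image3D:
    """Blood volume BV(x) = AUC of the tissue curve over AUC of the AIF.

    Dimensionless; equals 1 where the tissue curve reproduces the
    arterial input exactly.
    """
    aif_auc = float(np.trapezoid(aif.saturation, aif.times))
    if aif_auc <= 0:
        raise DegenerateInputError("AIF area under the curve must be positive")
    auc = np.trapezoid(phi_nano.values, phi_nano.times, axis=3)
    return Image3D(auc / aif_auc, phi_nano.spacing, phi_nano.origin)


def mean_flow_from_bv(bv: Image3D, dt: float) -> float:
    """Average flow rate Q (m^3/s) from the blood-volume map: (1/dt) * int BV dV."""
    if dt <= 0:
        raise ArgumentError(f"dt must be positive, got {dt}")
    vals = bv.values[np.isfinite(bv.values)]
    voxel_m3 = bv.voxel_volume * 1e-9
    return float(vals.sum()) * voxel_m3 / dt
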