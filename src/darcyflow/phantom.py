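"""Synthetic perfusion phantoms with exact ground truth.

The dynamic phantom realises the one-dimensional characteristic solution
of convective transport through porous tissue: along the normal from the
feeding vessel the nanoparticle saturation is the arterial input delayed
by distance over flow speed,

    s_nano(x, t) = s_AIF(t - d(x) / a(x)),

with d(x) the Euclidean distance to the vessel surface and a(x) a
piecewise-constant speed field. The CT signal is

    I(x, t) = I_b + C * phi(x) * s_nano(x, t) + eps,   eps ~ N(0, sigma),

where phi is the tissue porosity and C the HU enhancement of fully
saturated pore space. Vessel voxels carry the undelayed arterial input
(pure blood, phi = 1), so inlet arrival is observable in the image.

Mixture bookkeeping is exact by construction:
phi_tissue + phi_nano + phi_blood = 1 and s_nano + s_blood = 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import LABELS, AIFCurve, DynamicImage, Image3D, LabelMap
from .errors import ArgumentError
from .tofts import extended_tofts_forward
from .vessels import distance_map


def gamma_variate_aif(t0: float, alpha: float, beta: float, amplitude: float,
                      times: Sequence[float]) -> AIFCurve:
    """Gamma-variate bolus model, the standard first-pass AIF shape.

    s(t) = A * ((t - t0) / (alpha*beta))^alpha * exp(alpha - (t - t0)/beta)
    for t > t0 and 0 before arrival; the peak (value A) occurs at
    t0 + alpha*beta.
    """
    if alpha <= 0 or beta <= 0:
        raise ArgumentError(f"alpha and beta must be positive, got {alpha}, {beta}")
    if amplitude <= 0:
        raise ArgumentError(f"amplitude must be positive, got {amplitude}")
    t = np.asarray(times, dtype=float)
    dt = t - t0
    with np.errstate(invalid="ignore"):
        s = np.where(
            dt > 0,
            amplitude * (dt / (alpha * beta)) ** alpha * np.exp(alpha - dt / beta),
            0.0,
        )
    return AIFCurve(t, s, peak_enhancement=amplitude)


@dataclass
class PhantomConfig:
    """Study conditions for the dynamic transport phantom.

    Defaults match the package's reference phantom: a 60^3 voxel, 1 mm
    isotropic grid imaged over 30 frames at 2 s spacing, a straight
    cylindrical feeding vessel along z, and a 2x2x2 block speed field
    spanning 0.5-4 mm/s.
    """

    shape: tuple[int, int, int] = (60, 60, 60)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    # vessel: straight cylinder along `vessel_axis` through the grid centre
    vessel_axis: int = 2
    vessel_radius: float = 2.0          # mm
    aorta_extent: int = 6               # axial slabs labelled as AIF ROI
    tissue_radius: float = 20.0         # mm; tissue = cylinder shell around the vessel
    porosity: float = 0.3               # pore fraction phi in (0,1)
    block_grid: tuple[int, int, int] = (2, 2, 2)
    block_speeds: tuple[float, ...] = (0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0)  # mm/s
    # porosity_speed_coupling > 0 scales phi with the local speed so that
    # enhancement amplitude (hence fitted fpv) co-varies with flow speed
    porosity_speed_coupling: float = 0.0
    aif_t0: float = 4.0                 # s, bolus arrival at the inlet
    aif_alpha: float = 2.0
    aif_beta: float = 3.0               # s
    aif_amplitude: float = 1.0          # dimensionless saturation peak, <= 1
    baseline_hu: float = 40.0
    contrast_scale: float = 200.0       # HU of fully saturated pore space
    noise_sigma: float = 0.0            # HU
    n_frames: int = 30
    frame_dt: float = 2.0               # s
    seed: int = 12345

    def __post_init__(self):
        if self.vessel_radius <= 0:
            raise ArgumentError("vessel_radius must be positive")
        if not 0 < self.porosity < 1:
            raise ArgumentError(f"porosity must be in (0,1), got {self.porosity}")
        if len(self.block_speeds) != int(np.prod(self.block_grid)):
            raise ArgumentError("block_speeds length must equal prod(block_grid)")
        if any(a <= 0 for a in self.block_speeds):
            raise ArgumentError("all block speeds must be positive")
        if self.noise_sigma < 0:
            raise ArgumentError("noise_sigma must be nonnegative")
        if not 0 < self.aif_amplitude <= 1:
            raise ArgumentError("aif_amplitude must lie in (0,1] for a valid saturation")

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_dt


@dataclass
class PhantomGroundTruth:
    """Everything the series was generated from, for recovery tests."""

    speed: Image3D                  # mm/s, NaN outside tissue
    distance: Image3D               # mm to vessel surface
    porosity: Image3D               # phi, 1 inside vessel, 0 in background
    vessel_mask: np.ndarray
    tissue_mask: np.ndarray
    labels: LabelMap
    aif: AIFCurve
    s_nano: np.ndarray              # (nx,ny,nz,nt)
    s_blood: np.ndarray
    phi_tissue: np.ndarray          # (nx,ny,nz)
    phi_nano: np.ndarray            # (nx,ny,nz,nt)
    phi_blood: np.ndarray
    config: PhantomConfig = field(repr=False, default=None)


def _vessel_and_tissue_masks(cfg: PhantomConfig):
    nx, ny, nz = cfg.shape
    ax = cfg.vessel_axis
    plane = [i for i in range(3) if i != ax]
    coords = [np.arange(n) * s for n, s in zip(cfg.shape, cfg.spacing)]
    centre = [(n - 1) / 2.0 * s for n, s in zip(cfg.shape, cfg.spacing)]
    grid = np.meshgrid(*coords, indexing="ij")
    r2 = (grid[plane[0]] - centre[plane[0]]) ** 2 + (grid[plane[1]] - centre[plane[1]]) ** 2
    vessel = r2 <= cfg.vessel_radius**2
    if cfg.tissue_radius is None:
        tissue = ~vessel
    else:
        tissue = (r2 <= cfg.tissue_radius**2) & ~vessel
    return vessel, tissue


def _block_index(cfg: PhantomConfig) -> np.ndarray:
    """Regular block partition of the grid; returns flat block id per voxel."""
    idx = []
    for axis in range(3):
        n, b = cfg.shape[axis], cfg.block_grid[axis]
        edges = (np.arange(n) * b) // n
        idx.append(edges)
    bi, bj, bk = np.meshgrid(*idx, indexing="ij")
    g = cfg.block_grid
    return (bi * g[1] + bj) * g[2] + bk


def build_phantom(config: PhantomConfig) -> tuple[DynamicImage, PhantomGroundTruth]:
    """Generate the dynamic series and its exact ground truth.

    Deterministic for a fixed config (the seed drives the noise stream).
    """
    cfg = config
    times = cfg.times
    rng = np.random.default_rng(cfg.seed)
    vessel, tissue = _vessel_and_tissue_masks(cfg)

    # piecewise-constant true speed field (mm/s)
    speeds = np.asarray(cfg.block_speeds, dtype=float)
    block = _block_index(cfg)
    speed = np.full(cfg.shape, np.nan)
    speed[tissue] = speeds[block[tissue]]

    # porosity, optionally coupled to speed so amplitude tracks flow
    phi = np.zeros(cfg.shape)
    phi[tissue] = cfg.porosity
    if cfg.porosity_speed_coupling > 0:
        rel = speeds[block[tissue]] / speeds.mean()
        phi[tissue] = np.clip(
            cfg.porosity * (1.0 + cfg.porosity_speed_coupling * (rel - 1.0)), 0.05, 0.95
        )
    phi[vessel] = 1.0

    # labels: aorta = first slabs of the vessel along its axis
    lab = np.zeros(cfg.shape, dtype=np.int32)
    lab[tissue] = LABELS["parenchyma"]
    lab[vessel] = LABELS["vessel"]
    aorta_sel = np.zeros(cfg.shape, bool)
    sl = [slice(None)] * 3
    sl[cfg.vessel_axis] = slice(0, cfg.aorta_extent)
    aorta_sel[tuple(sl)] = True
    lab[vessel & aorta_sel] = LABELS["aorta"]
    labels = LabelMap(lab, cfg.spacing, (0.0, 0.0, 0.0))

    vessel_lm = LabelMap((vessel).astype(np.int32) * LABELS["vessel"], cfg.spacing,
                         (0.0, 0.0, 0.0))
    dist = distance_map(vessel_lm, labels=("vessel",))

    aif = gamma_variate_aif(cfg.aif_t0, cfg.aif_alpha, cfg.aif_beta, cfg.aif_amplitude, times)

    # delayed arterial input on the characteristics: s_nano(x,t) = s_AIF(t - d/a)
    delay = np.zeros(cfg.shape)
    delay[tissue] = dist.values[tissue] / speed[tissue]
    s_nano = np.zeros(cfg.shape + (len(times),))
    active = tissue | vessel
    arg = times[None, :] - delay[active][:, None]
    s_nano[active] = _gamma_eval(cfg, arg)
    s_blood = np.zeros_like(s_nano)
    s_blood[active] = 1.0 - s_nano[active]

    phi_tissue = 1.0 - phi
    phi_nano = phi[..., None] * s_nano
    phi_blood = phi[..., None] - phi_nano

    signal = cfg.baseline_hu + cfg.contrast_scale * phi_nano
    if cfg.noise_sigma > 0:
        signal = signal + rng.normal(0.0, cfg.noise_sigma, size=signal.shape)

    img = DynamicImage(signal, cfg.spacing, (0.0, 0.0, 0.0), times)
    gt = PhantomGroundTruth(
        speed=Image3D(speed, cfg.spacing),
        distance=dist,
        porosity=Image3D(phi, cfg.spacing),
        vessel_mask=vessel,
        tissue_mask=tissue,
        labels=labels,
        aif=aif,
        s_nano=s_nano,
        s_blood=s_blood,
        phi_tissue=phi_tissue,
        phi_nano=phi_nano,
        phi_blood=phi_blood,
        config=cfg,
    )
    return img, gt


def _gamma_eval(cfg: PhantomConfig, t: np.ndarray) -> np.ndarray:
    """Evaluate the configured gamma-variate AIF at arbitrary times."""
    dt = t - cfg.aif_t0
    with np.errstate(invalid="ignore"):
        return np.where(
            dt > 0,
            cfg.aif_amplitude
            * (dt / (cfg.aif_alpha * cfg.aif_beta)) ** cfg.aif_alpha
            * np.exp(cfg.aif_alpha - dt / cfg.aif_beta),
            0.0,
        )


def build_tofts_phantom(region_params: Sequence[dict], regions: np.ndarray,
                        aif: AIFCurve, times: Sequence[float],
                        noise_sigma: float = 0.0, seed: int = 0,
                        spacing=(1.0, 1.0, 1.0)) -> DynamicImage:
    """Forward extended-Tofts phantom: one parameter set per region.

    ``regions`` is an integer volume; ``region_params[i]`` holds keys
    ``ktrans`` (1/s), ``ve``, ``fpv`` for voxels labelled ``i``. Used for
    fit-recovery tests of the compartmental control model.
    """
    times = np.asarray(times, dtype=float)
    regions = np.asarray(regions)
    values = np.zeros(regions.shape + (len(times),))
    for i, p in enumerate(region_params):
        if p["ktrans"] > 0 and p["ve"] <= 0:
            raise ArgumentError(f"region {i}: ve must be positive when ktrans > 0")
        curve = extended_tofts_forward(p["ktrans"], p["ve"], p["fpv"], aif, times)
        values[regions == i] = curve
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        values = values + rng.normal(0.0, noise_sigma, size=values.shape)
    return DynamicImage(values, spacing, (0.0, 0.0, 0.0), times)
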