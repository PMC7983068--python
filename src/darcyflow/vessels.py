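"""Vessel geometry: distance maps, nearest-point queries, radius, vesselness.

Distances are Euclidean, measured in world millimetres to the vessel
*surface* (the segmented mask), spacing-aware on anisotropic grids.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import frangi
from skimage.morphology import skeletonize

from .core import Image3D, LabelMap
from .errors import DegenerateInputError
from typing import Sequence


@dataclass
class VesselGeometry:
    """Bundle of derived vessel quantities."""

    vessel_mask: np.ndarray
    distance: Image3D       # mm, 0 on vessel voxels
    mean_radius: float      # mm


def _vessel_mask(vessel: LabelMap | np.ndarray, labels: Sequence[str]) -> np.ndarray:
    if isinstance(vessel, LabelMap):
        mask = vessel.mask(*labels)
    else:
        mask = np.asarray(vessel, dtype=bool)
    if not mask.any():
        raise DegenerateInputError("vessel mask is empty")
    return mask


def distance_map(vessel: LabelMap | np.ndarray, spacing=None,
                 labels: Sequence[str] = ("vessel", "aorta")) -> Image3D:
    """Euclidean distance (mm) from every voxel to the nearest vessel voxel.

    Zero inside the vessel. ``spacing`` is taken from the label map when
    one is given.
    """
    if isinstance(vessel, LabelMap):
        spacing = vessel.spacing
    elif spacing is None:
        spacing = (1.0, 1.0, 1.0)
    mask = _vessel_mask(vessel, labels)
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    origin = vessel.origin if isinstance(vessel, LabelMap) else (0.0, 0.0, 0.0)
    return Image3D(d, spacing, origin)


def nearest_vessel_point(vessel: LabelMap | np.ndarray, x, spacing=None,
                         labels: Sequence[str] = ("vessel", "aorta")) -> np.ndarray:
    """World coordinate of the vessel voxel centre nearest to point ``x`` (mm).

    Ties are broken toward the lowest lexicographic voxel index.
    """
    if isinstance(vessel, LabelMap):
        spacing, origin = vessel.spacing, vessel.origin
    else:
        spacing = (1.0, 1.0, 1.0) if spacing is None else spacing
        origin = (0.0, 0.0, 0.0)
    mask = _vessel_mask(vessel, labels)
    idx = np.argwhere(mask)  # lexicographic order
    pts = idx * np.asarray(spacing) + np.asarray(origin)
    d2 = ((pts - np.asarray(x, dtype=float)) ** 2).sum(axis=1)
    return pts[int(np.argmin(d2))]  # argmin returns the first (lowest-index) minimum


def estimate_mean_radius(vessel: LabelMap | np.ndarray, spacing=None,
                         labels: Sequence[str] = ("vessel", "aorta")) -> float:
    """Mean vessel radius (mm) via skeletonization + internal distance transform.

    The mask is thinned to its skeleton and the maximal-inscribed-sphere
    radius (Euclidean distance to the mask boundary) is averaged over
    skeleton voxels. If thinning annihilates the mask (possible for
    symmetric tubes with no on-axis voxel), the ridge of the internal
    distance transform is used instead.
    """
    if isinstance(vessel, LabelMap):
        spacing = vessel.spacing
    elif spacing is None:
        spacing = (1.0, 1.0, 1.0)
    mask = _vessel_mask(vessel, labels)
    edt = ndimage.distance_transform_edt(mask, sampling=spacing)
    skel = skeletonize(mask)
    if not skel.any():
        # EDT ridge fallback: voxels that are local maxima of the internal EDT
        mx = ndimage.maximum_filter(edt, size=3)
        skel = mask & (edt >= mx - 1e-12)
        if not skel.any():
            raise DegenerateInputError("mask has an empty skeleton")
    return float(edt[skel].mean())


def vessel_geometry(vessel: LabelMap, labels: Sequence[str] = ("vessel", "aorta")) -> VesselGeometry:
    mask = _vessel_mask(vessel, labels)
    return VesselGeometry(
        vessel_mask=mask,
        distance=distance_map(vessel, labels=labels),
        mean_radius=estimate_mean_radius(vessel, labels=labels),
    )


def vesselness_mask(volume: Image3D, scales_mm: Sequence[float],
                    threshold: float = 0.05) -> LabelMap:
    """Binary vessel mask from a multiscale Hessian tubeness (Frangi) filter.

    ``volume`` should be an enhancement image (e.g. temporal maximum
    minus pre-contrast). ``scales_mm`` are tube radii to probe, converted
    to voxels with the mean spacing (near-isotropic grids assumed);
    ``threshold`` is relative to the peak filter response.
    """
    vals = volume.values.astype(float)
    if not np.any(vals != 0):
        warnings.warn("vesselness on an all-zero volume: returning empty mask")
        mask = np.zeros(volume.shape, dtype=np.int32)
    else:
        mean_sp = float(np.mean(volume.spacing))
        sigmas = [max(s / mean_sp, 0.5) for s in scales_mm]
        resp = frangi(vals, sigmas=sigmas, black_ridges=False)
        mask = (resp > threshold * resp.max()).astype(np.int32)
    from .core import LABELS
    return LabelMap(mask * LABELS["vessel"], volume.spacing, volume.origin)


def digital_cylinder_mask(radius_mm: float, spacing_mm: float, length_mm: float,
                          pad_voxels: int = 6) -> LabelMap:
    """Rasterize a straight cylinder along z on an isotropic grid.

    The cross-section grid is sized odd so a voxel centre lies on the
    axis; the tube is padded with background along z so its ends are
    interior to the volume. Intended for estimator validation.
    """
    n_xy = int(np.ceil(2 * radius_mm / spacing_mm)) + 11
    if n_xy % 2 == 0:
        n_xy += 1
    nz = int(np.ceil(length_mm / spacing_mm))
    c = (n_xy - 1) / 2.0
    i = np.arange(n_xy)
    X, Y = np.meshgrid((i - c) * spacing_mm, (i - c) * spacing_mm, indexing="ij")
    disk = (X**2 + Y**2) <= radius_mm**2
    vol = np.zeros((n_xy, n_xy, nz + 2 * pad_voxels), dtype=np.int32)
    vol[:, :, pad_voxels:pad_voxels + nz] = disk[:, :, None].astype(np.int32)
    from .core import LABELS
    return LabelMap(vol * LABELS["vessel"], (spacing_mm,) * 3, (0.0, 0.0, 0.0))
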