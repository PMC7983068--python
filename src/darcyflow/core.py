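"""Core data model for dynamic contrast-enhanced volumes.

Arrays are indexed ``(i, j, k)`` (and a trailing time axis for dynamic
series) with the world coordinate of a voxel centre given by
``origin + index * spacing``; spacing and origin are in millimetres,
acquisition times in seconds, intensities in Hounsfield units (HU).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .errors import ArgumentError, DegenerateInputError, StructuralError

#: Canonical tissue labels used throughout the package.
LABELS: Mapping[str, int] = {
    "background": 0,
    "parenchyma": 1,
    "tumor": 2,
    "vessel": 3,
    "aorta": 4,
}


def _as_tuple3(x) -> tuple[float, float, float]:
    t = tuple(float(v) for v in x)
    if len(t) != 3:
        raise StructuralError(f"expected 3 components, got {len(t)}")
    return t


@dataclass
class Image3D:
    """A single 3-D scalar volume on a regular grid."""

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise StructuralError(f"Image3D needs a 3-D array, got ndim={self.values.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ArgumentError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Image3D | DynamicImage | LabelMap") -> bool:
        return (
            self.shape == other.shape[:3]
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class DynamicImage:
    """A 4-D dynamic series: one 3-D volume per acquisition time.

    ``values`` has shape ``(nx, ny, nz, nt)``; ``times`` holds the frame
    acquisition times in seconds and must be strictly increasing.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    times: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 4:
            raise StructuralError(f"DynamicImage needs a 4-D array, got ndim={self.values.ndim}")
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ArgumentError(f"spacing must be positive, got {self.spacing}")
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1 or len(self.times) != self.values.shape[3]:
            raise StructuralError(
                f"times length {self.times.shape} does not match frame count {self.values.shape[3]}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("acquisition times must be strictly increasing")

    @property
    def shape(self):
        return self.values.shape

    @property
    def n_frames(self) -> int:
        return self.values.shape[3]

    def frame(self, i: int) -> Image3D:
        return Image3D(self.values[..., i], self.spacing, self.origin)

    def same_grid(self, other) -> bool:
        return (
            self.shape[:3] == other.shape[:3]
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class LabelMap:
    """Integer segmentation on the image grid.

    ``labels`` maps semantic names to integer codes; defaults to
    :data:`LABELS` (background / parenchyma / tumor / vessel / aorta).
    """

    values: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    labels: Mapping[str, int] = field(default_factory=lambda: dict(LABELS))

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise StructuralError(f"LabelMap needs a 3-D array, got ndim={self.values.ndim}")
        if not np.issubdtype(self.values.dtype, np.integer):
            if not np.array_equal(self.values, np.round(self.values)):
                raise StructuralError("label values must be integers")
            self.values = self.values.astype(np.int32)
        self.spacing = _as_tuple3(self.spacing)
        self.origin = _as_tuple3(self.origin)
        declared = set(self.labels.values())
        present = set(np.unique(self.values).tolist())
        if not present <= declared:
            raise StructuralError(f"labels {sorted(present - declared)} not in declared set {sorted(declared)}")

    @property
    def shape(self):
        return self.values.shape

    def mask(self, *names: str) -> np.ndarray:
        """Boolean mask of voxels carrying any of the named labels."""
        codes = [self.labels[n] for n in names]
        return np.isin(self.values, codes)

    def same_grid(self, other) -> bool:
        return (
            self.shape == other.shape[:3]
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class AIFCurve:
    """Arterial input function sampled at the acquisition times.

    ``saturation`` is dimensionless (unit peak after extraction);
    ``peak_enhancement`` preserves the raw HU peak used for the
    normalization so tissue enhancement can be put on the same scale.
    """

    times: np.ndarray
    saturation: np.ndarray
    peak_enhancement: float | None = None

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.saturation = np.asarray(self.saturation, dtype=float)
        if self.times.shape != self.saturation.shape or self.times.ndim != 1:
            raise StructuralError("AIF times and saturation must be 1-D arrays of equal length")
        if np.any(np.diff(self.times) <= 0):
            raise StructuralError("AIF times must be strictly increasing")

    def __len__(self):
        return len(self.times)

    def sample(self, t: np.ndarray) -> np.ndarray:
        """Linear interpolation of the curve; zero outside the sampled window."""
        return np.interp(t, self.times, self.saturation, left=0.0, right=0.0)


# ---------------------------------------------------------------------------
# contrast-to-saturation conversion


def compute_baseline(img: DynamicImage, n_pre: int) -> Image3D:
    """Pre-contrast baseline I_b(x): voxelwise mean of the first ``n_pre`` frames."""
    if not (1 <= n_pre < img.n_frames):
        raise ArgumentError(f"n_pre must be in [1, {img.n_frames - 1}], got {n_pre}")
    return Image3D(img.values[..., :n_pre].mean(axis=3), img.spacing, img.origin)


def enhancement(img: DynamicImage, baseline: Image3D) -> DynamicImage:
    """Contrast enhancement I(x,t) - I_b(x).

    Enhancement is linearly proportional to the local contrast-agent
    concentration; negative values (noise) are deliberately retained.
    """
    if not baseline.same_grid(img):
        raise StructuralError("baseline grid does not match dynamic series")
    return DynamicImage(
        img.values - baseline.values[..., None], img.spacing, img.origin, img.times
    )


def normalize_to_saturation(enh: DynamicImage, aif: AIFCurve) -> DynamicImage:
    """Scale enhancement to the dimensionless saturation scale of the AIF.

    Divides by the arterial peak enhancement so that tissue and arterial
    signals share one scale; the unknown HU-per-concentration constant
    cancels.
    """
    peak = aif.peak_enhancement
    if peak is None:
        peak = float(np.max(aif.saturation))
    if peak <= 0:
        raise DegenerateInputError(f"AIF peak must be positive, got {peak}")
    return replace(enh, values=enh.values / peak)
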