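"""Arterial input extraction and bolus-arrival-time (BAT) mapping.

BAT is the peak-gradient arrival estimate: the left endpoint of the
frame interval over which the forward-difference slope of the
enhancement curve is maximal. Ties resolve to the earliest interval.
The estimate is invariant to positive rescaling of the curve and
equivariant under temporal shifts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import AIFCurve, DynamicImage, Image3D, LabelMap
from .errors import DegenerateInputError


@dataclass
class BATMap:
    """Voxelwise bolus arrival time (s) with a validity mask."""

    times: Image3D
    valid: np.ndarray

    @property
    def values(self) -> np.ndarray:
        return self.times.values


def extract_aif(enh: DynamicImage, aorta_roi: LabelMap | np.ndarray,
                labels=("aorta",)) -> AIFCurve:
    """Mean enhancement over the aortic ROI, normalized to unit peak.

    The raw peak is kept on the curve (``peak_enhancement``) so tissue
    curves can be scaled onto the same dimensionless saturation scale.
    """
    mask = aorta_roi.mask(*labels) if isinstance(aorta_roi, LabelMap) else np.asarray(aorta_roi, bool)
    if not mask.any():
        raise DegenerateInputError("aorta ROI is empty")
    curve = enh.values[mask].mean(axis=0)
    peak = float(curve.max())
    if peak <= 0:
        raise DegenerateInputError(f"AIF peak must be positive, got {peak}")
    return AIFCurve(enh.times, curve / peak, peak_enhancement=peak)


def bolus_arrival_time(curve: np.ndarray, times: np.ndarray) -> float:
    """Peak-gradient BAT of one curve; NaN when the curve never rises.

    Returns the left time of the maximal forward-difference interval,
    earliest interval on ties.
    """
    curve = np.asarray(curve, dtype=float)
    times = np.asarray(times, dtype=float)
    if len(curve) < 3:
        raise DegenerateInputError("BAT needs at least 3 samples")
    grad = np.diff(curve) / np.diff(times)
    if np.max(grad) <= 0:
        return float("nan")
    return float(times[int(np.argmax(grad))])


def bat_map(enh: DynamicImage, mask: LabelMap | np.ndarray,
            labels=("parenchyma", "tumor", "vessel", "aorta")) -> BATMap:
    """Voxelwise peak-gradient BAT within a mask.

    Voxels whose curve never rises (zero or negative maximal gradient)
    are flagged invalid rather than assigned a time.
    """
    m = mask.mask(*labels) if isinstance(mask, LabelMap) else np.asarray(mask, bool)
    if not m.any():
        raise DegenerateInputError("BAT mask is empty")
    times = enh.times
    curves = enh.values[m]                      # (V, T)
    grad = np.diff(curves, axis=1) / np.diff(times)[None, :]
    arg = np.argmax(grad, axis=1)               # earliest max by argmax convention
    ok = grad[np.arange(len(arg)), arg] > 0
    bat = np.full(enh.shape[:3], np.nan)
    vals = np.where(ok, times[arg], np.nan)
    bat[m] = vals
    valid = np.zeros(enh.shape[:3], dtype=bool)
    valid[m] = ok
    return BATMap(Image3D(bat, enh.spacing, enh.origin), valid)
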