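"""Readers and writers for NRRD / NIfTI volumes, label maps, and AIF curves.

SimpleITK handles the on-disk formats; this layer converts to the
package's ``(i, j, k)`` array convention (SimpleITK's array view is
``(k, j, i)``) and attaches grid metadata. Direction matrices other than
identity are not supported — images are assumed axis-aligned.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import SimpleITK as sitk

from .core import LABELS, AIFCurve, DynamicImage, Image3D, LabelMap
from .errors import StructuralError


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3)):
        raise StructuralError("only axis-aligned (identity direction) images are supported")
    arr = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return arr, tuple(img.GetSpacing()), tuple(img.GetOrigin())


def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in spacing))
    img.SetOrigin(tuple(float(o) for o in origin))
    return img


def read_image(path: str | Path) -> Image3D:
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    return Image3D(arr.astype(np.float64), spacing, origin)


def write_image(img: Image3D, path: str | Path) -> None:
    sitk.WriteImage(_to_sitk(img.values.astype(np.float64), img.spacing, img.origin), str(path))


def read_label_map(path: str | Path, labels: dict | None = None) -> LabelMap:
    """Read an integer volume; ``labels`` may come from a JSON sidecar."""
    path = Path(path)
    arr, spacing, origin = _from_sitk(sitk.ReadImage(str(path)))
    if labels is None:
        sidecar = path.with_suffix("").with_suffix(".labels.json")
        labels = json.loads(sidecar.read_text()) if sidecar.exists() else dict(LABELS)
    return LabelMap(arr.astype(np.int32), spacing, origin, labels)


def write_label_map(lm: LabelMap, path: str | Path) -> None:
    path = Path(path)
    sitk.WriteImage(_to_sitk(lm.values.astype(np.int32), lm.spacing, lm.origin), str(path))
    sidecar = path.with_suffix("").with_suffix(".labels.json")
    sidecar.write_text(json.dumps(dict(lm.labels), indent=1))


def load_dynamic_series(paths: Sequence[str | Path], times: Sequence[float]) -> DynamicImage:
    """Assemble a 4-D series from an ordered list of 3-D volumes.

    All volumes must share one grid; ``times`` gives the acquisition time
    of each frame in seconds, in the same order as ``paths``.
    """
    if len(paths) != len(times):
        raise StructuralError(f"{len(paths)} files but {len(times)} times")
    frames = []
    grid = None
    for p in paths:
        arr, spacing, origin = _from_sitk(sitk.ReadImage(str(p)))
        if grid is None:
            grid = (arr.shape, spacing, origin)
        elif arr.shape != grid[0] or not np.allclose(spacing, grid[1]) or not np.allclose(origin, grid[2]):
            raise StructuralError(f"frame {p} grid does not match first frame")
        frames.append(arr.astype(np.float64))
    return DynamicImage(np.stack(frames, axis=3), grid[1], grid[2], np.asarray(times, float))


def write_dynamic_series(img: DynamicImage, out_dir: str | Path, stem: str = "frame",
                         ext: str = ".nrrd") -> list[Path]:
    """Write one volume per frame plus a ``<stem>_times.json`` sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i in range(img.n_frames):
        p = out_dir / f"{stem}_{i:03d}{ext}"
        write_image(img.frame(i), p)
        paths.append(p)
    (out_dir / f"{stem}_times.json").write_text(json.dumps(img.times.tolist()))
    return paths


def load_dynamic_series_dir(out_dir: str | Path, stem: str = "frame") -> DynamicImage:
    out_dir = Path(out_dir)
    times = json.loads((out_dir / f"{stem}_times.json").read_text())
    paths = sorted(p for p in out_dir.glob(f"{stem}_[0-9]*") if p.suffix in (".nrrd", ".nii", ".gz"))
    return load_dynamic_series(paths, times)


def write_aif(aif: AIFCurve, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": aif.times, "saturation": aif.saturation})
    df.to_csv(path, index=False, float_format="%.10g")


def read_aif(path: str | Path) -> AIFCurve:
    df = pd.read_csv(path)
    return AIFCurve(df["time_s"].to_numpy(), df["saturation"].to_numpy())
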