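"""NIfTI reading and writing for label maps and VNCa volumes.

Orientation handling is deliberately minimal: the inferior->superior axis
of a label map is taken from the NIfTI affine (the axis whose anatomical
code is S or I), never guessed from the data.  Volumes written by the
phantom generator use a diagonal RAS affine, so their superior axis is the
third array axis with increasing index pointing superior.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grids import LabelMap, OrientationError, VncaVolume

__all__ = ["save_label_map", "save_vnca", "load_label_map", "load_vnca"]


def _affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_label_map(labels: LabelMap, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(labels.data.astype(np.int16), _affine(labels.spacing))
    nib.save(img, path)
    return path


def save_vnca(volume: VncaVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(volume.data.astype(np.float32), _affine(volume.spacing))
    nib.save(img, path)
    return path


def _superior_axis(img: nib.Nifti1Image) -> tuple[int, int]:
    codes = nib.aff2axcodes(img.affine)
    for axis, code in enumerate(codes):
        if code == "S":
            return axis, 1
        if code == "I":
            return axis, -1
    raise OrientationError(
        f"no inferior/superior axis in NIfTI orientation {codes}; cannot order vertebrae"
    )


def load_label_map(path: str | Path) -> LabelMap:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    axis, sign = _superior_axis(img)
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-3):
            raise ValueError(f"{path}: label map voxels are not integers")
        data = rounded.astype(np.int32)
    return LabelMap(data, spacing, superior_axis=axis, superior_sign=sign)


def load_vnca(path: str | Path, level: str = "maximum") -> VncaVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VncaVolume(np.asanyarray(img.dataobj, dtype=float), spacing, level=level)
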