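"""In-memory containers for co-registered CT grids.

A study consists of an integer vertebra label map and one virtual
non-calcium (VNCa) attenuation volume per calcium-suppression level, all on
the same anisotropic voxel lattice.  The label map carries an orientation
tag naming the inferior->superior anatomical axis; vertebra ordering ("from
the bottom") is defined along that axis and is never guessed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["LabelMap", "VncaVolume", "GridMismatchError", "OrientationError"]


class GridMismatchError(ValueError):
    """Two volumes that must share a lattice do not."""


class OrientationError(ValueError):
    """The inferior->superior axis is not declared."""


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValueError(f"voxel spacing must be three positive mm values, got {spacing}")
    return spacing


@dataclass
class LabelMap:
    """Integer vertebra segmentation; 0 is background, each positive label
    marks one vertebra.

    ``superior_axis`` is the array axis running inferior->superior and
    ``superior_sign`` is +1 when increasing index moves superior, -1
    otherwise.  Both come from the image header, never from a guess.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    superior_axis: int | None = None
    superior_sign: int = 1

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("label map must be 3-D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("label map must be an integer grid")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")
        self.spacing = _check_spacing(self.spacing)
        if self.superior_axis is not None and self.superior_axis not in (0, 1, 2):
            raise ValueError("superior_axis must be 0, 1 or 2")
        if self.superior_sign not in (-1, 1):
            raise ValueError("superior_sign must be +1 or -1")

    def labels(self) -> np.ndarray:
        """Sorted positive labels present in the map."""
        u = np.unique(self.data)
        return u[u > 0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class VncaVolume:
    """A VNCa attenuation grid in Hounsfield units with its suppression tag."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    level: str = "maximum"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("VNCa volume must be 3-D")
        self.spacing = _check_spacing(self.spacing)


def require_same_grid(a, b) -> None:
    """Raise GridMismatchError unless the two containers share shape and spacing."""
    if a.data.shape != b.data.shape or not np.allclose(a.spacing, b.spacing):
        raise GridMismatchError(
            f"grids differ: shape {a.data.shape} / spacing {a.spacing} vs "
            f"shape {b.data.shape} / spacing {b.spacing}"
        )
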