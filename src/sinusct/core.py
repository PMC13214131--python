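"""Core in-memory containers for volumetric CT data.

All grids are numpy arrays in (x, y, z) voxel order with a per-axis voxel
spacing in millimetres.  Intensities are either calibrated Hounsfield units
(air about -1000 HU, water 0, cortical bone well above 0) or normalized to
[0, 1] after windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

LABEL_NAMES: dict[int, str] = {
    1: "maxillary",
    2: "ethmoid",
    3: "frontal",
    4: "sphenoid",
}
FOREGROUND_LABELS: tuple[int, ...] = (1, 2, 3, 4)


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing and an intensity domain tag."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    intensity_domain: str = "HU"  # "HU" or "normalized"

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("Volume grid must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")
        if self.intensity_domain not in ("HU", "normalized"):
            raise ValueError(f"unknown intensity domain {self.intensity_domain!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def copy(self) -> "Volume":
        return Volume(self.grid.copy(), self.spacing_mm, self.intensity_domain)


@dataclass
class LabelMask:
    """Integer segmentation grid aligned to a Volume.

    0 is background; 1-4 are the maxillary, ethmoid, frontal and sphenoid
    sinus compartments.
    """

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]
    label_names: dict[int, str] = field(default_factory=lambda: dict(LABEL_NAMES))

    def __post_init__(self):
        self.grid = np.asarray(self.grid)
        if not np.issubdtype(self.grid.dtype, np.integer):
            self.grid = np.rint(self.grid).astype(np.int16)
        else:
            self.grid = self.grid.astype(np.int16)
        if self.grid.ndim != 3:
            raise ValueError("LabelMask grid must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape

    def labels_present(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.grid) if v != 0)

    def copy(self) -> "LabelMask":
        return LabelMask(self.grid.copy(), self.spacing_mm, dict(self.label_names))


@dataclass
class ResidualMap:
    """Voxel-wise absolute reconstruction error |x - x_hat|; non-negative."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("ResidualMap grid must be 3D")
        if self.grid.size and float(self.grid.min()) < 0:
            raise ValueError("ResidualMap must be non-negative")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


@dataclass
class CAMMap:
    """Grad-CAM saliency grid, min-max normalized to [0, 1]."""

    grid: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.float32)
        if self.grid.ndim != 3:
            raise ValueError("CAMMap grid must be 3D")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.grid.shape


def check_geometry(*objs) -> None:
    """Raise if the given grid containers disagree in shape or spacing."""
    shapes = {tuple(o.shape) for o in objs}
    if len(shapes) > 1:
        raise ValueError(f"misaligned geometries: shapes {sorted(shapes)}")
    spacings = {tuple(np.round(o.spacing_mm, 6)) for o in objs}
    if len(spacings) > 1:
        raise ValueError(f"misaligned geometries: spacings {sorted(spacings)}")


__all__ = [
    "Volume", "LabelMask", "ResidualMap", "CAMMap",
    "LABEL_NAMES", "FOREGROUND_LABELS", "check_geometry", "replace",
]
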