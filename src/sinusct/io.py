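"""NIfTI reading/writing that preserves voxel spacing, plus manifest helpers."""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import LABEL_NAMES, LabelMask, Volume


def _affine(spacing_mm) -> np.ndarray:
    aff = np.diag(list(spacing_mm) + [1.0])
    return aff


def write_volume(v: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(v.grid.astype(np.float32), _affine(v.spacing_mm))
    img.header.set_zooms(v.spacing_mm)
    nib.save(img, str(path))


def read_volume(path: str | Path, intensity_domain: str = "HU") -> Volume:
    try:
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float32)
    except Exception as e:  # nibabel raises several unrelated types
        raise ValueError(f"cannot parse NIfTI file {path}: {e}") from e
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return Volume(grid, spacing, intensity_domain)


def write_mask(m: LabelMask, path: str | Path, validate_labels: bool = True) -> None:
    if validate_labels:
        _warn_unexpected(m.grid, path)
    img = nib.Nifti1Image(m.grid.astype(np.int16), _affine(m.spacing_mm))
    img.header.set_zooms(m.spacing_mm)
    nib.save(img, str(path))


def _warn_unexpected(grid: np.ndarray, path) -> None:
    unexpected = sorted(int(v) for v in np.unique(grid)
                        if v != 0 and int(v) not in LABEL_NAMES)
    if unexpected:
        warnings.warn(f"mask {path} contains unexpected labels {unexpected}; "
                      f"expected a subset of {sorted(LABEL_NAMES)}",
                      stacklevel=2)


def read_mask(path: str | Path, validate_labels: bool = True) -> LabelMask:
    try:
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj)
    except Exception as e:
        raise ValueError(f"cannot parse NIfTI file {path}: {e}") from e
    grid = np.rint(grid).astype(np.int16)
    if validate_labels:
        _warn_unexpected(grid, path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(grid, spacing)


def read_manifest(path: str | Path):
    """Read a JSON-lines cohort manifest into a pandas DataFrame."""
    import pandas as pd

    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                rows.append(json.loads(line))
    return pd.DataFrame(rows)


__all__ = ["read_volume", "write_volume", "read_mask", "write_mask", "read_manifest"]
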