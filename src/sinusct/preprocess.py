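"""Harmonization chain for CT volumes and their label masks.

The chain applied before any model sees a volume is: sanitize non-finite
voxels, resample to isotropic spacing, standardize the grid shape by
center-crop / symmetric zero-pad, and min-max normalize a fixed HU window
onto [0, 1].  A -500 HU threshold builds a hole-filled body mask used for
mask-guided cropping, so the air-filled sinus cavities inside the head stay
inside the retained region.  Augmentation is intensity-only (gamma and
rescale); geometry is never altered, and paired masks are never touched.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import LabelMask, Volume, check_geometry  # noqa: F401  (re-export)

DEFAULT_HU_WINDOW = (-1000.0, 2000.0)
DEFAULT_BODY_THRESHOLD_HU = -500.0


def sanitize(v: Volume) -> Volume:
    """Replace every non-finite voxel (NaN, +/-inf) with zero."""
    grid = v.grid
    finite = np.isfinite(grid)
    if finite.all():
        return v.copy()
    out = np.where(finite, grid, np.float32(0.0))
    return Volume(out, v.spacing_mm, v.intensity_domain)


def _resampled_shape(shape, spacing, target: float) -> tuple[int, ...]:
    return tuple(max(1, int(round(n * s / target)))
                 for n, s in zip(shape, spacing))


def resample_isotropic(obj: Volume | LabelMask, target_spacing_mm: float):
    """Resample to isotropic spacing; trilinear for volumes, nearest for labels."""
    if target_spacing_mm <= 0:
        raise ValueError("target spacing must be positive")
    out_shape = _resampled_shape(obj.shape, obj.spacing_mm, target_spacing_mm)
    new_spacing = (target_spacing_mm,) * 3
    if out_shape == tuple(obj.shape):
        out = obj.copy()
        out.spacing_mm = new_spacing
        return out
    zoom = [o / n for o, n in zip(out_shape, obj.shape)]
    if isinstance(obj, LabelMask):
        grid = ndimage.zoom(obj.grid, zoom, order=0, mode="nearest",
                            grid_mode=True, prefilter=False)
        grid = grid[:out_shape[0], :out_shape[1], :out_shape[2]]
        return LabelMask(grid, new_spacing, dict(obj.label_names))
    grid = ndimage.zoom(obj.grid.astype(np.float32), zoom, order=1,
                        mode="nearest", grid_mode=True, prefilter=False)
    grid = grid[:out_shape[0], :out_shape[1], :out_shape[2]]
    return Volume(grid, new_spacing, obj.intensity_domain)


def standardize_shape(obj: Volume | LabelMask, target_shape: tuple[int, int, int]):
    """Center-crop oversized axes; zero-pad undersized ones symmetrically.

    For odd size differences the extra voxel goes on the high-index side,
    both when cropping and when padding.
    """
    grid = obj.grid
    slices, pads = [], []
    for n, t in zip(grid.shape, target_shape):
        if n >= t:
            lo = (n - t) // 2
            slices.append(slice(lo, lo + t))
            pads.append((0, 0))
        else:
            d = t - n
            slices.append(slice(0, n))
            pads.append((d // 2, d - d // 2))
    out = grid[tuple(slices)]
    if any(p != (0, 0) for p in pads):
        out = np.pad(out, pads)
    if isinstance(obj, LabelMask):
        return LabelMask(out, obj.spacing_mm, dict(obj.label_names))
    return Volume(out, obj.spacing_mm, obj.intensity_domain)


def normalize_minmax(v: Volume, hu_window: tuple[float, float] = DEFAULT_HU_WINDOW
                     ) -> Volume:
    """Clip to the HU window and map affinely onto [0, 1]."""
    lo, hi = hu_window
    if lo >= hi:
        raise ValueError("hu_window must satisfy lo < hi")
    if v.intensity_domain != "HU":
        raise ValueError("normalize_minmax expects an HU-domain volume")
    out = (np.clip(v.grid, lo, hi) - lo) / np.float32(hi - lo)
    return Volume(out.astype(np.float32), v.spacing_mm, "normalized")


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def body_mask_from_threshold(v: Volume,
                             threshold_hu: float = DEFAULT_BODY_THRESHOLD_HU
                             ) -> np.ndarray:
    """Largest 6-connected supra-threshold component, with holes filled.

    Filling the interior holes keeps the air-filled sinus cavities inside the
    body mask even though they fall below the threshold.
    """
    if v.intensity_domain != "HU":
        raise ValueError("body mask extraction expects an HU-domain volume")
    fg = v.grid >= threshold_hu
    if not fg.any():
        raise ValueError(f"no voxel at or above {threshold_hu} HU")
    comps, ncomp = ndimage.label(fg, structure=_FACE_STRUCT)
    if ncomp > 1:
        sizes = np.bincount(comps.ravel())
        sizes[0] = 0
        fg = comps == sizes.argmax()
    return ndimage.binary_fill_holes(fg, structure=_FACE_STRUCT).astype(np.uint8)


def mask_guided_crop(v: Volume, mask: LabelMask | np.ndarray, margin_vox: int = 0):
    """Crop volume and mask to the mask's bounding box dilated by a margin."""
    mgrid = mask.grid if isinstance(mask, LabelMask) else np.asarray(mask)
    if mgrid.shape != v.grid.shape:
        raise ValueError("mask and volume shapes differ")
    nz = np.nonzero(mgrid)
    if len(nz[0]) == 0:
        raise ValueError("mask is empty; nothing to crop to")
    slices = []
    for ax in range(3):
        lo = max(0, int(nz[ax].min()) - margin_vox)
        hi = min(v.grid.shape[ax], int(nz[ax].max()) + 1 + margin_vox)
        slices.append(slice(lo, hi))
    sl = tuple(slices)
    v_out = Volume(v.grid[sl], v.spacing_mm, v.intensity_domain)
    if isinstance(mask, LabelMask):
        m_out = LabelMask(mgrid[sl], mask.spacing_mm, dict(mask.label_names))
    else:
        m_out = mgrid[sl]
    return v_out, m_out


def augment_intensity(v: Volume, gamma_range: tuple[float, float],
                      scale_range: tuple[float, float], seed: int) -> Volume:
    """Seeded gamma correction and intensity rescale: x -> clip(x**g * s, 0, 1).

    Geometry is untouched; any paired mask must be left unmodified by the
    caller — augmentation is intensity-only by design.
    """
    if min(gamma_range) <= 0:
        raise ValueError("gamma_range must be strictly positive")
    if v.intensity_domain != "normalized":
        raise ValueError("intensity augmentation expects a normalized volume")
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*gamma_range)
    scale = rng.uniform(*scale_range)
    out = np.clip(np.power(v.grid, np.float32(gamma)) * np.float32(scale), 0.0, 1.0)
    return Volume(out.astype(np.float32), v.spacing_mm, "normalized")


def standard_chain(v: Volume, target_spacing_mm: float = 1.0,
                   target_shape: tuple[int, int, int] = (64, 64, 64),
                   hu_window: tuple[float, float] = DEFAULT_HU_WINDOW,
                   labels: LabelMask | None = None):
    """sanitize -> resample -> standardize_shape -> normalize, optionally
    carrying a label mask through the geometric steps."""
    v = sanitize(v)
    v = resample_isotropic(v, target_spacing_mm)
    v = standardize_shape(v, target_shape)
    v = normalize_minmax(v, hu_window)
    if labels is None:
        return v
    m = resample_isotropic(labels, target_spacing_mm)
    m = standardize_shape(m, target_shape)
    return v, m


__all__ = [
    "Volume", "LabelMask", "sanitize", "resample_isotropic", "standardize_shape",
    "normalize_minmax", "body_mask_from_threshold", "mask_guided_crop",
    "augment_intensity", "standard_chain",
    "DEFAULT_HU_WINDOW", "DEFAULT_BODY_THRESHOLD_HU",
]
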