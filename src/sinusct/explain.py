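"""Grad-CAM saliency over the fusion network's final convolutional layer.

For a chosen scalar target (by default the maximal pretext output, the
class-discriminative analog for a network without a classifier), channel
weights are the spatial mean of the target's gradient with respect to the
final conv activations; the CAM is the rectified weighted channel sum,
trilinearly upsampled to the input geometry and min-max normalized onto
[0, 1].  An identically-zero map is passed through unchanged.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .core import CAMMap
from .fusion import FeatureExtractor, FusedInput
from .nn import Tensor


def grad_cam(model: FeatureExtractor, f: FusedInput,
             target: str | int = "max_pretext_output") -> CAMMap:
    """Compute a Grad-CAM map for one fused input.

    ``target``: either ``"max_pretext_output"`` or an integer pretext index
    (0..3, one per sinus compartment).
    """
    model.eval()  # dropout disabled; gradients still flow
    x = Tensor(f.channels[None])
    _, pretext, act = model.forward_with_activations(x)
    n_out = pretext.shape[-1]
    if isinstance(target, str):
        if target != "max_pretext_output":
            raise ValueError(f"unknown target {target!r}")
        idx = int(np.argmax(pretext.numpy()[0]))
    else:
        idx = int(target)
        if not 0 <= idx < n_out:
            raise ValueError(f"pretext index {idx} out of range [0, {n_out})")
    scalar = pretext[0, idx]
    scalar.backward()
    grads = act.grad[0]          # (C, x, y, z)
    acts = act.numpy()[0]
    cam = cam_from_activations(acts, grads, f.shape)
    return CAMMap(cam, f.spacing_mm)


def cam_from_activations(acts: np.ndarray, grads: np.ndarray,
                         out_shape: tuple[int, int, int]) -> np.ndarray:
    """The Grad-CAM formula on raw (C, x, y, z) activations and gradients.

    Channel weights are the spatial mean of the gradients; the rectified
    weighted channel sum is trilinearly upsampled to ``out_shape`` and
    min-max normalized onto [0, 1] (an all-zero map stays all-zero).
    """
    weights = grads.mean(axis=(1, 2, 3))
    cam = np.einsum("c,cxyz->xyz", weights, acts)
    cam = np.maximum(cam, 0.0)
    zoom = [t / c for t, c in zip(out_shape, cam.shape)]
    cam = ndimage.zoom(cam, zoom, order=1, mode="nearest", grid_mode=True,
                       prefilter=False)
    cam = cam[: out_shape[0], : out_shape[1], : out_shape[2]]
    mx = float(cam.max())
    if mx > 0:
        mn = float(cam.min())
        cam = (cam - mn) / (mx - mn) if mx > mn else np.ones_like(cam)
    return cam.astype(np.float32)


def cam_mass_fraction(cam: CAMMap, region: np.ndarray) -> float:
    """Fraction of total CAM mass inside ``region``; requires positive mass."""
    region = np.asarray(region).astype(bool)
    if region.shape != cam.grid.shape:
        raise ValueError("region shape differs from CAM geometry")
    total = float(cam.grid.sum())
    if total <= 0:
        raise ValueError("CAM has zero total mass; fraction undefined")
    return float(cam.grid[region].sum()) / total


__all__ = ["grad_cam", "cam_from_activations", "cam_mass_fraction"]
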