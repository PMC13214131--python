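"""Segmentation-guided structural embeddings from a three-channel 3D CNN.

The extractor consumes a three-channel volume — (0) the normalized CT, (1)
the segmentation mask scaled onto [0, 1], (2) the autoencoder residual map
robust-scaled by its 99th percentile — and produces a fixed-length embedding
of sinus morphology through three conv+max-pool blocks, global average
pooling and a 64-unit dense layer with dropout 0.3.

No disease labels exist, so the network is trained on a self-supervised
pretext task: regressing the mean residual inside each of the four sinus
compartments.  This keeps the optimisation label-free while forcing
attention onto the sinus regions and their structural deviations, and it
gives Grad-CAM a differentiable scalar target.  Channel-ablation variants
(``no_residual``, ``no_mask``) zero the corresponding channel in place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import FOREGROUND_LABELS, LabelMask, ResidualMap, Volume, check_geometry
from .nn import Tensor

ASSEMBLE_VARIANTS = ("full", "no_residual", "no_mask")


@dataclass
class FusedInput:
    """(3, X, Y, Z) channel stack; all channels in [0, 1]."""

    channels: np.ndarray
    spacing_mm: tuple[float, float, float]

    def __post_init__(self):
        self.channels = np.asarray(self.channels, np.float32)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError("FusedInput.channels must be (3, X, Y, Z)")

    @property
    def shape(self):
        return self.channels.shape[1:]


@dataclass
class StructEmbedding:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, np.float32).ravel()
        if not np.isfinite(self.values).all():
            raise ValueError("embedding contains non-finite values")


def assemble_input(v: Volume, m: LabelMask, r: ResidualMap,
                   variant: str = "full") -> FusedInput:
    """Stack CT / mask / residual channels, with ablation variants.

    Mask channel: label / 4, so labels 0..4 map to {0, .25, .5, .75, 1}.
    Residual channel: clipped at its own 99th percentile, then scaled to
    [0, 1] (a constant map stays constant).
    """
    if variant not in ASSEMBLE_VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    check_geometry(v, m, r)
    if v.intensity_domain != "normalized":
        raise ValueError("assemble_input expects a normalized CT volume")
    mask_ch = m.grid.astype(np.float32) / 4.0
    p99 = float(np.percentile(r.grid, 99))
    if p99 > 0:
        res_ch = np.clip(r.grid, 0, p99) / np.float32(p99)
    else:
        res_ch = np.zeros_like(r.grid)
    chans = np.stack([v.grid, mask_ch, res_ch])
    if variant == "no_residual":
        chans[2] = 0.0
    elif variant == "no_mask":
        chans[1] = 0.0
    return FusedInput(chans, v.spacing_mm)


def pretext_targets(m: LabelMask, r: ResidualMap) -> np.ndarray:
    """Mean residual inside each sinus compartment; 0 where a label is absent."""
    check_geometry(m, r)
    out = np.zeros(len(FOREGROUND_LABELS), np.float32)
    for i, c in enumerate(FOREGROUND_LABELS):
        sel = m.grid == c
        if sel.any():
            out[i] = float(r.grid[sel].mean())
    return out


class FeatureExtractor(nn.Module):
    """conv(3^3)+pool x3 -> global average pool -> dense-64 (dropout 0.3)
    embedding head, plus a 4-scalar pretext regression head."""

    def __init__(self, channels: int = 3, conv_filters=(32, 64, 128),
                 embed_len: int = 64, dropout: float = 0.3, seed: int = 0):
        super().__init__()
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0xf05e)))
        f1, f2, f3 = conv_filters
        self.conv1 = nn.Conv3d(channels, f1, 3, rng, padding=1)
        self.conv2 = nn.Conv3d(f1, f2, 3, rng, padding=1)
        self.conv3 = nn.Conv3d(f2, f3, 3, rng, padding=1)
        self.dense = nn.Linear(f3, embed_len, rng)
        self.drop = nn.Dropout(dropout, seed=int(rng.integers(2 ** 31)))
        # zero-init so an untrained pretext head predicts exactly 0
        self.pretext_head = nn.Linear(embed_len, len(FOREGROUND_LABELS), rng,
                                      zero_init=True)
        self.embed_len = embed_len

    def _backbone(self, x: Tensor) -> tuple[Tensor, Tensor]:
        a1 = self.conv1(x).relu()
        h = nn.maxpool3d(a1, 2)
        a2 = self.conv2(h).relu()
        h = nn.maxpool3d(a2, 2)
        a3 = self.conv3(h).relu()          # final conv activations (Grad-CAM)
        h = nn.maxpool3d(a3, 2)
        gap = h.mean(axis=(2, 3, 4))       # global average pooling
        emb = self.drop(self.dense(gap).relu())
        return emb, a3

    def forward(self, x: Tensor) -> Tensor:
        emb, _ = self._backbone(x)
        return self.pretext_head(emb)

    def forward_with_activations(self, x: Tensor):
        """Returns (embedding, pretext_output, final_conv_activations)."""
        emb, act = self._backbone(x)
        return emb, self.pretext_head(emb), act


def build_extractor(channels: int = 3, conv_filters=(32, 64, 128),
                    embed_len: int = 64, dropout: float = 0.3,
                    seed: int = 0) -> FeatureExtractor:
    return FeatureExtractor(channels, conv_filters, embed_len, dropout, seed)


@dataclass
class ExtractorTrainOpts:
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 30
    seed: int = 0


def train_extractor(model: FeatureExtractor, samples: list,
                    opts: ExtractorTrainOpts
                    ) -> tuple[FeatureExtractor, list[float]]:
    """Minimise MSE between the pretext head and per-sinus residual means.

    ``samples``: list of ``(FusedInput, target_vector)`` pairs.
    """
    if not samples:
        raise ValueError("empty training manifest")
    xs = np.stack([s[0].channels for s in samples])
    ys = np.stack([np.asarray(s[1], np.float32) for s in samples])
    rng = np.random.default_rng(np.random.SeedSequence((opts.seed, 0xf17)))
    optim = nn.AdamW(model.parameters(), lr=opts.lr, weight_decay=0.0)
    history = []
    n = len(samples)
    for _ in range(opts.epochs):
        order = rng.permutation(n)
        losses = []
        model.train()
        for start in range(0, n, opts.batch_size):
            idx = order[start:start + opts.batch_size]
            pred = model(Tensor(xs[idx]))
            diff = pred - Tensor(ys[idx])
            loss = (diff * diff).mean()
            optim.zero_grad()
            loss.backward()
            optim.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    model.eval()
    return model, history


def embed(model: FeatureExtractor, f: FusedInput) -> StructEmbedding:
    """Deterministic eval-mode embedding of one fused input."""
    if f.channels.shape[0] != model.conv1.weight.shape[1]:
        raise ValueError("channel count differs from model configuration")
    model.eval()
    with nn.no_grad():
        emb, _ = model._backbone(Tensor(f.channels[None]))
    return StructEmbedding(emb.numpy()[0])


__all__ = [
    "FusedInput", "StructEmbedding", "FeatureExtractor", "ExtractorTrainOpts",
    "assemble_input", "pretext_targets", "build_extractor", "train_extractor",
    "embed", "ASSEMBLE_VARIANTS",
]
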