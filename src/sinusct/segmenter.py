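"""Hybrid CNN-transformer multi-class 3D segmentation.

The encoder embeds the volume into patch tokens and runs four hierarchical
stages of windowed multi-head self-attention (alternating unshifted and
cyclically shifted windows, with wraparound masking so tokens from different
original windows never attend to each other), each stage interleaved with a
residual 3x3x3 convolution block under group normalization.  The decoder
mirrors the hierarchy with transposed convolutions and stage-wise skip
connections down to a full-resolution head.  Training minimises an
equal-weight soft-Dice + cross-entropy composite under AdamW with cosine
annealing; augmentation is intensity-only so sinus geometry is never
distorted.

Two ablation variants mirror the encoder study: ``cnn_only`` drops the
attention blocks (leaving the residual conv blocks and the conv
down/upsampling path), and ``transformer_only`` drops the interleaved conv
blocks.

Two named profiles are provided: the full-scale profile (96^3 patches,
embed 48, depths (2,2,6,2), heads (3,6,12,24), window 7^3, conv ladder
(32,64,128,256), AdamW 1e-4 cosine, batch 2, 200 epochs) and a small "desk"
profile sized for CPU experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import nn
from .core import LabelMask, Volume
from .nn import Tensor
from .preprocess import augment_intensity

DICE_SMOOTH = 1e-5
_NEG_INF = np.float32(-1e9)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class SegConfig:
    in_shape: tuple[int, int, int] = (96, 96, 96)
    num_classes: int = 5
    embed_dim: int = 48
    depths: tuple[int, int, int, int] = (2, 2, 6, 2)
    heads: tuple[int, int, int, int] = (3, 6, 12, 24)
    window: tuple[int, int, int] = (7, 7, 7)
    conv_filters: tuple[int, int, int, int] = (32, 64, 128, 256)
    variant: str = "full"  # full | cnn_only | transformer_only
    groupnorm_groups: int = 8
    patch_size: int = 2
    stem_channels: int = 16
    mlp_ratio: float = 4.0
    conv_per_block: int = 2  # convs inside each residual conv block (1 or 2)

    def stage_dims(self) -> tuple[int, ...]:
        return tuple(self.embed_dim * 2 ** i for i in range(4))

    def validate(self) -> None:
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if any(w < 1 for w in self.window):
            raise ValueError("window entries must be >= 1")
        if self.variant not in ("full", "cnn_only", "transformer_only"):
            raise ValueError(f"unknown variant {self.variant!r}")
        for dim, h in zip(self.stage_dims(), self.heads):
            if dim % h:
                raise ValueError(f"stage dim {dim} not divisible by heads {h}")
        for ax in self.in_shape:
            if ax % self.patch_size:
                raise ValueError("in_shape must be divisible by patch_size")


def desk_seg_config(variant: str = "full") -> SegConfig:
    """Small CPU-friendly profile used throughout the tests."""
    return SegConfig(
        in_shape=(48, 48, 48), embed_dim=24, depths=(1, 1, 2, 1),
        heads=(1, 2, 4, 8), window=(3, 3, 3), conv_filters=(24, 48, 96, 192),
        variant=variant, groupnorm_groups=4, patch_size=4, stem_channels=8,
        mlp_ratio=2.0, conv_per_block=1,
    )


def reference_seg_config(variant: str = "full") -> SegConfig:
    return SegConfig(variant=variant)


@dataclass
class TrainOpts:
    lr: float = 1e-4
    schedule: str = "cosine"  # cosine | constant
    batch_size: int = 2
    epochs: int = 200
    dice_weight: float = 0.5
    ce_weight: float = 0.5
    pseudo_label_weight: float = 1.0
    weight_decay: float = 0.01
    augment: bool = True
    seed: int = 0

    def validate(self) -> None:
        if self.dice_weight + self.ce_weight <= 0:
            raise ValueError("dice_weight + ce_weight must be positive")
        if not 0.0 <= self.pseudo_label_weight <= 1.0:
            raise ValueError("pseudo_label_weight must be in [0, 1]")


@dataclass
class SegPrediction:
    probs: np.ndarray  # (num_classes, X, Y, Z), sums to 1 per voxel
    labels: LabelMask  # argmax, ties -> lowest class index


# ---------------------------------------------------------------------------
# attention
# ---------------------------------------------------------------------------

def _window_mask(spatial, window, shift) -> np.ndarray | None:
    """Additive (-inf) attention mask for cyclically shifted windows.

    Tokens whose pre-shift window differs, and zero-padding tokens, get -inf
    so attention never crosses original window boundaries.  Returns
    ``None`` when no masking is needed.
    """
    pad = [(-s) % w for s, w in zip(spatial, window)]
    padded = tuple(s + p for s, p in zip(spatial, pad))
    ids = np.zeros(padded, dtype=np.int32)
    if any(shift):
        cnt = 0
        segs = []
        for ax in range(3):
            w, s = window[ax], shift[ax]
            if s:
                segs.append([slice(0, padded[ax] - w), slice(padded[ax] - w, padded[ax] - s),
                             slice(padded[ax] - s, padded[ax])])
            else:
                segs.append([slice(0, padded[ax])])
        for sx in segs[0]:
            for sy in segs[1]:
                for sz in segs[2]:
                    ids[sx, sy, sz] = cnt
                    cnt += 1
    if any(pad):
        ids = ids.copy()
        if pad[0]:
            ids[spatial[0]:, :, :] = -1
        if pad[1]:
            ids[:, spatial[1]:, :] = -1
        if pad[2]:
            ids[:, :, spatial[2]:] = -1
    if not any(shift) and not any(pad):
        return None
    if any(shift):
        ids = np.roll(ids, tuple(-s for s in shift), axis=(0, 1, 2))
    wins = _partition_np(ids[None, ..., None], window)[..., 0]  # (nW, T)
    mask = np.where(wins[:, :, None] == wins[:, None, :], np.float32(0), _NEG_INF)
    return mask  # (nW, T, T)


def _partition_np(x: np.ndarray, window):
    n, X, Y, Z, c = x.shape
    wx, wy, wz = window
    x = x.reshape(n, X // wx, wx, Y // wy, wy, Z // wz, wz, c)
    x = x.transpose(0, 1, 3, 5, 2, 4, 6, 7)
    return x.reshape(n * (X // wx) * (Y // wy) * (Z // wz), wx * wy * wz, c)


class WindowAttention(nn.Module):
    """Multi-head self-attention inside (optionally shifted) local windows."""

    def __init__(self, dim: int, window: tuple[int, int, int], heads: int,
                 shift: tuple[int, int, int], rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by {heads} heads")
        self.dim = dim
        self.window = tuple(window)
        self.heads = heads
        self.shift = tuple(shift)
        self.qkv = nn.Linear(dim, 3 * dim, rng)
        self.proj = nn.Linear(dim, dim, rng)
        self._mask_cache: dict[tuple, np.ndarray | None] = {}

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, X, Y, Z, C) token grid; returns the same shape."""
        n, X, Y, Z, C = x.shape
        spatial = (X, Y, Z)
        w = self.window
        shift = self.shift
        key = spatial
        if key not in self._mask_cache:
            self._mask_cache[key] = _window_mask(spatial, w, shift)
        mask = self._mask_cache[key]

        if any(shift):
            x = x.roll(tuple(-s for s in shift), (1, 2, 3))
        pad = [(-s) % ww for s, ww in zip(spatial, w)]
        if any(pad):
            x = x.pad(((0, 0), (0, pad[0]), (0, pad[1]), (0, pad[2]), (0, 0)))
        PX, PY, PZ = [s + p for s, p in zip(spatial, pad)]
        nx, ny, nz = PX // w[0], PY // w[1], PZ // w[2]
        T = w[0] * w[1] * w[2]

        t = x.reshape(n, nx, w[0], ny, w[1], nz, w[2], C)
        t = t.transpose(0, 1, 3, 5, 2, 4, 6, 7).reshape(n * nx * ny * nz, T, C)

        qkv = self.qkv(t)  # (B, T, 3C)
        B = n * nx * ny * nz
        hd = C // self.heads
        qkv = qkv.reshape(B, T, 3, self.heads, hd).transpose(2, 0, 3, 1, 4)
        q, k, v = qkv[0], qkv[1], qkv[2]  # (B, h, T, hd)
        att = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(hd))
        if mask is not None:
            # mask is (nW, T, T); tile over batch and heads
            m = np.broadcast_to(mask[None, :, None, :, :],
                                (n, nx * ny * nz, self.heads, T, T))
            att = att + Tensor(m.reshape(B, self.heads, T, T))
        att = nn.softmax(att, axis=-1)
        out = att @ v  # (B, h, T, hd)
        out = out.transpose(0, 2, 1, 3).reshape(B, T, C)
        out = self.proj(out)

        out = out.reshape(n, nx, ny, nz, w[0], w[1], w[2], C)
        out = out.transpose(0, 1, 4, 2, 5, 3, 6, 7).reshape(n, PX, PY, PZ, C)
        if any(pad):
            out = out[:, :X, :Y, :Z, :]
        if any(shift):
            out = out.roll(shift, (1, 2, 3))
        return out


def window_attention(attn: WindowAttention, features: Tensor) -> Tensor:
    """Functional entry point: apply a windowed-attention layer to a
    (N, X, Y, Z, C) token grid."""
    return attn(features)


class SwinBlock(nn.Module):
    """LN -> (shifted) window attention -> residual; LN -> MLP -> residual."""

    def __init__(self, dim, window, heads, shift, mlp_ratio, rng):
        super().__init__()
        self.norm1 = nn.LayerNorm(dim)
        self.attn = WindowAttention(dim, window, heads, shift, rng)
        self.norm2 = nn.LayerNorm(dim)
        hidden = max(1, int(dim * mlp_ratio))
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.fc2 = nn.Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        return x + self.fc2(self.fc1(self.norm2(x)).gelu())


class ResConvBlock(nn.Module):
    """Residual 3x3x3 convolution block with group normalization."""

    def __init__(self, dim, mid, groups, n_convs, rng):
        super().__init__()
        self.n_convs = n_convs
        if n_convs == 1:
            self.conv1 = nn.Conv3d(dim, dim, 3, rng, padding=1)
            self.gn1 = nn.GroupNorm(groups, dim)
        else:
            self.conv1 = nn.Conv3d(dim, mid, 3, rng, padding=1)
            self.gn1 = nn.GroupNorm(min(groups, mid), mid)
            self.conv2 = nn.Conv3d(mid, dim, 3, rng, padding=1)
            self.gn2 = nn.GroupNorm(groups, dim)

    def forward(self, x: Tensor) -> Tensor:
        y = self.gn1(self.conv1(x))
        if self.n_convs == 1:
            return (x + y).relu()
        y = self.gn2(self.conv2(y.relu()))
        return (x + y).relu()


class _ConvGNRelu(nn.Module):
    def __init__(self, cin, cout, k, groups, rng, stride=1):
        super().__init__()
        self.conv = nn.Conv3d(cin, cout, k, rng, stride=stride,
                              padding=(k - 1) // 2 if stride == 1 else 0)
        self.gn = nn.GroupNorm(min(groups, cout) if cout % min(groups, cout) == 0
                               else 1, cout)

    def forward(self, x):
        return self.gn(self.conv(x)).relu()


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------

def _gn_groups(pref: int, ch: int) -> int:
    g = min(pref, ch)
    while ch % g:
        g -= 1
    return g


class HybridSegmenter(nn.Module):
    def __init__(self, cfg: SegConfig, seed: int = 0):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(np.random.SeedSequence((seed, 0x5e6)))
        dims = cfg.stage_dims()
        g = cfg.groupnorm_groups

        self.stem = _ConvGNRelu(1, cfg.stem_channels, 3, _gn_groups(g, cfg.stem_channels), rng)
        self.patch_embed = nn.Conv3d(cfg.stem_channels, dims[0], cfg.patch_size,
                                     rng, stride=cfg.patch_size)

        r = [s // cfg.patch_size for s in cfg.in_shape]
        self.stage_res: list[tuple[int, ...]] = []
        self.stages: list[list[nn.Module]] = []
        self.downs: list[nn.Module] = []
        min_w = max(cfg.window)
        for i in range(4):
            self.stage_res.append(tuple(r))
            blocks: list[nn.Module] = []
            if cfg.variant != "cnn_only":
                for d in range(cfg.depths[i]):
                    shift = tuple(0 if d % 2 == 0 else w // 2 for w in cfg.window)
                    blocks.append(SwinBlock(dims[i], cfg.window, cfg.heads[i],
                                            shift, cfg.mlp_ratio, rng))
            if cfg.variant != "transformer_only":
                blocks.append(ResConvBlock(dims[i], cfg.conv_filters[i],
                                           _gn_groups(g, dims[i]),
                                           cfg.conv_per_block, rng))
            self.stages.append(blocks)
            if i < 3:
                if all(x % 2 == 0 and x // 2 >= 1 for x in r):
                    self.downs.append(nn.Conv3d(dims[i], dims[i + 1], 2, rng, stride=2))
                    r = [x // 2 for x in r]
                else:  # resolution floor reached: widen channels only
                    self.downs.append(nn.Conv3d(dims[i], dims[i + 1], 1, rng))

        # decoder: mirror the hierarchy with transposed convs + skips
        self.ups: list[nn.Module] = []
        self.fuses: list[nn.Module] = []
        self.refines: list[nn.Module] = []
        for i in range(3, 0, -1):
            if self.stage_res[i] != self.stage_res[i - 1]:
                self.ups.append(nn.ConvTranspose3d(dims[i], dims[i - 1], 2, rng, stride=2))
            else:
                self.ups.append(nn.Conv3d(dims[i], dims[i - 1], 1, rng))
            self.fuses.append(nn.Conv3d(2 * dims[i - 1], dims[i - 1], 1, rng))
            self.refines.append(_ConvGNRelu(dims[i - 1], dims[i - 1], 3,
                                            _gn_groups(g, dims[i - 1]), rng))

        # expansion from stage-0 resolution back to full resolution
        self.expands: list[nn.Module] = []
        ch = dims[0]
        n_up = int(np.log2(cfg.patch_size))
        for _ in range(n_up):
            nxt = max(cfg.stem_channels, ch // 2)
            self.expands.append(nn.ConvTranspose3d(ch, nxt, 2, rng, stride=2))
            ch = nxt
        self.stem_fuse = nn.Conv3d(ch + cfg.stem_channels, ch, 1, rng)
        self.head = nn.Conv3d(ch, cfg.num_classes, 1, rng)

    # -- helpers -----------------------------------------------------------
    @staticmethod
    def _to_tokens(x: Tensor) -> Tensor:
        return x.transpose(0, 2, 3, 4, 1)

    @staticmethod
    def _to_grid(x: Tensor) -> Tensor:
        return x.transpose(0, 4, 1, 2, 3)

    def forward(self, x: Tensor) -> Tensor:
        """x: (N, 1, X, Y, Z) normalized volume -> logits (N, C, X, Y, Z)."""
        stem = self.stem(x)
        f = self.patch_embed(stem)
        skips = []
        for i in range(4):
            for blk in self.stages[i]:
                if isinstance(blk, (SwinBlock,)):
                    f = self._to_grid(blk(self._to_tokens(f)))
                else:
                    f = blk(f)
            skips.append(f)
            if i < 3:
                f = self.downs[i](f)
        for j, i in enumerate(range(3, 0, -1)):
            f = self.ups[j](f)
            f = self.fuses[j](nn.concat([f, skips[i - 1]], axis=1))
            f = self.refines[j](f)
        for up in self.expands:
            f = up(f)
        f = self.stem_fuse(nn.concat([f, stem], axis=1))
        return self.head(f)


def build_segmenter(cfg: SegConfig, seed: int = 0) -> HybridSegmenter:
    return HybridSegmenter(cfg, seed)


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def composite_loss(probs: Tensor, target: np.ndarray, dice_weight: float,
                   ce_weight: float, num_classes: int | None = None) -> Tensor:
    """Equal-footing soft Dice + cross-entropy on per-voxel probabilities.

    ``probs``: (N, C, ...) class probabilities summing to 1 per voxel.
    ``target``: integer labels of shape (N, ...).  The Dice term averages the
    per-foreground-class soft Dice complement; the CE term is the mean
    voxel-wise negative log-probability of the target class.
    """
    target = np.asarray(target)
    C = probs.shape[1]
    if num_classes is None:
        num_classes = C
    if target.max() >= num_classes:
        raise ValueError(f"target contains labels >= num_classes ({num_classes})")
    onehot = np.moveaxis(np.eye(C, dtype=np.float32)[target], -1, 1)
    oh = Tensor(onehot)

    spatial_axes = tuple(range(2, probs.ndim))
    p_sum = probs.sum(axis=spatial_axes)          # (N, C)
    g_sum = onehot.sum(axis=spatial_axes)          # np (N, C)
    inter = (probs * oh).sum(axis=spatial_axes)    # (N, C)
    num = inter * 2.0 + DICE_SMOOTH
    den = p_sum + Tensor(g_sum) + DICE_SMOOTH
    dice_all = num / den                           # (N, C)
    fg = dice_all[:, 1:]
    dice_loss = 1.0 - fg.mean()

    p_t = (probs * oh).sum(axis=1)                 # (N, ...)
    ce = -((p_t + 1e-12).log()).mean()
    return dice_loss * dice_weight + ce * ce_weight


# ---------------------------------------------------------------------------
# training / inference
# ---------------------------------------------------------------------------

def train_segmenter(model: HybridSegmenter, samples: list, opts: TrainOpts
                    ) -> tuple[HybridSegmenter, list[float]]:
    """Train on (volume, labels[, is_pseudo]) triples of numpy arrays.

    Volumes must be normalized to [0, 1] and already at ``cfg.in_shape``.
    Pseudo-labelled samples contribute with weight ``opts.pseudo_label_weight``.
    Returns the model and the per-epoch mean loss history.
    """
    opts.validate()
    if not samples:
        raise ValueError("empty training manifest")
    prepared = []
    for s in samples:
        vol, lab = s[0], s[1]
        pseudo = bool(s[2]) if len(s) > 2 else False
        vol = np.asarray(vol, np.float32)
        if vol.shape != tuple(model.cfg.in_shape):
            raise ValueError("sample shape differs from cfg.in_shape")
        prepared.append((vol, np.asarray(lab), pseudo))

    rng = np.random.default_rng(np.random.SeedSequence((opts.seed, 0x7a1)))
    optim = nn.AdamW(model.parameters(), lr=opts.lr, weight_decay=opts.weight_decay)
    history: list[float] = []
    n = len(prepared)
    for epoch in range(opts.epochs):
        optim.lr = nn.lr_at_epoch(opts.lr, epoch, opts.epochs,
                                  "cosine" if opts.schedule == "cosine" else "constant")
        order = rng.permutation(n)
        losses = []
        model.train()
        for start in range(0, n, opts.batch_size):
            idx = order[start:start + opts.batch_size]
            vols, labs, wts = [], [], []
            for i in idx:
                vol, lab, pseudo = prepared[i]
                if opts.augment:
                    v = augment_intensity(Volume(vol, (1, 1, 1), "normalized"),
                                          (0.9, 1.1), (0.95, 1.05),
                                          seed=int(rng.integers(2 ** 31)))
                    vol = v.grid
                vols.append(vol)
                labs.append(lab)
                wts.append(opts.pseudo_label_weight if pseudo else 1.0)
            if all(w == 0.0 for w in wts):
                losses.append(0.0)
                continue
            x = Tensor(np.stack(vols)[:, None])
            logits = model(x)
            probs = nn.softmax(logits, axis=1)
            batch_loss = None
            for b, w in enumerate(wts):
                if w == 0.0:
                    continue
                li = composite_loss(probs[b:b + 1], np.stack(labs)[b:b + 1],
                                    opts.dice_weight, opts.ce_weight) * w
                batch_loss = li if batch_loss is None else batch_loss + li
            batch_loss = batch_loss * (1.0 / len(wts))
            optim.zero_grad()
            batch_loss.backward()
            optim.step()
            losses.append(batch_loss.item())
        history.append(float(np.mean(losses)))
    model.eval()
    return model, history


def _tile_starts(full: int, tile: int) -> list[int]:
    if full <= tile:
        return [0]
    step = max(1, tile // 2)  # 50% overlap
    starts = list(range(0, full - tile + 1, step))
    if starts[-1] != full - tile:
        starts.append(full - tile)
    return starts


def predict_mask(model: HybridSegmenter, v: Volume) -> SegPrediction:
    """Whole-volume inference by sliding-window tiling with mean-blended
    probabilities (50% tile overlap)."""
    if v.intensity_domain != "normalized":
        raise ValueError("predict_mask expects a normalized volume")
    cfg = model.cfg
    grid = v.grid
    tile = cfg.in_shape
    if any(g < t for g, t in zip(grid.shape, tile)):
        raise ValueError("volume smaller than model input; standardize_shape first")
    model.eval()
    acc = np.zeros((cfg.num_classes, *grid.shape), np.float32)
    cnt = np.zeros(grid.shape, np.float32)
    with nn.no_grad():
        for sx in _tile_starts(grid.shape[0], tile[0]):
            for sy in _tile_starts(grid.shape[1], tile[1]):
                for sz in _tile_starts(grid.shape[2], tile[2]):
                    sl = (slice(sx, sx + tile[0]), slice(sy, sy + tile[1]),
                          slice(sz, sz + tile[2]))
                    x = Tensor(grid[sl][None, None])
                    p = nn.softmax(model(x), axis=1).numpy()[0]
                    acc[(slice(None),) + sl] += p
                    cnt[sl] += 1.0
    probs = acc / cnt[None]
    labels = probs.argmax(axis=0).astype(np.int16)  # ties -> lowest index
    return SegPrediction(probs=probs, labels=LabelMask(labels, v.spacing_mm))


__all__ = [
    "SegConfig", "TrainOpts", "SegPrediction", "HybridSegmenter",
    "WindowAttention", "SwinBlock", "ResConvBlock",
    "build_segmenter", "window_attention", "composite_loss",
    "train_segmenter", "predict_mask", "desk_seg_config", "reference_seg_config",
    "DICE_SMOOTH",
]
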