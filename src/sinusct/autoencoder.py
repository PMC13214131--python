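"""Self-supervised 3D convolutional autoencoder for anomaly localization.

The CAE is trained only on structurally *normal* sinus regions, so it learns
a compact latent representation of healthy morphology.  At inference the
voxel-wise absolute difference between an input volume and its
reconstruction, r = |x - x_hat|, forms a residual map: structures the model
has never seen (opacified cavities, thickened walls, missing air cells)
reconstruct poorly and light up in r.

The reference architecture uses a 64^3 input, encoder filters (32, 64, 128)
into a 256-dimensional latent bottleneck and a symmetric transposed-conv
decoder, trained with a voxel-wise L2 loss under Adam (lr 1e-3, batch 4,
step decay x0.1 every 50 epochs).  An L1 reconstruction loss is available by
configuration.  The desk profile shrinks this to a 32^3 input with filters
(8, 16, 32) and a 64-dimensional latent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .core import ResidualMap, Volume
from .nn import Tensor


@dataclass
class CAEConfig:
    in_shape: tuple[int, int, int] = (64, 64, 64)
    enc_filters: tuple[int, int, int] = (32, 64, 128)
    latent_dim: int = 256
    recon_loss: str = "L2"  # "L2" (default) or "L1"
    seed: int = 0

    def validate(self) -> None:
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (self.enc_filters[0] < self.enc_filters[1] < self.enc_filters[2]):
            raise ValueError("enc_filters must be strictly increasing")
        if self.recon_loss not in ("L1", "L2"):
            raise ValueError("recon_loss must be 'L1' or 'L2'")
        for ax in self.in_shape:
            if ax % 8:
                raise ValueError("in_shape must be divisible by 2^3 "
                                 "(three stride-2 encoder stages)")


def desk_cae_config() -> CAEConfig:
    """CPU-scale profile: 32^3 crops, filters (8, 16, 32), latent 64."""
    return CAEConfig(in_shape=(32, 32, 32), enc_filters=(8, 16, 32), latent_dim=64)


@dataclass
class CAETrainOpts:
    lr: float = 1e-3
    batch_size: int = 4
    epochs: int = 100
    step_every: int = 50
    step_factor: float = 0.1
    seed: int = 0


@dataclass
class LatentCode:
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, np.float32).ravel()


class ConvAutoencoder(nn.Module):
    """Encoder: 3 stride-2 conv blocks -> dense latent; decoder mirrors with
    transposed convolutions and a logistic output onto [0, 1]."""

    def __init__(self, cfg: CAEConfig, seed: int | None = None):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        rng = np.random.default_rng(
            np.random.SeedSequence((cfg.seed if seed is None else seed, 0xcae)))
        f1, f2, f3 = cfg.enc_filters
        self.enc1 = nn.Conv3d(1, f1, 3, rng, stride=2, padding=1)
        self.enc2 = nn.Conv3d(f1, f2, 3, rng, stride=2, padding=1)
        self.enc3 = nn.Conv3d(f2, f3, 3, rng, stride=2, padding=1)
        self.bottleneck_shape = (f3,) + tuple(s // 8 for s in cfg.in_shape)
        flat = int(np.prod(self.bottleneck_shape))
        self.to_latent = nn.Linear(flat, cfg.latent_dim, rng)
        self.from_latent = nn.Linear(cfg.latent_dim, flat, rng)
        self.dec3 = nn.ConvTranspose3d(f3, f2, 2, rng, stride=2)
        self.dec2 = nn.ConvTranspose3d(f2, f1, 2, rng, stride=2)
        self.dec1 = nn.ConvTranspose3d(f1, f1, 2, rng, stride=2)
        self.out = nn.Conv3d(f1, 1, 3, rng, padding=1)

    def encode(self, x: Tensor) -> Tensor:
        h = self.enc1(x).relu()
        h = self.enc2(h).relu()
        h = self.enc3(h).relu()
        n = h.shape[0]
        return self.to_latent(h.reshape(n, -1))

    def decode(self, z: Tensor) -> Tensor:
        n = z.shape[0]
        h = self.from_latent(z).relu().reshape((n,) + self.bottleneck_shape)
        h = self.dec3(h).relu()
        h = self.dec2(h).relu()
        h = self.dec1(h).relu()
        return self.out(h).sigmoid()

    def forward(self, x: Tensor) -> Tensor:
        return self.decode(self.encode(x))


def build_cae(cfg: CAEConfig, seed: int | None = None) -> ConvAutoencoder:
    return ConvAutoencoder(cfg, seed)


def recon_loss(x: Tensor | np.ndarray, xhat: Tensor | np.ndarray,
               kind: str = "L2") -> Tensor:
    """Mean voxel-wise reconstruction error: L1 = mean|x-x^|, L2 = mean(x-x^)^2."""
    x = x if isinstance(x, Tensor) else Tensor(np.asarray(x, np.float32))
    xhat = xhat if isinstance(xhat, Tensor) else Tensor(np.asarray(xhat, np.float32))
    if x.shape != xhat.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {xhat.shape}")
    diff = x - xhat
    if kind == "L2":
        return (diff * diff).mean()
    if kind == "L1":
        return diff.abs().mean()
    raise ValueError("kind must be 'L1' or 'L2'")


def train_cae(model: ConvAutoencoder, samples: list, opts: CAETrainOpts
              ) -> tuple[ConvAutoencoder, list[float]]:
    """Train on normal-only volumes; refuses anomalous samples outright.

    ``samples``: list of ``(volume_array, anomaly_kind)`` pairs; every
    ``anomaly_kind`` must be ``"none"`` — the healthy-manifold premise of
    residual mapping breaks if the training set contains anomalies.
    Volumes must be normalized to [0, 1] at ``cfg.in_shape``.
    """
    if not samples:
        raise ValueError("empty training manifest")
    vols = []
    for i, (vol, anomaly) in enumerate(samples):
        if anomaly != "none":
            raise ValueError(
                f"sample {i} carries anomaly {anomaly!r}: the autoencoder must "
                "be trained on structurally normal samples only")
        vol = np.asarray(vol, np.float32)
        if vol.shape != tuple(model.cfg.in_shape):
            raise ValueError("sample shape differs from cfg.in_shape")
        vols.append(vol)

    rng = np.random.default_rng(np.random.SeedSequence((opts.seed, 0xcaef)))
    optim = nn.AdamW(model.parameters(), lr=opts.lr, weight_decay=0.0)
    history: list[float] = []
    n = len(vols)
    for epoch in range(opts.epochs):
        optim.lr = nn.lr_at_epoch(opts.lr, epoch, opts.epochs, "step",
                                  opts.step_every, opts.step_factor)
        order = rng.permutation(n)
        losses = []
        model.train()
        for start in range(0, n, opts.batch_size):
            idx = order[start:start + opts.batch_size]
            x = Tensor(np.stack([vols[i] for i in idx])[:, None])
            xhat = model(x)
            loss = recon_loss(x, xhat, model.cfg.recon_loss)
            optim.zero_grad()
            loss.backward()
            optim.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    model.eval()
    return model, history


def residual_map(model: ConvAutoencoder, v: Volume
                 ) -> tuple[Volume, ResidualMap, LatentCode]:
    """Reconstruction x_hat, residual r = |x - x_hat| and latent code z."""
    if v.grid.shape != tuple(model.cfg.in_shape):
        raise ValueError(f"volume shape {v.grid.shape} differs from "
                         f"cfg.in_shape {model.cfg.in_shape}")
    model.eval()
    with nn.no_grad():
        z = model.encode(Tensor(v.grid[None, None]))
        xhat = model.decode(z).numpy()[0, 0]
    recon = Volume(xhat, v.spacing_mm, "normalized")
    r = ResidualMap(np.abs(v.grid - xhat), v.spacing_mm)
    return recon, r, LatentCode(z.numpy()[0])


def prepare_cae_input(volume: Volume, labels, cfg: CAEConfig,
                      anomaly_mask: np.ndarray | None = None, margin_vox: int = 2):
    """Crop to the sinus bounding box, standardize to ``cfg.in_shape`` and
    normalize; labels and an optional anomaly mask undergo the identical
    geometric transform.

    Returns ``(volume, labels)`` or ``(volume, labels, anomaly_mask)``.
    """
    from .core import LabelMask
    from .preprocess import normalize_minmax, sanitize, standardize_shape

    lab_grid = labels.grid if isinstance(labels, LabelMask) else np.asarray(labels)
    nz = np.nonzero(lab_grid)
    if len(nz[0]) == 0:
        raise ValueError("label mask is empty; no sinus region to crop to")
    # one shared sinus bounding box applied to every aligned grid
    slices = tuple(
        slice(max(0, int(nz[ax].min()) - margin_vox),
              min(volume.grid.shape[ax], int(nz[ax].max()) + 1 + margin_vox))
        for ax in range(3))

    v_c = standardize_shape(
        Volume(sanitize(volume).grid[slices], volume.spacing_mm,
               volume.intensity_domain), cfg.in_shape)
    if v_c.intensity_domain == "HU":
        v_c = normalize_minmax(v_c)
    m_c = standardize_shape(
        LabelMask(lab_grid[slices], volume.spacing_mm), cfg.in_shape)
    if anomaly_mask is None:
        return v_c, m_c
    a_c = standardize_shape(
        LabelMask(np.asarray(anomaly_mask).astype(np.int16)[slices],
                  volume.spacing_mm), cfg.in_shape)
    return v_c, m_c, a_c.grid.astype(np.uint8)


def anomaly_contrast(r: ResidualMap, anomaly_mask: np.ndarray,
                     reference_mask: np.ndarray) -> float:
    """mean(r | anomaly) / mean(r | reference); inf when the reference
    residual is exactly zero.  The reference region is conventionally the
    labeled sinus voxels outside the anomaly."""
    am = np.asarray(anomaly_mask).astype(bool)
    rm = np.asarray(reference_mask).astype(bool)
    if am.shape != r.grid.shape or rm.shape != r.grid.shape:
        raise ValueError("masks must match the residual-map geometry")
    if not am.any() or not rm.any():
        raise ValueError("anomaly and reference masks must be nonempty")
    ref_mean = float(r.grid[rm].mean())
    anom_mean = float(r.grid[am].mean())
    if ref_mean == 0.0:
        return float("inf")
    return anom_mean / ref_mean


__all__ = [
    "CAEConfig", "CAETrainOpts", "LatentCode", "ConvAutoencoder",
    "build_cae", "recon_loss", "train_cae", "residual_map", "anomaly_contrast",
    "prepare_cae_input", "desk_cae_config",
]
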