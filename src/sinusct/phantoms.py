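"""Procedural sinus-like CT phantoms with ground-truth masks and anomalies.

Each phantom is a head-shaped ellipsoid of soft tissue wrapped in a bony
shell, sitting on an air background, and containing four bilateral pairs of
air-filled cavities with thin bony walls: maxillary (lateral-inferior),
ethmoid (central, subdivided into small cells by 1-voxel bone septations),
frontal (superior-anterior) and sphenoid (posterior-central).  Per-scan
intensity noise, Gaussian blur and a global intensity shift emulate the
variability of multiple CT scanners.  Structural anomalies — mucosal wall
thickening, partial or total opacification of a cavity with fluid, and
asymmetric cavity shrinkage — can be inserted into one randomly chosen
cavity, with a separate binary ground-truth mask.

All geometry is expressed in fractions of the head's semi-axes so the same
phantom renders consistently at any grid size.  Randomness is derived from a
single integer seed through ``numpy.random.SeedSequence`` spawning, so
cohorts are reproducible sample by sample.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import LABEL_NAMES, LabelMask, Volume

ANOMALY_KINDS = ("none", "wall_thickening", "partial_opacification",
                 "total_opacification", "asymmetry")

# Relative cavity geometry: centre and semi-radii in fractions of the head
# semi-axes; x mirrored for the left/right pair.  Chosen so all cavities fit
# inside the soft-tissue region with non-overlapping walls.
_CAVITY_GEOMETRY: dict[int, tuple[tuple[float, float, float], tuple[float, float, float]]] = {
    1: ((0.42, 0.18, -0.24), (0.20, 0.24, 0.26)),   # maxillary
    2: ((0.15, 0.30, 0.12), (0.11, 0.24, 0.14)),    # ethmoid
    3: ((0.17, 0.34, 0.52), (0.14, 0.11, 0.14)),    # frontal
    4: ((0.14, -0.22, 0.08), (0.12, 0.15, 0.13)),   # sphenoid
}
_HEAD_FRACTION = 0.46      # head semi-axes as fraction of the grid extent
_SKULL_INNER = 0.90        # skull shell spans normalized head radius (0.90, 1]
_WALL_FRACTION = 1.22      # cavity bony wall spans normalized radius (1, 1.22]

# Scanner-variability jitter ranges used by generate_cohort.
COHORT_NOISE_SD_HU = (2.0, 10.0)
COHORT_BLUR_SIGMA_VOX = (0.2, 0.8)
COHORT_SHIFT_HU = (-25.0, 25.0)
COHORT_ANOMALY_STRENGTH = (0.5, 1.0)


@dataclass
class PhantomSpec:
    """Full parameterisation of one phantom; deterministic given ``seed``."""

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    hu_air: float = -1000.0
    hu_soft: float = 40.0
    hu_bone: float = 700.0
    hu_fluid: float = 30.0
    cavity_scale: float = 1.0
    ethmoid_cells: int = 3
    noise_sd_hu: float = 0.0
    blur_sigma_vox: float = 0.0
    intensity_shift_hu: float = 0.0
    anomaly: str = "none"
    anomaly_strength: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not (self.hu_air < self.hu_fluid < self.hu_soft < self.hu_bone):
            raise ValueError("require hu_air < hu_fluid < hu_soft < hu_bone")
        if any(int(g) < 16 for g in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 16")
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm entries must be positive")
        if self.anomaly not in ANOMALY_KINDS:
            raise ValueError(f"unknown anomaly {self.anomaly!r}")
        if not 0.0 <= self.anomaly_strength <= 1.0:
            raise ValueError("anomaly_strength must be in [0, 1]")
        if self.cavity_scale <= 0:
            raise ValueError("cavity_scale must be positive")
        if self.ethmoid_cells < 1:
            raise ValueError("ethmoid_cells must be >= 1")
        if self.noise_sd_hu < 0 or self.blur_sigma_vox < 0:
            raise ValueError("noise_sd_hu and blur_sigma_vox must be non-negative")


@dataclass
class PhantomSample:
    volume: Volume
    labels: LabelMask
    anomaly_mask: np.ndarray
    spec: PhantomSpec = field(repr=False)


def cavity_parameters(spec: PhantomSpec):
    """Yield (label, side, centre_vox, radii_vox) for all 8 cavity instances."""
    shape = np.asarray(spec.grid_shape, float)
    head_c = (shape - 1.0) / 2.0
    head_r = _HEAD_FRACTION * shape
    for label, (cfrac, rfrac) in _CAVITY_GEOMETRY.items():
        for side in (-1, +1):
            centre = head_c + np.array([side * cfrac[0], cfrac[1], cfrac[2]]) * head_r
            radii = np.asarray(rfrac) * head_r * spec.cavity_scale
            yield label, side, centre, radii


def analytic_cavity_volume_vox(spec: PhantomSpec) -> float:
    """Sum of ellipsoid volumes (in voxels) over all cavity interiors."""
    total = 0.0
    for _, _, _, radii in cavity_parameters(spec):
        total += 4.0 / 3.0 * np.pi * float(np.prod(radii))
    return total


def _ellipsoid_rho(shape, centre, radii) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel centre."""
    ax = [(np.arange(n, dtype=np.float32) - c) / r
          for n, c, r in zip(shape, centre, radii)]
    return np.sqrt(ax[0][:, None, None] ** 2 + ax[1][None, :, None] ** 2
                   + ax[2][None, None, :] ** 2)


def generate_phantom(spec: PhantomSpec) -> PhantomSample:
    """Render one phantom; bit-identical for identical specs."""
    spec.validate()
    shape = tuple(int(g) for g in spec.grid_shape)
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))

    shape_arr = np.asarray(shape, float)
    head_c = (shape_arr - 1.0) / 2.0
    head_r = _HEAD_FRACTION * shape_arr
    rho_head = _ellipsoid_rho(shape, head_c, head_r)

    vol = np.full(shape, spec.hu_air, dtype=np.float32)
    vol[rho_head <= 1.0] = spec.hu_bone        # skull shell ...
    vol[rho_head <= _SKULL_INNER] = spec.hu_soft  # ... around soft tissue

    cavities = list(cavity_parameters(spec))

    # Anomaly target: one cavity instance chosen from the seeded stream.
    # The draw happens for every spec so the geometry stream is identical
    # between a normal phantom and its anomalous twin.
    target_idx = int(rng.integers(len(cavities)))

    labels = np.zeros(shape, dtype=np.int16)
    anomaly_mask = np.zeros(shape, dtype=np.uint8)

    for idx, (label, side, centre, radii) in enumerate(cavities):
        name = f"{LABEL_NAMES[label]} ({'right' if side > 0 else 'left'})"
        wall_r = radii * _WALL_FRACTION
        lo = centre - wall_r
        hi = centre + wall_r
        if (lo < 0).any() or (hi > shape_arr - 1).any():
            raise ValueError(
                f"cavity {name} exceeds grid bounds: extent {lo.round(1)}..{hi.round(1)}"
                f" vs grid {shape}")

        nominal_radii = radii.copy()
        is_target = idx == target_idx and spec.anomaly != "none"
        if is_target and spec.anomaly == "asymmetry":
            radii = radii * (1.0 - spec.anomaly_strength)

        rho_nominal = _ellipsoid_rho(shape, centre, nominal_radii)
        wall = (rho_nominal > 1.0) & (rho_nominal <= _WALL_FRACTION)
        vol[wall & (labels == 0)] = spec.hu_bone

        if (radii > 0).all():
            rho = _ellipsoid_rho(shape, centre, radii)
            interior = rho <= 1.0
        else:
            interior = np.zeros(shape, bool)
            rho = None

        vol[interior] = spec.hu_air
        cavity_label = interior.copy()

        if label == 2 and spec.ethmoid_cells > 1 and interior.any():
            # bone septations: 1-voxel planes splitting the cell along y
            cy, ry = centre[1], radii[1]
            ys = np.arange(shape[1], dtype=np.float32)
            septum_y = np.zeros(shape[1], bool)
            for i in range(1, spec.ethmoid_cells):
                boundary = cy - ry + 2.0 * ry * i / spec.ethmoid_cells
                septum_y |= np.abs(ys - boundary) < 0.5
            septa = interior & septum_y[None, :, None]
            vol[septa] = spec.hu_bone
            cavity_label &= ~septa

        labels[cavity_label] = label

        if is_target:
            if spec.anomaly == "asymmetry":
                removed = (rho_nominal <= 1.0) & ~interior
                vol[removed] = spec.hu_soft
                anomaly_mask[removed] = 1
            elif spec.anomaly == "wall_thickening":
                rind_depth = 0.45 * spec.anomaly_strength
                rind = interior & (rho > 1.0 - rind_depth)
                vol[rind] = spec.hu_soft
                anomaly_mask[rind] = 1
            elif spec.anomaly == "total_opacification":
                vol[cavity_label] = spec.hu_fluid
                anomaly_mask[cavity_label] = 1
            elif spec.anomaly == "partial_opacification":
                air_vox = np.argwhere(cavity_label)
                if len(air_vox):
                    # gravity-dependent fluid level: fill from inferior z up
                    zs = air_vox[:, 2]
                    k = int(round(spec.anomaly_strength * len(zs)))
                    if k > 0:
                        level = np.sort(zs)[k - 1]
                        fill = cavity_label & (
                            np.arange(shape[2])[None, None, :] <= level)
                        vol[fill] = spec.hu_fluid
                        anomaly_mask[fill] = 1

    # scanner emulation, applied last: noise, blur, global shift
    if spec.noise_sd_hu > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd_hu, size=shape).astype(np.float32)
    if spec.blur_sigma_vox > 0:
        vol = ndimage.gaussian_filter(vol, spec.blur_sigma_vox)
    if spec.intensity_shift_hu:
        vol = vol + np.float32(spec.intensity_shift_hu)

    return PhantomSample(
        volume=Volume(vol, spec.spacing_mm, "HU"),
        labels=LabelMask(labels, spec.spacing_mm),
        anomaly_mask=anomaly_mask,
        spec=spec,
    )


def cohort_specs(n: int, base_spec: PhantomSpec, anomaly_fraction: float,
                 seed: int,
                 anomaly_kinds: tuple[str, ...] = ANOMALY_KINDS[1:],
                 anomaly_strength_range: tuple[float, float] = COHORT_ANOMALY_STRENGTH,
                 ) -> list[PhantomSpec]:
    """Derive ``n`` per-sample specs with jittered scanner parameters.

    Exactly ``round(anomaly_fraction * n)`` specs carry a randomly chosen
    anomaly.  Each sample draws its parameters from an independent child
    stream of ``seed``, so cohorts of different sizes share their prefix.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0.0 <= anomaly_fraction <= 1.0:
        raise ValueError("anomaly_fraction must be in [0, 1]")
    n_anom = int(round(anomaly_fraction * n))
    parent = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(parent.spawn(1)[0])
    anom_idx = set(order_rng.permutation(n)[:n_anom].tolist())

    specs = []
    for i, child in enumerate(parent.spawn(n + 1)[1:]):
        rng = np.random.default_rng(child)
        jit = dict(
            noise_sd_hu=float(rng.uniform(*COHORT_NOISE_SD_HU)),
            blur_sigma_vox=float(rng.uniform(*COHORT_BLUR_SIGMA_VOX)),
            intensity_shift_hu=float(rng.uniform(*COHORT_SHIFT_HU)),
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        if i in anom_idx:
            jit["anomaly"] = str(rng.choice(list(anomaly_kinds)))
            jit["anomaly_strength"] = float(rng.uniform(*anomaly_strength_range))
        else:
            jit["anomaly"] = "none"
            jit["anomaly_strength"] = 0.0
        specs.append(replace(base_spec, **jit))
    return specs


def generate_cohort(n: int, base_spec: PhantomSpec, anomaly_fraction: float,
                    seed: int, out_dir: str | Path, **spec_kwargs) -> "object":
    """Render a cohort to disk as NIfTI files plus JSONL/TSV manifests.

    Returns a pandas DataFrame manifest with one row per sample (file paths,
    spec values, anomaly status).
    """
    import pandas as pd

    from .io import write_mask, write_volume

    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out_dir}: {e}") from e

    rows = []
    for i, spec in enumerate(cohort_specs(n, base_spec, anomaly_fraction, seed,
                                          **spec_kwargs)):
        sample = generate_phantom(spec)
        sid = f"phantom_{i:04d}"
        vol_path = out_dir / f"{sid}_volume.nii.gz"
        lab_path = out_dir / f"{sid}_labels.nii.gz"
        anom_path = out_dir / f"{sid}_anomaly.nii.gz"
        write_volume(sample.volume, vol_path)
        write_mask(sample.labels, lab_path)
        write_mask(LabelMask(sample.anomaly_mask.astype(np.int16), spec.spacing_mm),
                   anom_path, validate_labels=False)
        row = {"sample_id": sid, "volume": str(vol_path), "labels": str(lab_path),
               "anomaly_mask": str(anom_path), **asdict(spec)}
        row["grid_shape"] = list(spec.grid_shape)
        row["spacing_mm"] = list(spec.spacing_mm)
        rows.append(row)

    manifest = pd.DataFrame(rows)
    with open(out_dir / "manifest.jsonl", "w") as fh:
        for row in rows:
            fh.write(json.dumps(row) + "\n")
    manifest.to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
    return manifest


__all__ = [
    "ANOMALY_KINDS", "PhantomSpec", "PhantomSample",
    "generate_phantom", "cohort_specs", "generate_cohort",
    "cavity_parameters", "analytic_cavity_volume_vox",
]
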