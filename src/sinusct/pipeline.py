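"""End-to-end orchestration and the canonical desk-scale experiments.

The full workflow chains: phantom generation -> preprocessing -> hybrid
segmentation -> autoencoder residual mapping -> fused structural embeddings
-> Grad-CAM -> quantitative evaluation.  ``run_pipeline`` executes it into a
run directory with per-stage structured logs and a provenance manifest.

The ``desk_*_experiment`` functions are the package's reference experiments
at CPU scale: fixed cohort sizes and training budgets, everything derived
from one integer seed.  They are what the test suite and the results script
execute.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .autoencoder import (CAEConfig, CAETrainOpts, anomaly_contrast, build_cae,
                          desk_cae_config, prepare_cae_input, residual_map,
                          train_cae)
from .core import LabelMask, Volume
from .explain import cam_mass_fraction, grad_cam
from .fusion import (ExtractorTrainOpts, assemble_input, build_extractor,
                     embed, pretext_targets)
from .metrics import aggregate_reports, evaluate_segmentation
from .phantoms import PhantomSpec, cohort_specs, generate_phantom
from .preprocess import normalize_minmax, sanitize
from .segmenter import (SegConfig, TrainOpts, build_segmenter, desk_seg_config,
                        predict_mask, train_segmenter)

# ---------------------------------------------------------------------------
# seeding: one global seed deterministically derives per-stage seeds
# ---------------------------------------------------------------------------

_STAGE_IDS = {"phantoms": 1, "segmenter": 2, "cae": 3, "fusion": 4, "eval": 5,
              "sham": 6}


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable derived seed (< 2^31) for a named pipeline stage."""
    ss = np.random.SeedSequence((int(global_seed), _STAGE_IDS[stage]))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _norm(v: Volume) -> Volume:
    return normalize_minmax(sanitize(v))


# ---------------------------------------------------------------------------
# desk experiments (the reference protocol)
# ---------------------------------------------------------------------------

def desk_segmentation_experiment(seed: int, n_train: int = 32, n_test: int = 8,
                                 epochs: int = 30, lr: float = 3e-3,
                                 variant: str = "full",
                                 test_anomaly_fraction: float = 0.5) -> dict:
    """Train the desk segmenter on 48^3 phantoms and evaluate held out.

    Returns mean foreground Dice / HD95 over the held-out cohort, the loss
    history and the trained model.
    """
    s_gen = stage_seed(seed, "phantoms")
    s_train = stage_seed(seed, "segmenter")
    base = PhantomSpec(grid_shape=(48, 48, 48))
    train_specs = cohort_specs(n_train, base, 0.0, seed=s_gen)
    test_specs = cohort_specs(n_test, base, test_anomaly_fraction,
                              seed=s_gen + 1)

    samples = []
    for sp in train_specs:
        s = generate_phantom(sp)
        samples.append((_norm(s.volume).grid, s.labels.grid))
    model = build_segmenter(desk_seg_config(variant), seed=s_train)
    model, history = train_segmenter(
        model, samples, TrainOpts(lr=lr, epochs=epochs, batch_size=2,
                                  seed=s_train))

    reports = []
    for sp in test_specs:
        s = generate_phantom(sp)
        pred = predict_mask(model, _norm(s.volume))
        reports.append(evaluate_segmentation(pred.labels, s.labels))
    hd = [r.mean_hd95_mm for r in reports if r.mean_hd95_mm is not None]
    return {
        "model": model,
        "loss_history": history,
        "reports": reports,
        "mean_dice": float(np.mean([r.mean_dice for r in reports])),
        "mean_hd95_mm": float(np.mean(hd)) if hd else None,
    }


def desk_anomaly_experiment(seed: int, n_train: int = 16, n_test: int = 16,
                            epochs: int = 60, n_sham: int = 8) -> dict:
    """Train the CAE on normal phantoms only; quantify residual contrast.

    Contrast = mean residual in the anomaly region over mean residual in the
    remaining labeled sinus voxels.  The control cohort is all-normal with
    randomly placed sham regions inside the sinus labels.
    """
    cfg = desk_cae_config()
    base = PhantomSpec()
    s_gen = stage_seed(seed, "phantoms")
    s_train = stage_seed(seed, "cae")

    train = []
    for sp in cohort_specs(n_train, base, 0.0, seed=s_gen + 2):
        s = generate_phantom(sp)
        v, _ = prepare_cae_input(s.volume, s.labels, cfg)
        train.append((v.grid, sp.anomaly))
    cae = build_cae(cfg, seed=s_train)
    cae, history = train_cae(cae, train, CAETrainOpts(epochs=epochs, seed=s_train))

    contrasts = []
    for sp in cohort_specs(n_test, base, 1.0, seed=s_gen + 3):
        s = generate_phantom(sp)
        v, m, a = prepare_cae_input(s.volume, s.labels, cfg, s.anomaly_mask)
        if not (a > 0).any():
            continue
        _, r, _ = residual_map(cae, v)
        reference = (m.grid > 0) & ~(a > 0)
        contrasts.append(anomaly_contrast(r, a > 0, reference))

    sham_rng = np.random.default_rng(stage_seed(seed, "sham"))
    sham = []
    for sp in cohort_specs(n_sham, base, 0.0, seed=s_gen + 4):
        s = generate_phantom(sp)
        v, m = prepare_cae_input(s.volume, s.labels, cfg)
        _, r, _ = residual_map(cae, v)
        lab = np.argwhere(m.grid > 0)
        centre = lab[sham_rng.integers(len(lab))]
        region = np.zeros(m.grid.shape, bool)
        lo = np.maximum(centre - 4, 0)
        hi = centre + 4
        region[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        region &= m.grid > 0
        sham.append(anomaly_contrast(r, region, (m.grid > 0) & ~region))

    return {
        "cae": cae,
        "cae_config": cfg,
        "loss_history": history,
        "contrasts": contrasts,
        "median_contrast": float(np.median(contrasts)),
        "sham_contrasts": sham,
        "sham_median": float(np.median(sham)),
    }


def _fused_sample(sp: PhantomSpec, cae, cfg: CAEConfig, variant: str = "full",
                  with_anomaly: bool = False):
    s = generate_phantom(sp)
    if with_anomaly:
        v, m, a = prepare_cae_input(s.volume, s.labels, cfg, s.anomaly_mask)
    else:
        v, m = prepare_cae_input(s.volume, s.labels, cfg)
        a = None
    _, r, _ = residual_map(cae, v)
    f = assemble_input(v, m, r, variant)
    return f, pretext_targets(m, r), m, a


def desk_fusion_experiment(seed: int, cae, cae_cfg: CAEConfig,
                           n_cohort: int = 24, n_test: int = 16,
                           epochs: int = 40, n_strength: int = 8) -> dict:
    """Train the three-channel extractor; measure embedding separation,
    residual-channel sensitivity and Grad-CAM localization."""
    from sklearn.metrics import silhouette_score

    base = PhantomSpec()
    s_gen = stage_seed(seed, "phantoms")
    s_train = stage_seed(seed, "fusion")

    specs = cohort_specs(n_cohort, base, 0.5, seed=s_gen + 5)
    data = [_fused_sample(sp, cae, cae_cfg) for sp in specs]
    model = build_extractor(seed=s_train)
    model, history = train_extractor_checked(model, data, epochs, s_train)

    embs = np.stack([embed(model, f).values for f, _, _, _ in data])
    groups = np.array([0 if sp.anomaly == "none" else 1 for sp in specs])
    silhouette = float(silhouette_score(embs, groups))

    # channel ablation: zeroing the residual channel must displace embeddings
    disp = []
    for f, _, _, _ in data:
        from .fusion import FusedInput
        f0 = FusedInput(f.channels.copy(), f.spacing_mm)
        f0.channels[2] = 0.0
        disp.append(float(np.linalg.norm(
            embed(model, f).values - embed(model, f0).values)))

    fracs, enrich = [], []
    for sp in cohort_specs(n_test, base, 0.5, seed=s_gen + 6):
        f, _, m, _ = _fused_sample(sp, cae, cae_cfg)
        cam = grad_cam(model, f)
        union = m.grid > 0
        frac = cam_mass_fraction(cam, union)
        fracs.append(frac)
        enrich.append(frac / float(union.mean()))

    def _strength_cam(strength: float) -> float:
        vals = []
        for sp in cohort_specs(n_strength, base, 1.0, seed=s_gen + 7,
                               anomaly_strength_range=(strength, strength)):
            f, _, _, a = _fused_sample(sp, cae, cae_cfg, with_anomaly=True)
            if (a > 0).any():
                cam = grad_cam(model, f)
                vals.append(float(cam.grid[a > 0].mean()))
        return float(np.mean(vals))

    cam_strong = _strength_cam(1.0)
    cam_weak = _strength_cam(0.3)

    return {
        "extractor": model,
        "loss_history": history,
        "embeddings": embs,
        "groups": groups,
        "silhouette": silhouette,
        "residual_ablation_displacement": float(np.mean(disp)),
        "cam_mass_fractions": fracs,
        "median_cam_mass_fraction": float(np.median(fracs)),
        "median_cam_enrichment": float(np.median(enrich)),
        "cam_in_anomaly_strong": cam_strong,
        "cam_in_anomaly_weak": cam_weak,
    }


def train_extractor_checked(model, data, epochs: int, seed: int):
    from .fusion import train_extractor

    return train_extractor(model, [(f, t) for f, t, _, _ in data],
                           ExtractorTrainOpts(epochs=epochs, seed=seed))


# ---------------------------------------------------------------------------
# full pipeline into a run directory
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    out_dir: str
    profile: str = "desk"          # desk | reference
    seed: int = 0
    n_train: int = 32
    n_test: int = 8
    seg_epochs: int = 30
    cae_epochs: int = 60
    fusion_epochs: int = 40
    n_fusion_cohort: int = 24
    n_cae_train: int = 16
    n_cae_test: int = 16
    n_fusion_test: int = 16
    seg_config: SegConfig | None = None
    cae_config: CAEConfig | None = None

    def resolve(self) -> None:
        if self.profile not in ("desk", "reference"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.seg_config is None:
            self.seg_config = desk_seg_config() if self.profile == "desk" \
                else SegConfig()
        if self.cae_config is None:
            self.cae_config = desk_cae_config() if self.profile == "desk" \
                else CAEConfig()
        parent = Path(self.out_dir).parent
        if not parent.exists():
            raise ValueError(f"output parent directory {parent} does not exist")


def _cfg_hash(cfg: RunConfig) -> str:
    enc = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(enc.encode()).hexdigest()[:16]


def _array_hash(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:12]


class _StageLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def record(self, stage: str, t0: float, **info):
        row = {"stage": stage, "wall_s": round(time.time() - t0, 3), **info}
        with open(self.path, "a") as fh:
            fh.write(json.dumps(row) + "\n")


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full desk workflow; returns the run directory.

    Stages: generate -> preprocess -> segment -> residual -> embed ->
    explain -> evaluate.  Each stage consumes the previous stage's outputs;
    any failure aborts with the stage name and sample id.
    """
    cfg.resolve()
    run_dir = Path(cfg.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    log = _StageLog(run_dir / "stages.jsonl")
    provenance = {"config_hash": _cfg_hash(cfg), "seed": cfg.seed,
                  "config": dataclasses.asdict(cfg)}
    (run_dir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str))

    stage = "generate"
    sample_id = "-"
    try:
        # generate + segment
        t0 = time.time()
        seg = desk_segmentation_experiment(cfg.seed, cfg.n_train, cfg.n_test,
                                           cfg.seg_epochs)
        log.record("segment", t0, mean_dice=seg["mean_dice"],
                   mean_hd95_mm=seg["mean_hd95_mm"],
                   final_loss=seg["loss_history"][-1])

        stage = "residual"
        t0 = time.time()
        cae_res = desk_anomaly_experiment(cfg.seed, n_train=cfg.n_cae_train,
                                          n_test=cfg.n_cae_test,
                                          epochs=cfg.cae_epochs)
        log.record("residual", t0, median_contrast=cae_res["median_contrast"],
                   sham_median=cae_res["sham_median"])

        stage = "embed/explain"
        t0 = time.time()
        fus = desk_fusion_experiment(cfg.seed, cae_res["cae"],
                                     cae_res["cae_config"],
                                     n_cohort=cfg.n_fusion_cohort,
                                     n_test=cfg.n_fusion_test,
                                     epochs=cfg.fusion_epochs)
        log.record("embed_explain", t0, silhouette=fus["silhouette"],
                   median_cam_enrichment=fus["median_cam_enrichment"])

        stage = "write-artifacts"
        t0 = time.time()
        # masks + residual + CAM for a small illustrative cohort
        base = PhantomSpec(grid_shape=(48, 48, 48))
        art_dir = run_dir / "artifacts"
        art_dir.mkdir(exist_ok=True)
        rows = []
        for i, sp in enumerate(cohort_specs(4, base, 0.5,
                                            seed=stage_seed(cfg.seed, "eval"))):
            sample_id = f"sample_{i:03d}"
            s = generate_phantom(sp)
            v = _norm(s.volume)
            pred = predict_mask(seg["model"], v)
            sio.write_mask(pred.labels, art_dir / f"{sample_id}_pred.nii.gz")
            cv, cm, ca = prepare_cae_input(
                s.volume, s.labels, cae_res["cae_config"], s.anomaly_mask)
            _, r, _ = residual_map(cae_res["cae"], cv)
            sio.write_volume(Volume(r.grid, cv.spacing_mm, "normalized"),
                             art_dir / f"{sample_id}_residual.nii.gz")
            f = assemble_input(cv, cm, r)
            cam = grad_cam(fus["extractor"], f)
            sio.write_volume(Volume(cam.grid, cv.spacing_mm, "normalized"),
                             art_dir / f"{sample_id}_cam.nii.gz")
            emb = embed(fus["extractor"], f)
            rows.append({"sample_id": sample_id, "anomaly": sp.anomaly,
                         "volume_hash": _array_hash(s.volume.grid),
                         "pred_hash": _array_hash(pred.labels.grid),
                         **{f"emb_{j}": float(x)
                            for j, x in enumerate(emb.values[:8])}})
        import pandas as pd
        pd.DataFrame(rows).to_csv(run_dir / "embeddings.tsv", sep="\t",
                                  index=False)
        log.record("write-artifacts", t0, n=len(rows))

        stage = "evaluate"
        t0 = time.time()
        table = aggregate_reports(seg["reports"])
        table.to_csv(run_dir / "eval_report.tsv", sep="\t", index=False)
        summary = {
            "mean_dice": seg["mean_dice"],
            "mean_hd95_mm": seg["mean_hd95_mm"],
            "median_anomaly_contrast": cae_res["median_contrast"],
            "sham_contrast_median": cae_res["sham_median"],
            "embedding_silhouette": fus["silhouette"],
            "median_cam_enrichment": fus["median_cam_enrichment"],
        }
        (run_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        log.record("evaluate", t0, **summary)
    except Exception as e:
        raise RuntimeError(
            f"pipeline stage {stage!r} failed on sample {sample_id!r}: {e}"
        ) from e
    return run_dir


__all__ = [
    "RunConfig", "run_pipeline", "stage_seed",
    "desk_segmentation_experiment", "desk_anomaly_experiment",
    "desk_fusion_experiment",
]
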