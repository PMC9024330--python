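"""End-to-end orchestration: simulate -> fuse -> train -> predict ->
evaluate -> grade, all from one PipelineConfig and one seed.

Each stage reads/writes plain files under the run directory with the
manifest CSV as the contract between stages, so every stage is also usable
on its own. Re-running with the same config is bit-identical on CPU.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from . import fusion, grading, metrics, synthetic, training
from .config import PipelineConfig, save_config
from .model import build_model, save_checkpoint

log = logging.getLogger("pspgleason")

__all__ = ["run_pipeline", "load_annotation_set", "fuse_manifest"]


def _read_mask(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing mask file: {path}")
    return np.asarray(Image.open(path), dtype=np.int64)


def _read_image(path: Path) -> np.ndarray:
    if not path.exists():
        raise FileNotFoundError(f"missing image file: {path}")
    return np.asarray(Image.open(path).convert("RGB"), dtype=np.float64) / 255.0


def load_annotation_set(manifest: pd.DataFrame, image_id: str, root: Path) -> fusion.AnnotationSet:
    """Build one image's AnnotationSet from the manifest rows."""
    rows = manifest[manifest.image_id == image_id]
    if rows.empty:
        raise KeyError(f"image {image_id!r} not in manifest")
    masks = {r.rater_id: _read_mask(root / r.mask_path) for r in rows.itertuples()}
    seniority = {r.rater_id: int(r.seniority_rank) for r in rows.itertuples()}
    return fusion.AnnotationSet(image_id, masks, seniority)


def fuse_manifest(manifest: pd.DataFrame, root: Path, out_dir: Path, method: str = "staple",
                  tol: float = 1e-6, max_iter: int = 100) -> dict[str, Path]:
    """Fuse every image in the manifest; returns image_id -> fused path."""
    out_dir.mkdir(parents=True, exist_ok=True)
    fused_paths = {}
    for image_id in sorted(manifest.image_id.unique()):
        ann = load_annotation_set(manifest, image_id, root)
        if method == "staple":
            hard = fusion.staple_multiclass(ann, tol=tol, max_iter=max_iter).hard_mask
        elif method == "vote":
            hard = fusion.majority_vote(ann)
        else:
            raise ValueError(f"unknown fusion method {method!r}")
        p = out_dir / f"{image_id}.png"
        Image.fromarray(hard.astype(np.uint8)).save(p)
        fused_paths[image_id] = p
    return fused_paths


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run every stage in order; returns the artifacts directory.

    Artifacts: data/ (synthetic images, truth, rater masks, manifest),
    fused/ (STAPLE consensus masks), model.ckpt + log.csv, pred/ masks for
    the held-out fold, report.json (mean evaluation metrics vs the fused
    reference and vs the simulation truth), grades.csv and confusion.csv.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_config(cfg, out / "config.yaml")
    cfg_hash = hashlib.sha256((out / "config.yaml").read_bytes()).hexdigest()[:12]
    fh = logging.FileHandler(out / "run.log", mode="w")
    log.addHandler(fh)
    log.setLevel(logging.INFO)
    log.info("pipeline start: profile=%s seed=%d config=%s", cfg.profile, cfg.seed, cfg_hash)
    try:
        return _run_stages(cfg, out)
    except Exception as exc:                       # surface the failing stage
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_stages(cfg: PipelineConfig, out: Path) -> Path:
    data_dir = out / "data"
    log.info("stage simulate: %d cores of %d px", cfg.n_cores, cfg.image_size)
    profiles = synthetic.default_rater_profiles()
    manifest = synthetic.generate_dataset(cfg.n_cores, profiles, data_dir,
                                          seed=cfg.seed, image_size=cfg.image_size)

    log.info("stage fuse: STAPLE over %d images", manifest.image_id.nunique())
    fused = fuse_manifest(manifest, data_dir, out / "fused",
                          tol=cfg.fusion_tol, max_iter=cfg.fusion_max_iter)

    ids = sorted(fused)
    plan = training.make_folds(ids, k=cfg.k_folds, seed=cfg.seed)
    val_ids = set(plan.fold_ids(0))
    pairs = {i: (_read_image(data_dir / "images" / f"{i}.png"), _read_mask(fused[i]))
             for i in ids}
    train_set = [pairs[i] for i in ids if i not in val_ids]
    val_set = [pairs[i] for i in ids if i in val_ids] or train_set

    log.info("stage train: %d train / %d val images, %d epochs",
             len(train_set), len(val_set), cfg.epochs)
    model = build_model(cfg.model, seed=cfg.seed)
    sched = training.TrainingSchedule(cfg.schedule.eta0, cfg.epochs, cfg.schedule.beta)
    tlog, best_state = training.train(
        model, train_set, schedule=sched, loss_cfg=cfg.loss, epochs=cfg.epochs,
        batch_size=cfg.batch_size, seed=cfg.seed, val_dataset=val_set,
        short_side=cfg.short_side, crop=cfg.crop)
    model.load_state_dict(best_state)
    tlog.to_csv(out / "log.csv", index=False)
    save_checkpoint(model, out / "model.ckpt")

    log.info("stage predict+evaluate+grade: %d held-out images", len(val_ids))
    pred_dir = out / "pred"
    pred_dir.mkdir(exist_ok=True)
    reports_fused, reports_truth = [], []
    pred_grades, true_grades = [], []
    for i in sorted(val_ids) or ids:
        img = _read_image(data_dir / "images" / f"{i}.png")
        pred = model.predict(img)
        truth = _read_mask(data_dir / "truth" / f"{i}.png")
        pred[truth == synthetic.IGNORE_LABEL] = synthetic.IGNORE_LABEL
        Image.fromarray(pred.astype(np.uint8)).save(pred_dir / f"{i}.png")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reports_fused.append(metrics.evaluate_masks(pred, _read_mask(fused[i])))
            reports_truth.append(metrics.evaluate_masks(pred, truth))
        pred_grades.append(grading.core_grade(pred))
        true_grades.append(grading.core_grade(truth))

    def _mean(reports, attr):
        vals = [getattr(r, attr) for r in reports]
        return float(np.mean([v for v in vals if np.isfinite(v)]))

    report = {
        "n_val_images": len(reports_fused),
        "vs_fused": {k: _mean(reports_fused, k)
                     for k in ("mean_dsc", "kappa", "f1_macro", "f1_micro", "combined")},
        "vs_truth": {k: _mean(reports_truth, k)
                     for k in ("mean_dsc", "kappa", "f1_macro", "f1_micro", "combined")},
        "final_train_loss": float(tlog.L.iloc[-1]),
    }
    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))

    rows = []
    for i, g in zip(sorted(val_ids) or ids, pred_grades):
        bm, risk = grading.dichotomize(g)
        rows.append({"image_id": i, "majority": g.majority_class, "primary": g.primary,
                     "secondary": g.secondary, "malignant": bm == "malignant",
                     "high_risk": risk == "high_risk"})
    pd.DataFrame(rows).to_csv(out / "grades.csv", index=False)
    grading.core_confusion(pred_grades, true_grades).to_csv(out / "confusion.csv")
    log.info("pipeline done: %s", out)
    return out
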