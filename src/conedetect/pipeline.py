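"""End-to-end workflow stages: train -> tune -> detect -> evaluate.

Each stage reads/writes plain files under an output directory so the
expensive artifacts (trained weights, per-image probability maps) are
computed once and reused; a manifest records the configuration, seeds and
stage outputs so any stage can be reproduced bit-for-bit.

Dataset directory convention: one grayscale image per cone ROI
(``<stem>.tif`` or ``<stem>.png``) with its coordinate CSV ``<stem>.csv``
(header ``x,y``) alongside.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as cio
from .cnn import ConeCNN, TrainingConfig, build_network, train_network
from .metrics import (DEFAULT_BORDER_PX, bland_altman, compute_metrics,
                      cone_density, match_cones, match_radius)
from .preprocess import build_training_set, normalize_intensity
from .probmap import DetectionParams, ProbabilityMap, compute_probability_map, detect_cones
from .tuning import ParamGrid, default_grid, optimize_params

__all__ = [
    "RunConfig",
    "PipelineError",
    "load_dataset",
    "run_train",
    "run_tune",
    "run_detect",
    "run_evaluate",
    "run_all",
]

log = logging.getLogger("conedetect")


class PipelineError(RuntimeError):
    """A stage prerequisite is missing; the message names the stage to run."""


@dataclass
class RunConfig:
    train_dir: Path
    val_dir: Path
    out_dir: Path
    modality: str = "unknown"
    scale: float | None = None  # microns per pixel for density metrics
    training: TrainingConfig = field(default_factory=TrainingConfig)
    grid: ParamGrid = field(default_factory=default_grid)
    n_tune_images: int | None = None  # None = all training images
    border_px: float = DEFAULT_BORDER_PX

    def to_dict(self) -> dict:
        return {
            "train_dir": str(self.train_dir),
            "val_dir": str(self.val_dir),
            "out_dir": str(self.out_dir),
            "modality": self.modality,
            "scale": self.scale,
            "training": self.training.to_dict(),
            "grid": self.grid.to_dict(),
            "n_tune_images": self.n_tune_images,
            "border_px": self.border_px,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            train_dir=Path(d["train_dir"]),
            val_dir=Path(d["val_dir"]),
            out_dir=Path(d["out_dir"]),
            modality=d.get("modality", "unknown"),
            scale=d.get("scale"),
            training=TrainingConfig.from_dict(d.get("training", {})),
            grid=ParamGrid.from_dict(d["grid"]) if "grid" in d else default_grid(),
            n_tune_images=d.get("n_tune_images"),
            border_px=d.get("border_px", DEFAULT_BORDER_PX),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def load_dataset(directory: str | Path, scale: float | None = None,
                 modality: str = "unknown"):
    """(ids, images, marks) for every image/CSV pair in a dataset directory."""
    directory = Path(directory)
    if not directory.is_dir():
        raise FileNotFoundError(f"dataset directory {directory} does not exist")
    stems = sorted(
        p.stem for p in directory.iterdir()
        if p.suffix.lower() in (".tif", ".tiff", ".png")
    )
    ids, images, marks = [], [], []
    for stem in stems:
        img_path = next(p for p in directory.iterdir()
                        if p.stem == stem and p.suffix.lower() in (".tif", ".tiff", ".png"))
        csv_path = directory / f"{stem}.csv"
        if not csv_path.exists():
            continue
        img = cio.load_image(img_path, scale=scale, modality_tag=modality)
        ids.append(stem)
        images.append(img)
        marks.append(cio.load_coordinates(csv_path, source="manual",
                                          image_dims=(img.height, img.width)))
    if not ids:
        raise FileNotFoundError(f"no image/CSV pairs found in {directory}")
    return ids, images, marks


def _update_manifest(out_dir: Path, stage: str, payload: dict) -> None:
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = payload
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def run_train(config: RunConfig) -> Path:
    """Extract patches, train the CNN, save the model bundle. Returns its path."""
    config.out_dir.mkdir(parents=True, exist_ok=True)
    ids, images, marks = load_dataset(config.train_dir, config.scale, config.modality)
    patchset = build_training_set(images, marks, rng_seed=config.training.seed,
                                  image_ids=ids)
    log.info("training set: %d cone / %d non-cone patches from %d images",
             patchset.n_cone, patchset.n_noncone, len(ids))
    net = build_network(seed=config.training.seed, init_std=config.training.init_std)
    history = train_network(net, patchset.patches, patchset.labels, config.training,
                            log=lambda rec: log.info("epoch %(epoch)d loss %(mean_loss).4f "
                                                     "acc %(train_accuracy).4f", rec))
    bundle = cio.ModelBundle(
        arrays=net.state_arrays(),
        meta={
            "architecture": "cone-cnn-17",
            "normalization": cio.ModelBundle.NORMALIZATION_ID,
            "modality": config.modality,
            "class_order": ["noncone", "cone"],
            "training_config": config.training.to_dict(),
            "detection_params": None,
            "final_train_accuracy": history[-1]["train_accuracy"],
        },
    )
    model_dir = config.out_dir / "model"
    cio.save_model(bundle, model_dir)
    _update_manifest(config.out_dir, "train", {
        "config_hash": config.config_hash(), "model_dir": str(model_dir),
        "n_patches": len(patchset), "n_cone": patchset.n_cone,
        "epochs": config.training.epochs, "seed": config.training.seed,
    })
    return model_dir


def _load_net(config: RunConfig) -> tuple[ConeCNN, cio.ModelBundle, Path]:
    model_dir = config.out_dir / "model"
    if not (model_dir / "weights.npz").exists():
        raise PipelineError("no trained model found; run the 'train' stage first")
    bundle = cio.load_model(model_dir)
    net = build_network(seed=0)
    net.load_state_arrays(bundle.arrays)
    return net, bundle, model_dir


def _probmap_cache_dir(config: RunConfig) -> Path:
    return config.out_dir / "probmaps"


def _probability_map_cached(net: ConeCNN, image, stem: str, cache_dir: Path) -> ProbabilityMap:
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{stem}.npz"
    if path.exists():
        return ProbabilityMap(np.load(path)["values"])
    pm = compute_probability_map(net, normalize_intensity(image))
    np.savez_compressed(path, values=pm.values)
    return pm


def run_tune(config: RunConfig) -> DetectionParams:
    """Select (sigma, H, T) by mean-Dice grid search on training images."""
    net, bundle, model_dir = _load_net(config)
    ids, images, marks = load_dataset(config.train_dir, config.scale, config.modality)
    if config.n_tune_images is not None:
        ids = ids[:config.n_tune_images]
        images = images[:config.n_tune_images]
        marks = marks[:config.n_tune_images]
    cache = _probmap_cache_dir(config)
    probmaps = [_probability_map_cached(net, im, f"train_{stem}", cache)
                for stem, im in zip(ids, images)]
    result = optimize_params(probmaps, marks, config.grid, border=config.border_px)
    log.info("tuned params sigma=%.2f H=%.2f T=%.2f (mean Dice %.4f on %d images)",
             *result.params.astuple(), result.mean_dice, len(ids))
    bundle.meta["detection_params"] = {
        "sigma": result.params.sigma, "h": result.params.h, "t": result.params.t,
        "mean_dice_train": result.mean_dice,
    }
    cio.save_model(bundle, model_dir)
    result.scores.to_csv(config.out_dir / "tuning_scores.csv", index=False)
    _update_manifest(config.out_dir, "tune", {
        "config_hash": config.config_hash(),
        "params": bundle.meta["detection_params"], "n_tune_images": len(ids),
    })
    return result.params


def _detection_params(bundle: cio.ModelBundle) -> DetectionParams:
    meta = bundle.meta.get("detection_params")
    if meta is None:
        raise PipelineError("model bundle has no detection parameters; "
                            "run the 'tune' stage first")
    return DetectionParams(meta["sigma"], meta["h"], meta["t"])


def run_detect(config: RunConfig) -> Path:
    """Detect cones in every validation image; writes one CSV per image."""
    net, bundle, _ = _load_net(config)
    params = _detection_params(bundle)
    ids, images, _ = load_dataset(config.val_dir, config.scale, config.modality)
    out = config.out_dir / "detections"
    out.mkdir(parents=True, exist_ok=True)
    cache = _probmap_cache_dir(config)
    for stem, image in zip(ids, images):
        pm = _probability_map_cached(net, image, f"val_{stem}", cache)
        cones = detect_cones(image, net, params, pmap=pm)
        cio.save_coordinates(cones, out / f"{stem}.csv")
        log.info("detected %d cones in %s", len(cones), stem)
    _update_manifest(config.out_dir, "detect", {
        "config_hash": config.config_hash(), "detections_dir": str(out),
        "params": bundle.meta["detection_params"], "n_images": len(ids),
    })
    return out


def run_evaluate(config: RunConfig) -> pd.DataFrame:
    """Match detections to manual marks; per-image metrics + summary."""
    det_dir = config.out_dir / "detections"
    if not det_dir.is_dir():
        raise PipelineError("no detections found; run the 'detect' stage first")
    ids, images, marks = load_dataset(config.val_dir, config.scale, config.modality)
    rows = []
    for stem, image, manual in zip(ids, images, marks):
        det_path = det_dir / f"{stem}.csv"
        if not det_path.exists():
            raise PipelineError(f"missing detection CSV for {stem}; rerun 'detect'")
        auto = cio.load_coordinates(det_path, source="automatic")
        d = match_radius(manual)
        match = match_cones(auto, manual, d, (image.height, image.width),
                            config.border_px)
        rec = compute_metrics(match)
        row = {
            "image": stem, "n_manual": match.n_manual, "n_automatic": match.n_automatic,
            "n_tp": match.n_tp, "n_fp": match.n_fp, "n_fn": match.n_fn,
            "match_radius_px": d, "true_positive_rate": rec.true_positive_rate,
            "false_discovery_rate": rec.false_discovery_rate, "dice": rec.dice,
        }
        if image.scale is not None:
            row["manual_density_mm2"] = cone_density(manual, image)
            row["auto_density_mm2"] = cone_density(auto, image)
        rows.append(row)
    table = pd.DataFrame(rows)
    table.to_csv(config.out_dir / "metrics.csv", index=False)

    summary: dict = {}
    for col in ("true_positive_rate", "false_discovery_rate", "dice"):
        v = table[col].dropna()
        summary[col] = {"mean": float(v.mean()), "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                        "median": float(v.median())}
    if "manual_density_mm2" in table:
        diffs = (table["manual_density_mm2"] - table["auto_density_mm2"]).to_numpy()
        if len(diffs) >= 2:
            ba = bland_altman(diffs)
            summary["bland_altman_density"] = {
                "mean_difference": ba.mean_difference, "lower_limit": ba.lower_limit,
                "upper_limit": ba.upper_limit, "sd": ba.sd, "n": ba.n,
            }
    (config.out_dir / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n")
    _update_manifest(config.out_dir, "evaluate", {
        "config_hash": config.config_hash(), "summary": summary, "n_images": len(ids),
    })
    return table


def run_all(config: RunConfig) -> pd.DataFrame:
    run_train(config)
    run_tune(config)
    run_detect(config)
    return run_evaluate(config)
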