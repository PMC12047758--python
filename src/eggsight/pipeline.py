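"""End-to-end run orchestration: simulate -> preprocess -> balance ->
train -> explain -> quantify, with every stage talking to the next only
through files (manifests, PNGs, CSV/JSON) under one run directory.

Each run is stamped with the config hash and seed; reruns with the same
config and seed reproduce the manifests and tables byte-for-byte where the
stages are deterministic.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .augment import balance_dataset, build_policy
from .classify import (TrainConfig, build_model, evaluate, images_to_array,
                       predict, split_dataset, train)
from .gradcam import (aggregate_heatmaps, gradcam, major_impact_region,
                      overlay, save_heatmap, tiled_aggregate_figure)
from .preprocess import (boundary_band, default_band_radius, segment_egg,
                         standardize)
from .regions import (AttributionConfig, build_impact_table,
                      segment_pigmentation)
from .synthetic import DatasetConfig, default_profiles, generate_dataset

log = logging.getLogger("eggsight")

__all__ = ["RunConfig", "run_pipeline"]

_REQUIRED = ("seed", "out_dir")


@dataclass
class RunConfig:
    seed: int
    out_dir: str
    counts: list[int] = field(default_factory=lambda: [130, 21, 38, 34])
    canvas: int = 128
    image_size: int = 64
    clutch_size: int = 5
    augmentation: str = "heavy"
    balance_target: int | None = 60
    width_scale: float = 0.25
    learning_rate: float = 0.02
    epochs: int = 12
    batch_size: int = 8
    split_fractions: tuple[float, float, float] = (0.5, 0.2, 0.3)
    gradcam_blocks: tuple[int, ...] = (4, 5)
    n_explain_per_class: int = 2
    superpixel_size: int = 8
    n_permutations: int = 8
    verbosity: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        missing = [k for k in _REQUIRED if k not in raw]
        if missing:
            raise ValueError(f"config missing required field(s): {missing}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        if "split_fractions" in raw:
            raw["split_fractions"] = tuple(raw["split_fractions"])
        if "gradcam_blocks" in raw:
            raw["gradcam_blocks"] = tuple(raw["gradcam_blocks"])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _load_manifest_images(manifest: pd.DataFrame) -> list[np.ndarray]:
    return [iio.imread(p).astype(np.float64) / 255.0 for p in manifest["path"]]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in dependency order; returns the run summary."""
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    summary: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": {},
    }

    def stage(name):
        log.info("stage=%s t=%.1fs", name, time.time() - t0)
        summary["stages"][name] = {"t_start": round(time.time() - t0, 2)}

    # -- simulate ----------------------------------------------------------
    stage("simulate")
    profiles = default_profiles()[: len(config.counts)]
    if len(profiles) < 2:
        raise ValueError("need counts for at least 2 species")
    ds_cfg = DatasetConfig(profiles=profiles, counts=list(config.counts),
                           out_dir=out / "data", clutch_size=config.clutch_size,
                           canvas=config.canvas,
                           seed=int(rng.integers(2 ** 31)))
    manifest = generate_dataset(ds_cfg)
    summary["stages"]["simulate"]["n_images"] = len(manifest)

    # -- preprocess --------------------------------------------------------
    stage("preprocess")
    std_dir = out / "standardized"
    (std_dir / "images").mkdir(parents=True, exist_ok=True)
    (std_dir / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for _, row in manifest.iterrows():
        photo = iio.imread(row["path"]).astype(np.float64) / 255.0
        mask = segment_egg(photo)
        egg = standardize(photo, mask, size=config.image_size,
                          species=row["species"], clutch_id=row["clutch_id"])
        img_path = std_dir / "images" / f"{row['egg_id']}.png"
        mask_path = std_dir / "masks" / f"{row['egg_id']}.png"
        iio.imwrite(img_path, (egg.image * 255).round().astype(np.uint8))
        iio.imwrite(mask_path, (egg.egg_mask * 255).astype(np.uint8))
        rows.append({**row, "path": str(img_path), "mask_path": str(mask_path),
                     "blunt_end_up": egg.blunt_end_up,
                     "size": config.image_size})
    std_manifest = pd.DataFrame(rows)
    std_manifest.to_csv(std_dir / "manifest.csv", index=False)

    # -- split + balance ---------------------------------------------------
    stage("balance")
    tr, va, te = split_dataset(std_manifest, config.split_fractions, rng)
    policy = build_policy(config.augmentation)
    if config.balance_target:
        tr = balance_dataset(tr, policy, config.balance_target, rng)
    for name, part in (("train", tr), ("val", va), ("test", te)):
        part.to_csv(out / f"manifest_{name}.csv", index=False)
    summary["stages"]["balance"]["train_rows"] = len(tr)

    # -- train -------------------------------------------------------------
    stage("train")
    labels = sorted(std_manifest["species"].unique())
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    from .augment import apply_policy

    def load_part(part, augment_rows=False):
        imgs, ys = [], []
        for _, row in part.iterrows():
            src = row["path"]
            if augment_rows and row.get("augmented", 0) == 1:
                src = str(std_dir / "images" / f"{row['source_egg_id']}.png")
            arr = iio.imread(src).astype(np.float64) / 255.0
            if augment_rows and row.get("augmented", 0) == 1:
                arr, _ = apply_policy(arr, None, policy,
                                      np.random.default_rng(int(row["aug_seed"])))
            imgs.append(arr)
            ys.append(lab_idx[row["species"]])
        return images_to_array(imgs), np.array(ys)

    x_tr, y_tr = load_part(tr, augment_rows=True)
    x_va, y_va = load_part(va)
    x_te, y_te = load_part(te)
    tc = TrainConfig(learning_rate=config.learning_rate, batch_size=config.batch_size,
                     input_size=config.image_size, epochs=config.epochs,
                     width_scale=config.width_scale, seed=config.seed,
                     early_stop_val_acc=0.995,
                     split_fractions=config.split_fractions)
    model = build_model(config.image_size, len(labels), config.width_scale,
                        seed=config.seed)
    model.class_labels = labels
    history = train(model, x_tr, y_tr, x_va, y_va, tc, rng=rng)
    pd.DataFrame(history).to_csv(out / "history.csv", index=False)
    model.save(out / "weights.npz")

    probs = predict(model, x_te)
    cm, report = evaluate(y_te, probs.argmax(axis=1), labels)
    cm.to_frame().to_csv(out / "confusion_matrix.csv")
    metrics = {
        "accuracy": report.accuracy,
        "macro_precision": report.macro_precision,
        "macro_recall": report.macro_recall,
        "macro_f1": report.macro_f1,
        "per_class_f1": report.f1,
    }
    with open(out / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2)
    summary["stages"]["train"].update(metrics=metrics, epochs_run=len(history))

    # -- explain (Grad-CAM) ------------------------------------------------
    stage("explain")
    correct = probs.argmax(axis=1) == y_te
    cam_dir = out / "gradcam"
    cam_dir.mkdir(exist_ok=True)
    test_imgs = _load_manifest_images(te)
    aggregates = {}
    for ci, lab in enumerate(labels):
        sel = np.nonzero(correct & (y_te == ci))[0][: 8]
        if sel.size == 0:
            continue
        for block in config.gradcam_blocks:
            maps = [gradcam(model, x_te[i], ci, block) for i in sel]
            agg = aggregate_heatmaps(maps)
            aggregates[(lab, block)] = agg
            mask, contours = major_impact_region(agg)
            vis = overlay(test_imgs[sel[0]], agg, alpha=0.5, contours=contours)
            iio.imwrite(cam_dir / f"{lab}_block{block}_overlay.png",
                        (vis * 255).round().astype(np.uint8))
            save_heatmap(agg, cam_dir / f"{lab}_block{block}")
    if aggregates:
        tiled_aggregate_figure(aggregates, cam_dir / "aggregate_grid.png")

    # -- quantify (Shapley impact table) -----------------------------------
    stage("quantify")
    att_cfg = AttributionConfig(superpixel_size=config.superpixel_size,
                                n_permutations=config.n_permutations,
                                seed=config.seed)
    chosen: list[int] = []
    for ci in range(len(labels)):
        sel = np.nonzero(correct & (y_te == ci))[0][: config.n_explain_per_class]
        chosen.extend(sel.tolist())
    if chosen:
        band_r = default_band_radius(config.image_size)
        region_sets, imgs, ys = [], [], []
        for i in chosen:
            egg_mask = iio.imread(te.iloc[i]["mask_path"]) > 127
            rs = segment_pigmentation(test_imgs[i], egg_mask, seed=config.seed)
            rs.edge_mask = boundary_band(egg_mask, band_r)
            region_sets.append(rs)
            imgs.append(x_te[i])
            ys.append(y_te[i])
        baseline_idx = rng.choice(len(x_te), size=min(4, len(x_te)), replace=False)
        table = build_impact_table(model, imgs, ys, region_sets,
                                   [x_te[i] for i in baseline_idx],
                                   att_cfg, class_labels=labels)
        table.to_frame().to_csv(out / "impact_table.csv")
        with open(out / "impact_table.json", "w") as fh:
            json.dump({"q2": table.q2.to_dict(), "q3": table.q3.to_dict(),
                       "mean_positive": table.mean_positive.to_dict(),
                       "n_images": table.n_images}, fh, indent=2)

    summary["runtime_s"] = round(time.time() - t0, 2)
    with open(out / "run_summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    return summary
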