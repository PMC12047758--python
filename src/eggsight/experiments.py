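"""Reference desk-scale experiments run end-to-end in memory.

Two canned studies used both by the test suite and by the reproduction
script:

* :func:`desk_classification_experiment` — four well-separated species
  profiles, 200 eggs per class at 64x64, quarter-width network; measures
  test accuracy and per-class metrics.
* :func:`planted_cue_experiment` — four classes differing from a common
  baseline by exactly one planted cue (dark-spot ring / background hue /
  outline shape / none) at 128x128; trains the classifier, then asks the
  explanation stack whether it recovers each cue: the Block-5 aggregated
  Grad-CAM third-quartile mask is compared against the ground-truth ring
  band, and the Shapley impact table's per-class maximal-Q3 region is
  compared against the planted cue.

Problem sizes are chosen so each study finishes in a few minutes on one
CPU while leaving the class structure learnable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .classify import (TrainConfig, build_model, evaluate, images_to_array,
                       predict, split_dataset, train)
from .gradcam import aggregate_heatmaps, gradcam, major_impact_region
from .preprocess import boundary_band, default_band_radius
from .regions import AttributionConfig, build_impact_table, segment_pigmentation
from .synthetic import (SpeciesProfile, generate_clutch, planted_cue_profiles,
                        separable_profiles)

__all__ = [
    "generate_labeled_eggs",
    "desk_classification_experiment",
    "planted_cue_experiment",
]


def generate_labeled_eggs(profiles: list[SpeciesProfile], n_per_class: int,
                          canvas: int, seed: int, clutch_size: int = 5):
    """Generate eggs for each profile; returns (eggs, manifest DataFrame)."""
    rng = np.random.default_rng(seed)
    eggs = []
    for prof in profiles:
        produced = 0
        ci = 0
        while produced < n_per_class:
            n = min(clutch_size, n_per_class - produced)
            eggs.extend(generate_clutch(prof, n, rng, canvas=canvas,
                                        clutch_id=f"{prof.name}-c{ci:03d}"))
            produced += n
            ci += 1
    manifest = pd.DataFrame({
        "species": [e.species for e in eggs],
        "clutch_id": [e.clutch_id for e in eggs],
        "egg_id": np.arange(len(eggs)),
    })
    return eggs, manifest


def _train_on_eggs(eggs, manifest, config: TrainConfig, seed: int,
                   augment: str | None = None):
    """Split by clutch, optionally extend the training set with one
    augmented copy per image, and train the desk-scale network."""
    from .augment import apply_policy, build_policy

    labels = sorted(manifest["species"].unique())
    lab_idx = {lab: i for i, lab in enumerate(labels)}
    x = images_to_array(eggs)
    y = np.array([lab_idx[s] for s in manifest["species"]])
    rng = np.random.default_rng(seed)
    tr, va, te = split_dataset(manifest, config.split_fractions, rng)
    itr = tr["egg_id"].to_numpy()
    iva = va["egg_id"].to_numpy()
    ite = te["egg_id"].to_numpy()
    x_tr, y_tr = x[itr], y[itr]
    if augment:
        policy = build_policy(augment)
        copies = []
        for i in itr:
            img = np.transpose(x[i], (1, 2, 0)).astype(np.float64)
            out, _ = apply_policy(img, None, policy, rng)
            copies.append(np.transpose(out, (2, 0, 1)).astype(np.float32))
        x_tr = np.concatenate([x_tr, np.stack(copies)])
        y_tr = np.concatenate([y_tr, y[itr]])
    model = build_model(config.input_size, len(labels), config.width_scale,
                        seed=seed)
    model.class_labels = labels
    history = train(model, x_tr, y_tr, x[iva], y[iva], config, rng=rng)
    return model, history, x, y, ite, labels


def desk_classification_experiment(seed: int = 0, n_per_class: int = 200,
                                   size: int = 64) -> dict:
    """Train the quarter-width CNN on four separable profiles; returns test
    metrics plus the training history."""
    eggs, manifest = generate_labeled_eggs(separable_profiles(), n_per_class,
                                           canvas=size, seed=seed)
    config = TrainConfig.desk_scale(seed=seed, input_size=size)
    model, history, x, y, ite, labels = _train_on_eggs(eggs, manifest, config, seed)
    probs = predict(model, x[ite])
    cm, report = evaluate(y[ite], probs.argmax(axis=1), labels)
    return {
        "model": model,
        "labels": labels,
        "history": history,
        "confusion": cm,
        "report": report,
        "test_accuracy": report.accuracy,
        "n_train": int(len(x) - len(ite)),
        "n_test": int(len(ite)),
    }


def planted_cue_experiment(seed: int = 0, n_per_class: int = 80,
                           size: int = 128, n_explain_per_class: int = 3,
                           superpixel_size: int = 16,
                           n_permutations: int = 6, epochs: int = 10) -> dict:
    """Train on the planted-cue classes, then measure cue recovery.

    Training uses the medium augmentation tier (one augmented copy per
    training image) so features are translation-consistent rather than
    tied to absolute position — without it the saliency maps inherit the
    centred layout of the renders.  Returns the Block-5 aggregated
    Grad-CAM Q3 mask's IoU with the ground-truth ring band of the
    ring-cue class, and the impact table's argmax-Q3 region per class.
    """
    eggs, manifest = generate_labeled_eggs(planted_cue_profiles(), n_per_class,
                                           canvas=size, seed=seed)
    # a fixed epoch budget (no early stop): the saliency analysis benefits
    # from fully settled features, not just from separable logits
    config = TrainConfig.desk_scale(seed=seed, input_size=size, epochs=epochs,
                                    early_stop_val_acc=None)
    model, history, x, y, ite, labels = _train_on_eggs(eggs, manifest, config,
                                                       seed, augment="medium")
    probs = predict(model, x[ite])
    y_pred = probs.argmax(axis=1)
    _, report = evaluate(y[ite], y_pred, labels)
    correct = y_pred == y[ite]

    # --- Grad-CAM ring recovery (correct test images of the ring class)
    ring_idx = labels.index("ringed")
    sel = ite[correct & (y[ite] == ring_idx)]
    heatmaps = [gradcam(model, x[i], ring_idx, block=5) for i in sel]
    agg = aggregate_heatmaps(heatmaps)
    q3_mask, _ = major_impact_region(agg, 0.75)
    ring_truth = np.mean([eggs[i].ring_mask for i in sel], axis=0) > 0.5
    inter = (q3_mask & ring_truth).sum()
    union = (q3_mask | ring_truth).sum()
    ring_iou = float(inter / union) if union else 0.0

    # sharp-end contrast: the Q3 mask should overlap the ring band more
    # than the sharp-end third of the egg
    sharp_truth = np.zeros_like(ring_truth)
    egg_any = np.mean([eggs[i].egg_mask for i in sel], axis=0) > 0.5
    rows = np.nonzero(egg_any.any(axis=1))[0]
    cut = rows[0] + 2 * (rows[-1] - rows[0]) // 3
    sharp_truth[cut:] = egg_any[cut:]
    sharp_inter = (q3_mask & sharp_truth).sum()
    sharp_union = (q3_mask | sharp_truth).sum()
    sharp_iou = float(sharp_inter / sharp_union) if sharp_union else 0.0

    # --- Shapley impact table on a few correct test images per class
    chosen = []
    for ci in range(len(labels)):
        pool = ite[correct & (y[ite] == ci)][:n_explain_per_class]
        chosen.extend(pool.tolist())
    band_r = default_band_radius(size)
    region_sets = []
    for i in chosen:
        rs = segment_pigmentation(eggs[i].image, eggs[i].egg_mask, seed=seed)
        rs.edge_mask = boundary_band(eggs[i].egg_mask, band_r)
        region_sets.append(rs)
    rng = np.random.default_rng(seed + 1)
    baseline_idx = rng.choice(ite, size=3, replace=False)
    att_cfg = AttributionConfig(superpixel_size=superpixel_size,
                                n_permutations=n_permutations, seed=seed)
    table = build_impact_table(model, [x[i] for i in chosen],
                               y[np.array(chosen)], region_sets,
                               [x[i] for i in baseline_idx], att_cfg,
                               class_labels=labels)
    argmax_regions = {lab: table.argmax_region(lab) for lab in labels}
    cue_expected = {"darkspot": ("Cluster_0",),
                    "hue": ("Cluster_2", "Cluster_3"),
                    "shape": ("Edges",)}
    cue_hits = {lab: argmax_regions[lab] in exp
                for lab, exp in cue_expected.items()}
    return {
        "model": model,
        "labels": labels,
        "history": history,
        "report": report,
        "test_accuracy": report.accuracy,
        "n_ring_images": int(len(sel)),
        "ring_iou": ring_iou,
        "sharp_end_iou": sharp_iou,
        "impact_table": table,
        "argmax_regions": argmax_regions,
        "cue_hits": cue_hits,
        "n_cue_hits": int(sum(cue_hits.values())),
    }
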