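"""Augmentation tiers and dataset balancing.

Three nested augmentation tiers over standardized egg images:

* ``simple`` — vertical/horizontal flips and rotation restricted to 180
  degrees (pure pixel permutations);
* ``medium`` — simple plus free rotation and random sized crops;
* ``heavy`` — medium plus brightness/contrast and gamma perturbations.

Every operator fires independently with probability 0.5.  Geometric
operators are applied identically to the image and its mask; photometric
operators leave the mask untouched.  ``balance_dataset`` equalizes class
counts by undersampling classes above the target and filling classes below
it with augmented copies, so the least populated class receives the most
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import transform

__all__ = [
    "AugmentationPolicy",
    "build_policy",
    "apply_policy",
    "balance_dataset",
    "POLICY_NAMES",
]

POLICY_NAMES = ("none", "simple", "medium", "heavy")

# operator-id -> default parameter ranges
_OPERATOR_PARAMS = {
    "vertical_flip": {},
    "horizontal_flip": {},
    "rotate": {"limit": (0.0, 180.0)},
    "random_sized_crop": {"area": (0.70, 1.00)},
    "brightness_contrast": {"brightness": (-0.2, 0.2), "contrast": (-0.2, 0.2)},
    "gamma": {"gamma": (0.8, 1.25)},
}

# tiers are nested: simple's rotation is restricted to exactly 180 degrees
# (a pure pixel permutation); medium and heavy rotate freely in [0, 180].
_TIERS = {
    "none": [],
    "simple": ["vertical_flip", "horizontal_flip", "rotate"],
    "medium": ["vertical_flip", "horizontal_flip", "rotate",
               "random_sized_crop"],
    "heavy": ["vertical_flip", "horizontal_flip", "rotate",
              "random_sized_crop", "brightness_contrast", "gamma"],
}


@dataclass
class AugmentationPolicy:
    name: str
    operators: list[tuple[str, float, dict]] = field(default_factory=list)

    @property
    def operator_ids(self) -> set[str]:
        return {op for op, _, _ in self.operators}


def build_policy(name: str) -> AugmentationPolicy:
    """Build one of the four named policies (all probabilities 0.5)."""
    if name not in POLICY_NAMES:
        raise ValueError(f"unknown policy {name!r}; valid: {POLICY_NAMES}")
    ops = []
    for op in _TIERS[name]:
        params = dict(_OPERATOR_PARAMS[op])
        if op == "rotate" and name == "simple":
            params["limit"] = (180.0, 180.0)
        ops.append((op, 0.5, params))
    return AugmentationPolicy(name=name, operators=ops)


def _border_color(image: np.ndarray) -> np.ndarray:
    border = np.concatenate([image[0], image[-1], image[:, 0], image[:, -1]])
    return np.median(border, axis=0)


def _apply_operator(op: str, params: dict, image: np.ndarray,
                    mask: np.ndarray | None, rng: np.random.Generator):
    if op == "vertical_flip":
        image = image[::-1].copy()
        mask = None if mask is None else mask[::-1].copy()
    elif op == "horizontal_flip":
        image = image[:, ::-1].copy()
        mask = None if mask is None else mask[:, ::-1].copy()
    elif op == "rotate":
        angle = rng.uniform(*params["limit"]) * rng.choice([-1.0, 1.0])
        if abs(abs(angle) - 180.0) < 1e-9:  # exact half-turn: pure permutation
            image = image[::-1, ::-1].copy()
            mask = None if mask is None else mask[::-1, ::-1].copy()
            return image, mask
        cval = _border_color(image)
        image = np.stack([
            transform.rotate(image[..., c], angle, order=1, mode="constant",
                             cval=cval[c]) for c in range(image.shape[-1])
        ], axis=-1)
        if mask is not None:
            mask = transform.rotate(mask.astype(float), angle, order=0,
                                    mode="constant", cval=0) > 0.5
    elif op == "random_sized_crop":
        s = image.shape[0]
        area = rng.uniform(*params["area"])
        side = max(8, int(round(s * np.sqrt(area))))
        r0 = rng.integers(0, s - side + 1)
        c0 = rng.integers(0, s - side + 1)
        image = transform.resize(image[r0:r0 + side, c0:c0 + side], (s, s, 3),
                                 order=1, anti_aliasing=side > s)
        if mask is not None:
            mask = transform.resize(
                mask[r0:r0 + side, c0:c0 + side].astype(float), (s, s),
                order=0, anti_aliasing=False) > 0.5
    elif op == "brightness_contrast":
        beta = rng.uniform(*params["brightness"])
        alpha = 1.0 + rng.uniform(*params["contrast"])
        image = alpha * (image - 0.5) + 0.5 + beta
    elif op == "gamma":
        g = rng.uniform(*params["gamma"])
        image = np.power(np.clip(image, 0, 1), g)
    else:  # pragma: no cover
        raise ValueError(f"unknown operator {op!r}")
    return image, mask


def apply_policy(image: np.ndarray, mask: np.ndarray | None,
                 policy: AugmentationPolicy, rng: np.random.Generator
                 ) -> tuple[np.ndarray, np.ndarray | None]:
    """Apply a policy draw; returns a new (image, mask) pair.

    Each operator fires independently with its probability; geometric
    operators transform image and mask identically.  Output size equals
    input size and pixel values are clipped to [0, 1].
    """
    image = np.asarray(image, dtype=np.float64)
    for op, p, params in policy.operators:
        if rng.random() < p:
            image, mask = _apply_operator(op, params, image, mask, rng)
    return np.clip(image, 0.0, 1.0), mask


def balance_dataset(manifest: pd.DataFrame, policy: AugmentationPolicy,
                    target_per_class: int, rng: np.random.Generator,
                    class_column: str = "species") -> pd.DataFrame:
    """Equalize class counts at ``target_per_class`` rows per class.

    Classes above the target are undersampled without replacement; classes
    below it keep all original rows and are completed with augmented
    copies, each tagged with ``augmented = 1``, the source egg id, and a
    per-row augmentation seed.  Row provenance is always traceable through
    ``source_egg_id``.
    """
    if target_per_class <= 0:
        raise ValueError("target_per_class must be positive")
    out_frames = []
    for cls, group in manifest.groupby(class_column, sort=True):
        group = group.reset_index(drop=True)
        n = len(group)
        if n >= target_per_class:
            idx = rng.choice(n, size=target_per_class, replace=False)
            sel = group.iloc[np.sort(idx)].copy()
            sel["augmented"] = 0
            sel["source_egg_id"] = sel["egg_id"]
            sel["aug_seed"] = -1
            out_frames.append(sel)
        else:
            orig = group.copy()
            orig["augmented"] = 0
            orig["source_egg_id"] = orig["egg_id"]
            orig["aug_seed"] = -1
            n_extra = target_per_class - n
            src_idx = rng.integers(0, n, size=n_extra)
            extra = group.iloc[src_idx].copy()
            extra["augmented"] = 1
            extra["source_egg_id"] = extra["egg_id"].to_numpy()
            extra["egg_id"] = [
                f"{eid}-aug{j}" for j, eid in enumerate(extra["egg_id"])]
            extra["aug_seed"] = rng.integers(0, 2**31 - 1, size=n_extra)
            out_frames.append(pd.concat([orig, extra], ignore_index=True))
    return pd.concat(out_frames, ignore_index=True)
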