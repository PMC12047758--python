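"""Quantitative attribution analysis over pigmentation regions.

The pipeline mirrors a quantitative reading of Shapley-style saliency:

1. attribute the classifier's output to superpixels with a Shapley
   estimator (exact coalition enumeration for small problems, permutation
   sampling otherwise) and broadcast the values to pixels;
2. keep only positive attributions on correctly classified images;
3. segment each egg into pigmentation-intensity regions by K-means colour
   clustering (k = 6, keep the 4 darkest non-background clusters) and add
   a dilated boundary band as an "edges" region;
4. per class and region, record the mean positive attribution and the
   number of pixels above 50% (Q2) and 75% (Q3) of the per-image maximum.

The Q2/Q3 thresholds are taken against each image's own maximum because
attribution magnitudes vary strongly between instances; Q3 pixels are by
construction a subset of Q2 pixels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .classify import TrainedClassifier, predict

__all__ = [
    "AttributionConfig",
    "AttributionMap",
    "RegionSet",
    "ImpactTable",
    "grid_superpixels",
    "shap_attribution",
    "segment_pigmentation",
    "positive_part",
    "region_mean_positive",
    "quartile_counts",
    "build_impact_table",
]

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class AttributionConfig:
    """Settings for the superpixel Shapley estimator."""

    superpixel_size: int = 8        # square block side in pixels
    n_permutations: int = 8         # sampling budget (ignored in exact mode)
    exact_max_superpixels: int = 12  # full enumeration up to 2^12 coalitions
    batch_size: int = 96
    seed: int = 0


@dataclass
class AttributionMap:
    """Signed per-pixel attribution for one class."""

    values: np.ndarray              # (S, S) float
    explained_class: int
    baseline_reference: str = ""

    def validate(self) -> None:
        assert np.isfinite(self.values).all()


@dataclass
class RegionSet:
    """Pigmentation-cluster masks (dark to light) plus the edge band."""

    cluster_masks: list[np.ndarray]
    egg_mask: np.ndarray
    edge_mask: np.ndarray | None = None

    def validate(self) -> None:
        union = np.zeros_like(self.egg_mask)
        for m in self.cluster_masks:
            assert not (union & m).any(), "cluster masks overlap"
            assert not m[~self.egg_mask].any(), "cluster outside egg"
            union |= m

    def region_items(self) -> list[tuple[str, np.ndarray]]:
        items = [(f"Cluster_{i}", m) for i, m in enumerate(self.cluster_masks)]
        if self.edge_mask is not None:
            items.append(("Edges", self.edge_mask))
        return items


def grid_superpixels(size: int, block: int) -> np.ndarray:
    """Regular square superpixel grid as an integer label map."""
    if block < 1 or size % block:
        raise ValueError("superpixel size must divide the image size")
    n = size // block
    rows = np.repeat(np.arange(n), block)
    return (rows[:, None] * n + rows[None, :]).astype(np.int64)


def _model_fn(model) -> callable:
    if isinstance(model, TrainedClassifier):
        return lambda x: predict(model, x.astype(np.float32))
    return model


def _masked_batch(image, baseline, labels, orders):
    """Images along one permutation walk: baseline, then superpixels of the
    permutation switched to the explained image one at a time."""
    out = np.empty((len(orders) + 1,) + image.shape, dtype=image.dtype)
    cur = baseline.copy()
    out[0] = cur
    for k, sp in enumerate(orders):
        sel = labels == sp
        cur[:, sel] = image[:, sel]
        out[k + 1] = cur
    return out


def shap_attribution(model, image, baseline_set, config: AttributionConfig | None = None
                     ) -> dict[int, AttributionMap]:
    """Shapley-style per-pixel attribution of every class output.

    ``model`` is a TrainedClassifier or a callable mapping (N, 3, S, S)
    arrays to (N, n_classes) outputs.  ``image`` is (3, S, S) (or an
    EggImage); ``baseline_set`` is a nonempty list of images of the same
    shape whose mean output anchors the attributions.

    Superpixels on a regular grid are the players.  With at most
    ``exact_max_superpixels`` players every coalition is enumerated and
    the attribution is exact; otherwise a permutation-sampling estimator
    is used, with permutations spread evenly over the baselines so that
    the additivity identity sum(attr) = f(x) - mean_b f(b) holds exactly.
    Returns one AttributionMap per class index.
    """
    config = config or AttributionConfig()
    if hasattr(image, "image"):
        image = np.transpose(image.image, (2, 0, 1))
    image = np.asarray(image, dtype=np.float64)
    baselines = [np.transpose(b.image, (2, 0, 1)) if hasattr(b, "image")
                 else np.asarray(b, dtype=np.float64) for b in baseline_set]
    if not baselines:
        raise ValueError("baseline_set must be nonempty")
    size = image.shape[-1]
    labels = grid_superpixels(size, config.superpixel_size)
    n_sp = int(labels.max()) + 1
    fn = _model_fn(model)

    if n_sp <= config.exact_max_superpixels:
        phi = _exact_shapley(fn, image, baselines, labels, n_sp, config)
    else:
        phi = _sampled_shapley(fn, image, baselines, labels, n_sp, config)

    # broadcast superpixel attributions to pixels (value shared per pixel)
    n_classes = phi.shape[1]
    area = np.bincount(labels.ravel(), minlength=n_sp).astype(float)
    maps = {}
    ref = f"{len(baselines)} baseline image(s), {n_sp} superpixels"
    for c in range(n_classes):
        per_pixel = (phi[:, c] / area)[labels]
        maps[c] = AttributionMap(values=per_pixel, explained_class=c,
                                 baseline_reference=ref)
    return maps


def _eval_batches(fn, images, batch):
    outs = [fn(np.asarray(images[i:i + batch]))
            for i in range(0, len(images), batch)]
    return np.concatenate(outs, axis=0)


def _exact_shapley(fn, image, baselines, labels, n_sp, config):
    """Full coalition enumeration; factorial-weighted marginal averages."""
    from math import factorial

    coalitions = np.arange(2 ** n_sp, dtype=np.uint32)
    members = ((coalitions[:, None] >> np.arange(n_sp)) & 1).astype(bool)
    weights = np.array([factorial(s) * factorial(n_sp - s - 1) / factorial(n_sp)
                        for s in range(n_sp)])
    phi = None
    for b in baselines:
        imgs = np.empty((len(coalitions),) + image.shape)
        for ci, mem in enumerate(members):
            img = b.copy()
            sel = np.isin(labels, np.nonzero(mem)[0])
            img[:, sel] = image[:, sel]
            imgs[ci] = img
        f = _eval_batches(fn, imgs, config.batch_size)  # (2^n, C)
        phi_b = np.zeros((n_sp, f.shape[1]))
        sizes = members.sum(axis=1)
        for i in range(n_sp):
            without = ~members[:, i]
            s_with = coalitions[without] | (1 << i)
            gain = f[s_with] - f[coalitions[without]]
            phi_b[i] = (weights[sizes[without]][:, None] * gain).sum(axis=0)
        phi = phi_b if phi is None else phi + phi_b
    return phi / len(baselines)


def _sampled_shapley(fn, image, baselines, labels, n_sp, config):
    """Permutation sampling; baselines cycled evenly for exact additivity."""
    rng = np.random.default_rng(config.seed)
    n_b = len(baselines)
    n_perm = int(np.ceil(config.n_permutations / n_b)) * n_b
    phi = np.zeros((n_sp, 0))
    first = True
    for p in range(n_perm):
        order = rng.permutation(n_sp)
        base = baselines[p % n_b]
        batch = _masked_batch(image, base, labels, order)
        f = _eval_batches(fn, batch, config.batch_size)   # (n_sp + 1, C)
        if first:
            phi = np.zeros((n_sp, f.shape[1]))
            first = False
        gains = np.diff(f, axis=0)                        # (n_sp, C)
        phi[order] += gains
    return phi / n_perm


# ---------------------------------------------------------------------------
# pigmentation regions


def segment_pigmentation(image: np.ndarray, egg_mask: np.ndarray,
                         k: int = 6, keep: int = 4,
                         seed: int = 0) -> RegionSet:
    """K-means colour segmentation into pigmentation-intensity regions.

    Pixels inside a padded bounding box of the egg (so the frame's large
    uniform backdrop does not soak up centroids) are clustered in RGB
    space with ``k`` clusters; clusters whose mask lies mostly (> 50%)
    outside the egg are dropped as background, and the ``keep`` darkest
    remaining clusters are returned ordered dark to light (Cluster_0 =
    darkest).  Masks are restricted to the egg.
    """
    if hasattr(image, "image"):
        egg_mask = image.egg_mask if egg_mask is None else egg_mask
        image = image.image
    if k <= keep:
        raise ValueError("k must exceed keep")
    image = np.asarray(image, dtype=np.float64)
    egg_mask = np.asarray(egg_mask, dtype=bool)

    ys, xs = np.nonzero(egg_mask)
    if ys.size == 0:
        raise ValueError("empty egg mask")
    pad = max(2, (ys.max() - ys.min()) // 10)
    r0, r1 = max(0, ys.min() - pad), min(egg_mask.shape[0], ys.max() + pad + 1)
    c0, c1 = max(0, xs.min() - pad), min(egg_mask.shape[1], xs.max() + pad + 1)
    box_img = image[r0:r1, c0:c1].copy()
    box_egg = egg_mask[r0:r1, c0:c1]
    # homogenize the backdrop so its sensor noise cannot fragment it over
    # several centroids: the background then occupies exactly one cluster
    if (~box_egg).any():
        box_img[~box_egg] = np.median(box_img[~box_egg], axis=0)

    pixels = box_img.reshape(-1, 3)
    km = KMeans(n_clusters=k, n_init=4, random_state=seed)
    assign_box = km.fit_predict(pixels).reshape(box_egg.shape)
    assign = np.full(egg_mask.shape, -1, dtype=int)
    assign[r0:r1, c0:c1] = assign_box

    candidates = []
    for c in range(k):
        m = assign == c
        if m.sum() == 0:
            continue
        outside_frac = (m & ~egg_mask).sum() / m.sum()
        if outside_frac > 0.5:
            continue  # background-associated cluster
        luma = float(km.cluster_centers_[c] @ _LUMA)
        candidates.append((luma, c, m & egg_mask))
    if len(candidates) < keep:
        raise ValueError(
            f"only {len(candidates)} non-background clusters; "
            f"reduce keep below {keep}")
    candidates.sort(key=lambda t: t[0])
    chosen = candidates[:keep]
    return RegionSet(cluster_masks=[m for _, _, m in chosen],
                     egg_mask=np.asarray(egg_mask, dtype=bool))


def positive_part(attribution: AttributionMap | np.ndarray) -> np.ndarray:
    """Zero out negative attributions; positives pass through unchanged."""
    values = attribution.values if isinstance(attribution, AttributionMap) \
        else np.asarray(attribution)
    return np.maximum(values, 0.0)


def region_mean_positive(positive_map: np.ndarray, region_mask: np.ndarray
                         ) -> tuple[float, bool]:
    """Mean positive attribution over a region; (0, True) if it is empty."""
    if positive_map.shape != region_mask.shape:
        raise ValueError("map and mask sizes differ")
    n = int(region_mask.sum())
    if n == 0:
        return 0.0, True
    return float(positive_map[region_mask].mean()), False


def quartile_counts(positive_map: np.ndarray, region_mask: np.ndarray,
                    max_value: float | None = None) -> tuple[int, int]:
    """Pixels in the region above 50% (Q2) and 75% (Q3) of the maximum.

    ``max_value`` defaults to the map's own maximum; pass the maximum over
    the egg mask for per-image normalization.  Q3 <= Q2 by construction.
    """
    if positive_map.shape != region_mask.shape:
        raise ValueError("map and mask sizes differ")
    m = positive_map.max() if max_value is None else max_value
    if m <= 0:
        return 0, 0
    vals = positive_map[region_mask]
    return int((vals > 0.5 * m).sum()), int((vals > 0.75 * m).sum())


# ---------------------------------------------------------------------------
# impact table


@dataclass
class ImpactTable:
    """Per-class, per-region positive-attribution statistics."""

    classes: list[str]
    regions: list[str]
    q2: pd.DataFrame = field(default=None)   # classes x regions
    q3: pd.DataFrame = field(default=None)
    mean_positive: pd.DataFrame = field(default=None)
    n_images: dict[str, int] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Wide table with a (quartile, region) column MultiIndex."""
        q2 = self.q2.copy()
        q2.columns = pd.MultiIndex.from_product([["Q2"], q2.columns])
        q3 = self.q3.copy()
        q3.columns = pd.MultiIndex.from_product([["Q3"], q3.columns])
        return pd.concat([q2, q3], axis=1)

    def argmax_region(self, cls: str, quartile: str = "Q3") -> str:
        row = (self.q3 if quartile == "Q3" else self.q2).loc[cls]
        return str(row.idxmax())


def build_impact_table(model, images, y_true, region_sets, baseline_set,
                       config: AttributionConfig | None = None,
                       class_labels: list[str] | None = None,
                       attributions: list[dict[int, AttributionMap]] | None = None
                       ) -> ImpactTable:
    """Tabulate Q2/Q3 pixel counts and region means per class.

    Only correctly classified images contribute.  ``images`` is a list of
    EggImage (or (3,S,S) arrays with matching region sets); ``region_sets``
    provides each image's cluster masks and edge band.  Precomputed
    ``attributions`` (as returned by :func:`shap_attribution`) may be
    passed to skip the estimator, e.g. in tests with hand-set maps.
    """
    config = config or AttributionConfig()
    y_true = np.asarray(y_true)
    if class_labels is None:
        class_labels = (model.class_labels if isinstance(model, TrainedClassifier)
                        else [f"class_{i}" for i in range(int(y_true.max()) + 1)])
    regions = region_sets[0].region_items()
    region_names = [name for name, _ in regions]

    xs = np.stack([np.transpose(im.image, (2, 0, 1)) if hasattr(im, "image")
                   else np.asarray(im) for im in images]).astype(np.float32)
    fn = _model_fn(model)
    y_pred = _eval_batches(fn, xs, config.batch_size).argmax(axis=1)
    correct = y_pred == y_true

    q2 = pd.DataFrame(0, index=class_labels, columns=region_names, dtype=int)
    q3 = pd.DataFrame(0, index=class_labels, columns=region_names, dtype=int)
    mean_pos = pd.DataFrame(0.0, index=class_labels, columns=region_names)
    n_images = {c: 0 for c in class_labels}

    for i, keep in enumerate(correct):
        if not keep:
            continue
        cls = class_labels[y_true[i]]
        n_images[cls] += 1
        if attributions is not None:
            amap = attributions[i][int(y_true[i])]
        else:
            amap = shap_attribution(model, images[i], baseline_set, config)[
                int(y_true[i])]
        pos = positive_part(amap)
        rs = region_sets[i]
        egg_max = float(pos[rs.egg_mask].max()) if rs.egg_mask.any() else float(pos.max())
        for name, mask in rs.region_items():
            c2, c3 = quartile_counts(pos, mask, max_value=egg_max)
            q2.loc[cls, name] += c2
            q3.loc[cls, name] += c3
            mval, empty = region_mean_positive(pos, mask)
            if empty:
                warnings.warn(f"empty region {name} for image {i}", stacklevel=2)
            mean_pos.loc[cls, name] += mval

    for cls in class_labels:
        if n_images[cls] == 0:
            warnings.warn(f"class {cls!r} has no correctly classified images; "
                          "its row is all zeros", stacklevel=2)
        else:
            mean_pos.loc[cls] /= n_images[cls]
    return ImpactTable(classes=list(class_labels), regions=region_names,
                       q2=q2, q3=q3, mean_positive=mean_pos, n_images=n_images)
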