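"""Egg extraction and standardization.

Museum-style photographs show a single egg on a near-uniform backdrop.
This module re-specifies that extraction step as an explicit algorithm:

1. ``segment_egg`` — threshold the Euclidean distance from the median
   border-pixel colour (Otsu), clean up morphologically, keep the largest
   connected component;
2. ``standardize`` — crop with a margin, rotate the long axis vertical,
   put the blunt end up (the half with the larger mean width), and resample
   to a square working size (256, 128 or 64);
3. ``boundary_band`` — the dilated-minus-eroded band around the egg
   contour used as the "edges" region by the attribution quantification.

Conventions: row-major arrays, origin top-left, masks are boolean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import measure, morphology, transform

__all__ = [
    "EggImage",
    "SegmentationError",
    "segment_egg",
    "standardize",
    "boundary_band",
    "default_band_radius",
]

VALID_SIZES = (256, 128, 64)
MIN_AREA_FRACTION = 0.15
MAX_AREA_FRACTION = 0.85
ORIENTATION_TOLERANCE = 0.02  # relative width difference below which the
                              # blunt end is ambiguous


class SegmentationError(RuntimeError):
    """Segmentation failed; carries diagnostics in ``details``."""

    def __init__(self, message: str, **details):
        super().__init__(message)
        self.details = details


@dataclass
class EggImage:
    """A standardized square egg image with its mask."""

    image: np.ndarray           # (S, S, 3) float in [0, 1]
    egg_mask: np.ndarray        # (S, S) bool
    species: str | None = None
    clutch_id: str | None = None
    blunt_end_up: bool | None = None  # None = orientation ambiguous

    @property
    def size(self) -> int:
        return self.image.shape[0]

    def validate(self) -> None:
        s = self.size
        assert self.image.shape == (s, s, 3)
        lbl = measure.label(self.egg_mask)
        assert lbl.max() == 1, "egg mask must be a single component"
        filled = ndi.binary_fill_holes(self.egg_mask)
        assert (filled == self.egg_mask).all(), "egg mask has holes"
        frac = self.egg_mask.mean()
        assert MIN_AREA_FRACTION <= frac <= MAX_AREA_FRACTION, frac
        border = np.concatenate([
            self.egg_mask[0], self.egg_mask[-1],
            self.egg_mask[:2].ravel(), self.egg_mask[-2:].ravel(),
            self.egg_mask[:, :2].ravel(), self.egg_mask[:, -2:].ravel()])
        assert not border.any(), "mask touches the image border"


def _background_distance(photo: np.ndarray) -> np.ndarray:
    """Euclidean RGB distance from the median border-pixel colour."""
    border = np.concatenate([photo[0], photo[-1], photo[:, 0], photo[:, -1]])
    bg = np.median(border, axis=0)
    return np.linalg.norm(photo - bg, axis=-1)


def segment_egg(photo: np.ndarray, min_area_fraction: float = 0.02) -> np.ndarray:
    """Segment the egg from a single-egg photograph.

    Global Otsu thresholding of the background-distance image, followed by
    morphological opening, hole filling, and selection of the largest
    connected component.  Emits a warning when several sizeable components
    are present (e.g. two eggs in frame) and returns the largest.
    """
    from skimage.filters import threshold_otsu

    photo = np.asarray(photo, dtype=np.float64)
    if photo.ndim != 3 or photo.shape[-1] != 3:
        raise ValueError("expected an (H, W, 3) RGB image")
    dist = _background_distance(photo)
    if dist.max() - dist.min() < 1e-6:
        raise SegmentationError("image is uniform; nothing to segment",
                                dist_range=float(dist.max() - dist.min()))
    thr = threshold_otsu(dist)
    fg = dist > thr
    fg = ndi.binary_opening(fg, structure=morphology.disk(2))
    # bridge narrow gaps (a belt of spots whose colour is close to the
    # backdrop can sever the blunt cap from the body)
    close_r = max(2, min(photo.shape[:2]) // 32)
    fg = ndi.binary_closing(fg, structure=morphology.disk(close_r))
    fg = ndi.binary_fill_holes(fg)
    labels = measure.label(fg)
    if labels.max() == 0:
        raise SegmentationError("no foreground component found", threshold=float(thr))
    sizes = np.bincount(labels.ravel())[1:]
    order = np.argsort(sizes)[::-1]
    largest = order[0] + 1
    if len(sizes) > 1 and sizes[order[1]] > 0.25 * sizes[order[0]]:
        warnings.warn("multiple sizeable components; keeping the largest",
                      stacklevel=2)
    mask = labels == largest
    if mask.mean() < min_area_fraction:
        raise SegmentationError(
            "largest component below minimum area",
            area_fraction=float(mask.mean()), threshold=float(thr))
    # eggs are convex: the hull repairs boundary bites where dark spots
    # touch the contour and resemble the backdrop
    return morphology.convex_hull_image(mask)


def _principal_angle(mask: np.ndarray) -> float:
    """Angle (degrees) of the mask's principal axis from the vertical."""
    ys, xs = np.nonzero(mask)
    y = ys - ys.mean()
    x = xs - xs.mean()
    cov = np.cov(np.stack([y, x]))
    evals, evecs = np.linalg.eigh(cov)
    vy, vx = evecs[:, np.argmax(evals)]
    return float(np.degrees(np.arctan2(vx, vy)))


def _width_by_row(mask: np.ndarray) -> np.ndarray:
    return mask.sum(axis=1)


def standardize(photo: np.ndarray, mask: np.ndarray, size: int = 256,
                species: str | None = None, clutch_id: str | None = None,
                margin_fraction: float = 0.10) -> EggImage:
    """Crop, orient (long axis vertical, blunt end up) and resize.

    The blunt end is the half of the egg with the larger mean width; when
    the relative difference is below 2% the orientation is left as-is and
    flagged unknown (``blunt_end_up = None``).
    """
    if size not in VALID_SIZES:
        raise ValueError(f"size must be one of {VALID_SIZES}")
    photo = np.asarray(photo, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)

    # rotate long axis vertical (about the mask centroid)
    angle = _principal_angle(mask)
    if abs(angle) > 0.5:
        photo = transform.rotate(photo, angle, resize=True, order=1,
                                 mode="constant",
                                 cval=float(np.median(photo)))
        mask = transform.rotate(mask.astype(float), angle, resize=True,
                                order=0, mode="constant", cval=0) > 0.5

    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise SegmentationError("empty mask after rotation")
    h = ys.max() - ys.min() + 1
    w = xs.max() - xs.min() + 1
    pad = int(np.ceil(margin_fraction * max(h, w)))
    side = max(h, w) + 2 * pad
    cy, cx = (ys.max() + ys.min()) // 2, (xs.max() + xs.min()) // 2
    r0, c0 = cy - side // 2, cx - side // 2

    crop = np.full((side, side, 3), np.median(photo, axis=(0, 1)))
    crop_mask = np.zeros((side, side), dtype=bool)
    sr0, sc0 = max(0, -r0), max(0, -c0)
    pr0, pc0 = max(0, r0), max(0, c0)
    pr1 = min(photo.shape[0], r0 + side)
    pc1 = min(photo.shape[1], c0 + side)
    crop[sr0:sr0 + pr1 - pr0, sc0:sc0 + pc1 - pc0] = photo[pr0:pr1, pc0:pc1]
    crop_mask[sr0:sr0 + pr1 - pr0, sc0:sc0 + pc1 - pc0] = mask[pr0:pr1, pc0:pc1]

    # blunt end up: compare mean widths of the two halves
    widths = _width_by_row(crop_mask)
    occ = np.nonzero(widths)[0]
    mid = (occ[0] + occ[-1]) // 2
    top_w = widths[occ[0]:mid + 1]
    bot_w = widths[mid + 1:occ[-1] + 1]
    top_mean = top_w[top_w > 0].mean() if (top_w > 0).any() else 0.0
    bot_mean = bot_w[bot_w > 0].mean() if (bot_w > 0).any() else 0.0
    denom = max(top_mean, bot_mean, 1e-9)
    rel = (top_mean - bot_mean) / denom
    if abs(rel) < ORIENTATION_TOLERANCE:
        blunt_up: bool | None = None
    elif rel < 0:
        crop = crop[::-1].copy()
        crop_mask = crop_mask[::-1].copy()
        blunt_up = True
    else:
        blunt_up = True

    out = transform.resize(crop, (size, size, 3), order=1, anti_aliasing=True)
    out_mask = transform.resize(crop_mask.astype(float), (size, size),
                                order=0, anti_aliasing=False) > 0.5
    out_mask = _clip_mask_to_interior(out_mask)
    return EggImage(image=np.clip(out, 0, 1), egg_mask=out_mask,
                    species=species, clutch_id=clutch_id, blunt_end_up=blunt_up)


def _clip_mask_to_interior(mask: np.ndarray, margin: int = 2) -> np.ndarray:
    out = mask.copy()
    out[:margin] = False
    out[-margin:] = False
    out[:, :margin] = False
    out[:, -margin:] = False
    return out


def default_band_radius(size: int) -> int:
    """Default edge-band dilation radius: 5 px at 256, scaled with size."""
    return max(1, round(5 * size / 256))


def boundary_band(mask: np.ndarray, dilation_radius: int) -> np.ndarray:
    """Edge band: dilate(mask, r) minus erode(mask, r).

    The band encloses the mask contour symmetrically and is monotone in
    ``dilation_radius``.  Dilation and erosion use exact Euclidean
    distance transforms, so the band of a rasterized disc matches the
    ideal annulus area closely at any radius.
    """
    if dilation_radius <= 0:
        raise ValueError("dilation_radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    # +0.5: the object boundary runs halfway between pixel centres, so
    # "within r of the boundary" is EDT <= r + 0.5 on either side
    r = dilation_radius + 0.5
    dil = ~mask & (ndi.distance_transform_edt(~mask) <= r)
    dil |= mask
    ero = mask & (ndi.distance_transform_edt(mask) > r)
    return dil & ~ero
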