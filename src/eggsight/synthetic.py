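"""Synthetic egg-image generator with clutch-level signature structure.

Renders single eggs on a uniform background with full ground truth: the egg
mask, a blunt-end pigment-ring band, and one spot mask per contrast level.
The generator emulates the statistical structure of real shrike eggs that
the downstream analysis assumes:

* a species-specific shell background colour (e.g. a greenish background
  for one species),
* pigment spots whose longitudinal positions concentrate in a ring near
  the blunt end, at several darkness (contrast) levels,
* clutch structure — eggs of one clutch share a parameter draw and vary
  less within the clutch than between clutches ("signature" structure:
  replicable within a clutch, distinctive between clutches).

Eggs are rendered blunt-end-up on square canvases (default 256x256); all
randomness flows through an explicit :class:`numpy.random.Generator`.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "SpeciesProfile",
    "SyntheticEgg",
    "DatasetConfig",
    "default_profiles",
    "separable_profiles",
    "planted_cue_profiles",
    "sample_egg_shape",
    "render_egg",
    "generate_clutch",
    "generate_dataset",
]

DEFAULT_CLUTCH_SIZE = 5  # typical shrike clutch

# Relative between-clutch spreads for scalar generator parameters.  The
# within-clutch spread is clutch_sd_fraction times these.
_BETWEEN_SD = {
    "spot_density": 0.20,   # fraction of the mean
    "length": 0.04,
    "width": 0.04,
    "asymmetry_abs": 0.05,  # absolute
    "log_ring_conc": 0.15,  # on log(1 + kappa)
}

# longitudinal position of the pigment ring (0 = blunt pole); the ring sits
# in the blunt-end third, roughly where the "crown" band runs on real eggs
RING_CENTER = 0.28


class InvalidParameterError(ValueError):
    pass


class SpotPlacementError(RuntimeError):
    """Raised when the requested spot density cannot be placed disjointly."""


@dataclass
class SpeciesProfile:
    """Generating parameters for one species.

    ``contrast_levels`` are darkness offsets subtracted from the shell
    colour, ordered moderate < dark < darkest.  ``clutch_sd_fraction``
    scales within-clutch parameter spread relative to the between-clutch
    spread and must be < 1 so that clutches act as signatures.
    """

    name: str
    background_color_mean: tuple[float, float, float]
    background_color_sd: tuple[float, float, float] = (0.02, 0.02, 0.02)
    shape_params: tuple[float, float, float] = (200.0, 140.0, 0.25)  # length, width, asymmetry
    ring_concentration: float = 4.0
    spot_density_mean: float = 60.0
    contrast_levels: tuple[float, float, float] = (0.22, 0.40, 0.58)
    contrast_weights: tuple[float, float, float] = (0.5, 0.3, 0.2)
    clutch_sd_fraction: float = 0.3
    spot_radius_range: tuple[float, float] = (2.5, 6.0)  # px at 256
    noise_sd: float = 0.02
    # optional extra ring component layered over the diffuse field: a
    # Poisson(ring_extra_density) set of spots at ring_extra_level drawn
    # with concentration ring_extra_kappa around the ring centre
    ring_extra_density: float = 0.0
    ring_extra_kappa: float = 25.0
    ring_extra_level: int = 2
    # ring spots may be larger "blots" than the diffuse field (px at 256)
    ring_extra_radius_range: tuple[float, float] | None = None

    def __post_init__(self):
        cl = self.contrast_levels
        if not (cl[0] < cl[1] < cl[2]):
            raise InvalidParameterError("contrast_levels must be strictly increasing")
        for c in (*self.background_color_mean, *self.background_color_sd):
            if not (0.0 <= c <= 1.0):
                raise InvalidParameterError("colors must lie in [0, 1]")
        if not (0.0 <= self.clutch_sd_fraction < 1.0):
            raise InvalidParameterError("clutch_sd_fraction must be in [0, 1)")
        if self.ring_concentration < 0:
            raise InvalidParameterError("ring_concentration must be nonnegative")


@dataclass
class SyntheticEgg:
    """A rendered egg plus its complete ground truth."""

    image: np.ndarray            # (S, S, 3) float in [0, 1]
    egg_mask: np.ndarray         # (S, S) bool
    ring_mask: np.ndarray        # (S, S) bool, blunt-end ring band
    spot_masks: list[np.ndarray]  # one bool mask per contrast level
    species: str
    clutch_id: str
    egg_id: str = ""
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        assert self.ring_mask[~self.egg_mask].sum() == 0
        union = np.zeros_like(self.egg_mask)
        for m in self.spot_masks:
            assert m[~self.egg_mask].sum() == 0
            assert not (union & m).any(), "spot masks overlap"
            union |= m


def default_profiles() -> list[SpeciesProfile]:
    """Four shrike-like species profiles.

    Background colours, spot density and shape differ between species; the
    lesser-gray-like profile carries the distinctive greenish background.
    """
    return [
        SpeciesProfile(
            name="red-backed",
            background_color_mean=(0.82, 0.73, 0.66),
            spot_density_mean=70.0,
            ring_concentration=6.0,
            shape_params=(200.0, 145.0, 0.25),
        ),
        SpeciesProfile(
            name="lesser-gray",
            background_color_mean=(0.70, 0.78, 0.60),  # greenish
            spot_density_mean=50.0,
            ring_concentration=3.0,
            shape_params=(195.0, 140.0, 0.20),
        ),
        SpeciesProfile(
            name="great-gray",
            background_color_mean=(0.87, 0.85, 0.80),
            spot_density_mean=45.0,
            ring_concentration=2.0,
            contrast_weights=(0.25, 0.3, 0.45),  # darkest spots prominent
            shape_params=(210.0, 148.0, 0.22),
        ),
        SpeciesProfile(
            name="woodchat",
            background_color_mean=(0.84, 0.79, 0.70),
            spot_density_mean=30.0,
            ring_concentration=8.0,
            shape_params=(190.0, 130.0, 0.32),
        ),
    ]


def separable_profiles() -> list[SpeciesProfile]:
    """Four profiles with background-colour means at least five noise SDs
    apart, so a pixel-mean nearest-centroid rule separates the classes and
    the CNN task is learnable at desk scale."""
    colors = [(0.85, 0.70, 0.60), (0.62, 0.80, 0.55),
              (0.90, 0.88, 0.84), (0.72, 0.62, 0.80)]
    names = ["rufous", "greenish", "pale", "mauve"]
    out = []
    for name, color in zip(names, colors):
        out.append(SpeciesProfile(
            name=name, background_color_mean=color,
            background_color_sd=(0.015, 0.015, 0.015),
            spot_density_mean=25.0, ring_concentration=5.0))
    return out


def planted_cue_profiles() -> list[SpeciesProfile]:
    """Four profiles sharing a common baseline (a diffuse moderate/dark
    spot field on a beige shell) that differ by exactly one planted cue
    each, for explanation-recovery studies:

    * ``ringed`` — an extra blunt-end ring of small darkest-level spots
      (a spatially concentrated cue for saliency-map recovery);
    * ``darkspot`` — large darkest-level blots scattered over the shell
      (a pigment-intensity cue for region quantification);
    * ``hue`` — a greenish shell background;
    * ``shape`` — a narrower, more asymmetric outline.
    """
    base = dict(
        background_color_mean=(0.82, 0.76, 0.68),
        background_color_sd=(0.025, 0.025, 0.025),
        shape_params=(195.0, 140.0, 0.22),
        spot_density_mean=20.0,             # identical diffuse field in all
        ring_concentration=0.0,             # classes; only the cue differs
        contrast_weights=(0.7, 0.3, 0.0),   # moderate + dark, never darkest
        clutch_sd_fraction=0.3,
        noise_sd=0.04,
    )
    ringed = dict(base, ring_extra_density=35.0, ring_extra_kappa=25.0,
                  ring_extra_level=2)
    darkspot = dict(base, ring_extra_density=12.0, ring_extra_kappa=0.5,
                    ring_extra_level=2, ring_extra_radius_range=(10.0, 16.0))
    hue = dict(base, background_color_mean=(0.66, 0.80, 0.58))
    shape = dict(base, shape_params=(215.0, 108.0, 0.45))
    return [SpeciesProfile(name="ringed", **ringed),
            SpeciesProfile(name="darkspot", **darkspot),
            SpeciesProfile(name="hue", **hue),
            SpeciesProfile(name="shape", **shape)]


# ---------------------------------------------------------------------------
# shape


def _width_profile(t: np.ndarray, width: float, asymmetry: float) -> np.ndarray:
    """Egg half-width as a function of normalized long-axis position t in [0,1].

    w(t) = W * sin(pi t) * (1 + a cos(pi t)); t = 0 is the blunt pole, so
    positive asymmetry moves the widest point toward the blunt end.
    """
    return 0.5 * width * np.sin(np.pi * t) * (1.0 + asymmetry * np.cos(np.pi * t))


def sample_egg_shape(
    profile_or_params,
    rng: np.random.Generator,
    canvas: int = 256,
) -> tuple[np.ndarray, np.ndarray]:
    """Rasterize an asymmetric egg outline; returns (outline, mask).

    ``profile_or_params`` is a SpeciesProfile or a (length, width,
    asymmetry) triple.  The mask is a single simply connected component
    rendered blunt-end-up and centred on the canvas; the outline is an
    (n, 2) array of (row, col) boundary points.
    """
    if isinstance(profile_or_params, SpeciesProfile):
        length, width, asym = profile_or_params.shape_params
    else:
        length, width, asym = profile_or_params
    if length <= 0 or width <= 0:
        raise InvalidParameterError("egg length and width must be positive")
    # shape_params are expressed at the 256-px reference frame
    length *= canvas / 256.0
    width *= canvas / 256.0
    if length >= canvas - 4 or width >= canvas - 4:
        raise InvalidParameterError(
            f"egg ({length:.0f}x{width:.0f}) does not fit canvas {canvas}")

    # sub-pixel jitter of the centre keeps rasterization artifacts from
    # aligning across a dataset
    cy = canvas / 2.0 + rng.uniform(-0.5, 0.5)
    cx = canvas / 2.0 + rng.uniform(-0.5, 0.5)

    rows = np.arange(canvas)
    t = (rows - (cy - length / 2.0)) / length  # 0 at blunt (top), 1 at sharp
    inside_rows = (t >= 0) & (t <= 1)
    half_w = np.zeros(canvas)
    half_w[inside_rows] = _width_profile(t[inside_rows], width, asym)

    cols = np.arange(canvas)
    mask = np.abs(cols[None, :] - cx) <= half_w[:, None]
    mask &= inside_rows[:, None]

    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    outline = max(contours, key=len) if contours else np.zeros((0, 2))
    return outline, mask


# ---------------------------------------------------------------------------
# clutch parameter draws


def _draw_params(profile: SpeciesProfile, rng: np.random.Generator,
                 scale: float) -> dict:
    """One parameter perturbation at the given spread scale (1 = between-clutch)."""
    length, width, asym = profile.shape_params
    color = np.clip(
        np.asarray(profile.background_color_mean)
        + scale * np.asarray(profile.background_color_sd) * rng.standard_normal(3),
        0.0, 1.0,
    )
    return {
        "background_color": color,
        "spot_density": max(
            0.0,
            profile.spot_density_mean
            * (1.0 + scale * _BETWEEN_SD["spot_density"] * rng.standard_normal()),
        ),
        "length": length * (1.0 + scale * _BETWEEN_SD["length"] * rng.standard_normal()),
        "width": width * (1.0 + scale * _BETWEEN_SD["width"] * rng.standard_normal()),
        "asymmetry": float(
            np.clip(asym + scale * _BETWEEN_SD["asymmetry_abs"] * rng.standard_normal(),
                    0.0, 0.9)
        ),
        "ring_concentration": max(
            0.0,
            np.expm1(
                np.log1p(profile.ring_concentration)
                + scale * _BETWEEN_SD["log_ring_conc"] * rng.standard_normal()
            ),
        ),
    }


def _base_params(profile: SpeciesProfile) -> dict:
    """Unperturbed parameter means (spread scale 0)."""
    return _draw_params(profile, np.random.default_rng(0), scale=0.0)


def _clip_params(p: dict) -> dict:
    p["background_color"] = np.clip(p["background_color"], 0.0, 1.0)
    p["spot_density"] = max(0.0, p["spot_density"])
    p["asymmetry"] = float(np.clip(p["asymmetry"], 0.0, 0.9))
    p["ring_concentration"] = max(0.0, p["ring_concentration"])
    # keep the egg inside the canvas margin at every render scale
    p["length"] = float(np.clip(p["length"], 20.0, 230.0))
    p["width"] = float(np.clip(p["width"], 15.0, 230.0))
    return p


# ---------------------------------------------------------------------------
# rendering


def _ring_band(t_row: np.ndarray, egg_mask: np.ndarray, kappa: float,
               extra_half_t: float = 0.0) -> np.ndarray:
    """Blunt-end ring band: egg rows within two standard deviations of the
    spot-position distribution around the ring centre (covers ~95% of the
    ring spot centres), widened by ``extra_half_t`` to account for the
    spatial extent of the pigment itself (e.g. blot radii)."""
    if kappa <= 0:
        return np.zeros_like(egg_mask)
    # vonmises angle sd ~ 1/sqrt(kappa); t = angle / (2 pi)
    half = float(np.clip(2.0 / (np.sqrt(kappa) * 2.0 * np.pi), 0.04, 0.18))
    half += extra_half_t
    band_rows = (t_row >= RING_CENTER - half) & (t_row <= RING_CENTER + half)
    return egg_mask & band_rows[:, None]


def _sample_ring_positions(n: int, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Longitudinal spot positions t in (0, 1): von-Mises-like concentration
    around the ring centre; kappa = 0 degenerates to uniform."""
    if kappa <= 0:
        return rng.uniform(0.02, 0.98, size=n)
    theta = rng.vonmises(0.0, kappa, size=n)  # (-pi, pi]
    t = RING_CENTER + theta / (2.0 * np.pi)
    return np.clip(np.mod(t, 1.0), 0.02, 0.98)


def render_egg(
    profile: SpeciesProfile,
    clutch_params: dict,
    rng: np.random.Generator,
    canvas: int = 256,
    clutch_id: str = "clutch-0",
) -> SyntheticEgg:
    """Render one egg from realized clutch parameters.

    Spots are anti-aliased filled ellipses placed disjointly; each spot
    carries one contrast level.  Gaussian pixel noise (sd
    ``profile.noise_sd``) is added last.
    """
    p = clutch_params
    outline, egg_mask = sample_egg_shape(
        (p["length"], p["width"], p["asymmetry"]), rng, canvas=canvas)

    rows = np.arange(canvas)
    ys = np.where(egg_mask.any(axis=1))[0]
    top, bot = ys.min(), ys.max()
    t_row = np.clip((rows - top) / max(1, bot - top), 0.0, 1.0)

    img = np.empty((canvas, canvas, 3), dtype=np.float64)
    bg_outside = np.array([0.5, 0.5, 0.5])  # neutral mid-gray backdrop (photo tent)
    img[:] = bg_outside
    shell = np.asarray(p["background_color"])
    img[egg_mask] = shell  # uniform shell tone; noise is added at the end

    n_levels = len(profile.contrast_levels)
    spot_masks = [np.zeros((canvas, canvas), dtype=bool) for _ in range(n_levels)]
    # the diffuse field is kept disjoint; ring blots may overlap each other
    # (merging into a solid crown) but never the diffuse field
    occ_base = np.zeros((canvas, canvas), dtype=bool)
    occ_ring = np.zeros((canvas, canvas), dtype=bool)

    n_base = rng.poisson(p["spot_density"]) if p["spot_density"] > 0 else 0
    n_ring = (rng.poisson(profile.ring_extra_density)
              if profile.ring_extra_density > 0 else 0)
    scale = canvas / 256.0
    r_lo, r_hi = profile.spot_radius_range
    kappa = p["ring_concentration"]
    weights = np.asarray(profile.contrast_weights, dtype=float)
    weights = weights / weights.sum()

    # per-spot (position, concentration, level): the diffuse field first,
    # then the optional concentrated ring component
    t_spots = np.concatenate([
        _sample_ring_positions(n_base, kappa, rng),
        _sample_ring_positions(n_ring, profile.ring_extra_kappa, rng)])
    spot_kappa = np.concatenate([
        np.full(n_base, kappa), np.full(n_ring, profile.ring_extra_kappa)])
    levels = np.concatenate([
        rng.choice(n_levels, size=n_base, p=weights),
        np.full(n_ring, profile.ring_extra_level)]).astype(int)
    n_spots = n_base + n_ring
    placed = 0
    failures = 0
    ring_r = profile.ring_extra_radius_range or (r_lo, r_hi)
    for i in range(n_spots):
        level = int(levels[i])
        lo, hi = (ring_r if i >= n_base else (r_lo, r_hi))
        a_r = rng.uniform(lo, hi) * scale
        b_r = a_r * rng.uniform(0.6, 1.0)
        angle = rng.uniform(0.0, np.pi)
        ok = False
        for _attempt in range(20):
            # shrink the spot on successive attempts so dense rings still fill
            shrink = 0.9 ** _attempt
            ar = max(1.2 * scale, a_r * shrink)
            br = max(1.0 * scale, b_r * shrink)
            ti = t_spots[i] if _attempt == 0 else float(
                _sample_ring_positions(1, spot_kappa[i], rng)[0])
            row = top + ti * (bot - top)
            hw = _width_profile(np.array([ti]), p["width"], p["asymmetry"])[0]
            if hw < ar + 2:
                continue
            col = canvas / 2.0 + rng.uniform(-(hw - ar - 2), hw - ar - 2)
            is_ring = i >= n_base
            check = occ_base if is_ring else (occ_base | occ_ring)
            update = occ_ring if is_ring else occ_base
            if _place_spot(img, spot_masks[level], check, update, egg_mask,
                           row, col, ar, br, angle, shell,
                           profile.contrast_levels[level]):
                ok = True
                break
        if ok:
            placed += 1
        else:
            failures += 1
    if n_spots > 0 and placed < 0.5 * n_spots:
        raise SpotPlacementError(
            f"could only place {placed}/{n_spots} spots disjointly; "
            "reduce spot_density or spot size")

    img += rng.normal(0.0, profile.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)

    realized = {k: (v.tolist() if isinstance(v, np.ndarray) else float(v))
                for k, v in p.items()}
    realized.update(n_spots_requested=int(n_spots), n_spots_placed=int(placed))

    if profile.ring_extra_density > 0:
        band_kappa = profile.ring_extra_kappa
        mean_r = float(np.mean(profile.ring_extra_radius_range
                               or profile.spot_radius_range)) * scale
        extra_half = mean_r / max(1, bot - top)
    else:
        band_kappa, extra_half = kappa, 0.0
    return SyntheticEgg(
        image=img.astype(np.float32),
        egg_mask=egg_mask,
        ring_mask=_ring_band(t_row, egg_mask, band_kappa, extra_half),
        spot_masks=spot_masks,
        species=profile.name,
        clutch_id=clutch_id,
        params=realized,
    )


def _place_spot(img, level_mask, occ_check, occ_update, egg_mask, row, col,
                a_r, b_r, angle, shell, darkness) -> bool:
    """Blend one anti-aliased elliptical spot; refuse overlap with
    ``occ_check``; record occupancy in ``occ_update``. Returns success."""
    canvas = img.shape[0]
    r = int(np.ceil(max(a_r, b_r))) + 2
    r0, r1 = int(row) - r, int(row) + r + 1
    c0, c1 = int(col) - r, int(col) + r + 1
    if r0 < 0 or c0 < 0 or r1 > canvas or c1 > canvas:
        return False
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = yy - row, xx - col
    ca, sa = np.cos(angle), np.sin(angle)
    u = (ca * dx + sa * dy) / a_r
    v = (-sa * dx + ca * dy) / b_r
    d = np.sqrt(u * u + v * v)
    slope = max(1.5, a_r / 0.75)  # ~1 px anti-aliased edge at any radius
    alpha = np.clip(slope * (1.0 - d) + 0.5, 0.0, 1.0)
    # ground truth counts only pigment-dominant pixels; the blended rim
    # (alpha 0.5-0.75) is a colour mixture belonging to no contrast level
    core = alpha > 0.75
    patch_egg = egg_mask[r0:r1, c0:c1]
    if not core.any() or (core & ~patch_egg).any():
        return False
    if (core & occ_check[r0:r1, c0:c1]).any():
        return False
    spot_color = np.clip(shell - darkness, 0.0, 1.0)
    blend = alpha[..., None] * (patch_egg[..., None])
    img[r0:r1, c0:c1] = img[r0:r1, c0:c1] * (1 - blend) + spot_color * blend
    level_mask[r0:r1, c0:c1] |= core & patch_egg
    occ_update[r0:r1, c0:c1] |= (alpha > 0.05) & patch_egg
    return True


def generate_clutch(
    profile: SpeciesProfile,
    n_eggs: int = DEFAULT_CLUTCH_SIZE,
    rng: np.random.Generator | None = None,
    canvas: int = 256,
    clutch_id: str = "clutch-0",
) -> list[SyntheticEgg]:
    """Generate ``n_eggs`` eggs sharing one clutch-level parameter draw.

    Per-egg parameters are perturbed around the clutch draw with spread
    ``clutch_sd_fraction`` times the between-clutch spread, so that within-
    clutch variation is strictly smaller than between-clutch variation.
    """
    if n_eggs < 1:
        raise InvalidParameterError("n_eggs must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    clutch_draw = _draw_params(profile, rng, scale=1.0)
    base = _base_params(profile)
    eggs = []
    for i in range(n_eggs):
        egg_perturb = _draw_params(profile, rng, scale=profile.clutch_sd_fraction)
        params = _clip_params(
            {k: clutch_draw[k] + (egg_perturb[k] - base[k]) for k in clutch_draw})
        egg = render_egg(profile, params, rng, canvas=canvas, clutch_id=clutch_id)
        egg.egg_id = f"{clutch_id}-egg{i}"
        eggs.append(egg)
    return eggs


# ---------------------------------------------------------------------------
# dataset


@dataclass
class DatasetConfig:
    """Configuration for writing a synthetic dataset to disk."""

    profiles: list[SpeciesProfile]
    counts: list[int]                      # eggs per species
    out_dir: str | Path = "synthetic_eggs"
    clutch_size: int = DEFAULT_CLUTCH_SIZE
    canvas: int = 256
    seed: int = 0
    write_masks: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DatasetConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        profiles = [SpeciesProfile(**p) for p in raw.pop("profiles")]
        return cls(profiles=profiles, **raw)

    def to_yaml(self, path: str | Path) -> None:
        def plain(obj):
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            return obj

        raw = plain(dataclasses.asdict(self))
        raw["out_dir"] = str(self.out_dir)
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


def generate_eggs_in_memory(config: DatasetConfig) -> list[SyntheticEgg]:
    """Generate all eggs of a configuration without touching disk."""
    if len(config.profiles) < 2:
        raise InvalidParameterError("need at least 2 species profiles")
    if len(config.counts) != len(config.profiles):
        raise InvalidParameterError("counts must match profiles")
    rng = np.random.default_rng(config.seed)
    eggs: list[SyntheticEgg] = []
    for profile, count in zip(config.profiles, config.counts):
        produced = 0
        clutch_idx = 0
        while produced < count:
            n = min(config.clutch_size, count - produced)
            cid = f"{profile.name}-c{clutch_idx:04d}"
            eggs.extend(generate_clutch(profile, n, rng, canvas=config.canvas,
                                        clutch_id=cid))
            produced += n
            clutch_idx += 1
    return eggs


def generate_dataset(config: DatasetConfig) -> pd.DataFrame:
    """Write images (and optional ground-truth masks) plus a CSV manifest.

    Manifest columns: ``path,species,clutch_id,egg_id``.  Returns the
    manifest as a DataFrame; it is also written to ``out_dir/manifest.csv``.
    """
    eggs = generate_eggs_in_memory(config)
    out = Path(config.out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    if config.write_masks:
        (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for egg in eggs:
        fname = f"{egg.egg_id}.png"
        path = out / "images" / fname
        iio.imwrite(path, (egg.image * 255).round().astype(np.uint8))
        if config.write_masks:
            iio.imwrite(out / "masks" / fname,
                        (egg.egg_mask * 255).astype(np.uint8))
        rows.append({"path": str(path), "species": egg.species,
                     "clutch_id": egg.clutch_id, "egg_id": egg.egg_id})
    manifest = pd.DataFrame(rows, columns=["path", "species", "clutch_id", "egg_id"])
    manifest.to_csv(out / "manifest.csv", index=False)
    return manifest
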