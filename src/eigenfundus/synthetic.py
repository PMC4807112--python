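"""Synthetic fundus image generator with exact ground truth.

Renders grayscale images that reproduce the coarse photometric and geometric
layout of a left-eye fundus photograph: a circular field of view (FOV) on a
near-black camera background, a smoothly varying retinal background with a
mild vignette, a bright quasi-circular optic disc, a dark low-contrast fovea
at about 2.5 disc diameters temporal (to the right) of the disc along the
horizontal raphe, two dark parabolic vascular arcades converging at the disc
with a few thinner branches, optional bright exudate blobs, and additive
Gaussian noise.  Every scene records its ground-truth disc/fovea centres,
disc diameter, vessel mask and FOV mask, so training sets and evaluation
scenes need no real data or manual annotation.

The generator makes no claim of photorealism: illumination artefacts, colour,
texture and pathology beyond simple bright blobs are absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.morphology import dilation, disk

from .model import TrainingPatch

__all__ = [
    "SyntheticScene",
    "GroundTruth",
    "generate",
    "random_scene",
    "make_training_set",
    "make_test_scenes",
]


@dataclass(frozen=True)
class SyntheticScene:
    """Generative parameters of one synthetic fundus image.

    Intensities are on the 8-bit scale.  ``disc_peak`` and ``fovea_depth``
    are amplitudes relative to the local retinal background; ``fovea_depth``
    near ``noise_sd`` emulates the very poor foveal contrast of real images.
    The same seed always reproduces the identical image.
    """

    image_shape: tuple[int, int] = (500, 500)
    fov_radius: float = 240.0
    disc_centre: tuple[float, float] = (250.0, 110.0)
    disc_diameter: float = 80.0
    disc_peak: float = 100.0
    disc_axis_ratio: float = 1.0  # row/col sigma ratio; 1 = circular
    fovea_centre: tuple[float, float] = (250.0, 310.0)
    fovea_depth: float = 50.0
    arcade_extent: float = 170.0  # vertical half-extent of the arcades, px
    arcade_reach: float = 250.0  # horizontal reach of the arcades, px
    arcade_width_max: float = 8.0
    arcade_width_min: float = 3.0
    vessel_depth: float = 60.0
    n_exudates: int = 0
    exudate_peak: float = 90.0
    exudate_sigma_range: tuple[float, float] = (10.0, 45.0)
    background_base: float = 120.0
    background_gradient: tuple[float, float] = (0.0, 0.02)  # per-pixel slope
    vignette_depth: float = 15.0
    noise_sd: float = 5.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        H, W = self.image_shape
        centre = (H / 2.0, W / 2.0)
        for name, point in (("disc", self.disc_centre), ("fovea", self.fovea_centre)):
            d = np.hypot(point[0] - centre[0], point[1] - centre[1])
            if d + (self.disc_diameter / 2 if name == "disc" else 0) > self.fov_radius:
                raise ValueError(f"{name} centre lies outside the field of view")


@dataclass
class GroundTruth:
    """Exact geometry of a generated scene, for training and evaluation."""

    disc_centre: tuple[float, float]
    fovea_centre: tuple[float, float]
    disc_diameter: float
    vessel_mask: np.ndarray
    fov_mask: np.ndarray
    scene: SyntheticScene

    def summary(self) -> dict:
        return {
            "disc_centre": [float(x) for x in self.disc_centre],
            "fovea_centre": [float(x) for x in self.fovea_centre],
            "disc_diameter": float(self.disc_diameter),
            "rng_seed": int(self.scene.rng_seed),
        }


def _stamp_points(
    canvas: np.ndarray, rows: np.ndarray, cols: np.ndarray, widths: np.ndarray
) -> None:
    """Mark disks of varying radius along a sampled curve on a boolean canvas."""
    H, W = canvas.shape
    for r, c, w in zip(rows, cols, widths):
        rad = max(w / 2.0, 0.5)
        ir, ic = int(round(r)), int(round(c))
        lo_r, hi_r = max(0, ir - int(rad) - 1), min(H, ir + int(rad) + 2)
        lo_c, hi_c = max(0, ic - int(rad) - 1), min(W, ic + int(rad) + 2)
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        yy, xx = np.mgrid[lo_r:hi_r, lo_c:hi_c]
        canvas[lo_r:hi_r, lo_c:hi_c] |= (yy - r) ** 2 + (xx - c) ** 2 <= rad**2


def _render_vessels(scene: SyntheticScene) -> np.ndarray:
    """Boolean centreline+width mask of the arcades and minor branches."""
    mask = np.zeros(scene.image_shape, dtype=bool)
    dr0, dc0 = scene.disc_centre
    scale = scene.disc_diameter / 80.0
    extent = scene.arcade_extent * scale
    reach = scene.arcade_reach * scale
    curvature = reach / extent**2
    t = np.linspace(0.0, 1.0, 400)
    widths = scene.arcade_width_max + t * (
        scene.arcade_width_min - scene.arcade_width_max
    )
    for sign in (1.0, -1.0):
        rows = dr0 + sign * t * extent
        cols = dc0 + curvature * (t * extent) ** 2
        _stamp_points(mask, rows, cols, widths)
    # two thin nasal branches curving away from the macula
    t_thin = np.linspace(0.0, 1.0, 150)
    for sign in (1.0, -1.0):
        rows = dr0 + sign * t_thin * 0.7 * extent
        cols = dc0 - 0.5 * curvature * (t_thin * 0.7 * extent) ** 2
        _stamp_points(mask, rows, cols, np.full_like(t_thin, 2.0))
    return mask


def generate(scene: SyntheticScene) -> tuple[np.ndarray, GroundTruth]:
    """Render a scene to an 8-bit grayscale image plus its ground truth.

    By construction (noise off, no exudates) the brightest in-FOV pixel lies
    inside the disc and the darkest in-FOV non-vessel pixel inside the fovea.
    """
    H, W = scene.image_shape
    rng = np.random.default_rng(scene.rng_seed)
    rows, cols = np.mgrid[0:H, 0:W].astype(float)

    centre = (H / 2.0, W / 2.0)
    radial = np.hypot(rows - centre[0], cols - centre[1])
    fov = radial <= scene.fov_radius

    gr, gc = scene.background_gradient
    img = (
        scene.background_base
        + gr * (rows - centre[0])
        + gc * (cols - centre[1])
        - scene.vignette_depth * (radial / scene.fov_radius) ** 2
    )

    # optic disc: bright Gaussian, optionally elliptical
    sig_c = scene.disc_diameter / 3.0
    sig_r = sig_c * scene.disc_axis_ratio
    img += scene.disc_peak * np.exp(
        -(
            (rows - scene.disc_centre[0]) ** 2 / (2 * sig_r**2)
            + (cols - scene.disc_centre[1]) ** 2 / (2 * sig_c**2)
        )
    )

    # fovea: shallow dark Gaussian pit
    fov_sigma = 15.0 * scene.disc_diameter / 80.0
    img -= scene.fovea_depth * np.exp(
        -(
            (rows - scene.fovea_centre[0]) ** 2
            + (cols - scene.fovea_centre[1]) ** 2
        )
        / (2 * fov_sigma**2)
    )

    vessel_core = _render_vessels(scene)
    img -= scene.vessel_depth * gaussian_filter(vessel_core.astype(float), 1.0)

    for _ in range(scene.n_exudates):
        # placed in the temporal half, away from the disc itself
        for _attempt in range(50):
            er = rng.uniform(centre[0] - 0.7 * scene.fov_radius,
                             centre[0] + 0.7 * scene.fov_radius)
            ec = rng.uniform(centre[1] - 0.7 * scene.fov_radius,
                             centre[1] + 0.7 * scene.fov_radius)
            if np.hypot(er - scene.disc_centre[0], ec - scene.disc_centre[1]) > (
                scene.disc_diameter
            ):
                break
        esig = rng.uniform(*scene.exudate_sigma_range)
        img += scene.exudate_peak * np.exp(
            -((rows - er) ** 2 + (cols - ec) ** 2) / (2 * esig**2)
        )

    img = np.where(fov, img, 4.0)
    if scene.noise_sd > 0:
        img = img + rng.normal(0.0, scene.noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    # vessel ground truth includes the anti-aliased skirt of the rendering
    vessel_mask = dilation(vessel_core, disk(3))
    truth = GroundTruth(
        disc_centre=scene.disc_centre,
        fovea_centre=scene.fovea_centre,
        disc_diameter=scene.disc_diameter,
        vessel_mask=vessel_mask,
        fov_mask=fov,
        scene=scene,
    )
    return img, truth


def random_scene(seed_source, **overrides) -> SyntheticScene:
    """Sample a plausible left-eye scene: disc size varied +/-20 %, fovea at
    ~2.5 disc diameters along the raphe with small angular jitter.

    ``seed_source`` is an integer seed or a :class:`numpy.random.Generator`.
    Field values passed as keyword arguments override the sampled ones.
    """
    rng = (
        seed_source
        if isinstance(seed_source, np.random.Generator)
        else np.random.default_rng(seed_source)
    )
    diameter = float(rng.uniform(64.0, 96.0))
    disc_centre = (float(rng.uniform(210.0, 290.0)), float(rng.uniform(95.0, 140.0)))
    dist = float(rng.uniform(2.4, 2.6)) * diameter
    angle = float(rng.uniform(-0.15, 0.15))  # radians off the horizontal raphe
    fovea_centre = (
        disc_centre[0] + dist * np.sin(angle),
        disc_centre[1] + dist * np.cos(angle),
    )
    params = {
        "disc_centre": disc_centre,
        "disc_diameter": diameter,
        "disc_peak": float(rng.uniform(85.0, 115.0)),
        "disc_axis_ratio": float(rng.uniform(0.85, 1.15)),
        "fovea_centre": fovea_centre,
        "fovea_depth": float(rng.uniform(40.0, 60.0)),
        "background_gradient": (
            float(rng.uniform(-0.02, 0.02)),
            float(rng.uniform(-0.02, 0.03)),
        ),
        "rng_seed": int(rng.integers(0, 2**31 - 1)),
    }
    params.update(overrides)
    return SyntheticScene(**params)


def _centre_to_corner(centre: tuple[float, float], side: int) -> tuple[int, int]:
    half = (side + 1) // 2
    return (int(round(centre[0])) - half, int(round(centre[1])) - half)


def make_training_set(
    n_scenes: int,
    landmark: str = "disc",
    patch_size: int = 100,
    rng_seed: int = 0,
    jitter: int = 5,
    **scene_overrides,
) -> tuple[list[TrainingPatch], list[GroundTruth]]:
    """Crop one training patch per synthetic scene, centred on the landmark.

    The crop centre is jittered by up to ``jitter`` pixels per axis to mimic
    the variability of human-graded landmark centres.  The seed stream is
    disjoint from :func:`make_test_scenes` for every ``rng_seed``, so models
    are never evaluated on their own training scenes.

    Returns the patches plus the ground-truth records of the source scenes.
    """
    if n_scenes < 2:
        raise ValueError("need at least 2 training scenes")
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 0]))
    patches: list[TrainingPatch] = []
    truths: list[GroundTruth] = []
    for i in range(n_scenes):
        scene = random_scene(rng, **scene_overrides)
        image, truth = generate(scene)
        centre = truth.disc_centre if landmark == "disc" else truth.fovea_centre
        if jitter > 0:
            centre = (
                centre[0] + rng.integers(-jitter, jitter + 1),
                centre[1] + rng.integers(-jitter, jitter + 1),
            )
        corner = _centre_to_corner(centre, patch_size)
        H, W = image.shape
        if not (0 <= corner[0] <= H - patch_size and 0 <= corner[1] <= W - patch_size):
            raise ValueError("training patch would exceed image bounds")
        crop = image[
            corner[0] : corner[0] + patch_size, corner[1] : corner[1] + patch_size
        ].astype(float)
        patches.append(
            TrainingPatch(pixels=crop, source_id=f"synthetic-{i}", landmark=landmark)
        )
        truths.append(truth)
    return patches, truths


def make_test_scenes(
    n_scenes: int, rng_seed: int = 0, **scene_overrides
) -> list[tuple[np.ndarray, GroundTruth]]:
    """Generate held-out evaluation scenes on a seed stream disjoint from training."""
    rng = np.random.default_rng(np.random.SeedSequence([rng_seed, 1]))
    out = []
    for _ in range(n_scenes):
        scene = random_scene(rng, **scene_overrides)
        out.append(generate(scene))
    return out
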