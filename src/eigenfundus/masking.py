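"""Candidate-region masking to restrict the coarse eigen-template scan.

Three complementary strategies narrow the sliding-window search:

* **Vessel-tree masking.**  The optic disc sits at the junction of the thick
  vascular arcades, while the fovea is avascular.  Given a binary vessel tree,
  disc candidates are grid cells whose patch footprint contains enough thick
  vessel pixels; fovea candidates are cells whose footprint is (nearly) free
  of thick vessels.
* **Intensity clustering.**  The disc is typically the brightest structure and
  the fovea the darkest non-vessel structure inside the field of view, so
  connected clusters of extreme-quantile pixels seed candidate cells.
* **Fovea distance prior.**  The fovea lies at roughly 2.5 optic-disc
  diameters from the disc centre; once the disc is localized an annulus of
  cells around it is admissible.

A generic multi-orientation Gaussian matched filter is included to extract a
binary vessel tree when none is supplied; any externally produced vessel mask
may be used instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from scipy.signal import fftconvolve
from skimage.measure import label
from skimage.morphology import convex_hull_image, disk, opening

from .errors import GeometryError
from .matching import GridGeometry, Localization

__all__ = [
    "CandidateMask",
    "VesselTree",
    "matched_filter_vessels",
    "mask_from_vessels",
    "intensity_cluster_candidates",
    "fovea_annulus_prior",
    "fill_fov_border",
    "estimate_fov_mask",
]


@dataclass
class CandidateMask:
    """Boolean admissibility grid aligned with a distance map's geometry."""

    admissible: np.ndarray
    geometry: GridGeometry
    strategy: str

    def __and__(self, other: "CandidateMask") -> "CandidateMask":
        if self.geometry != other.geometry:
            raise GeometryError("cannot combine masks with different geometries")
        return CandidateMask(
            admissible=self.admissible & other.admissible,
            geometry=self.geometry,
            strategy=f"{self.strategy}&{other.strategy}",
        )

    @property
    def n_admissible(self) -> int:
        return int(self.admissible.sum())


@dataclass
class VesselTree:
    """Binary vessel segmentation plus its thick-vessel subset.

    ``thick`` marks vessels wide enough to survive a morphological opening;
    it is always a subset of ``binary``.
    """

    binary: np.ndarray
    thick: np.ndarray

    def __post_init__(self) -> None:
        if self.binary.shape != self.thick.shape:
            raise GeometryError("binary and thick vessel images must share a shape")


def _line_kernel(sigma: float, length: int, theta: float) -> np.ndarray:
    """Rotated negative-Gaussian line kernel with zero mean over its support."""
    half_w = int(np.ceil(3 * sigma))
    half_l = length // 2
    half = max(half_w, half_l)
    yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    # rotate coordinates: x' across the line, y' along it
    x_r = xx * np.cos(theta) + yy * np.sin(theta)
    y_r = -xx * np.sin(theta) + yy * np.cos(theta)
    support = (np.abs(y_r) <= half_l) & (np.abs(x_r) <= half_w)
    kernel = np.where(support, -np.exp(-(x_r**2) / (2 * sigma**2)), 0.0)
    kernel[support] -= kernel[support].mean()
    return kernel


def matched_filter_vessels(
    image: np.ndarray,
    sigma: float = 2.0,
    length: int = 9,
    n_orientations: int = 12,
    threshold_quantile: float = 0.98,
    thickness_radius: int = 2,
    fov_mask: np.ndarray | None = None,
) -> VesselTree:
    """Extract a binary vessel tree with a multi-orientation matched filter.

    Vessels present a dark Gaussian cross-section, so the maximum response
    over ``n_orientations`` rotated negative-Gaussian line kernels is large on
    vessel centrelines.  The response is thresholded at
    ``threshold_quantile`` of the in-FOV response distribution; the thick
    subset is the binary tree after opening with a disc of
    ``thickness_radius`` pixels (keeping vessels of width >= roughly
    ``2 * thickness_radius + 1``).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if img.max() == img.min():  # featureless image: nothing to detect
        empty = np.zeros(img.shape, dtype=bool)
        return VesselTree(binary=empty, thick=empty.copy())
    response = np.full(img.shape, -np.inf)
    for i in range(n_orientations):
        theta = np.pi * i / n_orientations
        resp = fftconvolve(img, _line_kernel(sigma, length, theta), mode="same")
        np.maximum(response, resp, out=response)

    if fov_mask is None:
        fov_mask = np.ones(img.shape, dtype=bool)
    in_fov = response[fov_mask]
    if in_fov.size == 0:
        raise ValueError("empty field-of-view mask")
    thresh = np.quantile(in_fov, threshold_quantile)
    binary = (response >= thresh) & fov_mask
    thick = opening(binary, disk(thickness_radius))
    return VesselTree(binary=binary, thick=thick)


def _footprint_counts(pixel_mask: np.ndarray, geometry: GridGeometry) -> np.ndarray:
    """Pixel counts of a boolean image inside every grid cell's patch footprint."""
    if pixel_mask.shape != geometry.image_shape:
        raise GeometryError(
            f"mask shape {pixel_mask.shape} != image shape {geometry.image_shape}"
        )
    n, s = geometry.patch_size, geometry.step
    gr, gc = geometry.grid_shape
    # integral image with zero padding at top/left
    integral = np.zeros((pixel_mask.shape[0] + 1, pixel_mask.shape[1] + 1))
    np.cumsum(np.cumsum(pixel_mask, axis=0), axis=1, out=integral[1:, 1:])
    r0 = geometry.origin[0] + np.arange(gr) * s
    c0 = geometry.origin[1] + np.arange(gc) * s
    r1, c1 = r0 + n, c0 + n
    return (
        integral[np.ix_(r1, c1)]
        - integral[np.ix_(r0, c1)]
        - integral[np.ix_(r1, c0)]
        + integral[np.ix_(r0, c0)]
    ).astype(int)


def mask_from_vessels(
    tree: VesselTree,
    geometry: GridGeometry,
    landmark: str,
    min_thick_pixels: int = 50,
    max_thick_pixels: int = 0,
) -> CandidateMask:
    """Admissibility from thick-vessel content of each patch footprint.

    Disc: a cell is admissible iff its footprint contains at least
    ``min_thick_pixels`` thick-vessel pixels (the disc lies at the arcade
    junction).  Fovea: admissible iff the footprint contains at most
    ``max_thick_pixels`` thick-vessel pixels (the fovea is avascular).
    """
    counts = _footprint_counts(tree.thick, geometry)
    if landmark == "disc":
        admissible = counts >= min_thick_pixels
        strategy = "vessel_require"
    elif landmark == "fovea":
        admissible = counts <= max_thick_pixels
        strategy = "vessel_exclude"
    else:
        raise ValueError(f"unknown landmark {landmark!r}")
    return CandidateMask(admissible=admissible, geometry=geometry, strategy=strategy)


def intensity_cluster_candidates(
    image: np.ndarray,
    geometry: GridGeometry,
    landmark: str,
    quantile: float | None = None,
    min_cluster_px: int = 100,
    fov_mask: np.ndarray | None = None,
    vessel_mask: np.ndarray | None = None,
) -> CandidateMask:
    """Admissibility from connected clusters of extreme-intensity pixels.

    For the disc the upper intensity tail is clustered (default quantile
    0.98); for the fovea the lower tail (default 0.05), with vessel pixels
    excluded beforehand since vessels are as dark as the fovea.  Connected
    components of at least ``min_cluster_px`` pixels become candidate
    regions; a cell is admissible when its patch footprint intersects one.
    """
    img = np.asarray(image, dtype=float)
    if fov_mask is None:
        fov_mask = estimate_fov_mask(img)
    if not fov_mask.any():
        raise ValueError("empty field-of-view mask")
    eligible = fov_mask.copy()
    if landmark == "fovea" and vessel_mask is not None:
        eligible &= ~vessel_mask

    vals = img[eligible]
    if vals.max() == vals.min():
        # constant region: no pixel is an intensity extreme
        strategy = "bright_cluster" if landmark == "disc" else "dark_cluster"
        return CandidateMask(
            admissible=np.zeros(geometry.grid_shape, dtype=bool),
            geometry=geometry,
            strategy=strategy,
        )
    if landmark == "disc":
        q = 0.98 if quantile is None else quantile
        extreme = eligible & (img >= np.quantile(vals, q))
        strategy = "bright_cluster"
    elif landmark == "fovea":
        q = 0.05 if quantile is None else quantile
        extreme = eligible & (img <= np.quantile(vals, q))
        strategy = "dark_cluster"
    else:
        raise ValueError(f"unknown landmark {landmark!r}")

    labels_img = label(extreme, connectivity=2)
    counts = np.bincount(labels_img.ravel())
    keep = np.zeros(counts.size, dtype=bool)
    keep[1:] = counts[1:] >= min_cluster_px
    clusters = keep[labels_img]
    admissible = _footprint_counts(clusters, geometry) > 0
    return CandidateMask(admissible=admissible, geometry=geometry, strategy=strategy)


def fovea_annulus_prior(
    disc_localization: Localization,
    disc_diameter: float,
    geometry: GridGeometry,
    tolerance_fraction: float = 0.2,
) -> CandidateMask:
    """Admissible cells whose patch centre lies ~2.5 disc diameters from the disc.

    The annulus spans ``[2.5 * (1 - tol), 2.5 * (1 + tol)]`` disc diameters
    of Euclidean distance from the disc centre; it is clipped implicitly by
    the grid, so a disc near the image border simply yields fewer cells.
    """
    if disc_diameter <= 0:
        raise ValueError("disc diameter must be positive")
    rr, cc = geometry.cell_centres()
    dr = rr - disc_localization.centre[0]
    dc = cc - disc_localization.centre[1]
    dist = np.hypot(dr, dc)
    lo = 2.5 * (1 - tolerance_fraction) * disc_diameter
    hi = 2.5 * (1 + tolerance_fraction) * disc_diameter
    return CandidateMask(
        admissible=(dist >= lo) & (dist <= hi),
        geometry=geometry,
        strategy="fovea_annulus",
    )


def estimate_fov_mask(image: np.ndarray) -> np.ndarray:
    """Heuristic circular field-of-view mask for an unannotated fundus image.

    The histogram of a fundus photograph is bimodal — near-black camera
    surround against the bright retina — so an Otsu threshold separates the
    two; the largest connected foreground component's convex hull is the FOV.
    A constant image (no surround at all) maps to an all-true mask.
    """
    img = np.asarray(image, dtype=float)
    if img.max() == img.min():
        return np.ones(img.shape, dtype=bool)
    from skimage.filters import threshold_otsu

    fg = img > threshold_otsu(img)
    if not fg.any():
        return np.ones(img.shape, dtype=bool)
    labels_img = label(fg, connectivity=2)
    counts = np.bincount(labels_img.ravel())
    counts[0] = 0
    biggest = labels_img == np.argmax(counts)
    return convex_hull_image(biggest)


def fill_fov_border(image: np.ndarray, fov_mask: np.ndarray) -> np.ndarray:
    """Replace out-of-FOV pixels with their nearest in-FOV neighbour's value.

    Fundus images have near-black corners outside the camera aperture that
    would otherwise dominate dark-cluster fovea candidates; in-FOV pixels are
    returned untouched.
    """
    img = np.asarray(image, dtype=float)
    fov_mask = np.asarray(fov_mask, dtype=bool)
    if img.shape != fov_mask.shape:
        raise GeometryError("image and FOV mask shapes differ")
    if not fov_mask.any():
        raise ValueError("FOV mask marks no in-retina pixels")
    if fov_mask.all():
        return img.copy()
    _, (ir, ic) = ndimage.distance_transform_edt(~fov_mask, return_indices=True)
    return img[ir, ic]
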