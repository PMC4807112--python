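"""High-level localization pipeline: masking setup, eye-side handling.

Ties the model, matching and masking layers together behind one call, the
same path the command-line interface uses.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .config import RunConfig
from .errors import NoCandidatesError
from .masking import (
    CandidateMask,
    estimate_fov_mask,
    fill_fov_border,
    fovea_annulus_prior,
    intensity_cluster_candidates,
    mask_from_vessels,
    matched_filter_vessels,
)
from .matching import GridGeometry, LocateResult, Localization, locate
from .model import EigenTemplateModel

__all__ = ["PipelineResult", "build_candidate_mask", "locate_landmark"]


@dataclass
class PipelineResult:
    """A :class:`LocateResult` plus bookkeeping of the orientation and mask."""

    result: LocateResult
    flipped: bool
    mask: CandidateMask | None

    @property
    def best(self) -> Localization:
        return self.result.best


def build_candidate_mask(
    image: np.ndarray,
    geometry: GridGeometry,
    cfg: RunConfig,
    vessel_mask: np.ndarray | None = None,
    fov_mask: np.ndarray | None = None,
    disc_localization: Localization | None = None,
    disc_diameter: float | None = None,
) -> CandidateMask | None:
    """Conjunction of the candidate strategies enabled in the config.

    ``vessel_mask`` (a binary vessel image) bypasses the built-in matched
    filter when supplied.  The ``annulus`` strategy needs a prior disc
    localization and diameter and is skipped with a ``ValueError`` otherwise.
    """
    if not cfg.masking:
        return None
    if fov_mask is None:
        fov_mask = estimate_fov_mask(image)
    mask: CandidateMask | None = None
    tree = None
    for strategy in cfg.masking:
        if strategy == "vessel":
            if tree is None:
                tree = _vessel_tree(image, cfg, vessel_mask, fov_mask)
            part = mask_from_vessels(
                tree,
                geometry,
                cfg.landmark,
                min_thick_pixels=cfg.min_thick_pixels,
                max_thick_pixels=cfg.max_thick_pixels,
            )
        elif strategy == "cluster":
            vm = None
            if cfg.landmark == "fovea":
                if tree is None:
                    tree = _vessel_tree(image, cfg, vessel_mask, fov_mask)
                vm = tree.binary
            part = intensity_cluster_candidates(
                image,
                geometry,
                cfg.landmark,
                quantile=cfg.cluster_quantile,
                min_cluster_px=cfg.min_cluster_px,
                fov_mask=fov_mask,
                vessel_mask=vm,
            )
        elif strategy == "annulus":
            if disc_localization is None or disc_diameter is None:
                raise ValueError(
                    "annulus masking needs a disc localization and diameter"
                )
            part = fovea_annulus_prior(
                disc_localization,
                disc_diameter,
                geometry,
                tolerance_fraction=cfg.annulus_tolerance,
            )
        else:
            raise ValueError(f"unknown masking strategy {strategy!r}")
        mask = part if mask is None else mask & part
    return mask


def _vessel_tree(image, cfg: RunConfig, vessel_mask, fov_mask):
    from .masking import VesselTree
    from skimage.morphology import disk, opening

    if vessel_mask is not None:
        binary = np.asarray(vessel_mask, dtype=bool)
        return VesselTree(
            binary=binary,
            thick=opening(binary, disk(cfg.vessel_thickness_radius)),
        )
    return matched_filter_vessels(
        image,
        sigma=cfg.vessel_sigma,
        n_orientations=cfg.vessel_n_orientations,
        threshold_quantile=cfg.vessel_threshold_quantile,
        thickness_radius=cfg.vessel_thickness_radius,
        fov_mask=fov_mask,
    )


def _locate_one_side(
    model: EigenTemplateModel,
    image: np.ndarray,
    cfg: RunConfig,
    vessel_mask,
    fov_mask,
    disc_localization,
    disc_diameter,
) -> LocateResult:
    # the FOV is estimated from the raw image: border filling makes the whole
    # frame look in-FOV afterwards
    if fov_mask is None and (cfg.masking or cfg.fill_border):
        fov_mask = estimate_fov_mask(image)
    work = image
    if cfg.landmark == "fovea" and cfg.fill_border:
        work = fill_fov_border(image, fov_mask)
    geometry = GridGeometry(work.shape, model.n, cfg.step)
    mask = build_candidate_mask(
        work,
        geometry,
        cfg,
        vessel_mask=vessel_mask,
        fov_mask=fov_mask,
        disc_localization=disc_localization,
        disc_diameter=disc_diameter,
    )
    return locate(
        model,
        work,
        step=cfg.step,
        k=cfg.k_minima,
        window=cfg.refine_window,
        mask=mask,
        mode=cfg.score_mode,
    )


def _flip_result(res: LocateResult, width: int) -> LocateResult:
    """Map a result computed on the mirrored image back to the original frame."""

    def flip_loc(loc: Localization) -> Localization:
        return replace(loc, corner=(loc.corner[0], width - loc.side - loc.corner[1]))

    return LocateResult(
        best=flip_loc(res.best),
        candidates=[flip_loc(c) for c in res.candidates],
        distance_map=res.distance_map,
        patches_scored=res.patches_scored,
        patches_total=res.patches_total,
    )


def locate_landmark(
    model: EigenTemplateModel,
    image: np.ndarray,
    cfg: RunConfig,
    vessel_mask: np.ndarray | None = None,
    fov_mask: np.ndarray | None = None,
    disc_localization: Localization | None = None,
    disc_diameter: float | None = None,
) -> PipelineResult:
    """Localize the model's landmark in an image under a run configuration.

    Eye-side handling: models are trained in left-eye orientation.  A
    declared right eye is mirrored before matching and the result mapped
    back; with ``eye_side='auto'`` both orientations are evaluated and the
    lower-error one wins.  Coordinates are always reported in the frame of
    the input image.
    """
    image = np.asarray(image, dtype=float)
    width = image.shape[1]
    sides = {
        "left": [False],
        "right": [True],
        "auto": [False, True],
    }[cfg.eye_side]

    outcomes: list[PipelineResult] = []
    errors: list[Exception] = []
    for flipped in sides:
        work = image[:, ::-1] if flipped else image
        vm = vessel_mask[:, ::-1] if (flipped and vessel_mask is not None) else vessel_mask
        fm = fov_mask[:, ::-1] if (flipped and fov_mask is not None) else fov_mask
        dl = disc_localization
        if flipped and disc_localization is not None:
            dl = replace(
                disc_localization,
                corner=(
                    disc_localization.corner[0],
                    width - disc_localization.side - disc_localization.corner[1],
                ),
            )
        try:
            res = _locate_one_side(model, work, cfg, vm, fm, dl, disc_diameter)
        except NoCandidatesError as exc:
            errors.append(exc)
            continue
        if flipped:
            res = _flip_result(res, width)
        outcomes.append(PipelineResult(result=res, flipped=flipped, mask=None))
    if not outcomes:
        raise errors[0] if errors else NoCandidatesError("no orientation produced candidates")
    return min(outcomes, key=lambda o: o.best.error)
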