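"""Training of eigen-template models from landmark patches.

An eigen-template model is a PCA decomposition of a small set of square
grayscale training patches, each cropped from a different retinal image and
centred on the same anatomical landmark (the optic disc or the fovea).  Each
patch is contrast-normalized to the full 8-bit range, the mean patch is
subtracted, and the centered patches are flattened row-major into the columns
of a data matrix ``D`` of shape ``(n**2, N)``.  The ``N x N`` covariance
``C = D.T @ D / N`` is eigen-decomposed; the matrix of its eigenvectors
(rows ordered by descending eigenvalue) is called ``featvec``, and the
eigen-templates are the rows of ``finaldat1 = featvec @ D.T`` — linear
combinations of the centered training patches, one per principal component.
The scalar ``sum1`` is the total squared energy of the eigen-templates and is
the constant offset of the literal matching error used at test time.

All intensities are kept as real numbers after normalization; nothing is
quantized back to integers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegeneratePatchError

__all__ = [
    "TrainingPatch",
    "EigenTemplateModel",
    "normalize_patch",
    "compute_mean",
    "center_and_flatten",
    "build_data_matrix",
    "covariance",
    "eigen_decompose",
    "train",
    "save_model",
    "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass(frozen=True)
class TrainingPatch:
    """A square grayscale crop centred on a landmark in one retinal image.

    Parameters
    ----------
    pixels
        ``(n, n)`` array of intensities; non-negative and finite.
    source_id
        Identifier of the retinal image the crop came from.
    landmark
        Either ``"disc"`` or ``"fovea"``.
    """

    pixels: np.ndarray
    source_id: str = ""
    landmark: str = "disc"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.shape[0] != px.shape[1]:
            raise ValueError(f"patch must be square, got shape {px.shape}")
        if px.shape[0] < 2:
            raise ValueError("patch side must be >= 2")
        if not np.all(np.isfinite(px)) or np.any(px < 0):
            raise ValueError("patch values must be finite and non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def _as_patch_array(patch) -> np.ndarray:
    if isinstance(patch, TrainingPatch):
        return patch.pixels
    arr = np.asarray(patch, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise ValueError(f"patch must be a square 2-D array, got shape {arr.shape}")
    return arr


def normalize_patch(patch) -> np.ndarray:
    """Stretch a patch's intensities linearly onto [0, 255].

    ``out = (patch - min(patch)) / max(patch - min(patch)) * 255``.  The
    output is real-valued; a patch already spanning [0, 255] is returned
    unchanged (up to floating point).

    Raises
    ------
    DegeneratePatchError
        If the patch is constant (zero intensity range).
    """
    arr = _as_patch_array(patch)
    mn = arr.min()
    rng = (arr - mn).max()
    if rng == 0:
        raise DegeneratePatchError("constant patch has zero intensity range")
    return (arr - mn) / rng * 255.0


def compute_mean(patches: Sequence) -> np.ndarray:
    """Element-wise mean of a non-empty list of same-sized normalized patches."""
    if len(patches) == 0:
        raise ValueError("need at least one patch")
    arrs = [_as_patch_array(p) for p in patches]
    n = arrs[0].shape[0]
    if any(a.shape != (n, n) for a in arrs):
        raise ValueError("all patches must share the same side length")
    return np.mean(arrs, axis=0)


def center_and_flatten(patch, mean_image: np.ndarray) -> np.ndarray:
    """Subtract the mean patch and flatten row-major to a length-``n**2`` vector.

    Row-major order lists row 0 completely before row 1, so element ``[r, c]``
    lands at flat index ``r * n + c``.
    """
    arr = _as_patch_array(patch)
    mean_image = np.asarray(mean_image, dtype=float)
    if arr.shape != mean_image.shape:
        raise ValueError(
            f"patch shape {arr.shape} does not match mean image {mean_image.shape}"
        )
    return (arr - mean_image).ravel(order="C")


def build_data_matrix(flattened: Sequence[np.ndarray]) -> np.ndarray:
    """Stack flattened centered patches as the columns of an ``(n**2, N)`` matrix."""
    vecs = [np.asarray(v, dtype=float).ravel() for v in flattened]
    if len(vecs) == 0:
        raise ValueError("need at least one vector")
    length = vecs[0].size
    if any(v.size != length for v in vecs):
        raise ValueError("all flattened patches must have the same length")
    return np.column_stack(vecs)


def covariance(D: np.ndarray) -> np.ndarray:
    """Patch-space covariance ``C = D.T @ D / N`` (divisor ``N``, not ``N - 1``)."""
    D = np.asarray(D, dtype=float)
    if D.ndim != 2:
        raise ValueError("D must be a 2-D matrix")
    N = D.shape[1]
    return D.T @ D / N


def eigen_decompose(C: np.ndarray) -> np.ndarray:
    """Orthonormal eigenvectors of a symmetric matrix, rows sorted by eigenvalue.

    Returns the ``(N, N)`` matrix whose row ``k`` is the unit eigenvector for
    the ``k``-th largest eigenvalue.  Two conventions make the output
    deterministic: eigenvalue ties keep a stable order, and each row is
    flipped so that its first nonzero component is positive.
    """
    C = np.asarray(C, dtype=float)
    if not np.all(np.isfinite(C)):
        raise ValueError("covariance matrix contains non-finite entries")
    C = (C + C.T) / 2.0  # absorb round-off asymmetry
    eigvals, eigvecs = np.linalg.eigh(C)
    order = np.argsort(-eigvals, kind="stable")
    featvec = eigvecs[:, order].T
    # sign rule: first component of each row with magnitude above tolerance > 0
    for row in featvec:
        nz = np.flatnonzero(np.abs(row) > 1e-12)
        if nz.size and row[nz[0]] < 0:
            row *= -1.0
    return featvec


@dataclass
class EigenTemplateModel:
    """Trained eigen-template model for one landmark.

    Attributes
    ----------
    n
        Patch side length in pixels.
    n_patches
        Number of training patches ``N``.
    mean_image
        ``(n, n)`` mean of the normalized training patches.
    featvec
        ``(N, N)`` eigenvector matrix of the covariance, rows in descending
        eigenvalue order.
    finaldat1
        ``(N, n**2)`` eigen-template matrix ``featvec @ D.T``.
    sum1
        Sum of squares of all entries of ``finaldat1``.
    landmark
        ``"disc"`` or ``"fovea"``.
    eye_side_convention
        Orientation the model was trained in; always ``"left"`` (right-eye
        source patches are mirrored before training).
    """

    n: int
    n_patches: int
    mean_image: np.ndarray
    featvec: np.ndarray
    finaldat1: np.ndarray
    sum1: float
    landmark: str = "disc"
    eye_side_convention: str = "left"
    _basis: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def mean_flat(self) -> np.ndarray:
        return self.mean_image.ravel(order="C")

    def projection_basis(self) -> np.ndarray:
        """Orthonormal basis (columns) of the span of the eigen-templates.

        Used by reconstruction-mode scoring; computed lazily and cached.  The
        span equals the column space of the centered data matrix, whose rank
        is at most ``N - 1`` because the centered patches sum to zero.
        """
        if self._basis is None:
            from scipy.linalg import orth

            self._basis = orth(self.finaldat1.T)
        return self._basis


def train(patches: Sequence, landmark: str | None = None) -> EigenTemplateModel:
    """Build an :class:`EigenTemplateModel` from at least two training patches.

    Patches must share one side length and, when given as
    :class:`TrainingPatch`, one landmark label.  Patches cropped from
    right-eye images must already be mirrored to left-eye orientation.
    """
    if len(patches) < 2:
        raise ValueError("training needs at least 2 patches")
    labels = {p.landmark for p in patches if isinstance(p, TrainingPatch)}
    if len(labels) > 1:
        raise ValueError(f"mixed landmark labels in training set: {sorted(labels)}")
    if landmark is None:
        landmark = labels.pop() if labels else "disc"

    normalized = [normalize_patch(p) for p in patches]
    n = normalized[0].shape[0]
    if any(p.shape != (n, n) for p in normalized):
        raise ValueError("all training patches must share the same side length")
    mean_image = compute_mean(normalized)
    flattened = [center_and_flatten(p, mean_image) for p in normalized]
    D = build_data_matrix(flattened)
    C = covariance(D)
    featvec = eigen_decompose(C)
    finaldat1 = featvec @ D.T
    sum1 = float(np.sum(finaldat1**2))
    return EigenTemplateModel(
        n=n,
        n_patches=len(patches),
        mean_image=mean_image,
        featvec=featvec,
        finaldat1=finaldat1,
        sum1=sum1,
        landmark=landmark,
    )


def save_model(model: EigenTemplateModel, path: str | Path) -> None:
    """Persist a model to a single ``.npz`` archive with a version tag."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "n": model.n,
        "n_patches": model.n_patches,
        "sum1": model.sum1,
        "landmark": model.landmark,
        "eye_side_convention": model.eye_side_convention,
    }
    np.savez_compressed(
        Path(path),
        mean_image=model.mean_image,
        featvec=model.featvec,
        finaldat1=model.finaldat1,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
    )


def load_model(path: str | Path) -> EigenTemplateModel:
    """Load a model saved by :func:`save_model`."""
    with np.load(Path(path)) as archive:
        meta = json.loads(archive["meta"].tobytes().decode())
        if meta.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(
                f"unsupported model format version {meta.get('format_version')}"
            )
        return EigenTemplateModel(
            n=int(meta["n"]),
            n_patches=int(meta["n_patches"]),
            mean_image=archive["mean_image"],
            featvec=archive["featvec"],
            finaldat1=archive["finaldat1"],
            sum1=float(meta["sum1"]),
            landmark=meta["landmark"],
            eye_side_convention=meta["eye_side_convention"],
        )
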