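"""Image and result input/output: readers, overlays, distance-map export.

Fundus photographs are commonly RGB; the green channel carries the best
vessel/landmark contrast and is used by default when a colour image is read.
All pixel coordinates in this package are 0-based ``(row, col)`` with the
origin at the top-left; localizations can additionally be exported with
bottom-left-corner coordinates for parity with display-oriented conventions.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np

from .matching import DistanceMap, Localization

__all__ = [
    "read_image",
    "write_image",
    "flip_to_left",
    "read_manifest",
    "render_overlay",
    "distance_map_to_png16",
    "write_distance_map_text",
    "localizations_to_records",
    "write_localizations_json",
    "write_localizations_csv",
]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


def read_image(path: str | Path, channel: str = "green") -> np.ndarray:
    """Read a grayscale image; colour inputs are reduced to one channel."""
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., _CHANNELS[channel]]
    return np.asarray(arr, dtype=float)

def write_image(path: str | Path, image: np.ndarray) -> None:
    iio.imwrite(Path(path), np.clip(image, 0, 255).astype(np.uint8))


def flip_to_left(image: np.ndarray, eye_side: str) -> np.ndarray:
    """Mirror right-eye images horizontally so the disc sits on the left."""
    if eye_side == "left":
        return np.asarray(image)
    if eye_side == "right":
        return np.asarray(image)[:, ::-1]
    raise ValueError(f"eye_side must be 'left' or 'right', got {eye_side!r}")


@dataclass(frozen=True)
class ManifestRow:
    """One training crop: source image, top-left corner, side, eye side."""

    image_path: str
    corner_row: int
    corner_col: int
    side: int
    eye_side: str = "left"


def read_manifest(path: str | Path) -> list[ManifestRow]:
    """Read a CSV manifest of training crops.

    Columns: ``image_path, corner_row, corner_col, side, eye_side``; a header
    row is required.  ``image_path`` is resolved relative to the manifest.
    """
    path = Path(path)
    rows: list[ManifestRow] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append(
                ManifestRow(
                    image_path=str((path.parent / rec["image_path"]).resolve()),
                    corner_row=int(rec["corner_row"]),
                    corner_col=int(rec["corner_col"]),
                    side=int(rec["side"]),
                    eye_side=rec.get("eye_side", "left").strip() or "left",
                )
            )
    if not rows:
        raise ValueError(f"manifest {path} lists no crops")
    return rows


_RANK_COLOURS = [(255, 40, 40), (255, 200, 0), (40, 220, 40), (60, 120, 255)]


def render_overlay(
    image: np.ndarray, localizations: Sequence[Localization], thickness: int = 2
) -> np.ndarray:
    """Draw bounding squares and centre crosses on an RGB copy of the image."""
    base = np.clip(np.asarray(image, dtype=float), 0, 255).astype(np.uint8)
    if base.ndim == 2:
        rgb = np.stack([base] * 3, axis=-1)
    else:
        rgb = base.copy()
    H, W = rgb.shape[:2]
    for loc in localizations:
        colour = _RANK_COLOURS[loc.rank % len(_RANK_COLOURS)]
        r0, c0 = loc.corner
        r1, c1 = r0 + loc.side - 1, c0 + loc.side - 1
        for t in range(thickness):
            rr0, cc0 = np.clip(r0 + t, 0, H - 1), np.clip(c0 + t, 0, W - 1)
            rr1, cc1 = np.clip(r1 - t, 0, H - 1), np.clip(c1 - t, 0, W - 1)
            rgb[rr0, max(c0, 0) : c1 + 1] = colour
            rgb[rr1, max(c0, 0) : c1 + 1] = colour
            rgb[max(r0, 0) : r1 + 1, cc0] = colour
            rgb[max(r0, 0) : r1 + 1, cc1] = colour
        cr, cc = loc.centre
        arm = 4
        rgb[np.clip(cr, 0, H - 1), max(cc - arm, 0) : cc + arm + 1] = colour
        rgb[max(cr - arm, 0) : cr + arm + 1, np.clip(cc, 0, W - 1)] = colour
    return rgb


def distance_map_to_png16(dmap: DistanceMap) -> np.ndarray:
    """Render a distance map as a 16-bit image; unevaluated cells are white.

    Finite errors are affinely rescaled to [0, 65534] (minimum black) so the
    minima read as the darkest cells; the NaN sentinel maps to 65535.
    """
    vals = dmap.values
    out = np.full(vals.shape, 65535, dtype=np.uint16)
    finite = np.isfinite(vals)
    if finite.any():
        lo, hi = vals[finite].min(), vals[finite].max()
        span = hi - lo if hi > lo else 1.0
        out[finite] = np.round((vals[finite] - lo) / span * 65534).astype(np.uint16)
    return out


def write_distance_map_text(path: str | Path, dmap: DistanceMap) -> None:
    """Plain-text matrix export of a distance map (NaN marks unevaluated cells)."""
    header = (
        f"patch_size={dmap.geometry.patch_size} step={dmap.geometry.step} "
        f"image_shape={dmap.geometry.image_shape}"
    )
    np.savetxt(Path(path), dmap.values, fmt="%.6g", header=header)


def localizations_to_records(
    localizations: Sequence[Localization],
    image: str = "",
    landmark: str = "",
    mode: str = "",
    bottom_left: bool = False,
    image_height: int | None = None,
) -> list[dict]:
    """Flatten localizations to JSON/CSV-ready dictionaries.

    With ``bottom_left=True`` the corner is reported as the square's
    bottom-left pixel counted from the image bottom (display convention),
    which requires ``image_height``.
    """
    records = []
    for loc in localizations:
        r, c = loc.corner
        if bottom_left:
            if image_height is None:
                raise ValueError("bottom_left output requires image_height")
            r = image_height - 1 - (r + loc.side - 1)
        records.append(
            {
                "image": image,
                "landmark": landmark,
                "corner_row": int(r),
                "corner_col": int(c),
                "side": int(loc.side),
                "centre_row": int(loc.centre[0]),
                "centre_col": int(loc.centre[1]),
                "error": float(loc.error),
                "rank": int(loc.rank),
                "refined": bool(loc.refined),
                "mode": mode,
            }
        )
    return records


def write_localizations_json(path: str | Path, payload: dict) -> None:
    with open(Path(path), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def write_localizations_csv(path: str | Path, records: Sequence[dict]) -> None:
    fields = [
        "image", "landmark", "corner_row", "corner_col", "side",
        "centre_row", "centre_col", "error", "rank", "refined", "mode",
    ]
    with open(Path(path), "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fields)
        writer.writeheader()
        writer.writerows(records)
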