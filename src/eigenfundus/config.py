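"""Run configuration with landmark-specific defaults and YAML round-trip."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "default_config"]

# printed defaults of the method: patch sizes, coarse step, minima counts,
# refinement window
_LANDMARK_DEFAULTS = {
    "disc": {"patch_size": 100, "k_minima": 3},
    "fovea": {"patch_size": 70, "k_minima": 4},
}


@dataclass
class RunConfig:
    """All tunable parameters of a localization run.

    ``masking`` lists the enabled candidate strategies in evaluation order:
    any of ``vessel`` (thick-vessel rule), ``cluster`` (bright/dark intensity
    clusters) and ``annulus`` (fovea-only 2.5-disc-diameter prior).
    """

    landmark: str = "disc"
    patch_size: int = 100
    step: int = 25
    k_minima: int = 3
    refine_window: int = 50
    score_mode: str = "reconstruction"  # or "literal"
    eye_side: str = "left"  # left | right | auto
    seed: int = 0

    masking: list[str] = field(default_factory=list)
    fill_border: bool = True  # fovea only: inpaint out-of-FOV border first
    # vessel strategy
    vessel_sigma: float = 2.0
    vessel_n_orientations: int = 12
    vessel_threshold_quantile: float = 0.98
    vessel_thickness_radius: int = 2
    min_thick_pixels: int = 50
    max_thick_pixels: int = 0
    # cluster strategy
    cluster_quantile: float | None = None  # None -> 0.98 disc / 0.05 fovea
    min_cluster_px: int = 100
    # annulus strategy
    annulus_tolerance: float = 0.2

    def to_yaml(self, path: str | Path) -> None:
        with open(Path(path), "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(Path(path)) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def default_config(landmark: str, **overrides) -> RunConfig:
    """A config with the landmark's standard patch size and minima count."""
    if landmark not in _LANDMARK_DEFAULTS:
        raise ValueError(f"unknown landmark {landmark!r}")
    params = {"landmark": landmark, **_LANDMARK_DEFAULTS[landmark]}
    params.update(overrides)
    return RunConfig(**params)
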