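"""Run configuration for the segmentation pipeline."""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path
from typing import Any

import yaml

from .enhance import DEFAULT_GAMMA
from .reconstruct import DEFAULT_THETA

__all__ = ["PipelineConfig", "VARIANTS"]

#: Pipeline variants, mirroring the ablation ladder: plain SLIC on the raw
#: image; SLIC after reconstruction+gamma; the gray-gated center update on
#: the preprocessed image; and the full texture-augmented algorithm.
VARIANTS = ("slic", "enforced_slic", "improved_slic", "proposed")


@dataclass
class PipelineConfig:
    """All tunables of the segmentation pipeline.

    Parameters
    ----------
    n_superpixels:
        Requested superpixel count K; the seeding grid realizes the
        nearest regular grid, so the actual count may differ slightly.
    n_iterations:
        Assignment/update sweeps; 10 is typically enough for the centers
        to settle.
    gamma:
        Power-law enhancement exponent (< 1 brightens dark tissue).
    theta:
        Deviation threshold of the histogram-cube reconstruction, in gray
        levels.
    compactness_gray, compactness_texture:
        Initial values of the adaptive gray / texture distance
        normalizers, in gray levels and code units respectively; after the
        first iteration each cluster adapts them to the largest distance
        observed among its members.
    variant:
        Which stages run (see :data:`VARIANTS`).
    enforce_connectivity:
        Merge sub-``S^2/4`` connected fragments into their largest
        neighbor after clustering.
    literal_distances:
        Use squared gray/texture differences inside the combined distance
        instead of absolute differences (a comparison mode; the default
        keeps all three distance components in first-power units).
    seed:
        Recorded for provenance; the pipeline itself is deterministic and
        only the synthetic phantom generator consumes seeds.
    """

    n_superpixels: int = 400
    n_iterations: int = 10
    gamma: float = DEFAULT_GAMMA
    theta: float = DEFAULT_THETA
    compactness_gray: float = 10.0
    compactness_texture: float = 10.0
    variant: str = "proposed"
    enforce_connectivity: bool = True
    literal_distances: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise ValueError(f"gamma must be > 0, got {self.gamma}")
        if self.n_superpixels < 1:
            raise ValueError("n_superpixels must be >= 1")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.theta < 0:
            raise ValueError("theta must be >= 0")
        if self.compactness_gray <= 0 or self.compactness_texture <= 0:
            raise ValueError("compactness normalizers must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )

    # -- stage wiring -----------------------------------------------------

    @property
    def use_preprocessing(self) -> bool:
        return self.variant in ("enforced_slic", "improved_slic", "proposed")

    @property
    def use_gated_update(self) -> bool:
        return self.variant in ("improved_slic", "proposed")

    @property
    def use_texture(self) -> bool:
        return self.variant == "proposed"

    # -- (de)serialization -------------------------------------------------

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "PipelineConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in fields(self)}
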