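"""Pipeline configuration and logging.

Every tunable threshold of the quantification pipeline lives in
:class:`PipelineConfig` so that a single YAML file can reproduce a run.
Defaults encode the published rule set (100-px cluster filter, 2,100 HU
calcium threshold, CAD-RADS 2.0 bands, HRP criteria) plus the numerical
choices documented in ``docs/methods.md``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import yaml

logger = logging.getLogger("coroquant")

#: Default in-plane pixel spacing (mm/pixel) assumed when metadata omits it.
DEFAULT_PIXEL_SPACING_MM = 0.35


@dataclass
class PipelineConfig:
    """All tunable parameters of the cMPR quantification pipeline.

    Attributes
    ----------
    min_component_px:
        Connected components of vessel/lesion labels with at most this many
        pixels are removed during mask post-processing (clusters of
        ``<= 100`` pixels are treated as segmentation noise).
    connectivity:
        In-plane pixel connectivity for component analysis (4 or 8).
    tangent_half_window:
        Half-window (in skeleton points) for smoothing centerline tangents.
    profile_step_factor:
        Normal-profile sampling step as a fraction of pixel spacing.
    profile_half_length_factor:
        Profile half-length as a multiple of the slice's estimated vessel
        radius.
    mld_smooth_window:
        Running-median window (samples) applied to the width profile before
        the lesion minimum (MLD) is extracted; suppresses half-pixel mask
        quantization noise. Must be odd.
    ref_len_mm:
        Length of the proximal/distal reference windows for RVD medians.
    gap_tolerance_pts:
        Stenotic runs separated by fewer than this many normal skeleton
        points are merged into one lesion.
    min_run_mm:
        Lesions shorter than this arc length are dropped.
    diameter_source:
        ``"mask"`` (default) measures FWHM on the binary segmentation;
        ``"intensity"`` measures it on the HU raster.
    calcium_threshold_hu:
        HU above which (strictly) a vessel voxel counts as calcified.
    calcium_cutoff_pct:
        Calcium fraction at/above which a vessel is flagged calcified.
    lap_threshold_hu:
        Mean plaque attenuation below which (strictly) the low-attenuation
        plaque criterion fires.
    remodeling_threshold:
        Remodeling index above which (strictly) positive remodeling fires.
    hrp_min_criteria:
        Number of high-risk-plaque criteria required for a "vulnerable" call.
    plaque_min_cluster_px:
        Plaque components at or below this size are discarded before
        presence calls.
    default_spacing_mm:
        Pixel spacing assumed when scan metadata omits it.
    """

    min_component_px: int = 100
    connectivity: int = 8
    tangent_half_window: int = 3
    profile_step_factor: float = 0.25
    profile_half_length_factor: float = 4.0
    mld_smooth_window: int = 5
    ref_len_mm: float = 10.0
    gap_tolerance_pts: int = 2
    min_run_mm: float = 1.0
    diameter_source: str = "mask"
    calcium_threshold_hu: float = 2100.0
    calcium_cutoff_pct: float = 1.0
    lap_threshold_hu: float = 30.0
    remodeling_threshold: float = 1.1
    hrp_min_criteria: int = 2
    plaque_min_cluster_px: int = 100
    default_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        if self.connectivity not in (4, 8):
            raise ValueError(f"connectivity must be 4 or 8, got {self.connectivity}")
        if self.diameter_source not in ("mask", "intensity"):
            raise ValueError(f"unknown diameter source {self.diameter_source!r}")
        if self.mld_smooth_window < 1 or self.mld_smooth_window % 2 == 0:
            raise ValueError("mld_smooth_window must be a positive odd integer")

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        """Load a configuration from a YAML mapping; unknown keys are rejected."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)
        return path
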