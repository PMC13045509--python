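"""Calcium scoring by Hounsfield-unit thresholding.

A vessel voxel of the pseudo-3D cMPR stack counts as calcified when its
attenuation strictly exceeds the threshold (default 2,100 HU on these
contrast-enhanced reconstructions); the calcium score is the calcified
fraction of all vessel voxels, pooled over the slices, expressed in
percent.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig
from .imaging_io import CMPRScan, LabelMask, VesselLabel

__all__ = ["CalciumScore", "calcium_fraction", "calcified_flag"]


@dataclass
class CalciumScore:
    vessel_label: VesselLabel
    calcified_voxels: int
    vessel_voxels: int
    threshold_hu: float

    @property
    def fraction_pct(self) -> float:
        return 100.0 * self.calcified_voxels / self.vessel_voxels


def calcium_fraction(
    scan: CMPRScan,
    vessel_mask: LabelMask,
    threshold_hu: float = 2100.0,
) -> CalciumScore:
    """Calcified voxel fraction of the vessel region.

    A voxel counts iff its HU strictly exceeds ``threshold_hu`` AND it lies
    inside the vessel region (mask labels 1 or 2); voxels of all slices are
    pooled. Raises on an empty vessel region or misaligned inputs.
    """
    if scan.slices.shape != vessel_mask.slices.shape:
        raise ValueError(
            f"scan {scan.slices.shape} and mask {vessel_mask.slices.shape} misaligned"
        )
    region = vessel_mask.vessel_region()
    n_vessel = int(region.sum())
    if n_vessel == 0:
        raise ValueError("empty vessel region; calcium fraction undefined")
    n_calc = int(np.count_nonzero((scan.slices > threshold_hu) & region))
    return CalciumScore(
        vessel_label=scan.vessel_label,
        calcified_voxels=n_calc,
        vessel_voxels=n_vessel,
        threshold_hu=threshold_hu,
    )


def calcified_flag(score: CalciumScore, cutoff_pct: Optional[float] = None) -> bool:
    """Binary calcification call: fraction at or above the cutoff."""
    cutoff = PipelineConfig().calcium_cutoff_pct if cutoff_pct is None else cutoff_pct
    if not (0.0 <= cutoff <= 100.0):
        raise ValueError("cutoff_pct must lie in [0, 100]")
    return score.fraction_pct >= cutoff
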