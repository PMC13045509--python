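"""CAD-RADS 2.0 grading, significant-CAD flag and high-risk-plaque logic.

Implements the standardized coronary stenosis reporting categories:

====  ==========================  ======================
cat.  stenosis severity           meaning
====  ==========================  ======================
0     exactly 0%                  documented absence of disease
1     (0, 25)%                    minimal
2     [25, 50)%                   mild
3     [50, 70)%                   moderate
4A    [70, 100)%                  severe (1-2 vessels)
4B    LM > 50% or 3-vessel >= 70  severe (high-risk anatomy)
5     100%                        occluded
====  ==========================  ======================

Patients are "significant CAD" when any vessel carries a stenosis of at
least 50%, and "obstructive" at category 3 or above. A plaque is labelled
vulnerable when at least two of the four CCTA high-risk features are
present: low-attenuation plaque (< 30 HU), positive remodeling (index
> 1.1), napkin-ring sign, spotty calcification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import PipelineConfig, logger
from .imaging_io import LabelMask, VesselLabel, filter_small_components

__all__ = [
    "CADRADSCategory",
    "HRPCriteria",
    "HRPResult",
    "VesselGrade",
    "PatientGrade",
    "PlaquePresence",
    "cadrads_vessel",
    "cadrads_patient",
    "significant_cad",
    "hrp_evaluate",
    "plaque_presence",
    "patient_plaque_presence",
]


class CADRADSCategory(str, Enum):
    CAT0 = "0"
    CAT1 = "1"
    CAT2 = "2"
    CAT3 = "3"
    CAT4A = "4A"
    CAT4B = "4B"
    CAT5 = "5"

    @property
    def rank(self) -> int:
        """Severity ordering 0 < 1 < 2 < 3 < 4A < 4B < 5."""
        return ["0", "1", "2", "3", "4A", "4B", "5"].index(self.value)

    @property
    def obstructive(self) -> bool:
        return self.rank >= CADRADSCategory.CAT3.rank


def cadrads_vessel(severity_pct: float) -> CADRADSCategory:
    """Map a per-vessel diameter-stenosis percentage to its CAD-RADS category.

    Band edges follow the printed integer bounds as half-open real
    intervals; category 0 requires exactly 0% and category 5 exactly 100%.
    """
    s = float(severity_pct)
    if not (0.0 <= s <= 100.0):
        raise ValueError(f"severity must be within [0, 100], got {s}")
    if s == 0.0:
        return CADRADSCategory.CAT0
    if s < 25.0:
        return CADRADSCategory.CAT1
    if s < 50.0:
        return CADRADSCategory.CAT2
    if s < 70.0:
        return CADRADSCategory.CAT3
    if s < 100.0:
        return CADRADSCategory.CAT4A
    return CADRADSCategory.CAT5


@dataclass
class VesselGrade:
    vessel_label: VesselLabel
    severity_pct: float
    category: CADRADSCategory = field(init=False)

    def __post_init__(self) -> None:
        self.category = cadrads_vessel(self.severity_pct)


@dataclass
class PatientGrade:
    vessel_grades: List[VesselGrade]
    left_main_severity_pct: Optional[float]
    category: CADRADSCategory
    significant_cad: bool

    @property
    def obstructive(self) -> bool:
        return self.category.obstructive


def significant_cad(severities: Sequence[float]) -> bool:
    """True iff any stenosis severity reaches 50%."""
    if len(severities) == 0:
        raise ValueError("significant_cad requires at least one severity")
    return max(float(s) for s in severities) >= 50.0


def cadrads_patient(
    grades: Sequence[VesselGrade],
    left_main_severity_pct: Optional[float] = None,
) -> PatientGrade:
    """Roll per-vessel grades up to a patient-level CAD-RADS category.

    Category 4B fires when the left main exceeds 50% stenosis or when three
    (or more) vessels are obstructive at >= 70%; otherwise the patient takes
    the maximum vessel category. The 3-vessel clause needs at least three
    graded vessels. The left main, when supplied, also contributes its own
    band category and the significant-CAD flag.
    """
    grades = list(grades)
    if not grades:
        raise ValueError("cadrads_patient requires at least one vessel grade")
    severities = [g.severity_pct for g in grades]
    categories = [g.category for g in grades]
    if left_main_severity_pct is not None:
        severities = severities + [float(left_main_severity_pct)]
        categories = categories + [cadrads_vessel(left_main_severity_pct)]

    lm_4b = left_main_severity_pct is not None and float(left_main_severity_pct) > 50.0
    n_severe = sum(1 for g in grades if g.severity_pct >= 70.0)
    if len(grades) < 3 and n_severe >= len(grades) and n_severe > 0:
        logger.info(
            "3-vessel 4B clause not evaluable with %d graded vessel(s)", len(grades)
        )
    three_vessel_4b = len(grades) >= 3 and n_severe >= 3

    if lm_4b or three_vessel_4b:
        category = CADRADSCategory.CAT4B
    else:
        category = max(categories, key=lambda c: c.rank)
    return PatientGrade(
        vessel_grades=grades,
        left_main_severity_pct=left_main_severity_pct,
        category=category,
        significant_cad=significant_cad(severities),
    )


# ---------------------------------------------------------------------------
# High-risk plaque
# ---------------------------------------------------------------------------

@dataclass
class HRPCriteria:
    """CCTA high-risk plaque features for one lesion."""

    lap_mean_hu: float
    remodeling_index: float
    napkin_ring: bool
    spotty_calcification: bool

    def __post_init__(self) -> None:
        if not (self.remodeling_index > 0):
            raise ValueError("remodeling_index must be positive")


@dataclass
class HRPResult:
    flags: Dict[str, bool]
    n_positive: int
    vulnerable: bool


def hrp_evaluate(criteria: HRPCriteria, config: Optional[PipelineConfig] = None) -> HRPResult:
    """Evaluate the four high-risk plaque criteria and the vulnerable label.

    Low-attenuation plaque fires strictly below 30 HU; positive remodeling
    strictly above 1.1; the imaging signs (napkin-ring, spotty
    calcification) are boolean inputs. "Vulnerable" requires at least two
    positive criteria.
    """
    cfg = config or PipelineConfig()
    flags = {
        "low_attenuation_plaque": criteria.lap_mean_hu < cfg.lap_threshold_hu,
        "positive_remodeling": criteria.remodeling_index > cfg.remodeling_threshold,
        "napkin_ring": bool(criteria.napkin_ring),
        "spotty_calcification": bool(criteria.spotty_calcification),
    }
    n = sum(flags.values())
    return HRPResult(flags=flags, n_positive=n, vulnerable=n >= cfg.hrp_min_criteria)


# ---------------------------------------------------------------------------
# Plaque presence
# ---------------------------------------------------------------------------

@dataclass
class PlaquePresence:
    slice_flags: List[bool]
    vessel_flag: bool


def plaque_presence(plaque_mask: LabelMask, min_cluster_px: int = 100) -> PlaquePresence:
    """Per-slice and per-vessel plaque presence after small-cluster removal.

    A slice is positive iff any plaque (label-2) component larger than
    ``min_cluster_px`` pixels survives; the vessel is positive iff any slice
    is.
    """
    if plaque_mask.mode != "plaque":
        raise ValueError("plaque_presence requires a mask in plaque mode")
    filtered = filter_small_components(
        plaque_mask, max_removed_size=min_cluster_px, labels={2}
    )
    slice_flags = [bool(np.any(sl == 2)) for sl in filtered.slices]
    return PlaquePresence(slice_flags=slice_flags, vessel_flag=any(slice_flags))


def patient_plaque_presence(vessel_flags: Sequence[bool]) -> bool:
    """Patient positive iff any vessel carries surviving plaque."""
    return any(bool(v) for v in vessel_flags)
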