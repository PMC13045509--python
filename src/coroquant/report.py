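"""Rule-based structured reporting.

Assembles per-vessel stenosis, calcium and plaque results plus the
patient-level CAD-RADS grade into a deterministic structured record, and
renders it either as JSON (lossless round trip) or as fixed-template text
with stable field order. Missing modalities are reported as
"not assessed", never dropped.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional, Sequence

from .calcium import CalciumScore
from .grading import (
    CADRADSCategory,
    PatientGrade,
    VesselGrade,
    cadrads_patient,
)
from .imaging_io import VesselLabel
from .stenosis import VesselStenosisResult

__all__ = ["LesionEntry", "VesselBlock", "PatientReport", "build_report", "render"]

_NOT_ASSESSED = "not assessed"


@dataclass
class LesionEntry:
    lesion_id: int
    slice_index: int
    s_start_mm: float
    s_end_mm: float
    severity_pct: float
    length_mm: float


@dataclass
class VesselBlock:
    vessel_label: str
    lesions: List[LesionEntry]
    max_severity_pct: float
    category: str
    calcium_fraction_pct: Optional[float]
    plaque_present: Optional[bool]


@dataclass
class PatientReport:
    patient_id: str
    vessels: List[VesselBlock]
    patient_category: str
    significant_cad: bool
    obstructive: bool

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PatientReport":
        vessels = [
            VesselBlock(
                vessel_label=v["vessel_label"],
                lesions=[LesionEntry(**l) for l in v["lesions"]],
                max_severity_pct=v["max_severity_pct"],
                category=v["category"],
                calcium_fraction_pct=v["calcium_fraction_pct"],
                plaque_present=v["plaque_present"],
            )
            for v in data["vessels"]
        ]
        return cls(
            patient_id=data["patient_id"],
            vessels=vessels,
            patient_category=data["patient_category"],
            significant_cad=data["significant_cad"],
            obstructive=data["obstructive"],
        )


def build_report(
    patient_id: str,
    vessel_results: Sequence[VesselStenosisResult],
    calcium_scores: Optional[Dict[str, CalciumScore]] = None,
    plaque_flags: Optional[Dict[str, bool]] = None,
    left_main_severity_pct: Optional[float] = None,
) -> PatientReport:
    """Assemble the structured patient report.

    ``calcium_scores`` and ``plaque_flags`` map vessel labels to results;
    vessels absent from a map get the "not assessed" sentinel. Patient
    grading (CAD-RADS incl. 4B, significant CAD) is recomputed from the
    vessel severities, so every number in the report traces back to a
    pipeline result.
    """
    if not vessel_results:
        raise ValueError("build_report requires at least one vessel result")
    calcium_scores = calcium_scores or {}
    plaque_flags = plaque_flags or {}

    grades = [
        VesselGrade(vessel_label=vr.vessel_label, severity_pct=vr.max_severity_pct)
        for vr in vessel_results
    ]
    patient = cadrads_patient(grades, left_main_severity_pct)

    vessels: List[VesselBlock] = []
    for vr, grade in zip(vessel_results, grades):
        key = vr.vessel_label.value
        score = calcium_scores.get(key)
        vessels.append(
            VesselBlock(
                vessel_label=key,
                lesions=[
                    LesionEntry(
                        lesion_id=l.lesion_id,
                        slice_index=l.slice_index,
                        s_start_mm=round(l.s_start_mm, 2),
                        s_end_mm=round(l.s_end_mm, 2),
                        severity_pct=round(l.severity_pct, 1),
                        length_mm=round(l.lesion_length_mm, 2),
                    )
                    for l in vr.lesions
                ],
                max_severity_pct=round(vr.max_severity_pct, 1),
                category=grade.category.value,
                calcium_fraction_pct=(
                    round(score.fraction_pct, 2) if score is not None else None
                ),
                plaque_present=plaque_flags.get(key),
            )
        )
    return PatientReport(
        patient_id=patient_id,
        vessels=vessels,
        patient_category=patient.category.value,
        significant_cad=patient.significant_cad,
        obstructive=patient.obstructive,
    )


def _render_text(report: PatientReport) -> str:
    lines = [
        f"Coronary CT report - patient {report.patient_id}",
        f"CAD-RADS category: {report.patient_category}"
        f" ({'obstructive' if report.obstructive else 'non-obstructive'})",
        f"Significant CAD (any stenosis >= 50%): "
        f"{'yes' if report.significant_cad else 'no'}",
        "",
    ]
    for v in report.vessels:
        lines.append(f"[{v.vessel_label}] CAD-RADS {v.category}, "
                     f"max stenosis {v.max_severity_pct:.1f}%")
        if v.lesions:
            for l in v.lesions:
                lines.append(
                    f"  lesion {l.lesion_id} (slice {l.slice_index}): "
                    f"{l.s_start_mm:.1f}-{l.s_end_mm:.1f} mm, "
                    f"severity {l.severity_pct:.1f}%, length {l.length_mm:.1f} mm"
                )
        else:
            lines.append("  no stenotic lesion")
        calc = (
            f"{v.calcium_fraction_pct:.2f}% of vessel voxels"
            if v.calcium_fraction_pct is not None
            else _NOT_ASSESSED
        )
        lines.append(f"  calcification: {calc}")
        plaque = (
            _NOT_ASSESSED
            if v.plaque_present is None
            else ("present" if v.plaque_present else "absent")
        )
        lines.append(f"  vulnerable plaque: {plaque}")
    lines.append("")
    return "\n".join(lines)


def render(report: PatientReport, fmt: str = "text") -> str:
    """Render a report as fixed-template ``text`` or lossless ``json``."""
    if fmt == "json":
        return json.dumps(report.to_dict(), indent=1, sort_keys=True)
    if fmt == "text":
        return _render_text(report)
    raise ValueError(f"unknown report format {fmt!r}")
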