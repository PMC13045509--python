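"""Lesion delineation and quantitative stenosis measurement.

For each slice the pipeline runs: cluster filter -> skeletonize -> prune ->
width profile -> lesion delineation -> measurement. A lesion is a maximal
contiguous run of stenotic-labelled centerline points (small gaps merged,
sub-millimetre runs dropped). Its minimal luminal diameter (MLD) is the
minimum of the (median-smoothed) width profile inside the lesion; the
reference vessel diameter (RVD) is the mean of the median widths over the
proximal and distal reference windows flanking the lesion; and the
diameter stenosis is

    severity % = (1 - MLD / RVD) * 100,   clamped to [0, 100].

Lesion length is the centerline arc length spanned by the run. The vessel
result aggregates lesions over all slices; the per-vessel severity is the
maximum lesion severity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .centerline import EmptySkeletonError, extract_centerline
from .config import PipelineConfig, logger
from .diameter import DiameterProfile, diameter_profile
from .imaging_io import CMPRScan, LabelMask, VesselLabel, filter_small_components

__all__ = [
    "LesionMeasurement",
    "VesselStenosisResult",
    "ReferenceUndefinedError",
    "delineate_lesions",
    "reference_diameters",
    "lesion_severity",
    "measure_vessel",
]


class ReferenceUndefinedError(ValueError):
    """No usable reference window on either side of a lesion."""


@dataclass
class LesionMeasurement:
    """Quantitative indices of one contiguous stenotic run."""

    lesion_id: int
    slice_index: int
    s_start_mm: float
    s_end_mm: float
    lesion_length_mm: float
    mld_mm: float
    rvd_proximal_mm: Optional[float]
    rvd_distal_mm: Optional[float]
    rvd_mm: float
    severity_pct: float

    def __post_init__(self) -> None:
        if not (self.s_end_mm > self.s_start_mm):
            raise ValueError("lesion must have positive extent")


@dataclass
class VesselStenosisResult:
    vessel_label: VesselLabel
    lesions: List[LesionMeasurement] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return len(self.lesions) > 0

    @property
    def max_severity_pct(self) -> float:
        return max((l.severity_pct for l in self.lesions), default=0.0)


def delineate_lesions(
    point_label: np.ndarray,
    s_mm: np.ndarray,
    min_run_mm: float = 1.0,
    gap_tolerance_pts: int = 2,
) -> List[Tuple[int, int]]:
    """Index ranges ``(i_start, i_end)`` (inclusive) of stenotic runs.

    Maximal contiguous runs of stenotic points are merged when separated by
    fewer than ``gap_tolerance_pts`` normal points, then dropped when their
    arc length falls below ``min_run_mm``.
    """
    labels = np.asarray(point_label).astype(bool)
    if not labels.any():
        return []
    idx = np.nonzero(labels)[0]
    runs: List[Tuple[int, int]] = []
    start = prev = int(idx[0])
    for i in idx[1:]:
        i = int(i)
        if i - prev - 1 < gap_tolerance_pts:  # gap strictly smaller than tolerance
            prev = i
        else:
            runs.append((start, prev))
            start = prev = i
    runs.append((start, prev))
    s = np.asarray(s_mm, dtype=np.float64)
    return [(a, b) for a, b in runs if s[b] - s[a] >= min_run_mm]


def reference_diameters(
    profile: DiameterProfile,
    lesion: Tuple[int, int],
    ref_len_mm: float = 10.0,
) -> Tuple[Optional[float], Optional[float], float]:
    """Proximal/distal reference diameters and their combination.

    Each reference is the median width over the window of up to
    ``ref_len_mm`` of centerline immediately flanking the lesion (lesion
    points excluded, undefined widths ignored). The combined RVD is the
    mean of the two medians, or the single available one when the lesion
    abuts a path end. Raises :class:`ReferenceUndefinedError` when neither
    side yields a reference.
    """
    a, b = lesion
    s = profile.s_mm
    w = profile.width_mm

    def _window(side: str) -> Optional[float]:
        if side == "proximal":
            sel = (np.arange(len(s)) < a) & (s >= s[a] - ref_len_mm)
        else:
            sel = (np.arange(len(s)) > b) & (s <= s[b] + ref_len_mm)
        vals = w[sel]
        vals = vals[np.isfinite(vals)]
        return float(np.median(vals)) if vals.size else None

    prox, dist = _window("proximal"), _window("distal")
    if prox is None and dist is None:
        raise ReferenceUndefinedError("no reference window on either side of lesion")
    if prox is None:
        rvd = dist
    elif dist is None:
        rvd = prox
    else:
        rvd = 0.5 * (prox + dist)
    return prox, dist, float(rvd)


def lesion_severity(mld_mm: float, rvd_mm: float) -> float:
    """Percent diameter stenosis, clamped to [0, 100]."""
    if not (rvd_mm > 0):
        raise ValueError("reference diameter must be positive")
    if mld_mm < 0:
        raise ValueError("MLD must be non-negative")
    return float(np.clip((1.0 - mld_mm / rvd_mm) * 100.0, 0.0, 100.0))


def _smoothed_widths(width_mm: np.ndarray, window: int) -> np.ndarray:
    """Running median of the width sequence, NaN-tolerant at the edges."""
    if window <= 1:
        return width_mm
    filled = width_mm.copy()
    nan = ~np.isfinite(filled)
    if nan.all():
        return width_mm
    if nan.any():  # pad undefined points with nearest defined width
        idx = np.nonzero(~nan)[0]
        filled[nan] = np.interp(np.nonzero(nan)[0], idx, filled[idx])
    out = ndimage.median_filter(filled, size=window, mode="nearest")
    out[nan] = np.nan
    return out


def measure_slice(
    mask_slice: np.ndarray,
    spacing_mm: float,
    config: PipelineConfig,
    slice_index: int = 0,
    scan_slice: Optional[np.ndarray] = None,
    lesion_id_offset: int = 0,
) -> List[LesionMeasurement]:
    """Quantify all stenotic lesions on one (already filtered) slice."""
    try:
        path = extract_centerline(mask_slice, spacing_mm)
    except EmptySkeletonError:
        return []
    if len(path) < 2:
        return []
    profile = diameter_profile(mask_slice, path, config, scan_slice=scan_slice)
    if profile.failed:
        logger.warning("slice %d: width profile failed; lesions skipped", slice_index)
        return []
    lesions = delineate_lesions(
        path.point_label, path.s_mm, config.min_run_mm, config.gap_tolerance_pts
    )
    smooth = _smoothed_widths(profile.width_mm, config.mld_smooth_window)
    out: List[LesionMeasurement] = []
    for k, (a, b) in enumerate(lesions):
        inside = smooth[a : b + 1]
        inside = inside[np.isfinite(inside)]
        if not inside.size:
            logger.warning("slice %d lesion %d: no defined widths; skipped", slice_index, k)
            continue
        mld = float(inside.min())
        try:
            prox, dist, rvd = reference_diameters(profile, (a, b), config.ref_len_mm)
        except ReferenceUndefinedError:
            logger.warning("slice %d lesion %d: no reference; skipped", slice_index, k)
            continue
        out.append(
            LesionMeasurement(
                lesion_id=lesion_id_offset + k,
                slice_index=slice_index,
                s_start_mm=float(path.s_mm[a]),
                s_end_mm=float(path.s_mm[b]),
                lesion_length_mm=float(path.s_mm[b] - path.s_mm[a]),
                mld_mm=mld,
                rvd_proximal_mm=prox,
                rvd_distal_mm=dist,
                rvd_mm=rvd,
                severity_pct=lesion_severity(mld, rvd),
            )
        )
    return out


def measure_vessel(
    mask: LabelMask,
    scan: Optional[CMPRScan] = None,
    config: Optional[PipelineConfig] = None,
) -> VesselStenosisResult:
    """End-to-end stenosis quantification for one vessel stack.

    Applies the small-cluster filter, then measures every slice and
    aggregates the lesion list (with slice provenance); the vessel severity
    is the maximum over lesions. An empty vessel yields an empty,
    undetected result.
    """
    cfg = config or PipelineConfig()
    if mask.mode != "stenosis":
        raise ValueError("measure_vessel requires a mask in stenosis mode")
    filtered = filter_small_components(
        mask, max_removed_size=cfg.min_component_px, connectivity=cfg.connectivity
    )
    vessel_label = scan.vessel_label if scan is not None else VesselLabel.LAD
    result = VesselStenosisResult(vessel_label=vessel_label)
    for k in range(filtered.slice_count):
        scan_slice = scan.slices[k] if scan is not None else None
        result.lesions.extend(
            measure_slice(
                filtered.slices[k],
                mask.pixel_spacing_mm,
                cfg,
                slice_index=k,
                scan_slice=scan_slice,
                lesion_id_offset=len(result.lesions),
            )
        )
    return result
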