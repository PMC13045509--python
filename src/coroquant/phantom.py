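"""Synthetic cMPR vessel phantoms with exact ground truth.

Each phantom emulates what a curved multiplanar reconstruction exports for
one coronary vessel: a stack of longitudinal cross-sections (13 slices of
512x512 by default) showing a gently curved contrast-filled lumen, plus a
perfectly known label mask and a truth record. The lumen follows a planar
sinusoidal centerline; its radius along arc length s is

    r(s) = R * (1 - sum_i (sev_i / 100) * g_i(s))

where each stenosis contributes a cosine-taper (Hann) unit bump g_i over
its lesion extent. The lesion label (2) covers lumen pixels where the bump
exceeds an onset fraction (0.1) of its peak, which fixes the ground-truth
lesion length unambiguously. Calcified foci and low-attenuation plaque
regions are painted as disks at exact HU values after the Gaussian noise
is applied, so threshold-based truths (e.g. the calcium fraction) are
exact by construction. Everything is deterministic given the seed.

The HU palette (lumen 350, wall 50, background -50, calcification 2500,
low-attenuation plaque 20 HU) is a modeling choice that leaves a wide
margin around the 2,100 HU calcium and 30 HU plaque thresholds; it does
not reproduce any particular scanner's statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import grading
from .config import DEFAULT_PIXEL_SPACING_MM
from .imaging_io import CMPRScan, LabelMask, VesselLabel

__all__ = [
    "StenosisSpec",
    "FocusSpec",
    "HRPFlagSpec",
    "PhantomSpec",
    "LesionTruth",
    "PhantomTruth",
    "PhantomSpecError",
    "CohortRanges",
    "generate_vessel",
    "generate_cohort",
    "truth_hrp",
]

#: Fraction of peak narrowing at which the lesion label switches on.
LESION_ONSET_FRACTION = 0.1

#: Half-extent of the labelled lesion, as a fraction of the nominal bump
#: length: the Hann bump exceeds the onset fraction within
#: +- L * acos(2 * onset - 1) / (2 pi) of its center.
_ONSET_HALF_FRACTION = math.acos(2 * LESION_ONSET_FRACTION - 1) / (2 * math.pi)


class PhantomSpecError(ValueError):
    """Raised for inconsistent phantom specifications."""


@dataclass
class StenosisSpec:
    """One parametric stenosis: Hann narrowing bump on the radius profile."""

    center_mm: float
    length_mm: float
    severity_pct: float


@dataclass
class FocusSpec:
    """A disk-shaped focal region (calcification or low-attenuation plaque)
    centered on the centerline at arc-length position ``center_mm``."""

    center_mm: float
    radius_mm: float
    hu_value: float


@dataclass
class HRPFlagSpec:
    """Per-lesion high-risk-plaque attributes carried by the spec."""

    napkin_ring: bool = False
    spotty_calcification: bool = False
    remodeling_index: float = 1.0


@dataclass
class PhantomSpec:
    seed: int = 0
    n_slices: int = 13
    shape: Tuple[int, int] = (512, 512)
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM
    base_radius_mm: float = 2.0
    curve_amplitude_px: float = 25.0
    curve_periods: float = 1.0
    margin_px: int = 6
    stenoses: List[StenosisSpec] = field(default_factory=list)
    hrp_flags: List[HRPFlagSpec] = field(default_factory=list)
    calcifications: List[FocusSpec] = field(default_factory=list)
    lap_regions: List[FocusSpec] = field(default_factory=list)
    noise_sd_hu: float = 10.0
    lumen_hu: float = 350.0
    wall_hu: float = 50.0
    background_hu: float = -50.0
    wall_thickness_mm: float = 0.5
    vessel_label: VesselLabel = VesselLabel.LAD
    patient_id: str = "phantom"


@dataclass
class LesionTruth:
    lesion_id: int
    s_start_mm: float
    s_end_mm: float
    length_mm: float
    mld_mm: float
    rvd_mm: float
    severity_pct: float
    hrp: Optional[grading.HRPResult]
    vulnerable: bool


@dataclass
class PhantomTruth:
    vessel_label: VesselLabel
    lesions: List[LesionTruth]
    calcium_fraction_pct: float
    cadrads_category: grading.CADRADSCategory

    @property
    def max_severity_pct(self) -> float:
        return max((l.severity_pct for l in self.lesions), default=0.0)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

def _centerline_samples(spec: PhantomSpec) -> Tuple[np.ndarray, np.ndarray]:
    """Finely sampled centerline: (points_px (n,2) as (row, col), s_mm (n,))."""
    H, W = spec.shape
    x = np.arange(spec.margin_px, W - spec.margin_px, 0.25)
    phase = 2 * math.pi * spec.curve_periods * (x - x[0]) / (x[-1] - x[0])
    y = H / 2.0 + spec.curve_amplitude_px * np.sin(phase)
    pts = np.stack([y, x], axis=1)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1) * spec.pixel_spacing_mm
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return pts, s


def _bump(s: np.ndarray, lesion: StenosisSpec) -> np.ndarray:
    """Hann unit bump over the lesion's nominal extent."""
    d = s - lesion.center_mm
    inside = np.abs(d) <= lesion.length_mm / 2.0
    g = np.zeros_like(s)
    g[inside] = 0.5 * (1.0 + np.cos(2 * math.pi * d[inside] / lesion.length_mm))
    return g


def _radius_mm(s: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    narrowing = np.zeros_like(s)
    for lesion in spec.stenoses:
        narrowing += (lesion.severity_pct / 100.0) * _bump(s, lesion)
    return spec.base_radius_mm * (1.0 - narrowing)


def _validate(spec: PhantomSpec, span_mm: float) -> None:
    if spec.n_slices < 1:
        raise PhantomSpecError("n_slices must be >= 1")
    if spec.base_radius_mm <= 0:
        raise PhantomSpecError("base_radius_mm must be positive")
    extents = []
    for lesion in spec.stenoses:
        if not (0.0 <= lesion.severity_pct <= 100.0):
            raise PhantomSpecError(f"severity {lesion.severity_pct} outside [0, 100]")
        lo = lesion.center_mm - lesion.length_mm / 2.0
        hi = lesion.center_mm + lesion.length_mm / 2.0
        if lo < 0.0 or hi > span_mm:
            raise PhantomSpecError(
                f"lesion extent [{lo:.1f}, {hi:.1f}] mm outside vessel span "
                f"[0, {span_mm:.1f}] mm"
            )
        extents.append((lo, hi))
    for (a0, a1), (b0, b1) in zip(sorted(extents), sorted(extents)[1:]):
        if b0 < a1:
            raise PhantomSpecError("stenoses must not overlap")
    if spec.hrp_flags and len(spec.hrp_flags) != len(spec.stenoses):
        raise PhantomSpecError("hrp_flags must match stenoses one-to-one")
    # curvature low enough that normals never cross inside the lumen:
    # kappa_max * r_max < 1 for the sinusoidal centerline
    H, W = spec.shape
    span_px = W - 2 * spec.margin_px
    kappa_max = spec.curve_amplitude_px * (2 * math.pi * spec.curve_periods / span_px) ** 2
    r_max_px = spec.base_radius_mm / spec.pixel_spacing_mm
    if kappa_max * r_max_px >= 1.0:
        raise PhantomSpecError(
            "centerline curvature too high: adjacent normals would cross inside the lumen"
        )


def _render_geometry(spec: PhantomSpec):
    """Render the (slice-invariant) geometry once.

    Returns (base_hu, mask_slice, focus_paint, pts, s) where ``focus_paint``
    is an HU overlay (NaN where untouched) applied after noise.
    """
    H, W = spec.shape
    pts, s = _centerline_samples(spec)
    _validate(spec, float(s[-1]))
    tree = cKDTree(pts)
    rows, cols = np.mgrid[0:H, 0:W]
    pix = np.stack([rows.ravel(), cols.ravel()], axis=1).astype(np.float64)
    dist_px, idx = tree.query(pix, k=1, workers=-1)
    dist_px = dist_px.reshape(H, W)
    s_pix = s[idx].reshape(H, W)

    r_px = _radius_mm(s[idx], spec).reshape(H, W) / spec.pixel_spacing_mm
    wall_px = spec.wall_thickness_mm / spec.pixel_spacing_mm
    lumen = dist_px < r_px
    wall = (dist_px < r_px + wall_px) & ~lumen

    base_hu = np.full((H, W), spec.background_hu, dtype=np.float64)
    base_hu[wall] = spec.wall_hu
    base_hu[lumen] = spec.lumen_hu

    in_lesion = np.zeros((H, W), dtype=bool)
    for lesion in spec.stenoses:
        half = _ONSET_HALF_FRACTION * lesion.length_mm
        in_lesion |= np.abs(s_pix - lesion.center_mm) < half
    mask_slice = np.zeros((H, W), dtype=np.uint8)
    mask_slice[lumen] = 1
    mask_slice[lumen & in_lesion] = 2

    focus_paint = np.full((H, W), np.nan)
    lap_footprint = np.zeros((H, W), dtype=bool)
    for focus_list, is_lap in ((spec.calcifications, False), (spec.lap_regions, True)):
        for focus in focus_list:
            if not (0.0 <= focus.center_mm <= s[-1]):
                raise PhantomSpecError(
                    f"focus at {focus.center_mm} mm outside vessel span"
                )
            center = pts[int(np.argmin(np.abs(s - focus.center_mm)))]
            d = np.hypot(rows - center[0], cols - center[1])
            disk = d < focus.radius_mm / spec.pixel_spacing_mm
            focus_paint[disk] = focus.hu_value
            if is_lap:
                lap_footprint |= disk
    return base_hu, mask_slice, focus_paint, lap_footprint, s


def truth_hrp(spec: PhantomSpec, lesion_index: int) -> grading.HRPResult:
    """High-risk-plaque truth for one lesion of a phantom spec.

    The low-attenuation criterion fires iff a plaque region whose center
    falls inside the lesion's nominal extent carries an HU value below
    30; remodeling index and the two imaging signs come from the spec's
    per-lesion flags.
    """
    lesion = spec.stenoses[lesion_index]
    flags = (
        spec.hrp_flags[lesion_index] if spec.hrp_flags else HRPFlagSpec()
    )
    lo = lesion.center_mm - lesion.length_mm / 2.0
    hi = lesion.center_mm + lesion.length_mm / 2.0
    lap_hus = [
        f.hu_value for f in spec.lap_regions if lo <= f.center_mm <= hi
    ]
    lap_mean_hu = min(lap_hus) if lap_hus else spec.lumen_hu
    return grading.hrp_evaluate(
        grading.HRPCriteria(
            lap_mean_hu=lap_mean_hu,
            remodeling_index=flags.remodeling_index,
            napkin_ring=flags.napkin_ring,
            spotty_calcification=flags.spotty_calcification,
        )
    )


def generate_vessel(
    spec: PhantomSpec, mask_mode: str = "stenosis"
) -> Tuple[CMPRScan, LabelMask, PhantomTruth]:
    """Render one phantom vessel: scan, label mask, exact truth record.

    ``mask_mode="stenosis"`` labels the lesion extent 2; ``"plaque"``
    labels the low-attenuation plaque footprint 2 instead. Deterministic
    given ``spec.seed``.
    """
    base_hu, mask_slice, focus_paint, lap_footprint, s = _render_geometry(spec)
    H, W = spec.shape
    rng = np.random.default_rng(spec.seed)
    painted = np.isfinite(focus_paint)
    slices = np.empty((spec.n_slices, H, W), dtype=np.float64)
    for k in range(spec.n_slices):
        sl = base_hu + rng.normal(0.0, spec.noise_sd_hu, size=(H, W))
        sl[painted] = focus_paint[painted]
        slices[k] = sl

    if mask_mode == "plaque":
        m = np.where(mask_slice > 0, 1, 0).astype(np.uint8)
        m[lap_footprint] = 2
        mask_slice = m
    mask = LabelMask(
        slices=np.repeat(mask_slice[None], spec.n_slices, axis=0),
        mode=mask_mode,
        pixel_spacing_mm=spec.pixel_spacing_mm,
    )
    scan = CMPRScan(
        patient_id=spec.patient_id,
        vessel_label=spec.vessel_label,
        slices=slices,
        pixel_spacing_mm=spec.pixel_spacing_mm,
    )

    # truth record, consistent with the rendered geometry
    lesions: List[LesionTruth] = []
    for i, lesion in enumerate(spec.stenoses):
        half = _ONSET_HALF_FRACTION * lesion.length_mm
        rvd = 2.0 * spec.base_radius_mm
        mld = rvd * (1.0 - lesion.severity_pct / 100.0)
        hrp = truth_hrp(spec, i)
        lesions.append(
            LesionTruth(
                lesion_id=i,
                s_start_mm=lesion.center_mm - half,
                s_end_mm=lesion.center_mm + half,
                length_mm=2.0 * half,
                mld_mm=mld,
                rvd_mm=rvd,
                severity_pct=lesion.severity_pct,
                hrp=hrp,
                vulnerable=hrp.vulnerable,
            )
        )
    region = mask.vessel_region()
    calcium_fraction = (
        100.0 * np.count_nonzero((slices > 2100.0) & region) / region.sum()
    )
    truth = PhantomTruth(
        vessel_label=spec.vessel_label,
        lesions=lesions,
        calcium_fraction_pct=float(calcium_fraction),
        cadrads_category=grading.cadrads_vessel(
            max((l.severity_pct for l in lesions), default=0.0)
        ),
    )
    return scan, mask, truth


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortRanges:
    """Sampling ranges for a phantom cohort (uniform unless noted)."""

    severity_pct: Tuple[float, float] = (40.0, 90.0)
    lesion_length_mm: Tuple[float, float] = (8.0, 20.0)
    base_radius_mm: Tuple[float, float] = (1.8, 2.2)
    n_stenoses: int = 1
    calcification_prob: float = 0.5
    calc_radius_mm: Tuple[float, float] = (0.3, 0.8)
    n_slices: int = 13
    shape: Tuple[int, int] = (512, 512)
    noise_sd_hu: float = 10.0

    def __post_init__(self) -> None:
        for name in ("severity_pct", "lesion_length_mm", "base_radius_mm", "calc_radius_mm"):
            lo, hi = getattr(self, name)
            if hi < lo:
                raise PhantomSpecError(f"empty range for {name}: ({lo}, {hi})")
        if self.n_stenoses < 0:
            raise PhantomSpecError("n_stenoses must be >= 0")


def generate_cohort(
    n: int,
    ranges: Optional[CohortRanges] = None,
    seed: int = 0,
) -> Tuple[List[Tuple[CMPRScan, LabelMask, PhantomTruth]], pd.DataFrame]:
    """Sample ``n`` phantom vessels and return them with a truth table.

    One truth-table row per vessel: max severity, per-lesion geometry of
    the first lesion, calcium fraction, CAD-RADS category. Reproducible
    given ``seed``.
    """
    if n < 1:
        raise PhantomSpecError("cohort size must be >= 1")
    ranges = ranges or CohortRanges()
    rng = np.random.default_rng(seed)
    triples = []
    rows = []
    vessel_cycle = [VesselLabel.LAD, VesselLabel.LCX, VesselLabel.RCA]
    for i in range(n):
        spec = PhantomSpec(
            seed=int(rng.integers(0, 2**31 - 1)),
            n_slices=ranges.n_slices,
            shape=ranges.shape,
            base_radius_mm=float(rng.uniform(*ranges.base_radius_mm)),
            noise_sd_hu=ranges.noise_sd_hu,
            vessel_label=vessel_cycle[i % 3],
            patient_id=f"phantom_{i:03d}",
        )
        # provisional span for lesion placement
        _, s = _centerline_samples(spec)
        span = float(s[-1])
        lesions = []
        for _ in range(ranges.n_stenoses):
            length = float(rng.uniform(*ranges.lesion_length_mm))
            # keep lesions away from the ends so references exist on both sides
            lo = 0.2 * span + length
            hi = 0.8 * span - length
            lesions.append(
                StenosisSpec(
                    center_mm=float(rng.uniform(lo, hi)),
                    length_mm=length,
                    severity_pct=float(rng.uniform(*ranges.severity_pct)),
                )
            )
        lesions.sort(key=lambda l: l.center_mm)
        for a, b in zip(lesions, lesions[1:]):  # resample overlaps away cheaply
            if b.center_mm - b.length_mm / 2 < a.center_mm + a.length_mm / 2:
                b.center_mm = a.center_mm + (a.length_mm + b.length_mm) / 2 + 2.0
        spec.stenoses = lesions
        if rng.uniform() < ranges.calcification_prob:
            spec.calcifications = [
                FocusSpec(
                    center_mm=float(rng.uniform(0.1 * span, 0.9 * span)),
                    radius_mm=float(rng.uniform(*ranges.calc_radius_mm)),
                    hu_value=2500.0,
                )
            ]
        scan, mask, truth = generate_vessel(spec)
        triples.append((scan, mask, truth))
        first = truth.lesions[0] if truth.lesions else None
        rows.append({
            "patient_id": spec.patient_id,
            "vessel_label": spec.vessel_label.value,
            "base_radius_mm": spec.base_radius_mm,
            "n_lesions": len(truth.lesions),
            "severity_pct": truth.max_severity_pct,
            "mld_mm": first.mld_mm if first else np.nan,
            "rvd_mm": first.rvd_mm if first else np.nan,
            "lesion_length_mm": first.length_mm if first else np.nan,
            "calcium_fraction_pct": truth.calcium_fraction_pct,
            "cadrads": truth.cadrads_category.value,
        })
    return triples, pd.DataFrame(rows)
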