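"""Reading, writing and post-processing of cMPR stacks and label masks.

A cMPR (curved multiplanar reconstruction) study exports, per coronary
vessel, an ordered stack of 2D longitudinal cross-sections in Hounsfield
units (by default 13 slices of 512x512). Segmentation masks live on the
same grid with labels 0 = background, 1 = vessel lumen, 2 = lesion
(stenosis or plaque depending on the segmentation model). This module
handles the container types, NIfTI / per-slice image round trips, the
pseudo-3D stacking, and the small-component cluster filter applied to
masks before any measurement.

Conventions: pixel coordinates are 0-based ``(row, col)``; slice index 0 is
the most proximal slice; NIfTI volumes store slices along the third axis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Set, Tuple, Union

import imageio.v3 as iio
import nibabel as nib
import numpy as np
from skimage import measure

from .config import DEFAULT_PIXEL_SPACING_MM, logger

__all__ = [
    "VesselLabel",
    "CMPRScan",
    "LabelMask",
    "Component",
    "ComponentSet",
    "FormatError",
    "read_scan",
    "write_scan",
    "read_mask",
    "write_mask",
    "connected_components",
    "filter_small_components",
    "stack_to_volume",
]

_IMG_EXTS = (".png", ".tif", ".tiff")
_SIDECAR = "metadata.json"


class FormatError(ValueError):
    """Raised for files that violate the cMPR stack / mask contracts."""


class VesselLabel(str, Enum):
    LAD = "LAD"
    LCX = "LCX"
    RCA = "RCA"
    LM = "LM"


@dataclass
class CMPRScan:
    """Ordered stack of cross-sectional HU rasters for one vessel.

    ``slices`` has shape ``(n_slices, H, W)``; slice 0 is most proximal.
    ``pixel_spacing_mm`` is the isotropic in-plane spacing in mm/pixel.
    """

    patient_id: str
    vessel_label: VesselLabel
    slices: np.ndarray
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise FormatError(f"scan must be (n_slices, H, W), got {self.slices.shape}")
        if not np.all(np.isfinite(self.slices)):
            raise FormatError("HU values must be finite")
        if not (self.pixel_spacing_mm > 0):
            raise FormatError("pixel spacing must be positive")
        self.vessel_label = VesselLabel(self.vessel_label)

    @property
    def slice_count(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> Tuple[int, int]:
        return self.slices.shape[1:]


@dataclass
class LabelMask:
    """Per-slice integer mask aligned to a :class:`CMPRScan`.

    Labels: 0 background, 1 vessel lumen, 2 lesion. ``mode`` records which
    segmentation produced label 2 ("stenosis" or "plaque"). Label-2 pixels
    are an independent class, not necessarily a subset of label 1.
    """

    slices: np.ndarray
    mode: str = "stenosis"
    pixel_spacing_mm: float = DEFAULT_PIXEL_SPACING_MM

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices)
        if self.slices.ndim != 3 or self.slices.shape[0] < 1:
            raise FormatError(f"mask must be (n_slices, H, W), got {self.slices.shape}")
        bad = np.setdiff1d(np.unique(self.slices), [0, 1, 2])
        if bad.size:
            raise FormatError(f"mask values outside {{0,1,2}}: {bad.tolist()}")
        self.slices = self.slices.astype(np.uint8)
        if self.mode not in ("stenosis", "plaque"):
            raise FormatError(f"unknown mask mode {self.mode!r}")

    @property
    def slice_count(self) -> int:
        return self.slices.shape[0]

    @property
    def slice_shape(self) -> Tuple[int, int]:
        return self.slices.shape[1:]

    def vessel_region(self) -> np.ndarray:
        """Boolean array of the full vessel region (labels 1 and 2)."""
        return self.slices > 0


@dataclass
class Component:
    label: int
    slice_index: int
    pixels: np.ndarray  # (n, 2) array of (row, col)

    @property
    def size(self) -> int:
        return len(self.pixels)


@dataclass
class ComponentSet:
    components: List[Component] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.components)

    def sizes(self) -> List[int]:
        return [c.size for c in self.components]


# ---------------------------------------------------------------------------
# File round trips
# ---------------------------------------------------------------------------

def _sidecar_path(path: Path) -> Path:
    if path.is_dir():
        return path / _SIDECAR
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _read_sidecar(path: Path) -> dict:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        return {}
    try:
        with open(sidecar) as fh:
            meta = json.load(fh)
    except json.JSONDecodeError as exc:
        raise FormatError(f"corrupt metadata JSON {sidecar}: {exc}") from exc
    if not isinstance(meta, dict):
        raise FormatError(f"metadata JSON {sidecar} must be an object")
    return meta


def _resolve_spacing(meta: dict, header_zooms: Optional[Sequence[float]]) -> float:
    if "pixel_spacing_mm" in meta:
        spacing = float(meta["pixel_spacing_mm"])
        if spacing <= 0:
            raise FormatError("pixel_spacing_mm must be positive")
        return spacing
    if header_zooms is not None and len(header_zooms) >= 2:
        rz, cz = float(header_zooms[0]), float(header_zooms[1])
        if rz > 0 and cz > 0 and not (rz == cz == 1.0):
            if not np.isclose(rz, cz):
                raise FormatError(f"anisotropic in-plane spacing {rz}x{cz} unsupported")
            return rz
    logger.warning(
        "pixel spacing missing from metadata; assuming %.2f mm/pixel",
        DEFAULT_PIXEL_SPACING_MM,
    )
    return DEFAULT_PIXEL_SPACING_MM


def _load_volume(path: Path) -> Tuple[np.ndarray, Optional[Sequence[float]]]:
    """Return (slices, header_zooms); slices shaped (n, H, W)."""
    if not path.exists():
        raise FileNotFoundError(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir() if p.suffix.lower() in _IMG_EXTS)
        if not files:
            raise FormatError(f"no image slices found in {path}")
        rasters = [np.asarray(iio.imread(p)) for p in files]
        shapes = {r.shape for r in rasters}
        if len(shapes) != 1 or rasters[0].ndim != 2:
            raise FormatError(f"inconsistent slice shapes in {path}: {sorted(shapes)}")
        return np.stack(rasters, axis=0), None
    name = path.name
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        try:
            img = nib.load(str(path))
            vol = np.asanyarray(img.dataobj)
        except Exception as exc:  # nibabel raises various types for corrupt files
            raise FormatError(f"cannot read NIfTI {path}: {exc}") from exc
        if vol.ndim == 2:
            vol = vol[..., np.newaxis]
        if vol.ndim != 3:
            raise FormatError(f"expected a 3D NIfTI, got shape {vol.shape}")
        # slices along the 3rd axis -> (n, H, W)
        return np.moveaxis(vol, 2, 0), img.header.get_zooms()
    raise FormatError(f"unsupported scan format: {path}")


def read_scan(path: Union[str, Path]) -> CMPRScan:
    """Read a cMPR stack from a NIfTI volume or a directory of 2D slices.

    Slice order (proximal to distal) follows the third NIfTI axis or the
    lexicographic order of the slice files. Identifiers and spacing come
    from a sidecar JSON ``{patient_id, vessel_label, pixel_spacing_mm,
    slice_count}``; spacing falls back to the NIfTI header and then to the
    package default (with a warning).
    """
    path = Path(path)
    slices, zooms = _load_volume(path)
    meta = _read_sidecar(path)
    spacing = _resolve_spacing(meta, zooms)
    declared = meta.get("slice_count")
    if declared is not None and int(declared) != slices.shape[0]:
        raise FormatError(
            f"metadata declares {declared} slices but {slices.shape[0]} were read"
        )
    return CMPRScan(
        patient_id=str(meta.get("patient_id", "unknown")),
        vessel_label=VesselLabel(meta.get("vessel_label", "LAD")),
        slices=slices.astype(np.float64),
        pixel_spacing_mm=spacing,
    )


def _write_sidecar(path: Path, meta: dict) -> None:
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)


def _write_volume(slices: np.ndarray, path: Path, dtype: np.dtype) -> Path:
    path = Path(path)
    name = path.name
    if name.endswith(".nii") or name.endswith(".nii.gz"):
        vol = np.moveaxis(slices.astype(dtype), 0, 2)
        img = nib.Nifti1Image(vol, affine=np.eye(4))
        nib.save(img, str(path))
        return path
    # directory of per-slice images
    path.mkdir(parents=True, exist_ok=True)
    ext = ".png" if dtype == np.uint8 else ".tif"
    for i, sl in enumerate(slices.astype(dtype)):
        iio.imwrite(path / f"slice_{i:03d}{ext}", sl)
    return path


def write_scan(scan: CMPRScan, path: Union[str, Path]) -> Path:
    """Write a scan as NIfTI (``.nii``/``.nii.gz``) or a slice directory.

    HU rasters are stored as signed 16-bit; the round trip is exact for
    integer-valued HU.
    """
    path = Path(path)
    out = _write_volume(np.rint(scan.slices), path, np.dtype(np.int16))
    _write_sidecar(path, {
        "patient_id": scan.patient_id,
        "vessel_label": scan.vessel_label.value,
        "pixel_spacing_mm": scan.pixel_spacing_mm,
        "slice_count": scan.slice_count,
    })
    return out


def read_mask(path: Union[str, Path], mode: str = "stenosis") -> LabelMask:
    """Read a label mask; values outside {0,1,2} raise :class:`FormatError`."""
    path = Path(path)
    slices, zooms = _load_volume(path)
    meta = _read_sidecar(path)
    spacing = _resolve_spacing(meta, zooms)
    return LabelMask(slices=slices, mode=meta.get("mode", mode), pixel_spacing_mm=spacing)


def write_mask(mask: LabelMask, path: Union[str, Path]) -> Path:
    path = Path(path)
    out = _write_volume(mask.slices, path, np.dtype(np.uint8))
    _write_sidecar(path, {
        "mode": mask.mode,
        "pixel_spacing_mm": mask.pixel_spacing_mm,
        "slice_count": mask.slice_count,
    })
    return out


# ---------------------------------------------------------------------------
# Mask post-processing
# ---------------------------------------------------------------------------

def connected_components(
    mask_slice: np.ndarray,
    label: int,
    connectivity: int = 8,
    slice_index: int = 0,
) -> ComponentSet:
    """Partition one label of a 2D mask slice into connected components.

    ``connectivity`` is 4 (edge-adjacent) or 8 (edge+corner adjacent),
    applied in-plane; components never span slices.
    """
    if label not in (1, 2):
        raise ValueError(f"label must be 1 or 2, got {label}")
    conn = {4: 1, 8: 2}.get(connectivity)
    if conn is None:
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    labeled = measure.label(np.asarray(mask_slice) == label, connectivity=conn)
    comps = []
    for region in measure.regionprops(labeled):
        comps.append(Component(label=label, slice_index=slice_index, pixels=region.coords))
    return ComponentSet(comps)


def filter_small_components(
    mask: LabelMask,
    max_removed_size: int = 100,
    labels: Set[int] = frozenset({1, 2}),
    connectivity: int = 8,
) -> LabelMask:
    """Remove small clusters from the mask (segmentation post-processing).

    Every connected component of the given labels with ``max_removed_size``
    pixels or fewer is set to background; components of at least
    ``max_removed_size + 1`` pixels survive. Idempotent.
    """
    if max_removed_size < 0:
        raise ValueError("max_removed_size must be >= 0")
    out = mask.slices.copy()
    for k, sl in enumerate(out):
        for label in sorted(labels):
            comps = connected_components(sl, label, connectivity, slice_index=k)
            for comp in comps.components:
                if comp.size <= max_removed_size:
                    sl[comp.pixels[:, 0], comp.pixels[:, 1]] = 0
    return LabelMask(slices=out, mode=mask.mode, pixel_spacing_mm=mask.pixel_spacing_mm)


def stack_to_volume(mask: LabelMask) -> np.ndarray:
    """Stack the 2D slices orthogonally into a pseudo-3D ``(H, W, n)`` volume.

    The third axis preserves proximal-to-distal slice order; per-label pixel
    counts are conserved.
    """
    return np.moveaxis(mask.slices, 0, 2).copy()
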