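"""Lesion volumetrics and localization.

Covers the mask-level measurements made before any disconnection modeling:
intracranial-volume (ICV) normalized lesion volumes, per-vascular-territory
infarct volumes, the bullseye parcellation of white matter used to localize
WMH burden (9 lobar sectors x 4 concentric relative-depth layers = 36
parcels, layer 1 periventricular, layer 4 juxtacortical), and voxelwise
lesion incidence maps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "LesionMask",
    "BullseyeParcellation",
    "VolumeRecord",
    "lesion_volume",
    "normalize_volume",
    "territory_volumes",
    "bullseye_parcellation",
    "parcel_loads",
    "incidence_map",
    "N_TERRITORIES",
    "N_LOBES",
    "N_LAYERS",
    "N_PARCELS",
]

N_TERRITORIES = 10  # 6 supratentorial + 4 infratentorial vascular territories
N_LOBES = 9
N_LAYERS = 4
N_PARCELS = N_LOBES * N_LAYERS


@dataclass
class LesionMask:
    """A binary lesion mask on a template grid.

    kind is "infarct" (acute, DWI-derived) or "wmh" (chronic FLAIR-derived
    white matter hyperintensities).
    """

    subject_id: str
    kind: str
    grid: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        if self.kind not in ("infarct", "wmh"):
            raise ValueError(f"unknown lesion kind {self.kind!r}")
        grid = np.asarray(self.grid)
        if not np.all(np.isin(np.unique(grid), (0, 1))):
            raise ValueError("lesion grid must be binary")
        self.grid = grid.astype(np.uint8)
        self.affine = np.asarray(self.affine, dtype=float)
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be invertible")


@dataclass
class BullseyeParcellation:
    """White-matter parcel labels: code = (lobe - 1) * 4 + layer, 1..36."""

    labels: np.ndarray
    layer_edges: tuple[float, float, float] = (0.25, 0.5, 0.75)


@dataclass
class VolumeRecord:
    subject_id: str
    raw_cm3: float
    normalized_cm3: float
    per_territory_cm3: np.ndarray
    dominant_territory: int | None = None
    per_parcel_cm3: np.ndarray | None = None


def _voxel_volume_mm3(affine: np.ndarray) -> float:
    return abs(float(np.linalg.det(np.asarray(affine, dtype=float)[:3, :3])))


def _binary(grid: np.ndarray) -> np.ndarray:
    grid = np.asarray(grid)
    if not np.all(np.isin(np.unique(grid), (0, 1))):
        raise ValueError("mask grid must be binary")
    return grid.astype(bool)


def lesion_volume(mask: LesionMask) -> float:
    """Lesion volume in cm³: voxel count x voxel volume / 1000."""
    grid = _binary(mask.grid)
    return int(grid.sum()) * _voxel_volume_mm3(mask.affine) / 1000.0


def normalize_volume(raw_cm3: float, subject_icv: float, cohort_mean_icv: float) -> float:
    """ICV-normalize a volume: raw x cohort mean ICV / subject ICV."""
    if subject_icv <= 0 or cohort_mean_icv <= 0:
        raise ValueError("intracranial volumes must be positive")
    return raw_cm3 * cohort_mean_icv / subject_icv


def _check_same_grid(mask: LesionMask, template) -> None:
    if tuple(mask.grid.shape) != tuple(template.shape):
        raise ValueError("mask and template grids differ in shape")
    if not np.allclose(mask.affine, template.affine, atol=1e-6):
        raise ValueError("mask and template affines differ")


def territory_volumes(mask: LesionMask, template) -> tuple[np.ndarray, int | None]:
    """Per-vascular-territory lesion volume (cm³) and the dominant territory.

    Returns a length-10 vector indexed by territory code 1..10 and the code
    holding the largest volume (ties broken toward the smallest code; None
    for an empty mask).
    """
    _check_same_grid(mask, template)
    grid = _binary(mask.grid)
    codes = np.asarray(template.territory_labels)
    counts = np.bincount(codes[grid], minlength=N_TERRITORIES + 1)[1:]
    vols = counts * _voxel_volume_mm3(mask.affine) / 1000.0
    if vols.sum() == 0:
        return vols, None
    return vols, int(np.argmax(vols)) + 1


def bullseye_parcellation(
    template, layer_edges: Sequence[float] = (0.25, 0.5, 0.75)
) -> BullseyeParcellation:
    """Bullseye white-matter parcellation: 9 lobes x 4 relative-depth layers.

    For each white-matter voxel (brain minus ventricles minus cortical
    shell) the relative depth is d = dv / (dv + dc), with dv and dc the
    Euclidean distances (mm) to the ventricle and cortex masks.  Layers are
    half-open quartile bins [0,.25), [.25,.5), [.5,.75), [.75,1]: layer 1
    hugs the ventricle, layer 4 is juxtacortical.  The parcel code combines
    the template's lobe label with the layer: (lobe-1)*4 + layer.
    """
    vent = np.asarray(template.ventricle_mask, dtype=bool)
    cortex = np.asarray(template.cortex_mask, dtype=bool)
    if not vent.any() or not cortex.any():
        raise ValueError("ventricle and cortex masks must be nonempty")
    sampling = np.sqrt((np.asarray(template.affine)[:3, :3] ** 2).sum(axis=0))
    dv = ndimage.distance_transform_edt(~vent, sampling=sampling)
    dc = ndimage.distance_transform_edt(~cortex, sampling=sampling)
    lobes = np.asarray(template.lobe_labels)
    wm = (lobes > 0) & ~vent & ~cortex
    if hasattr(template, "brain_mask"):
        wm &= np.asarray(template.brain_mask, dtype=bool)
    denom = dv + dc
    with np.errstate(invalid="ignore", divide="ignore"):
        depth = np.where(denom > 0, dv / np.where(denom > 0, denom, 1.0), 0.0)
    edges = np.asarray(layer_edges, dtype=float)
    layer = np.searchsorted(edges, depth, side="right") + 1  # d=edge -> next layer
    labels = np.zeros(vent.shape, dtype=np.int32)
    labels[wm] = (lobes[wm] - 1) * N_LAYERS + layer[wm]
    return BullseyeParcellation(labels=labels, layer_edges=tuple(edges))


def parcel_loads(wmh_mask: LesionMask, parcellation: BullseyeParcellation) -> np.ndarray:
    """WMH volume (cm³) in each of the 36 bullseye parcels."""
    labels = parcellation.labels
    if tuple(wmh_mask.grid.shape) != tuple(labels.shape):
        raise ValueError("mask and parcellation grids differ in shape")
    grid = _binary(wmh_mask.grid)
    counts = np.bincount(labels[grid], minlength=N_PARCELS + 1)[1:]
    return counts * _voxel_volume_mm3(wmh_mask.affine) / 1000.0


def incidence_map(masks: Iterable[LesionMask]) -> np.ndarray:
    """Voxelwise count of subjects with a lesion at each voxel."""
    masks = list(masks)
    if not masks:
        raise ValueError("no masks given")
    shape = masks[0].grid.shape
    out = np.zeros(shape, dtype=np.int32)
    for m in masks:
        if m.grid.shape != shape:
            raise ValueError("all masks must share one grid")
        out += _binary(m.grid)
    return out
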