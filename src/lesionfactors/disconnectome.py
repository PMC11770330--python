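"""Tract-based structural disconnection.

A normative streamline atlas (named tracts, each a bundle of 3-D polylines
in template mm coordinates) is intersected with a subject's binary lesion
mask.  A streamline is *disconnected* when at least one of the voxels it
traverses lies inside the lesion; the per-tract disconnection severity is
the percentage of the tract's streamlines that are disconnected.  The same
procedure is applied independently to acute infarct masks and to chronic
white-matter-hyperintensity masks, giving each subject one percent-
disconnection profile per lesion kind.

The atlas is an abstraction of population deterministic-tractography
atlases in which ~66 anatomist-curated bundles, with the corpus callosum
split into five segments, yield 70 named tracts; :func:`canonical_registry`
provides that naming schema.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Streamline",
    "Tract",
    "StreamlineAtlas",
    "DisconnectionProfile",
    "rasterize_streamline",
    "tract_disconnection",
    "disconnection_profile",
    "profiles_for_masks",
    "canonical_registry",
    "default_step_mm",
]


@dataclass
class Streamline:
    """One reconstructed fiber trajectory: an ordered polyline in mm.

    Parameters
    ----------
    points
        ``(n, 3)`` float array, ``n >= 2``, finite, with consecutive
        points distinct.
    """

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 2:
            raise ValueError("streamline needs an (n, 3) array with n >= 2")
        if not np.all(np.isfinite(pts)):
            raise ValueError("streamline coordinates must be finite")
        if np.any(np.all(np.diff(pts, axis=0) == 0.0, axis=1)):
            raise ValueError("consecutive streamline points must be distinct")
        self.points = pts


@dataclass
class Tract:
    """A named bundle of streamlines."""

    name: str
    streamlines: list[Streamline]

    def __post_init__(self) -> None:
        if not self.streamlines:
            raise ValueError(f"tract {self.name!r} has no streamlines")


@dataclass
class StreamlineAtlas:
    """A collection of named tracts sharing one template space."""

    tracts: list[Tract]
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        names = [t.name for t in self.tracts]
        if len(set(names)) != len(names):
            raise ValueError("tract names must be unique within an atlas")

    @property
    def tract_names(self) -> list[str]:
        return [t.name for t in self.tracts]

    def __len__(self) -> int:
        return len(self.tracts)


@dataclass
class DisconnectionProfile:
    """Per-tract percent disconnection for one subject and lesion kind."""

    subject_id: str
    kind: str
    pct: np.ndarray
    tract_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        pct = np.asarray(self.pct, dtype=float)
        if np.any(pct < 0.0) or np.any(pct > 100.0):
            raise ValueError("percent disconnection must lie in [0, 100]")
        self.pct = pct


def default_step_mm(affine: np.ndarray) -> float:
    """Half the smallest voxel dimension — no voxel can be stepped over."""
    zooms = np.sqrt((np.asarray(affine, dtype=float)[:3, :3] ** 2).sum(axis=0))
    return 0.5 * float(zooms.min())


def _sample_points(points: np.ndarray, step_mm: float) -> np.ndarray:
    """Sample along each polyline segment at spacing <= step_mm.

    Endpoints of every segment are always included.
    """
    segs = np.diff(points, axis=0)
    lengths = np.linalg.norm(segs, axis=1)
    chunks = [points[:1]]
    for i, L in enumerate(lengths):
        n = max(int(np.ceil(L / step_mm)), 1)
        t = np.arange(1, n + 1, dtype=float)[:, None] / n
        chunks.append(points[i] + t * segs[i])
    return np.concatenate(chunks, axis=0)


def _voxel_indices(
    points: np.ndarray,
    affine: np.ndarray,
    grid_shape: Sequence[int],
    step_mm: float,
) -> np.ndarray:
    """Unique in-grid voxel indices traversed by a polyline.

    Voxel membership uses the voxel-center convention: a sample at mm
    coordinate x belongs to voxel round(A^-1 x), 0-based.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("degenerate affine: voxel->mm map is not invertible")
    inv = np.linalg.inv(affine)
    samples = _sample_points(np.asarray(points, dtype=float), step_mm)
    vox = samples @ inv[:3, :3].T + inv[:3, 3]
    idx = np.rint(vox).astype(np.int64)
    shape = np.asarray(grid_shape, dtype=np.int64)
    keep = np.all((idx >= 0) & (idx < shape), axis=1)
    idx = idx[keep]
    if idx.size == 0:
        return idx.reshape(0, 3)
    return np.unique(idx, axis=0)


def rasterize_streamline(
    streamline: Streamline | np.ndarray,
    affine: np.ndarray,
    grid_shape: Sequence[int],
    step_mm: float,
) -> set[tuple[int, int, int]]:
    """Voxelize a streamline onto a grid.

    Parameters
    ----------
    streamline
        A :class:`Streamline` or an ``(n, 3)`` array of mm coordinates.
    affine
        4x4 voxel-to-mm map of the grid.
    grid_shape
        Grid dimensions; samples mapping outside are dropped.
    step_mm
        Maximum spacing between consecutive samples along the polyline.
        At half the smallest voxel dimension (:func:`default_step_mm`)
        no voxel along a segment can be skipped.

    Returns
    -------
    set of (i, j, k)
        Deduplicated 0-based voxel indices traversed by the streamline.
    """
    if step_mm <= 0:
        raise ValueError("step_mm must be positive")
    pts = streamline.points if isinstance(streamline, Streamline) else streamline
    idx = _voxel_indices(pts, affine, grid_shape, step_mm)
    return {tuple(int(v) for v in row) for row in idx}


def _check_mask(mask: np.ndarray) -> np.ndarray:
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("lesion mask must be binary (values 0/1)")
    return mask.astype(bool)


def tract_disconnection(
    tract: Tract,
    mask: np.ndarray,
    affine: np.ndarray,
    step_mm: float | None = None,
) -> float:
    """Percent of a tract's streamlines passing through a lesion mask.

    A streamline counts as disconnected when >= 1 of its traversed voxels
    lies in the mask (single-voxel contact suffices; there is no
    minimum-overlap rule).
    """
    if not tract.streamlines:
        raise ValueError("empty tract")
    grid = _check_mask(mask)
    if step_mm is None:
        step_mm = default_step_mm(affine)
    hits = 0
    for sl in tract.streamlines:
        idx = _voxel_indices(sl.points, affine, grid.shape, step_mm)
        if idx.size and grid[idx[:, 0], idx[:, 1], idx[:, 2]].any():
            hits += 1
    return 100.0 * hits / len(tract.streamlines)


def disconnection_profile(
    atlas: StreamlineAtlas,
    mask: np.ndarray,
    affine: np.ndarray,
    step_mm: float | None = None,
    subject_id: str = "",
    kind: str = "infarct",
) -> DisconnectionProfile:
    """Percent disconnection for every tract of an atlas (atlas order)."""
    pct = np.array(
        [tract_disconnection(t, mask, affine, step_mm) for t in atlas.tracts]
    )
    return DisconnectionProfile(
        subject_id=subject_id, kind=kind, pct=pct, tract_names=atlas.tract_names
    )


def profiles_for_masks(
    atlas: StreamlineAtlas,
    masks: Iterable,
    affine: np.ndarray,
    step_mm: float | None = None,
) -> "np.ndarray":
    """Disconnection matrix (subjects x tracts) for many masks at once.

    Rasterizes each streamline once and reuses the voxel sets across
    subjects, which is what makes cohort-scale profiling cheap.  ``masks``
    is an iterable of binary grids (all sharing the atlas grid/affine).
    """
    masks = list(masks)
    if not masks:
        return np.zeros((0, len(atlas)))
    grid_shape = np.asarray(masks[0]).shape
    if step_mm is None:
        step_mm = default_step_mm(affine)
    # flatten voxel indices per streamline, grouped by tract
    flat_per_tract: list[list[np.ndarray]] = []
    for tract in atlas.tracts:
        flat = []
        for sl in tract.streamlines:
            idx = _voxel_indices(sl.points, affine, grid_shape, step_mm)
            flat.append(np.ravel_multi_index((idx[:, 0], idx[:, 1], idx[:, 2]), grid_shape)
                        if idx.size else np.empty(0, dtype=np.int64))
        flat_per_tract.append(flat)
    out = np.zeros((len(masks), len(atlas)))
    for si, mask in enumerate(masks):
        m = _check_mask(mask).ravel()
        for ti, flat in enumerate(flat_per_tract):
            hits = sum(1 for f in flat if f.size and m[f].any())
            out[si, ti] = 100.0 * hits / len(flat)
    return out


# --- canonical tract naming schema -----------------------------------------

_CALLOSAL_PREFIX = "Corpus Callosum"
_CALLOSAL_SEGMENTS = (
    "Anterior Frontal",
    "Posterior Frontal",
    "Parietal",
    "Temporal",
    "Occipital",
)

_PAIRED_ASSOCIATION = (
    "Arcuate Fasciculus",
    "Superior Longitudinal Fasciculus I",
    "Superior Longitudinal Fasciculus II",
    "Superior Longitudinal Fasciculus III",
    "Inferior Longitudinal Fasciculus",
    "Inferior Fronto-Occipital Fasciculus",
    "Uncinate Fasciculus",
    "Cingulum",
    "Frontal Aslant Tract",
    "Extreme Capsule",
    "Middle Longitudinal Fasciculus",
    "Parietal Aslant Tract",
    "Vertical Occipital Fasciculus",
)

_PAIRED_PROJECTION = (
    "Corticospinal Tract",
    "Corticobulbar Tract",
    "Frontopontine Tract",
    "Parietopontine Tract",
    "Occipitopontine Tract",
    "Corticostriatal Pathway",
    "Anterior Thalamic Radiation",
    "Superior Thalamic Radiation",
    "Posterior Thalamic Radiation",
    "Optic Radiation",
    "Acoustic Radiation",
    "Fornix",
)

_PAIRED_BRAINSTEM = (
    "Medial Lemniscus",
    "Spinothalamic Tract",
    "Central Tegmental Tract",
    "Medial Longitudinal Fasciculus",
)

_PAIRED_CEREBELLAR = (
    "Superior Cerebellar Peduncle",
    "Inferior Cerebellar Peduncle",
)

_UNPAIRED = (
    "Middle Cerebellar Peduncle",
    "Cerebellar Vermis Tract",
    "Anterior Commissure",
)


def canonical_registry(callosal_segments: Sequence[str] | None = None) -> list[str]:
    """The 70-tract naming schema: 65 bundles + 5 callosal segments.

    The corpus callosum is represented by five segments (anterior frontal,
    posterior frontal, parietal, temporal, occipital by default) in place
    of a single commissural bundle, for interpretability of callosal
    disconnection.  Segment labels are configurable; this is a naming
    schema only — geometry for these names exists only in synthetic
    atlases.
    """
    if callosal_segments is None:
        callosal_segments = _CALLOSAL_SEGMENTS
    if len(callosal_segments) != 5:
        raise ValueError("exactly five callosal segment labels are required")
    names: list[str] = []
    for base in _PAIRED_ASSOCIATION + _PAIRED_PROJECTION + _PAIRED_BRAINSTEM + _PAIRED_CEREBELLAR:
        names.append(f"{base} L")
        names.append(f"{base} R")
    names.extend(_UNPAIRED)
    names.extend(f"{_CALLOSAL_PREFIX} - {seg}" for seg in callosal_segments)
    assert len(names) == 70 and len(set(names)) == 70
    return names
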