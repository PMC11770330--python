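"""File formats: NIfTI grids, atlas bundles, profile/corpus tables.

Masks, templates, parcellations and incidence maps travel as NIfTI-1.
A streamline atlas is a directory holding ``atlas.json`` (tract names,
space tag, streamline counts) plus ``coords.npz`` with three arrays:
``points`` — all streamline points stacked ``(total_points, 3)`` in mm;
``offsets`` — start index of each streamline in ``points`` (length
n_streamlines + 1); ``tract_index`` — tract id per streamline.
Profiles and corpora are CSV with a ``subject_id`` column followed by one
column per tract.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .disconnectome import Streamline, StreamlineAtlas, Tract
from .lesion_mapping import LesionMask
from .synth import TemplateSpace

__all__ = [
    "save_mask",
    "load_mask",
    "save_template",
    "load_template",
    "save_atlas",
    "load_atlas",
    "save_profiles",
    "load_profiles",
]

_TEMPLATE_GRIDS = ("brain", "ventricles", "cortex", "lobes", "territories")


def save_mask(mask: LesionMask, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.grid.astype(np.uint8), mask.affine)
    nib.save(img, str(path))
    return path


def load_mask(path, subject_id: str | None = None, kind: str = "infarct") -> LesionMask:
    img = nib.load(str(path))
    grid = np.asarray(img.dataobj)
    if subject_id is None:
        subject_id = Path(path).name.split(".")[0]
    return LesionMask(subject_id=subject_id, kind=kind, grid=(grid > 0).astype(np.uint8), affine=img.affine)


def save_template(template: TemplateSpace, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    grids = {
        "brain": template.brain_mask.astype(np.uint8),
        "ventricles": template.ventricle_mask.astype(np.uint8),
        "cortex": template.cortex_mask.astype(np.uint8),
        "lobes": template.lobe_labels.astype(np.int16),
        "territories": template.territory_labels.astype(np.int16),
    }
    for name, grid in grids.items():
        nib.save(nib.Nifti1Image(grid, template.affine), str(out / f"{name}.nii.gz"))
    return out


def load_template(in_dir) -> TemplateSpace:
    d = Path(in_dir)
    imgs = {name: nib.load(str(d / f"{name}.nii.gz")) for name in _TEMPLATE_GRIDS}
    affine = imgs["brain"].affine
    arr = {name: np.asarray(img.dataobj) for name, img in imgs.items()}
    return TemplateSpace(
        shape=tuple(arr["brain"].shape),
        affine=affine,
        brain_mask=arr["brain"].astype(bool),
        ventricle_mask=arr["ventricles"].astype(bool),
        cortex_mask=arr["cortex"].astype(bool),
        lobe_labels=arr["lobes"].astype(np.int32),
        territory_labels=arr["territories"].astype(np.int32),
    )


def save_atlas(atlas: StreamlineAtlas, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    points, offsets, tract_index = [], [0], []
    for ti, tract in enumerate(atlas.tracts):
        for sl in tract.streamlines:
            points.append(sl.points)
            offsets.append(offsets[-1] + len(sl.points))
            tract_index.append(ti)
    np.savez(
        out / "coords.npz",
        points=np.concatenate(points, axis=0),
        offsets=np.asarray(offsets, dtype=np.int64),
        tract_index=np.asarray(tract_index, dtype=np.int64),
    )
    header = {
        "space_tag": atlas.space_tag,
        "tract_names": atlas.tract_names,
        "n_streamlines": [len(t.streamlines) for t in atlas.tracts],
    }
    (out / "atlas.json").write_text(json.dumps(header, indent=2))
    return out


def load_atlas(in_dir) -> StreamlineAtlas:
    d = Path(in_dir)
    header = json.loads((d / "atlas.json").read_text())
    data = np.load(d / "coords.npz")
    points, offsets, tract_index = data["points"], data["offsets"], data["tract_index"]
    bundles: list[list[Streamline]] = [[] for _ in header["tract_names"]]
    for si, ti in enumerate(tract_index):
        pts = points[offsets[si]:offsets[si + 1]]
        bundles[int(ti)].append(Streamline(points=pts))
    tracts = [Tract(name=nm, streamlines=sls) for nm, sls in zip(header["tract_names"], bundles)]
    return StreamlineAtlas(tracts=tracts, space_tag=header["space_tag"])


def save_profiles(matrix: np.ndarray, tract_names, subject_ids, path) -> Path:
    df = pd.DataFrame(np.asarray(matrix), columns=list(tract_names))
    df.insert(0, "subject_id", list(subject_ids))
    df.to_csv(path, index=False, float_format="%.6g")
    return Path(path)


def load_profiles(path) -> tuple[np.ndarray, list[str], list[str]]:
    df = pd.read_csv(path)
    subject_ids = df["subject_id"].astype(str).tolist()
    tract_names = [c for c in df.columns if c != "subject_id"]
    return df[tract_names].to_numpy(dtype=float), tract_names, subject_ids
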