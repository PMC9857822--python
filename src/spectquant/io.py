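"""Reading and writing the pipeline's standard formats.

Volumes travel as NIfTI (via nibabel) with an isotropic diagonal affine;
VOIs as JSON sphere lists; measurement and cohort tables as CSV; generator
settings as YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Union

import nibabel as nib
import numpy as np
import yaml

from .quantify import SphereVoi, VoxelGrid

PathLike = Union[str, Path]


def save_volume(grid: VoxelGrid, path: PathLike) -> None:
    affine = np.diag([grid.voxel_size_mm] * 3 + [1.0])
    affine[:3, 3] = grid.origin_mm
    nib.save(nib.Nifti1Image(grid.values.astype(np.float32), affine), str(path))


def load_volume(path: PathLike) -> VoxelGrid:
    img = nib.load(str(path))
    affine = img.affine
    steps = np.sqrt((affine[:3, :3] ** 2).sum(axis=0))
    if not np.allclose(steps, steps[0], rtol=1e-4):
        raise ValueError(f"{path}: anisotropic voxels are not supported")
    return VoxelGrid(values=np.asarray(img.dataobj, dtype=float),
                     voxel_size_mm=float(steps[0]),
                     origin_mm=affine[:3, 3].astype(float))


def save_vois(vois: List[SphereVoi], path: PathLike) -> None:
    payload = [
        {"label": v.label, "site": v.site, "center_mm": list(v.center_mm),
         "radius_mm": v.radius_mm}
        for v in vois
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def load_vois(path: PathLike) -> List[SphereVoi]:
    payload = json.loads(Path(path).read_text())
    return [
        SphereVoi(center_mm=tuple(d["center_mm"]), radius_mm=d["radius_mm"],
                  label=d.get("label", ""), site=d.get("site", "other"))
        for d in payload
    ]


def load_config(path: PathLike) -> dict:
    return yaml.safe_load(Path(path).read_text())


def save_config(config: dict, path: PathLike) -> None:
    Path(path).write_text(yaml.safe_dump(config, sort_keys=False))
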