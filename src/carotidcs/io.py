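"""NIfTI volume and geometry sidecar I/O.

Volumes are written as magnitude NIfTI with a diagonal affine carrying the
voxel size in mm; the ground-truth geometry travels in a JSON sidecar so a
phantom dataset on disk is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import GroundTruthGeometry

__all__ = ["save_volume", "load_volume", "save_geometry", "load_geometry"]


def save_volume(path: str | Path, volume: np.ndarray, voxel_mm: tuple[float, float, float]) -> None:
    """Write a magnitude volume as NIfTI; complex input is magnitude-converted."""
    data = np.abs(volume) if np.iscomplexobj(volume) else np.asarray(volume)
    affine = np.diag([*voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float32), affine), str(path))


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    voxel = tuple(float(v) for v in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj, dtype=np.float32), voxel


def save_geometry(path: str | Path, geometry: GroundTruthGeometry) -> None:
    payload = {
        "bifurcation_index": int(geometry.bifurcation_index),
        "bifurcation_z_mm": float(geometry.bifurcation_z_mm),
        "voxel_mm": list(geometry.voxel_mm),
        "per_slice": geometry.per_slice.to_dict(orient="records"),
    }
    Path(path).write_text(json.dumps(payload))


def load_geometry(path: str | Path) -> GroundTruthGeometry:
    payload = json.loads(Path(path).read_text())
    return GroundTruthGeometry(
        per_slice=pd.DataFrame(payload["per_slice"]),
        bifurcation_index=payload["bifurcation_index"],
        bifurcation_z_mm=payload["bifurcation_z_mm"],
        voxel_mm=tuple(payload["voxel_mm"]),
    )
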