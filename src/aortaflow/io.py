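"""NIfTI + JSON sidecar layout for datasets and derived volumes.

A dataset directory contains::

    velocity.nii.gz      5D (X, Y, Z, T, 3) m/s   (or velocity_{x,y,z}.nii.gz)
    magnitude_0.nii.gz   4D (X, Y, Z, T) reference |S|
    magnitude_{1,2,3}.nii.gz   encoded |S_i|
    lumen_mask.nii.gz    3D uint8 ground-truth mask (phantoms only)
    sidecar.json         venc, spacing, timeframe fractions, landmarks,
                         provenance, and the generating spec when known
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .datatypes import Centerline, FlowDataset


def _affine(spacing: np.ndarray) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def save_flow_dataset(
    out_dir: str | Path,
    data: FlowDataset,
    lumen_mask: np.ndarray | None = None,
    landmarks_xyz: dict | None = None,
    extra_sidecar: dict | None = None,
    split_velocity: bool = False,
) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(data.voxel_spacing)
    # (T, X, Y, Z, 3) -> (X, Y, Z, T, 3)
    vel = np.moveaxis(data.velocity, 0, 3)
    if split_velocity:
        for c, name in enumerate("xyz"):
            nib.save(nib.Nifti1Image(vel[..., c], aff), out / f"velocity_{name}.nii.gz")
    else:
        nib.save(nib.Nifti1Image(vel, aff), out / "velocity.nii.gz")
    for k in range(4):
        mag = np.moveaxis(data.magnitudes[:, k], 0, 3)
        nib.save(nib.Nifti1Image(mag, aff), out / f"magnitude_{k}.nii.gz")
    if lumen_mask is not None:
        nib.save(
            nib.Nifti1Image(lumen_mask.astype(np.uint8), aff), out / "lumen_mask.nii.gz"
        )
    sidecar = {
        "venc": data.venc,
        "voxel_spacing": data.voxel_spacing,
        "timeframe_fractions": data.timeframe_fractions,
        "superior_axis": data.superior_axis,
        "split_velocity": split_velocity,
        "provenance": data.provenance,
    }
    if landmarks_xyz is not None:
        sidecar["landmarks_xyz"] = {k: np.asarray(v) for k, v in landmarks_xyz.items()}
    if extra_sidecar:
        sidecar.update(extra_sidecar)
    (out / "sidecar.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True, default=_json_default)
    )
    return out


def load_flow_dataset(in_dir: str | Path) -> tuple[FlowDataset, dict]:
    """Read a dataset directory back; returns (dataset, sidecar dict)."""
    src = Path(in_dir)
    sidecar = json.loads((src / "sidecar.json").read_text())
    if sidecar.get("split_velocity"):
        comps = [
            np.asarray(nib.load(src / f"velocity_{n}.nii.gz").dataobj, dtype=float)
            for n in "xyz"
        ]
        vel = np.stack(comps, axis=-1)
    else:
        vel = np.asarray(nib.load(src / "velocity.nii.gz").dataobj, dtype=float)
    velocity = np.moveaxis(vel, 3, 0)
    mags = [
        np.moveaxis(
            np.asarray(nib.load(src / f"magnitude_{k}.nii.gz").dataobj, dtype=float), 3, 0
        )
        for k in range(4)
    ]
    data = FlowDataset(
        velocity=velocity,
        magnitudes=np.stack(mags, axis=1),
        venc=np.asarray(sidecar["venc"], dtype=float),
        voxel_spacing=np.asarray(sidecar["voxel_spacing"], dtype=float),
        timeframe_fractions=np.asarray(sidecar["timeframe_fractions"], dtype=float),
        superior_axis=int(sidecar.get("superior_axis", 2)),
        provenance=list(sidecar.get("provenance", [])),
    )
    return data, sidecar


def load_lumen_mask(in_dir: str | Path) -> np.ndarray | None:
    p = Path(in_dir) / "lumen_mask.nii.gz"
    if not p.exists():
        return None
    return np.asarray(nib.load(p).dataobj) > 0


def save_centerline_csv(path: str | Path, centerline: Centerline) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "x_mm": centerline.points[:, 0],
            "y_mm": centerline.points[:, 1],
            "z_mm": centerline.points[:, 2],
            "s_mm": centerline.s,
        }
    ).to_csv(path, index=False)
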