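"""Readers and writers for the standard interchange formats.

Velocity fields travel as NIfTI — either one 5-D file (x, y, z, frame,
component) or one 4-D file per velocity component (``*_vx/vy/vz.nii``,
the per-component dialect common in phase-contrast exports); both are
readable.  Surfaces travel as STL or PLY; centerlines as CSV
(x, y, z, s); landmarks and ground-truth manifests as JSON; profiles as
CSV.  The NIfTI affine records the isotropic voxel spacing and the
position of voxel (0, 0, 0), keeping the millimetre world frame
unambiguous.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import trimesh

from .geometry import Centerline, RegionLandmarks, LANDMARK_NAMES
from .phantom import VelocityField4D

__all__ = [
    "save_velocity_field",
    "load_velocity_field",
    "save_surface",
    "load_surface",
    "save_centerline",
    "load_centerline",
    "save_landmarks",
    "load_landmarks",
    "save_manifest",
    "load_manifest",
    "save_vertex_scalars",
    "save_scalar_volume",
]

_COMPONENT_SUFFIXES = ("_vx", "_vy", "_vz")


def _affine(field: VelocityField4D) -> np.ndarray:
    aff = np.diag([field.spacing] * 3 + [1.0])
    aff[:3, 3] = field.origin
    return aff


def save_velocity_field(
    field: VelocityField4D, path: str | Path, dialect: str = "5d"
) -> list[Path]:
    """Write a velocity field as NIfTI; returns the written paths.

    ``dialect="5d"`` writes one file shaped (nx, ny, nz, nt, 3);
    ``dialect="components"`` writes three 4-D files (nx, ny, nz, nt), one
    per velocity component, with ``_vx/_vy/_vz`` suffixes.
    """
    path = Path(path)
    aff = _affine(field)
    # (nt, nx, ny, nz, 3) -> (nx, ny, nz, nt, 3)
    arr = np.moveaxis(field.data, 0, 3)
    written: list[Path] = []
    if dialect == "5d":
        img = nib.Nifti1Image(arr.astype(np.float32), aff)
        img.header["pixdim"][4] = np.diff(field.frame_times).mean() if field.n_frames > 1 else 0
        nib.save(img, str(path))
        written.append(path)
    elif dialect == "components":
        stem = path.with_suffix("").with_suffix("") if path.suffix else path
        for k, suffix in enumerate(_COMPONENT_SUFFIXES):
            p = Path(str(stem) + suffix + ".nii.gz")
            nib.save(nib.Nifti1Image(arr[..., k].astype(np.float32), aff), str(p))
            written.append(p)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    meta = path.with_suffix("").with_suffix("")
    meta = Path(str(meta) + "_frames.json")
    meta.write_text(json.dumps({"frame_times_ms": field.frame_times.tolist()}))
    written.append(meta)
    return written


def load_velocity_field(path: str | Path | list) -> VelocityField4D:
    """Read a velocity field from either NIfTI dialect.

    Pass a single 5-D file, or a list of three per-component 4-D files in
    (vx, vy, vz) order.
    """
    if isinstance(path, (list, tuple)):
        imgs = [nib.load(str(p)) for p in path]
        arr = np.stack([np.asarray(i.dataobj, dtype=np.float32) for i in imgs], axis=-1)
        img = imgs[0]
        base = Path(path[0])
        stem = str(base).rsplit("_v", 1)[0]
    else:
        img = nib.load(str(path))
        arr = np.asarray(img.dataobj, dtype=np.float32)
        if arr.ndim == 4:  # single-frame 5d file squeezed by nibabel
            arr = arr[:, :, :, None, :] if arr.shape[-1] == 3 else arr
        stem = str(Path(path).with_suffix("").with_suffix(""))
    if arr.ndim != 5 or arr.shape[-1] != 3:
        raise ValueError("expected a 5-D (x, y, z, t, component) velocity array")
    aff = img.affine
    spacing = float(aff[0, 0])
    origin = np.asarray(aff[:3, 3], dtype=float)
    data = np.moveaxis(arr, 3, 0)  # -> (nt, nx, ny, nz, 3)
    meta = Path(stem + "_frames.json")
    if meta.exists():
        frame_times = np.asarray(json.loads(meta.read_text())["frame_times_ms"])
    else:
        frame_times = np.arange(data.shape[0], dtype=float)
    return VelocityField4D(
        data=data, spacing=spacing, origin=origin, frame_times=frame_times
    )


def save_surface(surface: trimesh.Trimesh, path: str | Path) -> Path:
    """Write a lumen surface as STL or PLY (by extension)."""
    path = Path(path)
    surface.export(str(path))
    return path


def load_surface(path: str | Path) -> trimesh.Trimesh:
    mesh = trimesh.load(str(path), force="mesh")
    if not isinstance(mesh, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangulated surface")
    return mesh


def save_centerline(centerline: Centerline, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {
            "x": centerline.points[:, 0],
            "y": centerline.points[:, 1],
            "z": centerline.points[:, 2],
            "s": centerline.s,
        }
    )
    df.to_csv(path, index=False)
    return path


def load_centerline(path: str | Path) -> Centerline:
    df = pd.read_csv(path)
    return Centerline.from_points(df[["x", "y", "z"]].to_numpy(dtype=float))


def save_landmarks(landmarks: RegionLandmarks, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(
        json.dumps({n: getattr(landmarks, n) for n in LANDMARK_NAMES}, indent=2)
    )
    return path


def load_landmarks(path: str | Path) -> RegionLandmarks:
    d = json.loads(Path(path).read_text())
    return RegionLandmarks(**{n: float(d[n]) for n in LANDMARK_NAMES})


def save_vertex_scalars(
    surface: trimesh.Trimesh, values: np.ndarray, path: str | Path,
    name: str = "wss_pa",
) -> Path:
    """Write per-vertex scalars (e.g. wall shear stress) as CSV alongside
    the mesh: columns x, y, z, <name>."""
    path = Path(path)
    df = pd.DataFrame(surface.vertices, columns=["x", "y", "z"])
    df[name] = np.asarray(values, dtype=float)
    df.to_csv(path, index=False)
    return path


def save_scalar_volume(
    volume: np.ndarray, spacing: float, origin: np.ndarray, path: str | Path
) -> Path:
    """Write a per-voxel scalar volume (e.g. dissipation density) as NIfTI
    on the same grid convention as the velocity fields."""
    aff = np.diag([spacing] * 3 + [1.0])
    aff[:3, 3] = origin
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float32), aff), str(path))
    return Path(path)


def save_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2))
    return path


def load_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
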