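"""Readers and writers for the formats shared across the pipeline.

PLY (ascii and binary little-endian) for surface meshes, multi-page or
per-slice TIFF for voxel stacks (voxel size and origin travel in a JSON
sidecar), JSON for per-petal annotations, CSV for landmark tables and a
simple one-point-per-line landmark exchange text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import trimesh

from .landmarker import LandmarkConfiguration, PetalAnnotation
from .volseg import VoxelVolume


class FormatError(ValueError):
    pass


# -- meshes ------------------------------------------------------------------

def write_ply(mesh: trimesh.Trimesh, path, *, binary: bool = True) -> None:
    """Write a mesh as PLY, binary little-endian by default, ascii otherwise."""
    data = mesh.export(file_type="ply", encoding="binary" if binary else "ascii")
    Path(path).write_bytes(data if isinstance(data, bytes) else data.encode())


def read_ply(path) -> trimesh.Trimesh:
    path = Path(path)
    try:
        mesh = trimesh.load(path, file_type="ply", process=False)
    except Exception as exc:
        raise FormatError(f"cannot parse PLY {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0:
        raise FormatError(f"{path} contains no triangle mesh")
    return mesh


# -- voxel stacks ------------------------------------------------------------

def write_tiff_stack(volume: VoxelVolume, path) -> None:
    """Multi-page TIFF (one page per slice) plus a JSON sidecar with the
    voxel size and grid origin."""
    path = Path(path)
    tifffile.imwrite(path, volume.intensities, photometric="minisblack")
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps({
        "voxel_size_um": volume.voxel_size_um,
        "origin_mm": list(map(float, volume.origin_mm)),
    }))


def read_tiff_stack(path, voxel_size_um: float | None = None) -> VoxelVolume:
    """Read a multi-page TIFF or a directory of per-slice TIFFs (sorted by name)."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in (".tif", ".tiff"))
        if not files:
            raise FormatError(f"no TIFF slices in {path}")
        arr = np.stack([tifffile.imread(f) for f in files])
        sidecar = path / "stack.json"
    else:
        arr = tifffile.imread(path)
        if arr.ndim == 2:
            arr = arr[None]
        sidecar = path.with_suffix(path.suffix + ".json")
    origin = np.zeros(3)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        voxel_size_um = voxel_size_um or meta.get("voxel_size_um")
        origin = np.asarray(meta.get("origin_mm", [0, 0, 0]), float)
    if voxel_size_um is None:
        raise FormatError("voxel_size_um not given and no sidecar metadata found")
    return VoxelVolume(arr, voxel_size_um, origin)


# -- landmarks ---------------------------------------------------------------

def write_landmarks_csv(config: LandmarkConfiguration, path,
                        flower_id: str | None = None) -> None:
    # %.17g guarantees exact binary round trip of the coordinates
    config.to_dataframe(flower_id).to_csv(path, index=False, float_format="%.17g")


def read_landmarks_csv(path) -> LandmarkConfiguration:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"point_index", "petal", "role", "within_role",
                "lobe_member", "tube_member", "x", "y", "z"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"landmark CSV {path} missing columns {sorted(missing)}")
    return LandmarkConfiguration.from_dataframe(df)


def write_landmarks_text(config: LandmarkConfiguration, path) -> None:
    """Plain landmark exchange: a count header then one 'x y z' per line."""
    lines = [str(len(config))]
    lines += [f"{x:.9g} {y:.9g} {z:.9g}" for x, y, z in config.coords]
    Path(path).write_text("\n".join(lines) + "\n")


def read_landmarks_text(path) -> np.ndarray:
    lines = Path(path).read_text().strip().splitlines()
    try:
        n = int(lines[0])
        pts = np.array([[float(v) for v in ln.split()] for ln in lines[1:]])
    except (ValueError, IndexError) as exc:
        raise FormatError(f"malformed landmark text {path}: {exc}") from exc
    if len(pts) != n:
        raise FormatError(f"{path}: header says {n} points, found {len(pts)}")
    return pts


# -- annotations -------------------------------------------------------------

def write_annotations_json(annotations: list[PetalAnnotation], path) -> None:
    payload = {"petals": [{
        "petal_index": a.petal_index,
        "lm_I": a.lm_I.tolist(),
        "lm_II": a.lm_II.tolist(),
        "lm_III": a.lm_III.tolist(),
        "contour_points": a.contour_points.tolist(),
        "midrib_points": a.midrib_points.tolist(),
    } for a in annotations]}
    Path(path).write_text(json.dumps(payload))


def read_annotations_json(path) -> list[PetalAnnotation]:
    try:
        payload = json.loads(Path(path).read_text())
        petals = payload["petals"]
        anns = [PetalAnnotation(
            petal_index=int(p["petal_index"]),
            lm_I=np.asarray(p["lm_I"], float),
            lm_II=np.asarray(p["lm_II"], float),
            lm_III=np.asarray(p["lm_III"], float),
            contour_points=np.asarray(p["contour_points"], float),
            midrib_points=np.asarray(p["midrib_points"], float),
        ) for p in petals]
    except (KeyError, ValueError, TypeError) as exc:
        raise FormatError(f"malformed annotation JSON {path}: {exc}") from exc
    return sorted(anns, key=lambda a: a.petal_index)
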