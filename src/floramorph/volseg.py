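"""Flower-region segmentation of micro-CT slice stacks and surface extraction.

The raw scan of a mounted flower contains, besides the corolla itself, a
bright fastening base at a fixed position in every slice and sparse bright
"sparkle" noise in the background.  Segmentation proceeds slice by slice in
stack order: base removal, contrast stretching, binarisation, small-object
removal, masking of the original grayscale slice and a grayscale closing
with a radius-1 disc.  The cleaned volume is then converted to a triangle
surface mesh (marching cubes) scaled to millimetres.

Axis convention: array axes are (slice, row, col) = (Z, Y, X); world
coordinates in mm are ``index * voxel_size_um / 1000 + origin_mm`` with the
origin at the grid corner.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import ndimage
from skimage import exposure, filters, measure, morphology

log = logging.getLogger(__name__)


class SegmentationError(RuntimeError):
    pass


class ResourceError(RuntimeError):
    """Requested grid or mesh exceeds the configured resource cap."""


@dataclass(frozen=True)
class VoxelVolume:
    """Isotropic 3D grayscale grid with physical voxel size.

    ``origin_mm`` records where the grid corner sits in world coordinates so
    that meshes extracted from the volume live in the same frame as the
    geometry the volume was rasterised from.
    """

    intensities: np.ndarray
    voxel_size_um: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3 or arr.size == 0:
            raise ValueError("intensities must be a non-empty 3D grid")
        if not self.voxel_size_um > 0:
            raise ValueError("voxel_size_um must be > 0")
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "origin_mm", np.asarray(self.origin_mm, float).reshape(3))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_size_mm(self) -> float:
        return self.voxel_size_um / 1000.0

    def foreground_count(self) -> int:
        return int(np.count_nonzero(self.intensities))


@dataclass(frozen=True)
class SegmentationConfig:
    """All thresholds of the per-slice segmentation chain.

    The base detector zeroes connected components that are both larger than
    ``base_min_px`` and centred inside the configured slice region (default:
    the bottom 20% of rows) — size alone is not used because the flower can
    be the largest object in some slices.
    """

    base_region_frac: float = 0.2     # fraction of rows at the slice bottom
    base_min_px: int = 300
    low_pct: float = 1.0
    high_pct: float = 99.0
    gamma: float = 1.0
    binarize_method: str = "otsu"     # "otsu" or "fixed:<T>"
    min_px: int = 50                  # sparkle threshold (component pixels)
    connectivity: int = 2             # 8-neighbour in-slice
    iso_level: float = 0.5
    target_faces: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.low_pct < self.high_pct <= 100:
            raise ValueError("need 0 <= low_pct < high_pct <= 100")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if not 0 < self.base_region_frac <= 1:
            raise ValueError("base_region_frac must be in (0, 1]")


def downsample(volume: VoxelVolume, factor: int) -> VoxelVolume:
    """Reduce each axis by an integer ``factor`` using block means.

    Trailing voxels that do not complete a block are cropped.  The voxel
    size is multiplied by the factor (e.g. 35 um at factor 2 -> 70 um).
    """
    if factor < 1 or factor != int(factor):
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return volume
    arr = volume.intensities
    if any(s < factor for s in arr.shape):
        raise ValueError(f"factor {factor} exceeds a volume dimension {arr.shape}")
    crop = tuple(slice(0, (s // factor) * factor) for s in arr.shape)
    a = arr[crop].astype(float)
    nz, ny, nx = (s // factor for s in arr.shape)
    a = a.reshape(nz, factor, ny, factor, nx, factor).mean(axis=(1, 3, 5))
    out = a.astype(arr.dtype) if np.issubdtype(arr.dtype, np.integer) else a
    return VoxelVolume(out, volume.voxel_size_um * factor, volume.origin_mm)


def remove_base(slice_: np.ndarray, *, base_region_frac: float = 0.2,
                base_min_px: int = 300) -> np.ndarray:
    """Zero connected components that look like the fastening base.

    A component is removed when its pixel count exceeds ``base_min_px`` AND
    its centroid row lies inside the bottom ``base_region_frac`` of the
    slice.  Everything else is left untouched; a slice with no matching
    component is returned unchanged.
    """
    lab, n = ndimage.label(slice_ > 0, structure=np.ones((3, 3), int))
    if n == 0:
        return slice_.copy()
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    centroids = ndimage.center_of_mass(np.ones_like(lab), lab, np.arange(1, n + 1))
    cutoff_row = slice_.shape[0] * (1.0 - base_region_frac)
    out = slice_.copy()
    for i, (size, (crow, _ccol)) in enumerate(zip(sizes, centroids), start=1):
        if size > base_min_px and crow >= cutoff_row:
            out[lab == i] = 0
    return out


def stretch_contrast(slice_: np.ndarray, low_pct: float = 1.0,
                     high_pct: float = 99.0, gamma: float = 1.0) -> np.ndarray:
    """Percentile contrast stretch followed by a gamma map.

    The ``low_pct``/``high_pct`` intensity percentiles are mapped to the
    dtype min/max, then ``out = max * (in / max) ** gamma``; the combined
    transform is monotone non-decreasing.  A constant slice cannot be
    stretched and is returned unchanged with a warning.
    """
    if not 0 <= low_pct < high_pct <= 100:
        raise ValueError("need 0 <= low_pct < high_pct <= 100")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    lo, hi = np.percentile(slice_, [low_pct, high_pct])
    if hi <= lo:
        log.warning("constant slice: contrast stretch skipped")
        return slice_.copy()
    stretched = exposure.rescale_intensity(slice_, in_range=(lo, hi))
    return exposure.adjust_gamma(stretched, gamma)


def binarize(slice_: np.ndarray, method: str = "otsu") -> np.ndarray:
    """Binarise a grayscale slice; foreground is strictly above the threshold.

    ``method`` is ``"otsu"`` (between-class-variance maximising threshold)
    or ``"fixed:<T>"``.  A constant slice has no Otsu threshold and yields
    an all-background mask with a warning.
    """
    if method == "otsu":
        if slice_.min() == slice_.max():
            log.warning("constant slice: Otsu undefined, returning empty mask")
            return np.zeros(slice_.shape, bool)
        t = filters.threshold_otsu(slice_)
    elif method.startswith("fixed:"):
        t = float(method.split(":", 1)[1])
    else:
        raise ValueError(f"unknown binarization method {method!r}")
    return slice_ > t


def remove_small_objects(mask: np.ndarray, min_px: int,
                         connectivity: int = 2) -> np.ndarray:
    """Remove connected components smaller than ``min_px`` pixels (8-neighbour default)."""
    if min_px < 0:
        raise ValueError("min_px must be >= 0")
    if min_px <= 1:
        return mask.copy()
    # remove components of size <= min_px - 1, i.e. keep sizes >= min_px
    return morphology.remove_small_objects(mask.astype(bool), max_size=min_px - 1,
                                           connectivity=connectivity)


def mask_and_close(slice_: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Apply the binary mask to the grayscale slice, then a grayscale closing.

    The closing uses a disc of radius 1 pixel and fills isolated dark
    ("hollow") pixels inside the petals.
    """
    if slice_.shape != mask.shape:
        raise ValueError(f"shape mismatch: slice {slice_.shape} vs mask {mask.shape}")
    masked = np.where(mask, slice_, 0)
    return morphology.closing(masked, footprint=morphology.disk(1))


def segment_stack(volume: VoxelVolume, config: SegmentationConfig | None = None
                  ) -> VoxelVolume:
    """Run the per-slice segmentation chain over a whole stack, in order."""
    cfg = config or SegmentationConfig()
    out = np.zeros_like(volume.intensities)
    for i, sl in enumerate(volume.intensities):
        try:
            s = remove_base(sl, base_region_frac=cfg.base_region_frac,
                            base_min_px=cfg.base_min_px)
            if not s.any():      # nothing left in this slice
                continue
            s = stretch_contrast(s, cfg.low_pct, cfg.high_pct, cfg.gamma)
            mask = binarize(s, cfg.binarize_method)
            mask = remove_small_objects(mask, cfg.min_px, cfg.connectivity)
            out[i] = mask_and_close(s, mask)
            _, n_comp = ndimage.label(mask, structure=np.ones((3, 3), int))
            log.debug("slice %d: %d components, %d foreground px",
                      i, n_comp, int(mask.sum()))
        except Exception as exc:  # annotate failures with the slice index
            raise SegmentationError(f"slice {i}: {exc}") from exc
    return VoxelVolume(out, volume.voxel_size_um, volume.origin_mm)


def _cluster_decimate(mesh: trimesh.Trimesh, target_faces: int) -> trimesh.Trimesh:
    """Deterministic vertex-clustering decimation toward ``target_faces``."""
    current = mesh
    pitch = float(mesh.scale) / max(np.cbrt(2.0 * target_faces), 4.0)
    for _ in range(12):
        if len(current.faces) <= target_faces:
            break
        grid = np.round(mesh.vertices / pitch).astype(np.int64)
        _, inverse = np.unique(grid, axis=0, return_inverse=True)
        n_cells = int(inverse.max()) + 1
        centers = np.zeros((n_cells, 3))
        np.add.at(centers, inverse, mesh.vertices)
        centers /= np.bincount(inverse).astype(float)[:, None]
        faces = inverse[mesh.faces]
        keep = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) \
            & (faces[:, 0] != faces[:, 2])
        current = trimesh.Trimesh(vertices=centers, faces=faces[keep], process=True)
        pitch *= 1.5
    return current


def extract_surface(volume: VoxelVolume, iso_level: float = 0.5,
                    target_faces: int | None = None) -> trimesh.Trimesh:
    """Marching-cubes isosurface of a segmented volume, in mm.

    The volume is normalised to {0, 1} occupancy and the isosurface taken at
    ``iso_level`` (default 0.5); vertices are scaled by the voxel size and
    shifted by the volume origin.  Optional decimation (vertex clustering)
    reduces the mesh toward ``target_faces``.
    """
    occ = (volume.intensities > 0)
    if not occ.any():
        raise SegmentationError("no surface: volume has empty foreground")
    padded = np.pad(occ, 1).astype(np.float32)
    s = volume.voxel_size_mm
    verts, faces, _, _ = measure.marching_cubes(padded, level=iso_level,
                                                spacing=(s, s, s))
    verts -= s  # undo padding offset
    # (slice,row,col)=(z,y,x) -> world (x,y,z)
    verts = verts[:, ::-1] + volume.origin_mm
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    mesh.update_faces(mesh.nondegenerate_faces())
    if target_faces is not None and len(mesh.faces) > target_faces:
        mesh = _cluster_decimate(mesh, target_faces)
    return mesh


def segment_and_mesh(volume: VoxelVolume, config: SegmentationConfig | None = None
                     ) -> tuple[VoxelVolume, trimesh.Trimesh]:
    """Convenience: segmentation chain followed by surface extraction."""
    cfg = config or SegmentationConfig()
    seg = segment_stack(volume, cfg)
    return seg, extract_surface(seg, cfg.iso_level, cfg.target_faces)
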