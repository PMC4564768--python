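"""Parametric synthetic five-lobed corolla generator.

Emulates the study material — a gloxinia-like corolla with a fused basal
tube and free distal lobes — across an opening x asymmetry morphospace, so
that every downstream stage (segmentation, landmarking, shape statistics,
trait scoring) can be exercised against known ground truth without scanner
data.

Geometry
--------
The tube is an oblique vessel: horizontal circular cross sections whose
centres run along an axis tilted by a construction angle ``tau`` in the
dorsoventral (y-z) plane, with a radius profile that rises from a narrow
base into an inflated chamber and narrows again to a constricted rim at
the opening.  The rim constriction is what makes the landmark scheme
self-consistent on this geometry: because the rim is a steep local radius
minimum, the surface point nearest the midpoint of two adjacent lobe
intersections (the operational definition of the lobe/tube boundary
landmark IV) is the opening-rim point itself rather than a point partway
down the leaning tube wall.  The tube opens into a circle of radius ``tube_radius`` in the z = 0
plane (normal +z); the five lobe intersections sit exactly on that circle,
and the five midrib distal points sit exactly on the lobe-widening circle
of radius ``opening_ratio * tube_radius``, so the flower-opening trait
equals ``opening_ratio`` by construction.

The asymmetry trait is the angle between the first principal axis of the
tube landmarks and the opening normal; the principal axis of a finite
landmark cloud deviates slightly from the construction axis, so ``tau`` is
solved (1-D bracketed root find on the exact analytic configuration) such
that the measured asymmetry angle equals ``tilt_angle_deg`` to machine
precision.  Ground-truth trait values therefore round-trip through the
trait module exactly, not merely approximately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh
from scipy import ndimage
from scipy.stats import truncnorm


from .landmarker import (DEFAULT_SCHEME, LandmarkConfiguration, PetalAnnotation,
                         assemble_configuration)
from .volseg import ResourceError, VoxelVolume

log = logging.getLogger(__name__)


class ParameterError(ValueError):
    """A flower parameter violates its documented range."""


@dataclass(frozen=True)
class FlowerParams:
    """Generative parameters of one synthetic corolla.

    Units: lengths in mm, angles in degrees, voxel size in micrometres.
    ``opening_ratio`` is the target ratio of the lobe-widening circle
    diameter to the tube-opening circle diameter; ``tilt_angle_deg`` is the
    target asymmetry angle between the tube long axis and the opening-plane
    normal.  ``base_taper`` sets the tube base radius as a fraction of the
    opening radius (flowers narrow toward the pedicel).
    """

    n_petals: int = 5
    tube_length: float = 20.0
    tube_radius: float = 6.0
    lobe_length: float = 8.0
    opening_ratio: float = 1.74
    tilt_angle_deg: float = 16.19
    dorsal_index: int = 0
    noise_sparkle_density: float = 2e-4
    base_height: float = 3.0
    seed: int = 0
    voxel_size_um: float = 100.0
    base_taper: float = 0.35
    throat_bulge: float = 4.5

    def __post_init__(self) -> None:
        checks = [
            ("n_petals", self.n_petals >= 3),
            ("tube_radius", self.tube_radius > 0),
            ("tube_length", self.tube_length > 0),
            ("lobe_length", self.lobe_length > 0),
            ("opening_ratio", self.opening_ratio >= 1),
            ("tilt_angle_deg", 0 <= self.tilt_angle_deg < 90),
            ("dorsal_index", 0 <= self.dorsal_index < self.n_petals),
            ("noise_sparkle_density", 0 <= self.noise_sparkle_density < 1),
            ("base_height", self.base_height >= 0),
            ("voxel_size_um", self.voxel_size_um > 0),
            ("base_taper", 0 < self.base_taper <= 1),
            ("throat_bulge", self.throat_bulge >= 0),
        ]
        for name, ok in checks:
            if not ok:
                raise ParameterError(f"invalid value for field {name!r}: "
                                     f"{getattr(self, name)!r}")
        rim_slope = (self.throat_bulge - 1.0) * (1.0 - self.base_taper) \
            * self.tube_radius
        lean = self.tube_length * np.sin(np.deg2rad(self.tilt_angle_deg))
        if rim_slope <= 1.05 * lean:
            raise ParameterError(
                "invalid value for field 'throat_bulge': the rim constriction "
                f"(slope {rim_slope:.3g} mm) must exceed the axial lean "
                f"({lean:.3g} mm) for the boundary-landmark construction"
            )
        radial_gap = (self.opening_ratio - 1.0) * self.tube_radius
        if self.lobe_length <= radial_gap:
            raise ParameterError(
                "invalid value for field 'lobe_length': "
                f"{self.lobe_length} mm cannot span the radial gap "
                f"{radial_gap:.3g} mm implied by opening_ratio"
            )


@dataclass(frozen=True)
class GroundTruth:
    """Exact landmark configuration and trait values of a generated flower."""

    landmarks: LandmarkConfiguration
    true_opening: float
    true_asymmetry_sine: float
    annotations: list[PetalAnnotation]
    contour_polylines: list[np.ndarray]
    midrib_polylines: list[np.ndarray]


def _tube_radius_profile(params: FlowerParams, t: np.ndarray) -> np.ndarray:
    """Cross-section radius at tube fraction t: narrow base, inflated chamber,
    constricted rim.

    g(t) = t * (1 + A(1-t)) rises from the base, swells into a belly wider
    than the opening, and narrows back to the opening radius at t = 1 with
    slope 1 - A < 0.  The rim being a local radius minimum (steeply enough
    to beat the axial lean: (A-1)(rho_t - rho_b) > tube_length * sin(tau))
    makes the opening rim the surface point nearest the lobe-intersection
    chord midpoints, which is how the lobe/tube boundary landmark is
    defined operationally.
    """
    rho_t = params.tube_radius
    rho_b = params.base_taper * rho_t
    t = np.asarray(t, float)
    g = t * (1.0 + params.throat_bulge * (1.0 - t))
    return rho_b + (rho_t - rho_b) * g


def _petal_azimuths(params: FlowerParams) -> np.ndarray:
    """Midrib azimuth per petal; the dorsal petal's midrib points along +y."""
    n = params.n_petals
    p = np.arange(n)
    return np.deg2rad(90.0) + (p - params.dorsal_index) * 2.0 * np.pi / n


def _radial(phi: float | np.ndarray) -> np.ndarray:
    return np.stack([np.cos(phi), np.sin(phi), np.zeros_like(np.asarray(phi, float))],
                    axis=-1)


def _contour_profile(u: np.ndarray, exponent: float = 0.5) -> np.ndarray:
    """Symmetric bulge profile along a lobe contour, 0 at the ends, 1 at the apex."""
    u = np.asarray(u, float)
    w = np.clip(np.cos(np.pi * u / 2.0), 0.0, 1.0) ** exponent
    return np.where(np.abs(u) >= 1.0, 0.0, w)   # exact zeros at the intersections


def _lobe_lift(params: FlowerParams) -> float:
    """Vertical rise of the midrib distal point above the opening plane."""
    d_rad = (params.opening_ratio - 1.0) * params.tube_radius
    return float(np.sqrt(params.lobe_length ** 2 - d_rad ** 2))


def _ground_geometry(params: FlowerParams, tau: float,
                     scheme: tuple[int, int, int],
                     contour_samples: int, midrib_samples: int):
    """Analytic annotations + assembled configuration for a construction tilt."""
    n = params.n_petals
    axis = np.array([0.0, np.sin(tau), np.cos(tau)])
    L = params.tube_length
    opening_center = np.zeros(3)
    base_center = opening_center - L * axis
    rho_t = params.tube_radius
    rho_w = params.opening_ratio * rho_t
    h_w = _lobe_lift(params)

    phi = _petal_azimuths(params)                  # midrib azimuths
    psi = phi - np.pi / n                          # intersection azimuths (I of petal p)

    pts_I = opening_center + rho_t * _radial(psi)
    pts_III = base_center + _tube_radius_profile(params, 0.0) * _radial(phi)
    pts_IV = opening_center + rho_t * _radial(phi)
    pts_V = np.array([0.0, 0.0, h_w]) + rho_w * _radial(phi)

    half_step = np.pi / n

    def contour_point(p: int, u: np.ndarray) -> np.ndarray:
        ang = phi[p] + half_step * u
        w = _contour_profile(u)
        r = rho_t + (rho_w - rho_t) * w
        return np.stack([r * np.cos(ang), r * np.sin(ang), h_w * w], axis=-1)

    annotations: list[PetalAnnotation] = []
    contours, midribs = [], []
    u_grid = np.linspace(-1.0, 1.0, contour_samples)     # odd count: apex sampled
    n_tube = (midrib_samples + 1) // 2
    n_lobe = midrib_samples - n_tube + 1
    t_grid = np.linspace(0.0, 1.0, n_tube)
    v_grid = np.linspace(0.0, 1.0, n_lobe)[1:]
    rho_grid = _tube_radius_profile(params, t_grid)
    for p in range(n):
        contour = contour_point(p, u_grid)
        tube_mid = (base_center + t_grid[:, None] * L * axis
                    + rho_grid[:, None] * _radial(phi[p]))
        lobe_mid = pts_IV[p] + v_grid[:, None] * (pts_V[p] - pts_IV[p])
        midrib = np.vstack([tube_mid, lobe_mid])
        contours.append(contour)
        midribs.append(midrib)
        annotations.append(PetalAnnotation(
            petal_index=p, lm_I=pts_I[p], lm_II=pts_I[(p + 1) % n],
            lm_III=pts_III[p], contour_points=contour, midrib_points=midrib))

    config = assemble_configuration(
        None, annotations, scheme, expected_petals=n,
        shared_tol=1e-9, endpoint_tol=1e-9, iv_points=pts_IV)
    return config, annotations, contours, midribs, contour_point, h_w


def _solve_construction_tilt(params: FlowerParams, scheme, contour_samples: int,
                             midrib_samples: int) -> float:
    """Construction tilt tau whose measured asymmetry angle equals the target.

    The asymmetry angle measured on the assembled configuration (first
    principal axis of the 50 tube landmarks vs the opening normal) slightly
    exceeds the construction tilt because the horizontal cross-section
    spread pulls the principal axis away from the opening normal; the
    mapping tau -> measured angle is continuous and increasing on
    [0, theta], so a bracketed root find pins the target exactly.
    """
    from scipy.optimize import brentq

    from .floraltraits import asymmetry_score

    theta = params.tilt_angle_deg
    if theta <= 1e-12:
        return 0.0

    def measured_minus_target(tau: float) -> float:
        config, *_ = _ground_geometry(params, tau, scheme,
                                      contour_samples, midrib_samples)
        return asymmetry_score(config)[1] - theta

    hi = np.deg2rad(theta)
    f_hi = measured_minus_target(hi)
    if f_hi < 0:
        raise ParameterError(
            "invalid value for field 'tube_length': tube too short relative "
            "to its radius for the principal-axis construction")
    return float(brentq(measured_minus_target, 0.0, hi, xtol=1e-14, rtol=1e-15))


def make_flower(params: FlowerParams,
                scheme: tuple[int, int, int] = DEFAULT_SCHEME,
                *, contour_samples: int = 71, midrib_samples: int = 81,
                mesh_azimuth_steps: int = 144, mesh_axial_steps: int = 49,
                ) -> tuple[trimesh.Trimesh, GroundTruth]:
    """Generate one synthetic corolla mesh together with its exact ground truth.

    Returns the triangle surface mesh (mm) and a :class:`GroundTruth`
    carrying the assembled landmark configuration, per-petal annotations
    (contour/midrib point lists as an operator would pick them, ~70 and ~80
    points), and the exact trait values.
    """
    tau = _solve_construction_tilt(params, scheme, contour_samples, midrib_samples)
    config, annotations, contours, midribs, contour_point, h_w = _ground_geometry(
        params, tau, scheme, contour_samples, midrib_samples)

    mesh = _build_mesh(params, tau, contour_point,
                       mesh_azimuth_steps, mesh_axial_steps)

    gt = GroundTruth(
        landmarks=config,
        true_opening=float(params.opening_ratio),
        true_asymmetry_sine=float(np.sin(np.deg2rad(params.tilt_angle_deg))),
        annotations=annotations,
        contour_polylines=contours,
        midrib_polylines=midribs,
    )
    return mesh, gt


def _build_mesh(params: FlowerParams, tau: float, contour_point,
                n_az: int, n_ax: int) -> trimesh.Trimesh:
    """Triangulate tube wall, base cap and lobe fans into one surface mesh."""
    n = params.n_petals
    axis = np.array([0.0, np.sin(tau), np.cos(tau)])
    L = params.tube_length
    rho_t = params.tube_radius
    base_center = -L * axis

    verts: list[np.ndarray] = []
    faces: list[tuple[int, int, int]] = []

    def add_grid(grid: np.ndarray, wrap: bool) -> None:
        """Triangulate an (nu, nv, 3) quad grid; wrap closes the u direction."""
        base = len(verts)
        nu, nv = grid.shape[:2]
        verts.extend(grid.reshape(-1, 3))
        for i in range(nu if wrap else nu - 1):
            i2 = (i + 1) % nu
            for j in range(nv - 1):
                a = base + i * nv + j
                b = base + i2 * nv + j
                faces.append((a, b, b + 1))
                faces.append((a, b + 1, a + 1))

    # tube wall: horizontal rings from base to opening; rings are packed
    # toward the rim where the radius profile changes fastest.  The azimuth
    # grid carries an incommensurate phase offset so the tessellation has no
    # mirror symmetry about any petal plane: the nearest-surface-point search
    # for the boundary landmark then has a strict, perturbation-stable argmin
    t = np.sin(np.linspace(0.0, 1.0, n_ax) * np.pi / 2.0) ** 0.75
    ang = (np.arange(n_az) + 0.618) * 2.0 * np.pi / n_az
    centers = base_center + t[:, None] * L * axis
    radii = _tube_radius_profile(params, t)
    rings = centers[None, :, :] + radii[None, :, None] * _radial(ang)[:, None, :]
    add_grid(rings, wrap=True)

    # base cap: fan over the bottom ring
    rho_b = float(_tube_radius_profile(params, 0.0))
    cap_base = len(verts)
    verts.append(base_center)
    bottom = base_center + rho_b * _radial(ang)
    b0 = len(verts)
    verts.extend(bottom)
    for i in range(n_az):
        faces.append((cap_base, b0 + (i + 1) % n_az, b0 + i))

    # lobes: blend from the opening rim to the contour; interior u samples
    # get a deterministic asymmetric jitter, again to avoid mirror-symmetric
    # chord pairs around the midrib plane
    u = np.linspace(-1.0, 1.0, max(2 * (n_az // (2 * n)) + 1, 9))
    du = u[1] - u[0]
    u[1:-1] += 0.2 * du * np.sin(2.399 * np.arange(1, len(u) - 1) + 0.7)
    v = np.linspace(0.0, 1.0, 17)
    phi = _petal_azimuths(params)
    half_step = np.pi / n
    for p in range(n):
        outer = contour_point(p, u)                      # (nu, 3)
        ang_u = phi[p] + half_step * u
        rim = rho_t * _radial(ang_u)                     # (nu, 3), z=0
        grid = rim[:, None, :] + v[None, :, None] * (outer - rim)[:, None, :]
        add_grid(grid, wrap=False)

    mesh = trimesh.Trimesh(vertices=np.array(verts), faces=np.array(faces),
                           process=True)
    mesh.update_faces(mesh.nondegenerate_faces())
    return mesh


# ---------------------------------------------------------------------------
# voxelisation


def _rasterize_surface(mesh: trimesh.Trimesh, origin: np.ndarray, pitch: float,
                       shape: tuple[int, int, int]
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Mark voxels touched by the mesh surface (dense barycentric sampling).

    Returns the shell occupancy and, for orientable surfaces, the subset of
    shell voxels whose centre is not clearly on the outward side of the
    surface (used to trim the half-voxel dilation a shell rasterisation
    would otherwise add to solid objects).
    """
    occ = np.zeros(shape, dtype=bool)   # (z, y, x)
    min_dot = np.full(shape, np.inf, dtype=np.float32).reshape(-1)
    tris = mesh.triangles
    normals = mesh.face_normals
    edge = np.linalg.norm(np.diff(np.concatenate([tris, tris[:, :1]], axis=1),
                                  axis=1), axis=2).max(axis=1)
    depth = np.ceil(edge / (0.4 * pitch)).astype(int).clip(1, 512)
    strides = np.array([shape[1] * shape[2], shape[2], 1])
    for d in np.unique(depth):
        sel = depth == d
        i, j = np.meshgrid(np.arange(d + 1), np.arange(d + 1), indexing="ij")
        keep = (i + j) <= d
        bi, bj = i[keep] / d, j[keep] / d
        bary = np.stack([1.0 - bi - bj, bi, bj], axis=1)              # (s, 3)
        pts = np.einsum("sk,nkd->nsd", bary, tris[sel])               # (n, s, 3)
        nrm = np.repeat(normals[sel], bary.shape[0], axis=0)
        pts = pts.reshape(-1, 3)
        idx = np.floor((pts - origin) / pitch).astype(np.int64)
        np.clip(idx, 0, np.array(shape)[::-1] - 1, out=idx)
        centers = origin + (idx + 0.5) * pitch
        dot = np.einsum("ij,ij->i", centers - pts, nrm)
        flat = idx[:, 2] * strides[0] + idx[:, 1] * strides[1] + idx[:, 0]
        occ.reshape(-1)[flat] = True
        np.minimum.at(min_dot, flat, dot.astype(np.float32))
    inner = (min_dot <= 0.25 * pitch).reshape(shape)
    return occ, inner


def voxelize(mesh: trimesh.Trimesh, params: FlowerParams,
             *, max_voxels: int = 600_000_000, pad_mm: float = 1.0,
             flower_value: int = 200, base_value: int = 240,
             sparkle_value: int = 220) -> VoxelVolume:
    """Rasterise a surface mesh into an 8-bit voxel stack with scan artefacts.

    The mesh surface is sampled onto the grid and enclosed cavities are
    filled, giving a binary-interior solid for watertight meshes and a thin
    shell for open ones.  A half-disc fastening base of radius
    ``base_height`` is drawn at the bottom rows of every slice, and isolated
    bright sparkle voxels are scattered over the background at
    ``noise_sparkle_density`` using the parameter seed.
    """
    pitch = params.voxel_size_um / 1000.0
    lo, hi = mesh.bounds.copy()
    lo -= pad_mm
    hi += pad_mm
    hi[1] += params.base_height + 1.0 if params.base_height > 0 else 0.0
    dims = np.ceil((hi - lo) / pitch).astype(int)  # (x, y, z)
    if int(np.prod(dims.astype(np.int64))) > max_voxels:
        raise ResourceError(
            f"requested grid {tuple(dims)} exceeds max_voxels={max_voxels}")
    shape = (int(dims[2]), int(dims[1]), int(dims[0]))  # (slice,row,col)

    shell, inner = _rasterize_surface(mesh, lo, pitch, shape)
    occ = ndimage.binary_fill_holes(shell)
    if mesh.is_watertight:
        # trim shell voxels whose centre lies clearly outside the solid;
        # open sheets keep their full shell (they have no interior)
        occ &= ~shell | inner
    vol = np.where(occ, np.uint8(flower_value), np.uint8(0))

    if params.base_height > 0:
        r_px = params.base_height / pitch
        rows = np.arange(shape[1])[:, None]
        cols = np.arange(shape[2])[None, :]
        r0, c0 = shape[1] - 1, (shape[2] - 1) / 2.0
        disc = (rows - r0) ** 2 + (cols - c0) ** 2 <= r_px ** 2
        vol[:, disc] = base_value

    if params.noise_sparkle_density > 0:
        rng = np.random.default_rng(params.seed)
        forbidden = ndimage.binary_dilation(vol > 0, iterations=2)
        bg_flat = np.flatnonzero(~forbidden)
        n_spark = int(params.noise_sparkle_density * bg_flat.size)
        if n_spark:
            chosen = rng.choice(bg_flat, size=n_spark, replace=False)
            vol.reshape(-1)[chosen] = sparkle_value

    return VoxelVolume(vol, params.voxel_size_um, origin_mm=lo)


# ---------------------------------------------------------------------------
# populations

#: study-population trait distributions: flower opening mean/STD as reported,
#: tilt angle centred on the angle whose sine matches the reported asymmetry
#: mean, with an SD that reproduces the reported asymmetry STD at that mean
DEFAULT_PARAM_MEANS = {"opening_ratio": 1.74, "tilt_angle_deg": 16.19}
DEFAULT_PARAM_SDS = {"opening_ratio": 0.12, "tilt_angle_deg": 4.2}


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, size: int) -> np.ndarray:
    if sd < 0:
        raise ParameterError("invalid value for field 'sd': must be >= 0")
    if sd == 0:
        if not lo <= mean <= hi:
            raise ParameterError(f"mean {mean} outside truncation bounds [{lo}, {hi}]")
        return np.full(size, mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def draw_population_params(n: int,
                           param_means: dict[str, float] | None = None,
                           param_sds: dict[str, float] | None = None,
                           seed: int = 0,
                           base_params: FlowerParams | None = None,
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Independent truncated-normal draws of (opening_ratio, tilt_angle_deg).

    Opening is truncated to [1.05, a bound the lobe length can realise];
    tilt to [0, 89) degrees.  Reproducible under ``seed``.
    """
    if n < 1:
        raise ParameterError("invalid value for field 'n': must be >= 1")
    means = {**DEFAULT_PARAM_MEANS, **(param_means or {})}
    sds = {**DEFAULT_PARAM_SDS, **(param_sds or {})}
    base = base_params or FlowerParams()
    rng = np.random.default_rng(seed)
    open_hi = 1.0 + 0.95 * base.lobe_length / base.tube_radius
    open_lo, open_hi = 1.05, min(2.2, open_hi)
    log.info("population truncation bounds: opening [%.3g, %.3g], tilt [0, 89) deg",
             open_lo, open_hi)
    openings = _truncated_normal(rng, means["opening_ratio"], sds["opening_ratio"],
                                 open_lo, open_hi, n)
    tilts = _truncated_normal(rng, means["tilt_angle_deg"], sds["tilt_angle_deg"],
                              0.0, 89.0, n)
    return openings, tilts


def make_population(n: int,
                    param_means: dict[str, float] | None = None,
                    param_sds: dict[str, float] | None = None,
                    seed: int = 0,
                    base_params: FlowerParams | None = None,
                    scheme: tuple[int, int, int] = DEFAULT_SCHEME,
                    ) -> list[tuple[trimesh.Trimesh, GroundTruth]]:
    """Simulate a population with independent opening and tilt variation.

    ``opening_ratio`` and ``tilt_angle_deg`` are drawn independently from
    truncated normal distributions (see :func:`draw_population_params`);
    the whole population is reproducible under ``seed``.
    """
    base = base_params or FlowerParams()
    openings, tilts = draw_population_params(n, param_means, param_sds, seed, base)
    flowers = []
    for i in range(n):
        p = replace(base, opening_ratio=float(openings[i]),
                    tilt_angle_deg=float(tilts[i]),
                    seed=int((seed + 1) * 100_003 + i) % (2 ** 31))
        flowers.append(make_flower(p, scheme))
    return flowers
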