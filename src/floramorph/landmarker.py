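"""Homologous landmark configurations for five-lobed corollas.

Each petal contributes five primary landmarks — the two lobe intersections
(I, II; II is shared with the next petal), the midrib proximal point (III),
the lobe/tube boundary on the midrib (IV), and the midrib distal point (V) —
plus secondary landmarks (semilandmarks) resampled at equal arc length along
the two semi-lobe contours, the lobe midrib and the tube midrib.  With five
petals and the default per-petal scheme (3, 2, 7) this yields 95 landmarks:
20 primary and 75 secondary, of which 55 belong to the lobe compartment and
50 to the tube compartment with 10 shared between the two.

Landmark IV is computed, not picked: it is the surface point of the corolla
mesh closest (Euclidean) to the midpoint of landmarks I and II.  Landmark V
is the point on the lobe contour geodesically equidistant from I and II,
i.e. the contour's arc-length midpoint.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import trimesh

from .polyline import Polyline, build_polyline

log = logging.getLogger(__name__)

#: default number of secondary landmarks on (semi-lobe contour, lobe midrib,
#: tube midrib)
DEFAULT_SCHEME = (3, 2, 7)

PRIMARY_ROLES = ("I", "III", "IV", "V")
SECONDARY_ROLES = ("semi_contour_L", "semi_contour_R", "lobe_midrib", "tube_midrib")

# compartment membership per role: (lobe_member, tube_member)
_ROLE_COMPARTMENTS = {
    "I": (True, True),          # lobe intersection, on the tube opening rim
    "III": (False, True),
    "IV": (True, True),         # lobe/tube boundary
    "V": (True, False),
    "semi_contour_L": (True, False),
    "semi_contour_R": (True, False),
    "lobe_midrib": (True, False),
    "tube_midrib": (False, True),
}


class AnnotationError(ValueError):
    """Inconsistent or incomplete per-petal annotations."""


@dataclass(frozen=True)
class PetalAnnotation:
    """Manually picked inputs for one petal.

    ``contour_points`` runs from landmark I to landmark II along the lobe
    contour; ``midrib_points`` runs from landmark III distally along the
    petal midrib (over the lobe/tube boundary out to the lobe tip).
    """

    petal_index: int
    lm_I: np.ndarray
    lm_II: np.ndarray
    lm_III: np.ndarray
    contour_points: np.ndarray
    midrib_points: np.ndarray

    def __post_init__(self) -> None:
        for name in ("lm_I", "lm_II", "lm_III"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        for name in ("contour_points", "midrib_points"):
            pts = np.asarray(getattr(self, name), float)
            if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
                raise AnnotationError(f"{name} must be an (n>=2, 3) point list")
            object.__setattr__(self, name, pts)

    def validate_endpoints(self, tol: float) -> None:
        d0 = np.linalg.norm(self.contour_points[0] - self.lm_I)
        d1 = np.linalg.norm(self.contour_points[-1] - self.lm_II)
        if d0 > tol or d1 > tol:
            raise AnnotationError(
                f"petal {self.petal_index}: contour endpoints deviate from "
                f"landmarks I/II by ({d0:.3g}, {d1:.3g}) > tol {tol:.3g}"
            )


@dataclass(frozen=True)
class LandmarkConfiguration:
    """Ordered landmark coordinate matrix with role / petal / compartment labels.

    Canonical ordering: petals in dorsoventral order (0 = dorsal); within a
    petal: I, III, IV, V, semi-contour-left 1..a, semi-contour-right 1..a,
    lobe-midrib 1..b, tube-midrib 1..c.  Landmark II of petal p is landmark I
    of petal p+1 and is stored once.
    """

    coords: np.ndarray
    petal: np.ndarray       # int, owning petal
    role: np.ndarray        # str
    within_role: np.ndarray  # int index within (petal, role)
    lobe_member: np.ndarray  # bool
    tube_member: np.ndarray  # bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        n = len(self.coords)
        for name in ("petal", "role", "within_role", "lobe_member", "tube_member"):
            arr = np.asarray(getattr(self, name))
            if len(arr) != n:
                raise ValueError(f"label array {name} length {len(arr)} != {n} points")
            object.__setattr__(self, name, arr)

    def __len__(self) -> int:
        return len(self.coords)

    @property
    def n_petals(self) -> int:
        return int(self.petal.max()) + 1

    def select(self, *, role: str | None = None, petal: int | None = None,
               compartment: str | None = None) -> np.ndarray:
        """Coordinates filtered by role, petal and/or compartment ('lobe'/'tube')."""
        m = np.ones(len(self), bool)
        if role is not None:
            m &= self.role == role
        if petal is not None:
            m &= self.petal == petal
        if compartment == "lobe":
            m &= self.lobe_member
        elif compartment == "tube":
            m &= self.tube_member
        elif compartment is not None:
            raise ValueError("compartment must be 'lobe' or 'tube'")
        return self.coords[m]

    def counts(self) -> dict[str, int]:
        primary = int(np.isin(self.role, PRIMARY_ROLES).sum())
        return {
            "total": len(self),
            "primary": primary,
            "secondary": len(self) - primary,
            "lobe": int(self.lobe_member.sum()),
            "tube": int(self.tube_member.sum()),
            "shared": int((self.lobe_member & self.tube_member).sum()),
        }

    def to_dataframe(self, flower_id: str | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "point_index": np.arange(len(self)),
            "petal": self.petal,
            "role": self.role,
            "within_role": self.within_role,
            "lobe_member": self.lobe_member,
            "tube_member": self.tube_member,
            "x": self.coords[:, 0],
            "y": self.coords[:, 1],
            "z": self.coords[:, 2],
        })
        if flower_id is not None:
            df.insert(0, "flower_id", flower_id)
        return df

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "LandmarkConfiguration":
        df = df.sort_values("point_index")
        return cls(
            coords=df[["x", "y", "z"]].to_numpy(float),
            petal=df["petal"].to_numpy(int),
            role=df["role"].to_numpy(str),
            within_role=df["within_role"].to_numpy(int),
            lobe_member=df["lobe_member"].to_numpy(bool),
            tube_member=df["tube_member"].to_numpy(bool),
        )

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None,
                    scale: float = 1.0) -> "LandmarkConfiguration":
        """A copy with coords mapped through x -> scale * R x + t."""
        c = self.coords * scale
        if rotation is not None:
            c = c @ np.asarray(rotation, float).T
        if translation is not None:
            c = c + np.asarray(translation, float)
        return LandmarkConfiguration(c, self.petal, self.role, self.within_role,
                                     self.lobe_member, self.tube_member)


def compute_landmark_IV(mesh: trimesh.Trimesh, lm_I: np.ndarray,
                        lm_II: np.ndarray) -> np.ndarray:
    """Surface point closest to the midpoint of landmarks I and II.

    The search is over every triangle of the mesh (closest point on the
    triangle, not merely the nearest vertex); ties break to the lowest face
    index via ``argmin``.
    """
    if mesh is None or len(mesh.faces) == 0:
        raise ValueError("empty mesh: landmark IV undefined")
    q = (np.asarray(lm_I, float) + np.asarray(lm_II, float)) / 2.0
    tris = mesh.triangles
    # candidate prefilter: a face can only beat the best vertex distance if
    # its nearest vertex lies within best + (its) max edge length; using the
    # global max edge keeps the bound valid and the search exact
    vert_d = np.linalg.norm(mesh.vertices - q, axis=1)
    face_min = vert_d[mesh.faces].min(axis=1)
    edges = np.linalg.norm(np.diff(np.concatenate([tris, tris[:, :1]], axis=1),
                                   axis=1), axis=2)
    cand = np.flatnonzero(face_min <= vert_d.min() + edges.max())
    closest = trimesh.triangles.closest_point(tris[cand],
                                              np.tile(q, (len(cand), 1)))
    d2 = np.einsum("ij,ij->i", closest - q, closest - q)
    order = np.lexsort((cand, d2))  # ties break to the lowest face index
    return closest[order[0]]


def compute_landmark_V(contour: Polyline) -> np.ndarray:
    """Geodesically equidistant point from the contour's two ends (landmark V)."""
    return contour.midpoint()


def resample_secondary(polyline: Polyline, n_interior: int) -> np.ndarray:
    """Equally distributed interior points along a contour/midrib segment."""
    return polyline.resample_interior(n_interior)


def _merge_intersections(annotations: list[PetalAnnotation], tol: float) -> np.ndarray:
    """Average each petal's lm_I with the previous petal's lm_II (cyclic)."""
    n = len(annotations)
    merged = np.empty((n, 3))
    for p in range(n):
        a = annotations[p].lm_I
        b = annotations[(p - 1) % n].lm_II
        gap = np.linalg.norm(a - b)
        if gap > tol:
            raise AnnotationError(
                f"shared intersection between petals {(p - 1) % n} and {p} "
                f"disagrees by {gap:.4g} mm > tolerance {tol:.4g} mm"
            )
        merged[p] = (a + b) / 2.0
    return merged


def assemble_configuration(
    mesh: trimesh.Trimesh | None,
    annotations: list[PetalAnnotation],
    scheme: tuple[int, int, int] = DEFAULT_SCHEME,
    *,
    expected_petals: int = 5,
    shared_tol: float = 0.3,
    endpoint_tol: float = 0.5,
    iv_points: np.ndarray | None = None,
) -> LandmarkConfiguration:
    """Assemble the full homologous configuration from per-petal annotations.

    Parameters
    ----------
    mesh:
        Corolla surface mesh used to compute landmark IV.  May be ``None``
        when ``iv_points`` supplies exact boundary points (e.g. synthetic
        ground truth).
    annotations:
        One :class:`PetalAnnotation` per petal, in dorsoventral order.
    scheme:
        Secondary-landmark counts (semi-lobe contour, lobe midrib, tube
        midrib) per petal.
    expected_petals:
        Required number of annotations; flowers whose lobe count deviates
        from the analysed morph are rejected rather than silently handled.
    shared_tol:
        Maximum disagreement (mm) between adjacent petals' picks of the same
        lobe intersection; within tolerance the picks are averaged.
    """
    n = len(annotations)
    if n != expected_petals:
        raise AnnotationError(
            f"petal count: got {n} annotations, expected {expected_petals}"
        )
    a, b, c = scheme
    if min(a, b, c) < 0:
        raise ValueError("scheme counts must be non-negative")
    order = [ann.petal_index for ann in annotations]
    if order != list(range(n)):
        raise AnnotationError(f"annotations must be ordered petal 0..{n - 1}, got {order}")
    for ann in annotations:
        ann.validate_endpoints(endpoint_tol)

    intersections = _merge_intersections(annotations, shared_tol)

    coords, petal_lab, role_lab, wr_lab = [], [], [], []

    def emit(p: int, role: str, pts: np.ndarray) -> None:
        pts = np.atleast_2d(pts)
        for k, pt in enumerate(pts):
            coords.append(pt)
            petal_lab.append(p)
            role_lab.append(role)
            wr_lab.append(k)

    for p, ann in enumerate(annotations):
        contour = build_polyline(ann.contour_points)
        midrib = build_polyline(ann.midrib_points)

        if iv_points is not None:
            lm_iv = np.asarray(iv_points[p], float)
        else:
            lm_iv = compute_landmark_IV(mesh, ann.lm_I, ann.lm_II)
        lm_v = compute_landmark_V(contour)

        # split the midrib at the points nearest IV and V; the distance of IV
        # to the midrib is a QC metric (IV is computed on the mesh surface,
        # the midrib is an independent manual pick)
        s_iv, d_iv = midrib.project(lm_iv)
        s_v, d_v = midrib.project(lm_v)
        log.debug("petal %d: IV at midrib arc %.3f (off-midrib %.3g mm), "
                  "V at %.3f (off %.3g mm)", p, s_iv, d_iv, s_v, d_v)
        if not 0 < s_iv < s_v:
            raise AnnotationError(
                f"petal {p}: midrib split points out of order "
                f"(III at 0 < IV at {s_iv:.3g} < V at {s_v:.3g} required)"
            )
        tube_midrib = midrib.sub(0.0, s_iv)
        lobe_midrib = midrib.sub(s_iv, s_v)
        half = contour.length / 2.0
        semi_left = contour.sub(0.0, half)
        semi_right = contour.sub(half, contour.length)

        emit(p, "I", intersections[p])
        emit(p, "III", ann.lm_III)
        emit(p, "IV", lm_iv)
        emit(p, "V", lm_v)
        emit(p, "semi_contour_L", resample_secondary(semi_left, a))
        emit(p, "semi_contour_R", resample_secondary(semi_right, a))
        emit(p, "lobe_midrib", resample_secondary(lobe_midrib, b))
        emit(p, "tube_midrib", resample_secondary(tube_midrib, c))

    role_arr = np.array(role_lab)
    lobe = np.array([_ROLE_COMPARTMENTS[r][0] for r in role_lab])
    tube = np.array([_ROLE_COMPARTMENTS[r][1] for r in role_lab])
    return LandmarkConfiguration(
        coords=np.array(coords),
        petal=np.array(petal_lab),
        role=role_arr,
        within_role=np.array(wr_lab),
        lobe_member=lobe,
        tube_member=tube,
    )


def expected_counts(n_petals: int, scheme: tuple[int, int, int] = DEFAULT_SCHEME
                    ) -> dict[str, int]:
    """Closed-form landmark counts for ``n_petals`` and a per-petal scheme."""
    a, b, c = scheme
    primary = 4 * n_petals          # shared intersections + III + IV + V
    secondary = n_petals * (2 * a + b + c)
    return {
        "total": primary + secondary,
        "primary": primary,
        "secondary": secondary,
        "lobe": n_petals * (3 + 2 * a + b),
        "tube": n_petals * (3 + c),
        "shared": 2 * n_petals,
    }
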