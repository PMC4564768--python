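"""2D front/side projections of 3D corollas and 2D shape analysis.

The conventional way to phenotype flower shape is from 2D photographs; this
module mimics that camera by projecting a 3D landmark configuration
orthographically into two canonical frames derived from the flower itself:
the front view looks along the tube-opening circle normal with the dorsal
petal up, the side view looks along the normal of the dorsoventral plane.
Front-view landmarks are resampled from the projected lobe contours (default
6 per petal -> 30), side-view landmarks from the projected tube midribs
(default 15).  The same GPA+PCA machinery then runs with k = 2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import shapestats
from .floraltraits import DegenerateGeometryError, tube_opening_circle
from .landmarker import LandmarkConfiguration
from .polyline import build_polyline

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ViewFrame:
    """Orthonormal camera frame: ``forward = right x up`` points at the viewer."""

    origin: np.ndarray
    right: np.ndarray
    up: np.ndarray
    forward: np.ndarray

    def __post_init__(self) -> None:
        for name in ("origin", "right", "up", "forward"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), float).reshape(3))
        basis = np.stack([self.right, self.up, self.forward])
        if not np.allclose(basis @ basis.T, np.eye(3), atol=1e-10):
            raise ValueError("view frame basis is not orthonormal")
        if not np.allclose(np.cross(self.right, self.up), self.forward, atol=1e-10):
            raise ValueError("frame must satisfy forward = right x up")


def view_frames(config: LandmarkConfiguration) -> tuple[ViewFrame, ViewFrame]:
    """Front and side view frames derived from the flower's own geometry.

    Front: forward along the tube-opening circle normal (toward the viewer),
    up along the dorsal direction (dorsal-petal landmark centroid minus
    circle centre) projected into the view plane.  Side: forward along the
    front frame's right vector (the dorsoventral-plane normal), same up.
    """
    circle = tube_opening_circle(config)
    forward = circle.normal
    dorsal = config.select(petal=0).mean(axis=0) - circle.center
    up = dorsal - np.dot(dorsal, forward) * forward
    norm = np.linalg.norm(up)
    if norm < 1e-9 * max(np.linalg.norm(dorsal), 1e-300):
        raise DegenerateGeometryError(
            "dorsal direction parallel to the opening normal: side view undefined")
    up = up / norm
    right = np.cross(up, forward)
    front = ViewFrame(origin=circle.center, right=right, up=up, forward=forward)
    side = ViewFrame(origin=circle.center, right=np.cross(up, right), up=up,
                     forward=right)
    return front, side


def project(points: np.ndarray, frame: ViewFrame) -> np.ndarray:
    """Orthographic projection onto the frame's (right, up) plane."""
    rel = np.atleast_2d(np.asarray(points, float)) - frame.origin
    return np.stack([rel @ frame.right, rel @ frame.up], axis=1)


def _petal_contour_points(config: LandmarkConfiguration, p: int) -> np.ndarray:
    """Ordered lobe-contour landmark chain of petal p: I, left semis, V,
    right semis, then the next petal's I (the shared intersection II)."""
    n = config.n_petals
    return np.vstack([
        config.select(role="I", petal=p),
        config.select(role="semi_contour_L", petal=p),
        config.select(role="V", petal=p),
        config.select(role="semi_contour_R", petal=p),
        config.select(role="I", petal=(p + 1) % n),
    ])


def _petal_tube_midrib_points(config: LandmarkConfiguration, p: int) -> np.ndarray:
    """Ordered tube-midrib landmark chain of petal p: III, interiors, IV."""
    return np.vstack([
        config.select(role="III", petal=p),
        config.select(role="tube_midrib", petal=p),
        config.select(role="IV", petal=p),
    ])


def view_landmarks_2d(config: LandmarkConfiguration,
                      frames: tuple[ViewFrame, ViewFrame] | None = None,
                      front_scheme: int = 6,
                      side_scheme: int = 15) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic 2D landmark sets for the front and side views.

    Front: each petal's projected lobe-contour chain is resampled at equal
    arc length into ``front_scheme`` points starting at the first
    intersection and excluding the last one (it opens the next petal's
    chain), so 5 petals x 6 = 30 distinct landmarks.  Side: the projected
    dorsal tube midrib resampled to ceil(n/2) points plus the pointwise mean
    of the two ventral-most petals' midribs resampled to floor(n/2), default
    8 + 7 = 15.  Counts are pose-independent.
    """
    if frames is None:
        frames = view_frames(config)
    front_frame, side_frame = frames
    n = config.n_petals

    front_pts = []
    if front_scheme > 0:
        for p in range(n):
            chain2d = project(_petal_contour_points(config, p), front_frame)
            poly = build_polyline(chain2d)
            # front_scheme points at arc fractions k/front_scheme, k=0..front_scheme-1
            s = np.arange(front_scheme) * poly.length / front_scheme
            front_pts.append(poly.point_at(s))
    front = np.vstack(front_pts) if front_pts else np.empty((0, 2))

    side_pts = []
    if side_scheme > 0:
        n_dorsal = (side_scheme + 1) // 2
        n_ventral = side_scheme - n_dorsal
        dorsal_chain = project(_petal_tube_midrib_points(config, 0), side_frame)
        if n_dorsal >= 2:
            side_pts.append(build_polyline(dorsal_chain).resample(n_dorsal))
        elif n_dorsal == 1:
            side_pts.append(dorsal_chain[-1:])
        if n_ventral:
            pv1, pv2 = n // 2, (n + 1) // 2  # the two petals flanking the ventral seam
            chain = (_petal_tube_midrib_points(config, pv1)
                     + _petal_tube_midrib_points(config, pv2)) / 2.0
            ventral_chain = project(chain, side_frame)
            if n_ventral >= 2:
                side_pts.append(build_polyline(ventral_chain).resample(n_ventral))
            else:
                side_pts.append(ventral_chain[-1:])
    side = np.vstack(side_pts) if side_pts else np.empty((0, 2))

    if len(front) and len(front) != n * front_scheme:
        raise ValueError("front scheme exceeds available contour points")
    log.debug("2D landmark counts: front %d, side %d", len(front), len(side))
    return front, side


def gm_2d(landmark_sets: list[np.ndarray], tol: float = 1e-10,
          max_iter: int = 100) -> shapestats.PCModel:
    """GPA + PCA on 2D landmark sets through the dimension-agnostic code path."""
    if len(landmark_sets) < 2:
        raise ValueError("need >= 2 specimens for 2D shape analysis")
    samples, _ = shapestats.gpa([np.asarray(s, float) for s in landmark_sets],
                                tol=tol, max_iter=max_iter)
    return shapestats.pca(samples)
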