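"""Flower opening and corolla asymmetry from 3D landmark configurations.

Flower opening is the ratio of the diameter of the lobe-widening circle
(best-fit circle through the five midrib distal landmarks, V) to the
diameter of the tube-opening circle (best-fit circle through the five lobe
intersections).  Corolla asymmetry is sin(theta), where theta is the angle
between the corolla tube's long axis — the first principal axis of the tube
landmark positions — and the normal of the tube-opening circle, folded to
[0, 90] degrees.  Both scores are invariant to translation, rotation and
uniform scaling of the configuration by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .landmarker import LandmarkConfiguration

log = logging.getLogger(__name__)


class DegenerateGeometryError(ValueError):
    pass


@dataclass(frozen=True)
class Circle3D:
    """A circle in 3D: centre (mm), radius (mm), unit plane normal."""

    center: np.ndarray
    radius: float
    normal: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, float).reshape(3))
        n = np.asarray(self.normal, float).reshape(3)
        norm = np.linalg.norm(n)
        if not self.radius > 0:
            raise DegenerateGeometryError("circle radius must be > 0")
        if abs(norm - 1.0) > 1e-12:
            n = n / norm
        object.__setattr__(self, "normal", n)

    @property
    def diameter(self) -> float:
        return 2.0 * self.radius


@dataclass(frozen=True)
class TraitScores:
    opening: float
    asymmetry_sine: float
    asymmetry_angle_deg: float


def fit_circle_3d(points: np.ndarray, *, geometric: bool = False) -> Circle3D:
    """Least-squares circle through >= 3 non-collinear 3D points.

    Total-least-squares plane (SVD), points projected in-plane, then the
    algebraic (Kasa) circle fit — exact whenever the points are exactly
    co-circular, deterministic and iteration-free.  ``geometric=True``
    refines centre and radius by minimising true point-to-circle distances.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 3:
        raise DegenerateGeometryError("need >= 3 three-dimensional points")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] <= 1e-12 * max(s[0], 1e-300):
        raise DegenerateGeometryError("points are collinear or coincident")
    normal = vt[2]
    e1, e2 = vt[0], vt[1]
    xy = centered @ np.stack([e1, e2], axis=1)     # (n, 2) in-plane coords

    # Kasa fit: minimise ||x|^2 - 2 c.x - r2t|^2 (linear least squares)
    A = np.column_stack([2.0 * xy, np.ones(len(xy))])
    bvec = np.einsum("ij,ij->i", xy, xy)
    sol, *_ = np.linalg.lstsq(A, bvec, rcond=None)
    cx, cy, r2t = sol
    radius = float(np.sqrt(max(r2t + cx ** 2 + cy ** 2, 0.0)))
    if radius <= 0:
        raise DegenerateGeometryError("degenerate circle fit (zero radius)")

    if geometric:
        def residuals(q):
            return np.hypot(xy[:, 0] - q[0], xy[:, 1] - q[1]) - q[2]
        res = least_squares(residuals, x0=[cx, cy, radius])
        cx, cy, radius = res.x
        radius = float(radius)

    center = centroid + cx * e1 + cy * e2
    return Circle3D(center=center, radius=radius, normal=normal)


def _principal_axis(points: np.ndarray) -> np.ndarray:
    pts = np.asarray(points, float)
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered
    w, v = np.linalg.eigh(cov)
    if w[-1] <= 1e-12 * max(abs(w).max(), 1e-300):
        raise DegenerateGeometryError("tube landmarks are coincident")
    return v[:, -1]


def tube_opening_circle(config: LandmarkConfiguration, **kw) -> Circle3D:
    """Best-fit circle through the lobe intersections, normal oriented away
    from the tube proximal centroid (i.e. toward the viewer)."""
    inter = config.select(role="I")
    proximal = config.select(role="III").mean(axis=0)
    circ = fit_circle_3d(inter, **kw)
    n = circ.normal
    if np.dot(n, circ.center - proximal) < 0:
        n = -n
    return Circle3D(circ.center, circ.radius, n)


def lobe_widening_circle(config: LandmarkConfiguration, **kw) -> Circle3D:
    """Best-fit circle through the five midrib distal landmarks (V)."""
    return fit_circle_3d(config.select(role="V"), **kw)


def tube_long_axis(config: LandmarkConfiguration) -> np.ndarray:
    """First principal axis of the tube landmarks, oriented from the tube
    proximal centroid (mean of the III landmarks) toward the opening centre."""
    tube_pts = config.select(compartment="tube")
    axis = _principal_axis(tube_pts)
    proximal = config.select(role="III").mean(axis=0)
    opening = tube_opening_circle(config)
    if np.dot(axis, opening.center - proximal) < 0:
        axis = -axis
    return axis


def opening_score(config: LandmarkConfiguration, *, geometric: bool = False) -> float:
    """Diameter of the lobe-widening circle over the tube-opening circle."""
    widening = lobe_widening_circle(config, geometric=geometric)
    opening = tube_opening_circle(config, geometric=geometric)
    return widening.diameter / opening.diameter


def asymmetry_score(config: LandmarkConfiguration) -> tuple[float, float]:
    """(sin(theta), theta in degrees): tube axis vs opening-circle normal,
    folded to [0, 90] degrees to remove axis-direction ambiguity."""
    axis = tube_long_axis(config)
    normal = tube_opening_circle(config).normal
    cosang = np.clip(abs(float(np.dot(axis, normal))), 0.0, 1.0)
    theta = np.degrees(np.arccos(cosang))
    return float(np.sin(np.radians(theta))), float(theta)


def score_config(config: LandmarkConfiguration) -> TraitScores:
    sine, angle = asymmetry_score(config)
    return TraitScores(opening=opening_score(config),
                       asymmetry_sine=sine, asymmetry_angle_deg=angle)


def trait_table(configs: list[LandmarkConfiguration],
                flower_ids: list[str] | None = None) -> pd.DataFrame:
    """Per-flower trait scores plus mean/STD summary rows and the pairwise
    correlation of the two traits (NaN where undefined, e.g. n = 1)."""
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    ids = flower_ids or [f"flower_{i:03d}" for i in range(len(configs))]
    rows = []
    for fid, cfg in zip(ids, configs):
        s = score_config(cfg)
        rows.append({"flower_id": fid, "opening": s.opening,
                     "asymmetry_sine": s.asymmetry_sine,
                     "asymmetry_angle_deg": s.asymmetry_angle_deg})
    df = pd.DataFrame(rows)
    numeric = ["opening", "asymmetry_sine", "asymmetry_angle_deg"]
    mean_row = {"flower_id": "mean", **{c: df[c].mean() for c in numeric}}
    std_row = {"flower_id": "std",
               **{c: (df[c].std(ddof=1) if len(df) > 1 else np.nan) for c in numeric}}
    if len(df) > 1 and df["opening"].std() > 0 and df["asymmetry_sine"].std() > 0:
        corr = float(np.corrcoef(df["opening"], df["asymmetry_sine"])[0, 1])
    else:
        corr = np.nan
    corr_row = {"flower_id": "correlation_opening_asymmetry", "opening": corr,
                "asymmetry_sine": corr, "asymmetry_angle_deg": np.nan}
    return pd.concat([df, pd.DataFrame([mean_row, std_row, corr_row])],
                     ignore_index=True)
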