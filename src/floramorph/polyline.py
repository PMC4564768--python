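"""Piecewise-linear curves with arc-length parametrisation.

Annotated lobe contours and petal midribs are modelled as open polylines;
every geodesic quantity in the landmark scheme (the midrib distal point,
equally spaced semilandmarks) is defined by arc length along these curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class DegeneratePolylineError(ValueError):
    """Raised when fewer than two distinct points are supplied."""


def dedupe_consecutive(points: np.ndarray, tol: float = 0.0) -> np.ndarray:
    """Drop consecutive points closer than ``tol`` (exact duplicates by default)."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be an (n, k) array")
    if len(points) == 0:
        return points
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > tol:
            keep.append(i)
    return points[keep]


@dataclass(frozen=True)
class Polyline:
    """An open polyline in k dimensions with cumulative arc length per vertex."""

    points: np.ndarray
    arclen: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        pts = dedupe_consecutive(np.asarray(self.points, dtype=float))
        if len(pts) < 2:
            raise DegeneratePolylineError(
                "polyline needs at least 2 distinct points, got %d" % len(pts)
            )
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "arclen", cum)

    @property
    def length(self) -> float:
        return float(self.arclen[-1])

    @property
    def dim(self) -> int:
        return self.points.shape[1]

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Point(s) at arc length ``s`` by linear interpolation (clamped to [0, L])."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        idx = np.clip(np.searchsorted(self.arclen, s, side="right") - 1, 0,
                      len(self.points) - 2)
        s0 = self.arclen[idx]
        seg_len = self.arclen[idx + 1] - s0
        t = np.where(seg_len > 0, (s - s0) / np.where(seg_len > 0, seg_len, 1.0), 0.0)
        p = self.points[idx] + t[..., None] * (self.points[idx + 1] - self.points[idx])
        return p if np.ndim(s) else p.reshape(self.dim)

    def midpoint(self) -> np.ndarray:
        """The geodesically equidistant point from the two endpoints."""
        return self.point_at(self.length / 2.0)

    def resample_interior(self, n_interior: int) -> np.ndarray:
        """``n_interior`` points at arc lengths k*L/(n+1), k = 1..n (endpoints excluded)."""
        if n_interior < 0:
            raise ValueError("n_interior must be >= 0")
        if n_interior == 0:
            return np.empty((0, self.dim))
        k = np.arange(1, n_interior + 1)
        return self.point_at(k * self.length / (n_interior + 1))

    def resample(self, n: int) -> np.ndarray:
        """``n`` points at equal arc spacing including both endpoints (n >= 2)."""
        if n < 2:
            raise ValueError("n must be >= 2")
        return self.point_at(np.linspace(0.0, self.length, n))

    def project(self, point: np.ndarray) -> tuple[float, float]:
        """Arc-length parameter and distance of the closest point on the polyline.

        The projection is exact per segment (clamped foot of perpendicular);
        ties resolve to the earliest segment.
        """
        q = np.asarray(point, dtype=float)
        a = self.points[:-1]
        d = self.points[1:] - a
        seg2 = np.einsum("ij,ij->i", d, d)
        t = np.clip(np.einsum("ij,ij->i", q - a, d) / np.where(seg2 > 0, seg2, 1.0), 0, 1)
        foot = a + t[:, None] * d
        dist = np.linalg.norm(foot - q, axis=1)
        i = int(np.argmin(dist))
        s = self.arclen[i] + t[i] * np.sqrt(seg2[i])
        return float(s), float(dist[i])

    def sub(self, s0: float, s1: float) -> "Polyline":
        """Sub-polyline between arc lengths ``s0`` < ``s1`` (endpoints interpolated)."""
        if not 0.0 <= s0 < s1 <= self.length + 1e-12:
            raise ValueError("need 0 <= s0 < s1 <= length")
        s1 = min(s1, self.length)
        inside = (self.arclen > s0 + 1e-12) & (self.arclen < s1 - 1e-12)
        pts = np.vstack([
            self.point_at(s0)[None, :],
            self.points[inside],
            self.point_at(s1)[None, :],
        ])
        return Polyline(pts)


def build_polyline(points: np.ndarray) -> Polyline:
    """Build a :class:`Polyline` from ordered points (consecutive duplicates removed)."""
    return Polyline(np.asarray(points, dtype=float))
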