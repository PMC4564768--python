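"""Generalized Procrustes analysis and PCA of landmark configurations.

GPA removes the variation irrelevant to shape: each configuration is
centred, scaled to unit centroid size, and rotated (proper rotations only —
reflections are disallowed because the flowers are chiral once dorsoventral
labels are fixed) to minimise the summed squared distance to an evolving
mean shape, iterating until the objective no longer decreases.  The aligned
coordinates are then flattened and decomposed by covariance PCA; shapes can
be reconstructed from manipulated principal-component scores (inverse PCA)
and per-landmark deformation vectors derived from them.

Everything is dimension-agnostic: the same code path handles 3D corolla
configurations and 2D projected views.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ShapeSample:
    """A Procrustes-aligned configuration plus its original centroid size."""

    coords: np.ndarray          # (n_landmarks, k), centred, unit centroid size
    centroid_size: float        # of the raw configuration, in input units

    def __post_init__(self) -> None:
        object.__setattr__(self, "coords", np.asarray(self.coords, float))
        if not self.centroid_size > 0:
            raise ValueError("centroid_size must be > 0")


@dataclass(frozen=True)
class PCModel:
    """Mean shape, orthonormal eigenbasis, variances and per-flower scores."""

    mean_shape: np.ndarray          # (n_landmarks, k)
    eigenvectors: np.ndarray        # (n_components, n_landmarks * k), rows
    eigenvalues: np.ndarray         # descending, >= 0
    scores: np.ndarray              # (n_samples, n_components)

    @property
    def n_landmarks(self) -> int:
        return self.mean_shape.shape[0]

    @property
    def dim(self) -> int:
        return self.mean_shape.shape[1]

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        return self.eigenvalues / total if total > 0 else self.eigenvalues

    def save(self, path) -> None:
        np.savez(path, mean_shape=self.mean_shape, eigenvectors=self.eigenvectors,
                 eigenvalues=self.eigenvalues, scores=self.scores)

    @classmethod
    def load(cls, path) -> "PCModel":
        d = np.load(path)
        return cls(d["mean_shape"], d["eigenvectors"], d["eigenvalues"], d["scores"])


def centroid_size(config: np.ndarray) -> float:
    """Root summed squared deviation of the landmarks from their centroid."""
    c = np.asarray(config, float)
    return float(np.linalg.norm(c - c.mean(axis=0)))


def optimal_rotation(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Proper rotation R (det +1) minimising ||A R - B||_F for centred A, B.

    Solved by the orthogonal decomposition of the cross-covariance; the
    smallest singular direction is sign-flipped when the unconstrained
    optimum would be a reflection.
    """
    A = np.asarray(A, float)
    B = np.asarray(B, float)
    if A.shape != B.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {B.shape}")
    H = A.T @ B
    U, s, Vt = np.linalg.svd(H)
    if s[-1] <= 1e-12 * max(s[0], 1e-300) and A.shape[1] > 1:
        raise np.linalg.LinAlgError(
            "rank-deficient cross-covariance: configurations are degenerate "
            "(landmarks confined to a lower-dimensional subspace)")
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.eye(A.shape[1])
    D[-1, -1] = d
    return U @ D @ Vt


def _center_and_scale(config: np.ndarray) -> tuple[np.ndarray, float]:
    c = np.asarray(config, float)
    size = centroid_size(c)
    if size <= 0:
        raise ValueError("degenerate configuration: zero centroid size")
    return (c - c.mean(axis=0)) / size, size


def gpa(configs: list[np.ndarray], tol: float = 1e-10, max_iter: int = 100
        ) -> tuple[list[ShapeSample], np.ndarray]:
    """Generalized Procrustes superimposition of landmark configurations.

    Each configuration is centred and scaled to unit centroid size, then
    iteratively rotated onto the running mean; the mean is recomputed (and
    renormalised to unit size) each round.  Iteration stops when the
    relative decrease of the summed squared distance to the mean drops
    below ``tol`` or after ``max_iter`` rounds.  The per-iteration
    objective is logged and non-increasing.
    """
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    shapes = [np.asarray(c, float) for c in configs]
    ref_shape = shapes[0].shape
    if any(s.shape != ref_shape for s in shapes):
        raise ValueError("all configurations must share landmark count and dimension")

    scaled, sizes = zip(*(_center_and_scale(c) for c in shapes))
    aligned = [c.copy() for c in scaled]
    if len(aligned) == 1:
        return [ShapeSample(aligned[0], sizes[0])], aligned[0].copy()

    mean = aligned[0].copy()
    prev_obj = np.inf
    for it in range(max_iter):
        aligned = [c @ optimal_rotation(c, mean) for c in aligned]
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        norm = np.linalg.norm(new_mean)
        if norm <= 0:
            raise ValueError("degenerate mean shape during GPA")
        mean = new_mean / norm
        obj = float(sum(np.sum((c - mean) ** 2) for c in aligned))
        log.debug("GPA iteration %d: objective %.12g", it, obj)
        if prev_obj - obj < tol * max(prev_obj, 1.0):
            break
        prev_obj = obj
    samples = [ShapeSample(c, s) for c, s in zip(aligned, sizes)]
    return samples, mean


def gpa_objective_trace(configs: list[np.ndarray], tol: float = 1e-10,
                        max_iter: int = 100) -> np.ndarray:
    """Per-iteration GPA objective values (for monotonicity audits)."""
    shapes = [np.asarray(c, float) for c in configs]
    scaled = [(_center_and_scale(c))[0] for c in shapes]
    aligned = [c.copy() for c in scaled]
    mean = aligned[0].copy()
    trace = []
    prev_obj = np.inf
    for _ in range(max_iter):
        aligned = [c @ optimal_rotation(c, mean) for c in aligned]
        new_mean = np.mean(aligned, axis=0)
        new_mean -= new_mean.mean(axis=0)
        mean = new_mean / np.linalg.norm(new_mean)
        obj = float(sum(np.sum((c - mean) ** 2) for c in aligned))
        trace.append(obj)
        if prev_obj - obj < tol * max(prev_obj, 1.0):
            break
        prev_obj = obj
    return np.array(trace)


def pca(samples: list[ShapeSample]) -> PCModel:
    """Covariance PCA of the flattened aligned coordinates.

    Components are sorted by descending variance; per-component sign is
    fixed by making the largest-magnitude loading positive so repeated runs
    are reproducible.
    """
    if len(samples) < 2:
        raise ValueError("PCA needs at least 2 samples")
    data = np.stack([s.coords.reshape(-1) for s in samples])
    k = samples[0].coords.shape[1]
    mean_flat = data.mean(axis=0)
    centered = data - mean_flat
    U, s, Vt = np.linalg.svd(centered, full_matrices=False)
    eigenvalues = s ** 2 / (len(samples) - 1)
    # fix eigenvector signs: largest-|loading| entry positive
    flips = np.sign(Vt[np.arange(len(Vt)), np.argmax(np.abs(Vt), axis=1)])
    flips[flips == 0] = 1.0
    Vt = Vt * flips[:, None]
    scores = centered @ Vt.T
    return PCModel(mean_shape=mean_flat.reshape(-1, k), eigenvectors=Vt,
                   eigenvalues=eigenvalues, scores=scores)


def reconstruct(model: PCModel, pc_values: dict[int, float]) -> np.ndarray:
    """Inverse PCA: mean shape plus the named PC displacements.

    ``pc_values`` maps 0-based PC index to a score value; unspecified PCs
    stay at their mean (zero after centring).  Scores are in the same units
    the model's ``scores`` use, so e.g. ``{0: 2 * std_pc1}`` reproduces a
    "mean + 2 STD along PC1" shape.
    """
    flat = model.mean_shape.reshape(-1).copy()
    for pc, value in pc_values.items():
        if not 0 <= pc < len(model.eigenvectors):
            raise KeyError(f"unknown PC index {pc}")
        flat = flat + value * model.eigenvectors[pc]
    return flat.reshape(model.mean_shape.shape)


def deformation_vectors(model: PCModel, pc: int, magnitude: float) -> np.ndarray:
    """Per-landmark displacement from the mean shape along one PC."""
    return reconstruct(model, {pc: magnitude}) - model.mean_shape


def scree_table(model: PCModel):
    """Eigenvalue / variance-fraction table, CSV-writable."""
    import pandas as pd

    vf = model.variance_fractions
    return pd.DataFrame({
        "pc": np.arange(1, len(model.eigenvalues) + 1),
        "eigenvalue": model.eigenvalues,
        "variance_fraction": vf,
        "cumulative_fraction": np.cumsum(vf),
    })
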