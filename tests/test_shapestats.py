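"""GPA superimposition and shape PCA, checked against independent oracles."""

import numpy as np
import pytest
from scipy.linalg import orthogonal_procrustes

from conftest import random_rotation
from floramorph import make_population
from floramorph.shapestats import (ShapeSample, centroid_size, deformation_vectors,
                                   gpa, gpa_objective_trace, optimal_rotation, pca,
                                   reconstruct)


def naive_gpa(configs, n_iter=400):
    """Independent reference: plain alternating minimisation, no early stop.

    Uses scipy's orthogonal Procrustes solution with an explicit reflection
    fix, looping far past convergence.
    """
    scaled = []
    for c in configs:
        c = c - c.mean(axis=0)
        scaled.append(c / np.linalg.norm(c))
    aligned = [c.copy() for c in scaled]
    mean = aligned[0]
    for _ in range(n_iter):
        new = []
        for c in aligned:
            R, _ = orthogonal_procrustes(c, mean)
            if np.linalg.det(R) < 0:
                U, s, Vt = np.linalg.svd(c.T @ mean)
                D = np.eye(c.shape[1])
                D[-1, -1] = -1
                R = U @ D @ Vt
            new.append(c @ R)
        aligned = new
        mean = np.mean(aligned, axis=0)
        mean = (mean - mean.mean(axis=0)) / np.linalg.norm(mean - mean.mean(axis=0))
    return aligned, mean, float(sum(np.sum((c - mean) ** 2) for c in aligned))


class TestOptimalRotation:
    def test_recovers_known_rotation(self, rng):
        A = rng.normal(size=(10, 3))
        A -= A.mean(axis=0)
        R0 = random_rotation(rng)
        assert np.abs(optimal_rotation(A, A @ R0) - R0).max() < 1e-9

    def test_identity_for_equal_inputs(self, rng):
        A = rng.normal(size=(8, 3))
        A -= A.mean(axis=0)
        assert np.abs(optimal_rotation(A, A) - np.eye(3)).max() < 1e-9

    def test_beats_random_rotations(self, rng):
        A = rng.normal(size=(10, 3))
        B = rng.normal(size=(10, 3))
        A -= A.mean(axis=0)
        B -= B.mean(axis=0)
        R = optimal_rotation(A, B)
        best = np.sum((A @ R - B) ** 2)
        for _ in range(10_000):
            Rr = random_rotation(rng)
            assert np.sum((A @ Rr - B) ** 2) >= best - 1e-9

    def test_never_returns_reflection(self, rng):
        # force a case where the unconstrained optimum is a reflection
        A = rng.normal(size=(20, 3))
        A -= A.mean(axis=0)
        B = A.copy()
        B[:, 2] = -B[:, 2]
        R = optimal_rotation(A, B)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_input_raises(self):
        A = np.zeros((5, 3))
        A[:, 0] = np.arange(5) - 2.0     # collinear
        with pytest.raises(np.linalg.LinAlgError):
            optimal_rotation(A, A)


class TestGPA:
    def test_transformed_copies_align_perfectly(self, rng):
        base = rng.normal(size=(12, 3))
        configs = []
        for _ in range(6):
            R = random_rotation(rng)
            s = rng.uniform(0.5, 2.0)
            t = rng.normal(scale=5, size=3)
            configs.append(s * base @ R + t)
        samples, _ = gpa(configs)
        for s1 in samples:
            for s2 in samples:
                assert np.abs(s1.coords - s2.coords).max() < 1e-8

    def test_single_config_returned_normalised(self, rng):
        c = rng.normal(size=(7, 3))
        samples, mean = gpa([c])
        assert np.abs(samples[0].coords.mean(axis=0)).max() < 1e-12
        assert centroid_size(samples[0].coords) == pytest.approx(1.0)
        assert np.array_equal(samples[0].coords, mean)

    def test_matches_naive_alternating_minimisation(self, rng):
        configs = [rng.normal(size=(10, 3)) for _ in range(20)]
        samples, mean = gpa(configs, tol=1e-14, max_iter=500)
        obj = float(sum(np.sum((s.coords - mean) ** 2) for s in samples))
        _, _, obj_ref = naive_gpa(configs)
        assert obj == pytest.approx(obj_ref, abs=1e-8)

    def test_objective_monotone_nonincreasing(self, rng):
        configs = [rng.normal(size=(9, 3)) for _ in range(15)]
        trace = gpa_objective_trace(configs)
        assert (np.diff(trace) <= 1e-12).all()

    def test_invariant_to_rigid_and_scale_pretransforms(self, rng):
        configs = [rng.normal(size=(11, 3)) for _ in range(8)]
        samples_a, _ = gpa(configs)
        moved = [rng.uniform(0.2, 3.0) * c @ random_rotation(rng)
                 + rng.normal(scale=9, size=3) for c in configs]
        samples_b, _ = gpa(moved)
        for sa, sb in zip(samples_a, samples_b):
            # aligned shapes agree up to the joint rotation of the whole set
            R = optimal_rotation(sb.coords, sa.coords)
            assert np.abs(sb.coords @ R - sa.coords).max() < 1e-8

    def test_inconsistent_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            gpa([rng.normal(size=(5, 3)), rng.normal(size=(6, 3))])


class TestPCA:
    def _samples(self, rng, n=12, k=3, p=9):
        return [ShapeSample(*_norm(rng.normal(size=(p, k)))) for _ in range(n)]

    def test_rank_one_variation_concentrates_variance(self, rng):
        base = rng.normal(size=(10, 3))
        direction = rng.normal(size=(10, 3))
        samples = []
        for t in np.linspace(-1, 1, 9):
            c, size = _norm(base + 0.05 * t * direction)
            samples.append(ShapeSample(c, size))
        model = pca(samples)
        assert model.variance_fractions[0] > 0.999

    def test_full_basis_round_trip(self, rng):
        samples = self._samples(rng)
        model = pca(samples)
        for i, s in enumerate(samples):
            rebuilt = reconstruct(model, dict(enumerate(model.scores[i])))
            assert np.abs(rebuilt - s.coords).max() < 1e-8

    def test_eigenvector_orthonormality_and_fraction_sum(self, rng):
        model = pca(self._samples(rng))
        V = model.eigenvectors
        assert np.abs(V @ V.T - np.eye(len(V))).max() < 1e-8
        assert model.variance_fractions.sum() == pytest.approx(1.0, abs=1e-8)
        assert (np.diff(model.eigenvalues) <= 1e-12).all()

    def test_scores_have_zero_mean(self, rng):
        model = pca(self._samples(rng))
        assert np.abs(model.scores.mean(axis=0)).max() < 1e-10

    def test_recovers_generative_parameters(self):
        # independent opening and tilt variation: each parameter is matched
        # one-to-one to a top-2 PC with |r| >= 0.9 (n large enough that the
        # sampling correlation of the draws cannot rotate the basis much)
        pop = make_population(120, seed=7)
        opens = np.array([g.true_opening for _, g in pop])
        sines = np.array([g.true_asymmetry_sine for _, g in pop])
        samples, _ = gpa([g.landmarks.coords for _, g in pop])
        model = pca(samples)
        r = np.array([[abs(np.corrcoef(model.scores[:, pc], param)[0, 1])
                       for param in (opens, sines)] for pc in (0, 1)])
        best = max(r[0, 0] * r[1, 1], r[0, 1] * r[1, 0])
        matched = (r[0, 0], r[1, 1]) if r[0, 0] * r[1, 1] == best else (r[0, 1], r[1, 0])
        assert min(matched) >= 0.9

    def test_fewer_than_two_samples_rejected(self, rng):
        with pytest.raises(ValueError):
            pca(self._samples(rng, n=1))


class TestReconstruction:
    def test_zero_values_give_mean_shape(self, rng):
        model = pca([ShapeSample(*_norm(rng.normal(size=(6, 3)))) for _ in range(8)])
        assert np.array_equal(reconstruct(model, {}), model.mean_shape)

    def test_deformation_scales_linearly(self, rng):
        model = pca([ShapeSample(*_norm(rng.normal(size=(6, 3)))) for _ in range(8)])
        v1 = deformation_vectors(model, 0, 1.0)
        v3 = deformation_vectors(model, 0, 3.0)
        assert np.abs(v3 - 3 * v1).max() < 1e-12
        assert np.sum(deformation_vectors(model, 1, 0.0) ** 2) == 0.0

    def test_unit_magnitude_deformation_has_unit_norm(self, rng):
        # eigenvectors are unit-norm, so the summed squared vector norms
        # at magnitude 1 equal 1
        model = pca([ShapeSample(*_norm(rng.normal(size=(6, 3)))) for _ in range(8)])
        assert np.sum(deformation_vectors(model, 0, 1.0) ** 2) == pytest.approx(1.0)

    def test_unknown_pc_rejected(self, rng):
        model = pca([ShapeSample(*_norm(rng.normal(size=(6, 3)))) for _ in range(4)])
        with pytest.raises(KeyError):
            reconstruct(model, {99: 1.0})


class TestDimensionAgnostic:
    def test_2d_toy_triangles_match_pairwise_procrustes(self, rng):
        # two triangles: GPA of a pair must reach the pairwise full-Procrustes
        # residual computed by scipy's reference implementation
        from scipy.spatial import procrustes as scipy_procrustes
        A = rng.normal(size=(3, 2))
        B = rng.normal(size=(3, 2))
        samples, mean = gpa([A, B], tol=1e-15, max_iter=500)
        obj = sum(np.sum((s.coords - mean) ** 2) for s in samples)
        _, _, disparity = scipy_procrustes(A, B)
        # pairwise disparity d relates to the symmetric two-shape GPA
        # objective: both shapes end distance d/2-ish from the midpoint shape
        m1, m2, _ = scipy_procrustes(A, B)
        midpoint = (m1 + m2) / 2
        midpoint = midpoint / np.linalg.norm(midpoint)
        obj_ref = sum(np.sum((m / np.linalg.norm(m) - midpoint) ** 2)
                      for m in (m1, m2))
        assert obj <= obj_ref + 1e-8

    def test_2d_code_path_matches_naive_oracle(self, rng):
        configs = [rng.normal(size=(6, 2)) for _ in range(10)]
        samples, mean = gpa(configs, tol=1e-14, max_iter=500)
        obj = float(sum(np.sum((s.coords - mean) ** 2) for s in samples))
        _, _, obj_ref = naive_gpa(configs)
        assert obj == pytest.approx(obj_ref, abs=1e-8)


def _norm(c):
    c = c - c.mean(axis=0)
    size = float(np.linalg.norm(c))
    return c / size, size
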