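"""Per-slice segmentation chain and surface extraction."""

import numpy as np
import pytest
from scipy import ndimage

from floramorph import (FlowerParams, SegmentationConfig, VoxelVolume, binarize,
                        downsample, extract_surface, make_flower, mask_and_close,
                        remove_base, remove_small_objects, segment_stack,
                        stretch_contrast, voxelize)
from floramorph.volseg import SegmentationError


def _disc(shape, center, radius, value=255):
    out = np.zeros(shape, np.uint8)
    rr, cc = np.mgrid[: shape[0], : shape[1]]
    out[(rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2] = value
    return out


class TestDownsample:
    def test_factor_one_is_identity(self):
        vol = VoxelVolume(np.arange(27, dtype=np.uint8).reshape(3, 3, 3), 35.0)
        out = downsample(vol, 1)
        assert np.array_equal(out.intensities, vol.intensities)

    def test_voxel_size_doubles_at_factor_two(self):
        vol = VoxelVolume(np.zeros((4, 4, 4), np.uint8), 35.0)
        assert downsample(vol, 2).voxel_size_um == 70.0

    def test_block_mean_of_constant_volume(self):
        vol = VoxelVolume(np.full((4, 4, 4), 7, np.uint8), 35.0)
        out = downsample(vol, 2)
        assert out.shape == (2, 2, 2)
        assert (out.intensities == 7).all()

    def test_factor_exceeding_dimension_rejected(self):
        vol = VoxelVolume(np.zeros((2, 8, 8), np.uint8), 35.0)
        with pytest.raises(ValueError):
            downsample(vol, 4)


class TestRemoveBase:
    def test_base_only_slice_becomes_empty(self):
        sl = np.zeros((100, 100), np.uint8)
        sl[85:, 30:70] = 255                       # large blob at the bottom
        assert not remove_base(sl).any()

    def test_flower_blob_survives_base_removal(self):
        flower = _disc((100, 100), (40, 50), 15)
        base = np.zeros_like(flower)
        base[88:, 25:75] = 255
        cleaned = remove_base(flower + base)
        assert np.array_equal(cleaned > 0, flower > 0)

    def test_empty_slice_passthrough(self):
        sl = np.zeros((50, 50), np.uint8)
        assert not remove_base(sl).any()

    def test_small_bottom_object_kept(self):
        sl = np.zeros((100, 100), np.uint8)
        sl[95:97, 50:52] = 200                     # tiny: below base_min_px
        assert remove_base(sl).sum() == sl.sum()


class TestStretchContrast:
    def test_full_range_identity(self):
        sl = np.array([[0, 128, 255]], np.uint8)
        out = stretch_contrast(sl, 0, 100, 1.0)
        assert np.array_equal(out, sl)

    def test_two_valued_slice_maps_to_endpoints(self):
        sl = np.array([[10, 200]], np.uint8)
        out = stretch_contrast(sl, 0, 100, 1.0)
        assert set(np.unique(out).tolist()) == {0, 255}

    def test_gamma_half_on_mid_gray(self):
        sl = np.array([[0, 128, 255]], np.uint8)
        out = stretch_contrast(sl, 0, 100, 0.5)
        assert out[0, 1] == round(255 * (128 / 255) ** 0.5)   # = 181

    def test_monotone_nondecreasing(self):
        rng = np.random.default_rng(0)
        sl = rng.integers(0, 256, (64, 64)).astype(np.uint8)
        out = stretch_contrast(sl, 2, 98, 0.7)
        flat_in, flat_out = sl.ravel(), out.ravel()
        order = np.argsort(flat_in, kind="stable")
        assert (np.diff(flat_out[order].astype(int))
                [np.diff(flat_in[order].astype(int)) > 0] >= 0).all()

    def test_constant_slice_unchanged(self):
        sl = np.full((8, 8), 42, np.uint8)
        assert np.array_equal(stretch_contrast(sl), sl)


class TestBinarize:
    def test_fixed_threshold(self):
        sl = np.array([[50, 150]], np.uint8)
        assert binarize(sl, "fixed:100").tolist() == [[False, True]]

    def test_otsu_matches_exhaustive_search(self):
        # oracle: maximise between-class variance over every threshold
        rng = np.random.default_rng(1)
        sl = np.concatenate([rng.normal(60, 10, 600), rng.normal(190, 12, 400)])
        sl = np.clip(sl, 0, 255).astype(np.uint8).reshape(40, 25)
        best_t, best_v = None, -1.0
        vals = sl.ravel().astype(float)
        for t in range(1, 255):
            fg, bg = vals[vals > t], vals[vals <= t]
            if len(fg) == 0 or len(bg) == 0:
                continue
            v = len(fg) * len(bg) * (fg.mean() - bg.mean()) ** 2
            if v > best_v:
                best_t, best_v = t, v
        assert np.array_equal(binarize(sl, "otsu"), sl > best_t)

    def test_all_zero_slice_gives_empty_mask(self):
        assert not binarize(np.zeros((5, 5), np.uint8)).any()


class TestRemoveSmallObjects:
    def test_only_large_blob_survives(self):
        mask = np.zeros((60, 60), bool)
        mask[5:7, 5:7] = True                      # size 4
        mask[20:40, 20:40] = True                  # size 400
        out = remove_small_objects(mask, 50)
        assert out.sum() == 400

    def test_min_px_zero_is_identity(self):
        rng = np.random.default_rng(2)
        mask = rng.random((30, 30)) > 0.7
        assert np.array_equal(remove_small_objects(mask, 0), mask)

    def test_component_sizes_audited_by_flood_fill(self):
        # every surviving component must have >= min_px pixels (8-connectivity)
        rng = np.random.default_rng(3)
        mask = rng.random((80, 80)) > 0.75
        out = remove_small_objects(mask, 6)
        lab, n = ndimage.label(out, structure=np.ones((3, 3), int))
        sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
        assert (sizes >= 6).all()
        # and removed pixels all belonged to undersized components
        lab_in, n_in = ndimage.label(mask, structure=np.ones((3, 3), int))
        sizes_in = ndimage.sum_labels(np.ones_like(lab_in), lab_in,
                                      np.arange(1, n_in + 1))
        keep = np.zeros(n_in + 1, bool)
        keep[1:] = sizes_in >= 6
        assert np.array_equal(out, keep[lab_in])

    def test_sparkle_field_cleared(self):
        mask = np.zeros((50, 50), bool)
        mask[::7, ::7] = True                      # isolated singletons
        assert not remove_small_objects(mask, 2).any()


class TestMaskAndClose:
    def test_solid_region_unchanged(self):
        sl = np.zeros((20, 20), np.uint8)
        sl[5:15, 5:15] = 200
        out = mask_and_close(sl, np.ones_like(sl, bool))
        assert np.array_equal(out, sl)

    def test_single_hollow_pixel_filled(self):
        sl = np.full((9, 9), 200, np.uint8)
        sl[4, 4] = 0
        out = mask_and_close(sl, np.ones_like(sl, bool))
        assert out[4, 4] == 200

    def test_empty_mask_zeroes_slice(self):
        sl = np.full((6, 6), 99, np.uint8)
        assert not mask_and_close(sl, np.zeros_like(sl, bool)).any()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mask_and_close(np.zeros((4, 4), np.uint8), np.zeros((5, 5), bool))


@pytest.fixture(scope="module")
def noisy_volume():
    mesh, _ = make_flower(FlowerParams(noise_sparkle_density=1e-3,
                                       base_height=3.0, voxel_size_um=250.0))
    return voxelize(mesh, FlowerParams(noise_sparkle_density=1e-3,
                                       base_height=3.0, voxel_size_um=250.0))


class TestSegmentStack:

    def test_output_free_of_base_and_sparkles(self, noisy_volume):
        cfg = SegmentationConfig(min_px=4, base_min_px=50)
        seg = segment_stack(noisy_volume, cfg)
        for i, sl in enumerate(seg.intensities):
            lab, n = ndimage.label(sl > 0, structure=np.ones((3, 3), int))
            if n == 0:
                continue
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, np.arange(1, n + 1))
            assert (sizes >= 4).all(), f"undersized component in slice {i}"
            centroids = ndimage.center_of_mass(np.ones_like(lab), lab,
                                               np.arange(1, n + 1))
            big_bottom = [(s, c) for s, c in zip(sizes, centroids)
                          if s > 50 and c[0] >= 0.8 * sl.shape[0]]
            assert not big_bottom, f"base-like object left in slice {i}"

    def test_clean_input_foreground_preserved(self):
        # noise-free, base-free input: nothing is lost; the only growth the
        # chain may add is the radius-1 closing's own closure of the support
        from skimage.morphology import closing, disk
        params = FlowerParams(noise_sparkle_density=0.0, base_height=0.0,
                              voxel_size_um=300.0)
        mesh, _ = make_flower(params)
        vol = voxelize(mesh, params)
        seg = segment_stack(vol, SegmentationConfig(min_px=0))
        in_fg = vol.intensities > 0
        out_fg = seg.intensities > 0
        assert (in_fg <= out_fg).all()
        closure = np.stack([closing(sl, disk(1)) for sl in in_fg])
        assert (out_fg <= closure).all()

    def test_deterministic(self, noisy_volume):
        cfg = SegmentationConfig()
        a = segment_stack(noisy_volume, cfg)
        b = segment_stack(noisy_volume, cfg)
        assert np.array_equal(a.intensities, b.intensities)

    def test_masking_never_adds_foreground(self, noisy_volume):
        # segmentation only removes; growth is bounded by the closing's closure
        from skimage.morphology import closing, disk
        seg = segment_stack(noisy_volume, SegmentationConfig())
        closure = np.stack([closing(sl > 0, disk(1))
                            for sl in noisy_volume.intensities])
        assert not ((seg.intensities > 0) & ~closure).any()


class TestExtractSurface:
    def test_sphere_vertices_at_analytic_radius(self):
        r = 20
        zz, yy, xx = np.mgrid[-24:25, -24:25, -24:25]
        occ = (xx ** 2 + yy ** 2 + zz ** 2 <= r ** 2).astype(np.uint8) * 255
        vol = VoxelVolume(occ, 1000.0)   # 1 mm voxels
        mesh = extract_surface(vol)
        center = np.array([24.0, 24.0, 24.0])
        d = np.linalg.norm(mesh.vertices - center, axis=1)
        assert (np.abs(d - r) <= 1.0).all()

    def test_box_surface_area_matches_analytic(self):
        occ = np.zeros((30, 24, 18), np.uint8)
        occ[5:25, 4:20, 3:15] = 255                # 20 x 16 x 12 voxel box
        mesh = extract_surface(VoxelVolume(occ, 1000.0))
        analytic = 2 * (20 * 16 + 20 * 12 + 16 * 12)
        assert abs(mesh.area - analytic) / analytic < 0.05

    def test_empty_volume_raises(self):
        with pytest.raises(SegmentationError, match="no surface"):
            extract_surface(VoxelVolume(np.zeros((5, 5, 5), np.uint8), 100.0))

    def test_decimation_reduces_faces(self):
        zz, yy, xx = np.mgrid[-24:25, -24:25, -24:25]
        occ = (xx ** 2 + yy ** 2 + zz ** 2 <= 400).astype(np.uint8)
        mesh = extract_surface(VoxelVolume(occ, 1000.0), target_faces=500)
        assert len(mesh.faces) <= 500

    def test_segmented_flower_mesh_hugs_generating_surface(self):
        # >= 99% of extracted vertices within 2 voxels of the true surface
        from scipy.spatial import cKDTree
        params = FlowerParams(voxel_size_um=200.0)
        mesh, _ = make_flower(params)
        vol = voxelize(mesh, params)
        seg = segment_stack(vol, SegmentationConfig())
        surf = extract_surface(seg)
        ref = np.asarray(mesh.sample(300_000))
        d, _ = cKDTree(ref).query(surf.vertices)
        assert (d <= 2 * vol.voxel_size_mm).mean() >= 0.99
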