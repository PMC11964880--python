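"""Rigid registration recovery and conditional-fusion semantics."""

import numpy as np
import pytest
from conftest import PLANTED_TRANSFORM, make_grid

from ihcfusion.fusion import (
    FusionClass,
    binarize_grid,
    fuse_heatmaps,
    register_pair,
    resample_grid,
)
from ihcfusion.heatmap import RED, TURQUOISE
from ihcfusion.types import ParameterError, RigidTransform


class TestRigidTransform:
    @pytest.mark.parametrize("tf", [
        RigidTransform(5.0, -3.0, 2.0),
        RigidTransform(-17.2, 8.9, -2.5),
        RigidTransform(0.0, 0.0, 3.0),
    ])
    def test_inverse_round_trip_within_half_pixel(self, tf):
        pts = np.random.default_rng(0).uniform(0, 512, (50, 2))
        fwd = tf.apply_points(pts, (512, 512))
        back = tf.inverse().apply_points(fwd, (512, 512))
        assert np.abs(back - pts).max() < 0.5


class TestRegistration:
    def test_identity_on_same_tile(self, standard_pair):
        tile_a, _, _ = standard_pair
        tf = register_pair(tile_a, tile_a)
        assert abs(tf.dx) < 0.5 and abs(tf.dy) < 0.5
        assert abs(tf.rotation) < 0.1
        assert not tf.low_confidence

    def test_recovers_planted_transform(self, standard_pair):
        tile_a, tile_b, truth = standard_pair
        tf = register_pair(tile_a, tile_b)
        planted = truth.intersection_transform
        assert abs(tf.dx - planted.dx) <= 1.0
        assert abs(tf.dy - planted.dy) <= 1.0
        assert abs(tf.rotation - planted.rotation) <= 0.5

    def test_pure_rotation_recovered(self):
        from ihcfusion.synthetic import MarkerStainModel, TissueModel, generate_tile_pair

        tissue = TissueModel(tile_size=512, necrosis_fraction=0.25,
                             glass_fraction=0.1, cell_density=1.5, rng_seed=13)
        ma = MarkerStainModel(marker_name="A", cellular_fraction=0.6, rim_intensity=0.5)
        mb = MarkerStainModel(marker_name="B", cellular_fraction=0.15,
                              diffuse_in_necrosis=0.6)
        tile_a, tile_b, _ = generate_tile_pair(tissue, ma, mb,
                                               RigidTransform(0.0, 0.0, 2.0))
        tf = register_pair(tile_a, tile_b)
        assert abs(tf.rotation - 2.0) <= 0.5
        assert abs(tf.dx) <= 1.0 and abs(tf.dy) <= 1.0

    def test_dimension_mismatch_rejected(self, standard_pair):
        from ihcfusion.types import RgbTile

        tile_a, _, _ = standard_pair
        small = RgbTile(tile_a.pixels[:256, :256])
        with pytest.raises(ParameterError):
            register_pair(tile_a, small)


class TestBinarize:
    def test_all_zero_grid_no_high(self):
        assert not binarize_grid(make_grid(np.zeros((6, 6))), 0.75).any()

    def test_single_max_patch_high(self):
        vals = np.full((10, 10), 0.2)
        vals[4, 4] = 1.0
        high = binarize_grid(make_grid(vals), 0.99)
        assert high.sum() == 1 and high[4, 4]

    def test_planted_hotspot_fraction(self):
        rng = np.random.default_rng(1)
        vals = 0.05 + 0.05 * rng.random((50, 50))
        planted = np.zeros((50, 50), dtype=bool)
        planted[:10, :] = True  # 20% of patches
        vals[planted] = 0.9 + 0.05 * rng.random(planted.sum())
        high = binarize_grid(make_grid(vals), 0.8)
        assert high.mean() == pytest.approx(0.20, abs=0.02)

    def test_threshold_validation(self):
        with pytest.raises(ParameterError):
            binarize_grid(make_grid(np.zeros((4, 4))), 1.5)


class TestFusionSemantics:
    def test_identical_grids_no_discordance(self):
        rng = np.random.default_rng(2)
        vals = rng.random((12, 12))
        ga, gb = make_grid(vals), make_grid(vals.copy())
        fm = fuse_heatmaps(ga, gb, 0.75)
        assert (fm.classes != FusionClass.DISCORDANT).all()
        high = binarize_grid(ga, 0.75)
        assert np.array_equal(fm.classes == FusionClass.CONCORDANT_HIGH, high)

    def test_disjoint_highs_all_discordant(self):
        vals_a = np.full((8, 8), 0.1)
        vals_b = np.full((8, 8), 0.1)
        vals_a[:2] = 1.0   # A high top rows
        vals_b[6:] = 1.0   # B high bottom rows
        fm = fuse_heatmaps(make_grid(vals_a), make_grid(vals_b), 0.75)
        high_any = (vals_a >= np.quantile(vals_a, 0.75)) | (vals_b >= np.quantile(vals_b, 0.75))
        assert (fm.classes[high_any] == FusionClass.DISCORDANT).all()
        assert (fm.classes == FusionClass.CONCORDANT_HIGH).sum() == 0

    def test_symmetry(self):
        rng = np.random.default_rng(3)
        va, vb = rng.random((9, 9)), rng.random((9, 9))
        f1 = fuse_heatmaps(make_grid(va), make_grid(vb), 0.75)
        f2 = fuse_heatmaps(make_grid(vb), make_grid(va), 0.75)
        assert np.array_equal(f1.classes, f2.classes)

    def test_classes_partition_grid(self):
        rng = np.random.default_rng(4)
        va, vb = rng.random((10, 10)), rng.random((10, 10))
        va[0, :3] = np.nan
        fm = fuse_heatmaps(make_grid(va), make_grid(vb), 0.75)
        counts = fm.counts()
        assert sum(counts.values()) == 100

    def test_color_contract(self):
        vals_a = np.array([[1.0, 0.0, 1.0, np.nan]])
        vals_b = np.array([[1.0, 0.0, 0.0, 0.5]])
        fm = fuse_heatmaps(make_grid(vals_a), make_grid(vals_b), 0.5)
        assert (fm.rendered[0, 0] == RED).all()          # both high
        assert (fm.rendered[0, 1] == TURQUOISE).all()    # both low
        assert (fm.rendered[0, 2] == [255, 255, 255]).all()  # discordant
        assert fm.classes[0, 3] == FusionClass.BACKGROUND

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ParameterError):
            fuse_heatmaps(make_grid(np.zeros((4, 4))), make_grid(np.zeros((5, 5))))


class TestNoiseFloor:
    @pytest.mark.parametrize("seed", range(3))
    def test_identical_markers_low_discordance(self, seed):
        # same stain model, identity placement, no cell turnover:
        # discordance reflects chromogen noise only
        from ihcfusion.experiments import identical_marker_discordance

        res = identical_marker_discordance(seed=seed, section_resample=0.0)
        assert res["discordant_fraction"] <= 0.05


class TestResampleGrid:
    def test_identity_transform_preserves_grid(self):
        rng = np.random.default_rng(5)
        vals = rng.random((16, 16))
        grid = make_grid(vals)
        out = resample_grid(grid, RigidTransform(), (256, 256))
        np.testing.assert_allclose(out.values, vals)

    def test_patch_aligned_shift(self):
        vals = np.arange(64, dtype=float).reshape(8, 8) / 64
        grid = make_grid(vals)
        # content of B sits one patch to the right of A's content
        out = resample_grid(grid, RigidTransform(dx=16.0), (128, 128))
        np.testing.assert_allclose(out.values[:, :-1], vals[:, 1:])
        assert np.isnan(out.values[:, -1]).all() or (out.tissue_fraction[:, -1] == 0).all()
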