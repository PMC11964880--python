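"""Generator contracts: determinism, planted geometry, mass conservation."""

import numpy as np
import pytest
from scipy import ndimage

from ihcfusion.synthetic import (
    MarkerStainModel,
    TissueModel,
    generate_tile,
    generate_tile_pair,
    plant_cells,
)
from ihcfusion.types import ParameterError, RigidTransform


def small_tissue(**kw):
    defaults = dict(tile_size=256, necrosis_fraction=0.25, glass_fraction=0.1,
                    cell_density=1.5, rng_seed=0)
    defaults.update(kw)
    return TissueModel(**defaults)


def markers():
    return (
        MarkerStainModel(marker_name="A", cellular_fraction=0.5, rim_intensity=0.4),
        MarkerStainModel(marker_name="B", cellular_fraction=0.1, diffuse_in_necrosis=0.5),
    )


class TestDeterminismAndValidation:
    def test_same_seed_bitwise_identical(self):
        ma, mb = markers()
        out1 = generate_tile_pair(small_tissue(), ma, mb)
        out2 = generate_tile_pair(small_tissue(), ma, mb)
        assert np.array_equal(out1[0].pixels, out2[0].pixels)
        assert np.array_equal(out1[1].pixels, out2[1].pixels)
        assert np.array_equal(out1[2].necrosis_mask, out2[2].necrosis_mask)

    def test_different_seeds_differ(self):
        ma, mb = markers()
        a1, _, _ = generate_tile_pair(small_tissue(rng_seed=1), ma, mb)
        a2, _, _ = generate_tile_pair(small_tissue(rng_seed=2), ma, mb)
        assert not np.array_equal(a1.pixels, a2.pixels)

    @pytest.mark.parametrize("bad", [
        dict(necrosis_fraction=1.2), dict(hypocellular_factor=-0.1),
        dict(tile_size=64), dict(cell_density=-1.0),
    ])
    def test_invalid_tissue_params_rejected(self, bad):
        ma, mb = markers()
        with pytest.raises(ParameterError):
            generate_tile_pair(small_tissue(**bad), ma, mb)

    def test_invalid_marker_fraction_rejected(self):
        ma, _ = markers()
        bad = MarkerStainModel(marker_name="B", cellular_fraction=1.5)
        with pytest.raises(ParameterError):
            generate_tile_pair(small_tissue(), ma, bad)

    def test_oversized_translation_rejected(self):
        ma, mb = markers()
        with pytest.raises(ParameterError):
            generate_tile_pair(small_tissue(), ma, mb, RigidTransform(dx=100, dy=0))


class TestGeometry:
    def test_zero_necrosis_means_empty_masks(self):
        ma, mb = markers()
        _, _, truth = generate_tile_pair(small_tissue(necrosis_fraction=0.0), ma, mb)
        assert not truth.necrosis_mask.any()
        assert not truth.palisade_mask.any()

    def test_realized_necrosis_fraction_tracks_target(self):
        # +-10% relative, averaged over seeds
        ma, mb = markers()
        fracs = []
        for seed in range(10):
            _, _, truth = generate_tile_pair(small_tissue(rng_seed=seed), ma, mb)
            fracs.append(truth.necrosis_mask.sum() / truth.tissue_mask.sum())
        assert abs(np.mean(fracs) - 0.25) / 0.25 < 0.10

    def test_palisade_disjoint_and_adjacent_to_necrosis(self):
        ma, mb = markers()
        width = 12
        _, _, truth = generate_tile_pair(small_tissue(palisade_width=width), ma, mb)
        assert not (truth.palisade_mask & truth.necrosis_mask).any()
        reach = ndimage.binary_dilation(
            truth.necrosis_mask, ndimage.generate_binary_structure(2, 1),
            iterations=width,
        )
        assert (truth.palisade_mask & ~reach).sum() == 0

    def test_glass_fraction_realized(self):
        ma, mb = markers()
        _, _, truth = generate_tile_pair(small_tissue(glass_fraction=0.4), ma, mb)
        assert truth.tissue_mask.mean() == pytest.approx(0.6, abs=0.02)


class TestStainTruth:
    def test_dab_mask_within_tissue(self):
        ma, mb = markers()
        _, _, truth = generate_tile_pair(small_tissue(), ma, mb)
        assert not (truth.dab_mask_per_marker["A"] & ~truth.tissue_mask).any()
        assert not (truth.dab_mask_per_marker["B"] & ~truth.tissue_mask_b).any()

    def test_dab_mask_is_union_of_components(self):
        # mass conservation: every painted pixel is recorded, nothing more
        ma, mb = markers()
        _, _, truth = generate_tile_pair(small_tissue(), ma, mb)
        for name, mask in truth.dab_mask_per_marker.items():
            union = np.zeros_like(mask)
            for comp in truth.dab_components_per_marker[name].values():
                union |= comp
            assert np.array_equal(mask, union)

    def test_planted_diffuse_coverage_in_necrosis(self):
        # coverage of the necrotic mask matches the requested fraction
        tissue = TissueModel(tile_size=1024, necrosis_fraction=0.25,
                             cell_density=1.5, rng_seed=5)
        ma = MarkerStainModel(marker_name="A", cellular_fraction=0.5)
        mb = MarkerStainModel(marker_name="B", cellular_fraction=0.0,
                              diffuse_in_necrosis=0.30)
        _, _, truth = generate_tile_pair(tissue, ma, mb)
        cov = (truth.dab_mask_per_marker["B"] & truth.necrosis_mask_b).sum()
        assert cov / truth.necrosis_mask_b.sum() == pytest.approx(0.30, abs=0.03)

    def test_hypocellularity_ratio(self):
        ratios = []
        for seed in range(8):
            ma, mb = markers()
            _, _, truth = generate_tile_pair(
                small_tissue(rng_seed=seed, hypocellular_factor=0.2,
                             tile_size=512), ma, mb)
            viable = (truth.tissue_mask & ~truth.necrosis_mask & ~truth.palisade_mask)
            d_viable = truth.cell_counts["viable"] / viable.sum()
            d_necro = truth.cell_counts["necrosis"] / max(truth.necrosis_mask.sum(), 1)
            ratios.append(d_necro / d_viable)
        assert np.mean(ratios) == pytest.approx(0.2, rel=0.3)


class TestPlantCells:
    def test_zero_density_plants_nothing(self):
        rng = np.random.default_rng(0)
        mask = np.ones((200, 200), dtype=bool)
        pop = plant_cells(mask, 0.0, rng)
        assert pop.count == 0 and not pop.nucleus_mask.any()

    def test_empty_region_plants_nothing(self):
        rng = np.random.default_rng(0)
        pop = plant_cells(np.zeros((100, 100), dtype=bool), 2.0, rng)
        assert pop.count == 0

    def test_poisson_mean(self):
        # density 2.0 over 100,000 px^2 -> mean 200, check within 3*sqrt(200)
        mask = np.ones((250, 400), dtype=bool)
        counts = [plant_cells(mask, 2.0, np.random.default_rng(s)).count
                  for s in range(20)]
        assert abs(np.mean(counts) - 200) < 3 * np.sqrt(200) / np.sqrt(20)

    def test_count_proportional_to_area(self):
        full = np.ones((256, 256), dtype=bool)
        half = full.copy()
        half[:, 128:] = False
        n_full = np.mean([plant_cells(full, 2.0, np.random.default_rng(s)).count
                          for s in range(10)])
        n_half = np.mean([plant_cells(half, 2.0, np.random.default_rng(100 + s)).count
                          for s in range(10)])
        assert n_full / n_half == pytest.approx(2.0, rel=0.15)

    def test_cells_inside_region(self):
        mask = np.zeros((128, 128), dtype=bool)
        mask[30:90, 40:100] = True
        pop = plant_cells(mask, 5.0, np.random.default_rng(1))
        xs, ys = pop.centers[:, 0].astype(int), pop.centers[:, 1].astype(int)
        assert mask[ys, xs].all()


class TestSingleTile:
    def test_single_tile_matches_pair_tile_a(self):
        ma, mb = markers()
        tile, truth = generate_tile(small_tissue(), ma)
        tile_a, _, truth_pair = generate_tile_pair(small_tissue(), ma, mb)
        assert np.array_equal(tile.pixels, tile_a.pixels)
        assert np.array_equal(truth.dab_mask_per_marker["A"],
                              truth_pair.dab_mask_per_marker["A"])
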