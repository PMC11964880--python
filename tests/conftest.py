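import numpy as np
import pytest

from ihcfusion.heatmap import IntensityGrid
from ihcfusion.synthetic import MarkerStainModel, TissueModel, generate_tile_pair
from ihcfusion.types import RigidTransform

PLANTED_TRANSFORM = RigidTransform(dx=7.0, dy=-3.0, rotation=1.5)


@pytest.fixture(scope="session")
def standard_pair():
    """A 512^2 adjacent-section pair: cellular marker A (IBA1-like, strong
    pseudopalisading rim), diffuse-in-necrosis marker B (CD163-like)."""
    tissue = TissueModel(
        tile_size=512, necrosis_fraction=0.25, glass_fraction=0.15,
        cell_density=1.5, rng_seed=42,
    )
    marker_a = MarkerStainModel(marker_name="IBA1", cellular_fraction=0.6, rim_intensity=0.5)
    marker_b = MarkerStainModel(
        marker_name="CD163", cellular_fraction=0.15, diffuse_in_necrosis=0.6,
        rim_intensity=0.1,
    )
    tile_a, tile_b, truth = generate_tile_pair(tissue, marker_a, marker_b, PLANTED_TRANSFORM)
    return tile_a, tile_b, truth


def make_grid(values, tissue_fraction=None, patch_size=16, value_range=(0.0, 1.0)):
    values = np.asarray(values, dtype=np.float64)
    if tissue_fraction is None:
        tissue_fraction = np.where(np.isnan(values), 0.0, 1.0)
    return IntensityGrid(
        values=values, patch_size=patch_size,
        tissue_fraction=np.asarray(tissue_fraction, dtype=np.float64),
        value_range=value_range,
    )
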