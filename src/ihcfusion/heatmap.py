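"""Patch-grid intensity heatmaps of DAB immunoreactivity.

A tile is divided into square patches (16x16 px by default); each patch's
intensity is the mean chromogen darkness (1 - HSV value) over its
DAB-positive pixels, so the strongest immunoreactivity maps to the highest
value.  The grid is normalized by its own maximum and rendered on a
turquoise (low) -> red (high) color scale; patches without tissue carry
NaN and are excluded from all statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor

from .extraction import StainMask
from .types import ParameterError, RgbTile

TURQUOISE = np.array([64, 224, 208], dtype=np.uint8)
RED = np.array([255, 0, 0], dtype=np.uint8)
BACKGROUND_RGB = np.array([235, 235, 235], dtype=np.uint8)


@dataclass
class IntensityGrid:
    """Per-patch normalized DAB intensity on a regular grid.

    ``values`` is Hp x Wp with tissue patches in [0, 1] and background
    patches (zero tissue coverage) NaN.  ``value_range`` records the raw
    (lo, hi) used for max-normalization so raw intensities can be
    recovered as ``values * hi``.
    """

    values: np.ndarray
    patch_size: int
    tissue_fraction: np.ndarray
    value_range: tuple[float, float] = (0.0, 1.0)
    origin: tuple[int, int] = (0, 0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def background(self) -> np.ndarray:
        """Boolean Hp x Wp mask of patches with no tissue."""
        return self.tissue_fraction <= 0.0

    def tissue_values(self) -> np.ndarray:
        """1-D array of values over tissue patches."""
        return self.values[~self.background]


@dataclass
class HeatmapRender:
    rgb: np.ndarray  # Hp x Wp x 3 uint8
    colormap_name: str
    value_range: tuple[float, float]


def _patch_reduce(arr: np.ndarray, ps: int) -> np.ndarray:
    """Sum over non-overlapping ps x ps blocks, trailing partials dropped."""
    h, w = arr.shape
    hp, wp = h // ps, w // ps
    v = arr[: hp * ps, : wp * ps].reshape(hp, ps, wp, ps)
    return v.sum(axis=(1, 3))


def darkness_channel(tile: RgbTile) -> np.ndarray:
    """Chromogen darkness: 1 - HSV value, in [0, 1]."""
    hsv = skcolor.rgb2hsv(tile.as_float())
    return 1.0 - hsv[..., 2]


def aggregate_patch_intensity(
    tile: RgbTile, mask: StainMask, patch_size: int = 16
) -> IntensityGrid:
    """Mean DAB darkness per patch, max-normalized over the tile.

    Per patch, intensity is the mean of (1 - value) over the patch's
    DAB-masked pixels; patches without DAB pixels score 0 and patches
    without tissue are background (NaN).  Trailing partial patches are
    dropped.  The grid is normalized to [0, 1] by the tile-level maximum,
    recorded in ``value_range``.
    """
    if patch_size < 4:
        raise ParameterError("patch_size must be >= 4")
    h, w = tile.shape
    if h < patch_size or w < patch_size:
        raise ParameterError("patch_size larger than the tile")

    dark = darkness_channel(tile)
    dab = mask.dab_mask.astype(np.float64)
    dark_sum = _patch_reduce(dark * dab, patch_size)
    dab_count = _patch_reduce(dab, patch_size)
    tissue_frac = _patch_reduce(mask.tissue_mask.astype(np.float64), patch_size) / (
        patch_size * patch_size
    )

    raw = np.zeros_like(dark_sum)
    np.divide(dark_sum, dab_count, out=raw, where=dab_count > 0)

    background = tissue_frac <= 0.0
    hi = float(raw[~background].max()) if (~background).any() else 0.0
    values = raw / hi if hi > 0 else raw.copy()
    values[background] = np.nan
    return IntensityGrid(
        values=values,
        patch_size=patch_size,
        tissue_fraction=tissue_frac,
        value_range=(0.0, hi),
    )


# ---------------------------------------------------------------------------
# rendering


def colormap_value_to_rgb(v: np.ndarray | float) -> np.ndarray:
    """Turquoise(0) -> red(1) colormap: linear path in HSV.

    Hue runs monotonically from turquoise's (~174 deg) down through
    green/yellow/orange to red (0 deg); saturation and value interpolate
    between the anchors.
    """
    v = np.atleast_1d(np.asarray(v, dtype=np.float64))
    hsv_lo = skcolor.rgb2hsv((TURQUOISE / 255.0)[None, None, :])[0, 0]
    hsv_hi = skcolor.rgb2hsv((RED / 255.0)[None, None, :])[0, 0]
    t = np.clip(v, 0.0, 1.0)
    hsv = hsv_lo[None, :] * (1 - t)[:, None] + hsv_hi[None, :] * t[:, None]
    rgb = skcolor.hsv2rgb(hsv[None, :, :])[0]
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def render_heatmap(grid: IntensityGrid, colormap_name: str = "turquoise_red") -> HeatmapRender:
    """Render a grid through the turquoise->red scale; background neutral."""
    vals = np.where(np.isnan(grid.values), 0.0, grid.values)
    rgb = colormap_value_to_rgb(vals.ravel()).reshape(*grid.shape, 3)
    rgb[grid.background] = BACKGROUND_RGB
    return HeatmapRender(rgb=rgb, colormap_name=colormap_name, value_range=grid.value_range)


def hotspot_patches(grid: IntensityGrid, quantile: float) -> np.ndarray:
    """Patches at or above the given quantile of tissue-patch values.

    Ties are included; background patches are never hotspots.  An
    all-background grid yields an empty hotspot set.
    """
    if not 0.0 < quantile < 1.0:
        raise ParameterError("quantile must lie in (0, 1)")
    tv = grid.tissue_values()
    out = np.zeros(grid.shape, dtype=bool)
    if len(tv) == 0:
        return out
    thr = np.quantile(tv, quantile)
    with np.errstate(invalid="ignore"):
        out = np.where(np.isnan(grid.values), False, grid.values >= thr)
    return out
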