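"""Agreement statistics between two markers' heatmaps.

Correlations are computed at patch granularity — patches are the
heatmap's pixels — over patches carrying tissue in both grids.  Region
summaries contrast the markers inside anatomically defined compartments
(necrosis, pseudopalisading rim, viable tissue).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .fusion import binarize_grid
from .heatmap import IntensityGrid
from .types import InsufficientDataError

MIN_CO_TISSUE_PATCHES = 10


@dataclass
class CorrelationReport:
    """Pearson/Spearman agreement between two markers' patch grids.

    ``pearson_r`` / ``spearman_rho`` are NaN with ``undefined_reason`` set
    when either grid has zero variance (a uniform slide is a legitimate
    edge case, not a zero correlation).
    """

    pearson_r: float
    spearman_rho: float
    n_patches: int
    undefined_reason: str | None = None
    by_region: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "pearson_r": None if np.isnan(self.pearson_r) else self.pearson_r,
            "spearman_rho": None if np.isnan(self.spearman_rho) else self.spearman_rho,
            "n_patches": self.n_patches,
            "undefined_reason": self.undefined_reason,
        }
        if self.by_region is not None:
            d["by_region"] = self.by_region.to_dict(orient="records")
        return d


def _co_tissue(grid_a: IntensityGrid, grid_b: IntensityGrid) -> np.ndarray:
    if grid_a.shape != grid_b.shape:
        raise InsufficientDataError("grids must share shape")
    return ~grid_a.background & ~grid_b.background


def heatmap_correlation(
    grid_a: IntensityGrid, grid_b_aligned: IntensityGrid
) -> CorrelationReport:
    """Pearson and Spearman correlation over co-tissue patches."""
    co = _co_tissue(grid_a, grid_b_aligned)
    n = int(co.sum())
    if n < MIN_CO_TISSUE_PATCHES:
        raise InsufficientDataError(
            f"only {n} co-tissue patches; need >= {MIN_CO_TISSUE_PATCHES}"
        )
    a = grid_a.values[co]
    b = grid_b_aligned.values[co]
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        return CorrelationReport(
            pearson_r=float("nan"),
            spearman_rho=float("nan"),
            n_patches=n,
            undefined_reason="zero variance in at least one grid",
        )
    pr = sps.pearsonr(a, b).statistic
    sr = sps.spearmanr(a, b).statistic
    return CorrelationReport(pearson_r=float(pr), spearman_rho=float(sr), n_patches=n)


def project_regions_to_patches(
    region_masks: dict[str, np.ndarray], patch_size: int
) -> np.ndarray:
    """Majority-vote region label per patch.

    ``region_masks`` maps region name -> pixel-level boolean mask; the
    masks should partition tissue.  Returns an Hp x Wp array of region
    indices into ``sorted(region_masks)``, -1 where no region covers the
    patch.
    """
    names = sorted(region_masks)
    h, w = next(iter(region_masks.values())).shape
    hp, wp = h // patch_size, w // patch_size
    cover = np.zeros((len(names), hp, wp))
    for i, name in enumerate(names):
        m = region_masks[name][: hp * patch_size, : wp * patch_size]
        cover[i] = m.reshape(hp, patch_size, wp, patch_size).sum(axis=(1, 3))
    labels = np.argmax(cover, axis=0)
    labels[cover.sum(axis=0) == 0] = -1
    return labels


def region_summary(
    grid_a: IntensityGrid,
    grid_b_aligned: IntensityGrid,
    region_masks: dict[str, np.ndarray],
    high_threshold: float = 0.75,
) -> pd.DataFrame:
    """Per-region marker contrast table.

    For each region: patch count, mean normalized intensity of each
    marker, fraction of high (positive) patches of each marker, and the
    mean difference B - A.  Regions with zero patches are emitted with
    count 0 and NaN means (flagged, not dropped).
    """
    co = _co_tissue(grid_a, grid_b_aligned)
    labels = project_regions_to_patches(region_masks, grid_a.patch_size)
    names = sorted(region_masks)
    high_a = binarize_grid(grid_a, high_threshold)
    high_b = binarize_grid(grid_b_aligned, high_threshold)

    rows = []
    for i, name in enumerate(names):
        sel = (labels == i) & co
        n = int(sel.sum())
        if n == 0:
            rows.append(
                {
                    "region": name, "n_patches": 0,
                    "mean_a": np.nan, "mean_b": np.nan,
                    "positive_fraction_a": np.nan, "positive_fraction_b": np.nan,
                    "diff_b_minus_a": np.nan,
                }
            )
            continue
        ma = float(grid_a.values[sel].mean())
        mb = float(grid_b_aligned.values[sel].mean())
        rows.append(
            {
                "region": name, "n_patches": n,
                "mean_a": ma, "mean_b": mb,
                "positive_fraction_a": float(high_a[sel].mean()),
                "positive_fraction_b": float(high_b[sel].mean()),
                "diff_b_minus_a": mb - ma,
            }
        )
    return pd.DataFrame(rows)


def compare_markers(
    grid_a: IntensityGrid,
    grid_b_aligned: IntensityGrid,
    region_masks: dict[str, np.ndarray] | None = None,
    high_threshold: float = 0.75,
) -> CorrelationReport:
    """Full report: correlations plus optional per-region table."""
    rep = heatmap_correlation(grid_a, grid_b_aligned)
    if region_masks is not None:
        rep.by_region = region_summary(grid_a, grid_b_aligned, region_masks, high_threshold)
    return rep
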