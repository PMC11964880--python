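"""DAB-positive (brown) region extraction from RGB tiles.

The method groups pixel colors by k-means clustering (Lloyd's algorithm in
CIELAB space), picks the number of clusters automatically by silhouette
score, then extracts as positive every cluster whose center is brown and
darker than a configurable darkness threshold.  A tissue mask separates
tissue from bare glass so positive fractions refer to tissue area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import morphology
from sklearn.cluster import kmeans_plusplus
from sklearn.metrics import silhouette_score

from .types import ParameterError, RgbTile

MAX_K = 16
SELECT_K_SUBSAMPLE = 50_000
SILHOUETTE_SUBSAMPLE = 4_000


@dataclass
class ExtractionConfig:
    """Tunables of the brown-extraction pipeline (all overridable)."""

    color_space: str = "lab"          # clustering space: "lab" or "rgb"
    k: int | None = None              # fixed k; None = automatic
    k_range: tuple[int, int] = (2, 6)
    darkness_threshold: float = 0.75  # HSV value ceiling for brown clusters
    brown_hue_range: tuple[float, float] = (10.0, 50.0)  # degrees
    brown_saturation_min: float = 0.15
    tissue_saturation_min: float = 0.05
    tissue_value_max: float = 0.88
    fit_max_pixels: int | None = 200_000  # subsample for Lloyd fitting; None = all
    max_iter: int = 100
    tol: float = 1e-4
    seed: int = 0


@dataclass
class ColorClustering:
    """Result of k-means color clustering of a tile.

    ``centers`` live in ``color_space``; ``labels`` assigns every pixel a
    cluster in [0, k).  ``inertia_trace`` records the within-cluster sum
    of squares at each Lloyd assignment step (non-increasing).
    ``empty_clusters`` flags clusters that ended with no members (e.g.
    fewer distinct colors than k).
    """

    k: int
    centers: np.ndarray            # (k, 3) in clustering space
    labels: np.ndarray             # (H, W) int
    inertia: float
    seed: int
    color_space: str = "lab"
    inertia_trace: list[float] = field(default_factory=list)
    empty_clusters: list[int] = field(default_factory=list)

    def centers_rgb(self) -> np.ndarray:
        """Cluster centers converted to RGB floats in [0, 1]."""
        return _space_to_rgb(self.centers, self.color_space)

    def centers_hsv(self) -> np.ndarray:
        rgb = np.clip(self.centers_rgb(), 0.0, 1.0)
        return skcolor.rgb2hsv(rgb[None, :, :])[0]


@dataclass
class StainMask:
    """DAB-positive pixels plus the tissue mask they are referred to."""

    dab_mask: np.ndarray
    tissue_mask: np.ndarray
    positive_fraction: float
    k_used: int | None = None

    def __post_init__(self) -> None:
        if (self.dab_mask & ~self.tissue_mask).any():
            raise ParameterError("dab_mask must be a subset of tissue_mask")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ParameterError("positive_fraction outside [0, 1]")


# ---------------------------------------------------------------------------
# color spaces


def _rgb_to_space(rgb01: np.ndarray, space: str) -> np.ndarray:
    """(N, 3) RGB in [0,1] -> feature space."""
    if space == "rgb":
        return rgb01.astype(np.float64)
    if space == "lab":
        return skcolor.rgb2lab(rgb01[None, :, :])[0]
    raise ParameterError(f"unknown color space {space!r}")


def _space_to_rgb(feats: np.ndarray, space: str) -> np.ndarray:
    if space == "rgb":
        return feats
    if space == "lab":
        return skcolor.lab2rgb(feats[None, :, :])[0]
    raise ParameterError(f"unknown color space {space!r}")


def tile_features(tile: RgbTile, space: str) -> np.ndarray:
    """Per-pixel feature vectors (H*W, 3) in the clustering color space."""
    h, w = tile.shape
    return _rgb_to_space(tile.as_float().reshape(h * w, 3), space)


# ---------------------------------------------------------------------------
# tissue mask


def compute_tissue_mask(
    tile: RgbTile,
    saturation_min: float = 0.05,
    value_max: float = 0.88,
    min_object_px: int = 64,
    closing_radius: int = 2,
) -> np.ndarray:
    """Separate tissue from bare glass.

    A pixel is tissue when its HSV saturation exceeds ``saturation_min``
    or its value (brightness) falls below ``value_max`` — glass is bright
    and unsaturated.  Speckle is removed and small holes are closed so
    positivity fractions refer to coherent tissue.
    """
    hsv = skcolor.rgb2hsv(tile.as_float())
    raw = (hsv[..., 1] > saturation_min) | (hsv[..., 2] < value_max)
    if closing_radius > 0:
        pad = closing_radius + 1  # edge-replicate so closing cannot eat borders
        padded = np.pad(raw, pad, mode="edge")
        closed = ndimage.binary_closing(padded, structure=morphology.disk(closing_radius))
        raw = closed[pad:-pad, pad:-pad]
    if min_object_px > 0:
        raw = _drop_small_components(raw, min_object_px)
        raw = ~_drop_small_components(~raw, min_object_px * 4)  # fill small holes
    return raw


def _drop_small_components(mask: np.ndarray, min_px: int) -> np.ndarray:
    lab, n = ndimage.label(mask)
    if n == 0:
        return mask
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_px) + 1
    return np.isin(lab, keep)


# ---------------------------------------------------------------------------
# k-means (Lloyd)


def _lloyd(
    x: np.ndarray,
    centers0: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, list[float]]:
    """Vectorized Lloyd iterations from given initial centers.

    Returns final centers, labels and the inertia trace (one entry per
    assignment step; non-increasing by construction).
    """
    centers = centers0.astype(np.float64).copy()
    k = len(centers)
    trace: list[float] = []
    labels = np.zeros(len(x), dtype=np.int32)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        labels = np.argmin(d2, axis=1).astype(np.int32)
        trace.append(float(d2[np.arange(len(x)), labels].sum()))
        new_centers = centers.copy()
        counts = np.bincount(labels, minlength=k)
        for j in range(3):
            sums = np.bincount(labels, weights=x[:, j], minlength=k)
            np.divide(sums, counts, out=new_centers[:, j], where=counts > 0)
        shift = np.sqrt(((new_centers - centers) ** 2).sum(axis=1)).max()
        centers = new_centers
        if shift < tol:
            # final assignment against converged centers
            d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            labels = np.argmin(d2, axis=1).astype(np.int32)
            trace.append(float(d2[np.arange(len(x)), labels].sum()))
            break
    return centers, labels, trace


def _assign(x: np.ndarray, centers: np.ndarray, chunk: int = 1 << 20) -> tuple[np.ndarray, float]:
    """Nearest-center assignment (chunked to bound memory)."""
    labels = np.empty(len(x), dtype=np.int32)
    inertia = 0.0
    for s in range(0, len(x), chunk):
        xs = x[s : s + chunk]
        d2 = ((xs[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        lab = np.argmin(d2, axis=1)
        labels[s : s + chunk] = lab
        inertia += float(d2[np.arange(len(xs)), lab].sum())
    return labels, inertia


def kmeans_features(
    x: np.ndarray,
    k: int,
    seed: int,
    max_iter: int = 100,
    tol: float = 1e-4,
    fit_sample: int | None = None,
    init_centers: np.ndarray | None = None,
    fit_index: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, float, list[float], list[int]]:
    """k-means on raw feature vectors; shared by clustering and k selection.

    ``fit_index`` restricts the rows centers are learned from (all rows
    are still assigned); ``fit_sample`` additionally caps the fitting set
    by seeded subsampling.
    """
    if not 1 <= k <= MAX_K:
        raise ParameterError(f"k={k} outside [1, {MAX_K}]")
    rng = np.random.default_rng(seed)
    x_fit = x if fit_index is None else x[fit_index]
    if fit_sample is not None and len(x_fit) > fit_sample:
        idx = rng.choice(len(x_fit), size=fit_sample, replace=False)
        x_fit = x_fit[idx]
    if init_centers is None:
        n_distinct = len(np.unique(x_fit, axis=0))
        if n_distinct >= k:
            init_centers, _ = kmeans_plusplus(
                x_fit, n_clusters=k, random_state=int(seed) % (2**32)
            )
        else:
            uniq = np.unique(x_fit, axis=0)
            reps = np.tile(uniq, (int(np.ceil(k / len(uniq))), 1))[:k]
            init_centers = reps.astype(np.float64)
    centers, _, trace = _lloyd(x_fit, init_centers, max_iter, tol)
    labels, inertia = _assign(x, centers)
    empty = [j for j in range(k) if not (labels == j).any()]
    return centers, labels, inertia, trace, empty


def cluster_colors(
    tile: RgbTile,
    k: int,
    seed: int,
    color_space: str = "lab",
    max_iter: int = 100,
    tol: float = 1e-4,
    fit_sample: int | None = None,
    init_centers: np.ndarray | None = None,
    fit_mask: np.ndarray | None = None,
) -> ColorClustering:
    """Group a tile's pixel colors into ``k`` clusters with Lloyd k-means.

    Deterministic for a given seed (k-means++ initialization).  With
    ``fit_sample`` set, centers are fitted on a seeded subsample and all
    pixels are then assigned once — useful on megapixel tiles.
    ``fit_mask`` restricts center learning to the masked pixels (e.g.
    tissue only) while still labeling every pixel.  Fewer distinct
    colors than ``k`` yields empty clusters flagged on the result, not
    an exception.
    """
    h, w = tile.shape
    x = tile_features(tile, color_space)
    centers, labels, inertia, trace, empty = kmeans_features(
        x, k, seed, max_iter=max_iter, tol=tol, fit_sample=fit_sample,
        init_centers=init_centers,
        fit_index=None if fit_mask is None else fit_mask.ravel(),
    )
    return ColorClustering(
        k=k,
        centers=centers,
        labels=labels.reshape(h, w),
        inertia=inertia,
        seed=seed,
        color_space=color_space,
        inertia_trace=trace,
        empty_clusters=empty,
    )


# ---------------------------------------------------------------------------
# automatic k


def choose_k_from_scores(scores: dict[int, float]) -> int:
    """Largest-score k; ties (and near-ties within 1e-12) go to smaller k."""
    best_k = None
    best_s = -np.inf
    for k in sorted(scores):
        if scores[k] > best_s + 1e-12:
            best_k, best_s = k, scores[k]
    assert best_k is not None
    return best_k


def select_k(
    tile: RgbTile,
    k_range: tuple[int, int] = (2, 6),
    seed: int = 0,
    color_space: str = "lab",
    subsample: int = SELECT_K_SUBSAMPLE,
    mask: np.ndarray | None = None,
) -> tuple[int, dict[int, float]]:
    """Pick the number of color clusters by mean silhouette score.

    Clusters a uniform random subsample of at most ``subsample`` pixels
    (optionally restricted to ``mask``, e.g. tissue) for each k in
    ``k_range`` (inclusive) and returns the k maximizing the silhouette,
    ties broken toward smaller k, plus the score table.
    """
    k_lo, k_hi = k_range
    if not (2 <= k_lo <= k_hi <= MAX_K):
        raise ParameterError(f"k_range {k_range} must lie within [2, {MAX_K}]")
    x = tile_features(tile, color_space)
    if mask is not None:
        x = x[mask.ravel()]
    rng = np.random.default_rng(seed)
    if len(x) > subsample:
        x = x[rng.choice(len(x), size=subsample, replace=False)]
    if len(x) < k_hi:
        raise ParameterError("subsample smaller than the largest k")
    scores: dict[int, float] = {}
    for k in range(k_lo, k_hi + 1):
        _, labels, _, _, empty = kmeans_features(x, k, seed)
        n_nonempty = k - len(empty)
        if n_nonempty < 2:
            scores[k] = -1.0
            continue
        if len(x) > SILHOUETTE_SUBSAMPLE:
            sub = rng.choice(len(x), size=SILHOUETTE_SUBSAMPLE, replace=False)
            xs, ls = x[sub], labels[sub]
            if len(np.unique(ls)) < 2:
                scores[k] = -1.0
                continue
        else:
            xs, ls = x, labels
        scores[k] = float(silhouette_score(xs, ls))
    return choose_k_from_scores(scores), scores


# ---------------------------------------------------------------------------
# brown rule and full extraction


def _is_brown(
    hsv: np.ndarray,
    darkness_threshold: float,
    hue_range: tuple[float, float],
    saturation_min: float,
) -> bool:
    h_deg = hsv[0] * 360.0
    return (
        hue_range[0] <= h_deg <= hue_range[1]
        and hsv[1] >= saturation_min
        and hsv[2] <= darkness_threshold
    )


def identify_brown_clusters(
    clustering: ColorClustering,
    darkness_threshold: float = 0.75,
    hue_range: tuple[float, float] = (10.0, 50.0),
    saturation_min: float = 0.15,
) -> set[int]:
    """Clusters whose center is brown (DAB-like) and dark enough.

    A center qualifies when its hue lies in the brown window, saturation
    is at least ``saturation_min``, and HSV value does not exceed
    ``darkness_threshold``.  May be empty.
    """
    hsv = clustering.centers_hsv()
    return {
        j
        for j in range(clustering.k)
        if j not in clustering.empty_clusters
        and _is_brown(hsv[j], darkness_threshold, hue_range, saturation_min)
    }


def extract_brown_mask(tile: RgbTile, config: ExtractionConfig | None = None) -> StainMask:
    """Full DAB extraction: tissue mask, k-means, brown-cluster selection.

    Composes :func:`compute_tissue_mask`, :func:`select_k` (unless a fixed
    k is configured), :func:`cluster_colors`, and
    :func:`identify_brown_clusters`; positive pixels are those labeled
    with any brown cluster, restricted to tissue.  Both the choice of k
    and the cluster centers are learned from tissue pixels only — glass
    carries no stain information and would otherwise absorb a cluster —
    though every pixel still receives a label.  A uniform-color tile
    bypasses clustering: the mask is the whole tissue or nothing,
    depending on whether the single color itself satisfies the brown rule.
    """
    cfg = config or ExtractionConfig()
    tissue = compute_tissue_mask(
        tile,
        saturation_min=cfg.tissue_saturation_min,
        value_max=cfg.tissue_value_max,
    )
    if not tissue.any():
        return StainMask(np.zeros_like(tissue), tissue, 0.0, k_used=None)

    flat = tile.pixels.reshape(-1, 3)
    distinct = np.unique(flat, axis=0)
    if len(distinct) == 1:
        hsv = skcolor.rgb2hsv((distinct / 255.0)[None, :, :])[0, 0]
        brown = _is_brown(hsv, cfg.darkness_threshold, cfg.brown_hue_range, cfg.brown_saturation_min)
        dab = tissue.copy() if brown else np.zeros_like(tissue)
        return StainMask(dab, tissue, float(dab.sum() / tissue.sum()), k_used=1)

    if cfg.k is not None:
        k = cfg.k
    else:
        k, _ = select_k(tile, cfg.k_range, seed=cfg.seed,
                        color_space=cfg.color_space, mask=tissue)
    clustering = cluster_colors(
        tile, k, seed=cfg.seed, color_space=cfg.color_space,
        max_iter=cfg.max_iter, tol=cfg.tol, fit_sample=cfg.fit_max_pixels,
        fit_mask=tissue,
    )
    brown_idx = identify_brown_clusters(
        clustering, cfg.darkness_threshold, cfg.brown_hue_range, cfg.brown_saturation_min
    )
    dab = np.isin(clustering.labels, sorted(brown_idx)) & tissue
    frac = float(dab.sum() / tissue.sum()) if tissue.any() else 0.0
    return StainMask(dab, tissue, frac, k_used=k)
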