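"""Rigid registration of adjacent sections and conditional heatmap fusion.

Adjacent paraffin sections differ mostly by slide placement, so alignment
is rigid: translation by phase correlation on downsampled grayscale,
rotation by a coarse-to-fine grid search maximizing normalized
cross-correlation.  Fusion then compares the two markers' binarized
patch grids: patches high in both render red (concordant), high in
exactly one render white (discordant), low in both stay turquoise.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from skimage import color as skcolor
from skimage.registration import phase_cross_correlation
from skimage.transform import downscale_local_mean

from .heatmap import BACKGROUND_RGB, RED, TURQUOISE, IntensityGrid
from .types import ParameterError, RgbTile, RigidTransform, warp_image

WHITE = np.array([255, 255, 255], dtype=np.uint8)

#: NCC below this flags the estimated transform as low-confidence; two
#: sections stained for different markers correlate weakly even when
#: perfectly aligned, so the floor is deliberately permissive.
SCORE_FLOOR = 0.1


class FusionClass(enum.IntEnum):
    BACKGROUND = 0
    CONCORDANT_LOW = 1
    CONCORDANT_HIGH = 2
    DISCORDANT = 3


FUSION_COLORS = {
    FusionClass.BACKGROUND: BACKGROUND_RGB,
    FusionClass.CONCORDANT_LOW: TURQUOISE,
    FusionClass.CONCORDANT_HIGH: RED,
    FusionClass.DISCORDANT: WHITE,
}


@dataclass
class FusionMap:
    """Per-patch concordance classes and their rendered RGB form."""

    classes: np.ndarray  # Hp x Wp of FusionClass values
    rendered: np.ndarray  # Hp x Wp x 3 uint8
    high_threshold: float

    def counts(self) -> dict[str, int]:
        return {c.name.lower(): int((self.classes == c).sum()) for c in FusionClass}


# ---------------------------------------------------------------------------
# registration


def _ncc(a: np.ndarray, b: np.ndarray, valid: np.ndarray) -> float:
    av, bv = a[valid], b[valid]
    if len(av) < 16:
        return -1.0
    av = av - av.mean()
    bv = bv - bv.mean()
    denom = np.sqrt((av**2).sum() * (bv**2).sum())
    return float((av * bv).sum() / denom) if denom > 0 else -1.0


def _gray(tile: RgbTile) -> np.ndarray:
    return skcolor.rgb2gray(tile.as_float())


def _translation_at_rotation(
    ref: np.ndarray, mov: np.ndarray, rot_deg: float, upsample: int
) -> RigidTransform:
    """Estimate translation given a candidate rotation, on one scale.

    Un-rotates the moving image about its centre, phase-correlates, and
    converts the recovered shift of the un-rotated image back into the
    translation component of the forward transform.
    """
    if rot_deg != 0.0:
        mov_unrot = warp_image(mov, RigidTransform(rotation=-rot_deg), order=1)
    else:
        mov_unrot = mov
    shift, _, _ = phase_cross_correlation(ref, mov_unrot, upsample_factor=upsample)
    # shift is (row, col) taking mov_unrot onto ref; the forward transform
    # moved content by s = -shift (xy), and t = R(theta) @ s.
    s = np.array([-shift[1], -shift[0]])
    th = np.radians(rot_deg)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    t = rot @ s
    return RigidTransform(dx=float(t[0]), dy=float(t[1]), rotation=rot_deg)


def _score_transform(ref: np.ndarray, mov: np.ndarray, tf: RigidTransform) -> float:
    """NCC between ref and mov brought back into ref's frame."""
    back = warp_image(mov, tf.inverse(), order=1, cval=np.nan)
    valid = ~np.isnan(back)
    return _ncc(ref, np.nan_to_num(back), valid)


def register_pair(
    tile_a: RgbTile,
    tile_b: RgbTile,
    rotation_range: float = 4.0,
    coarse_step: float = 0.5,
    fine_step: float = 0.1,
    max_dim: int = 256,
) -> RigidTransform:
    """Estimate the rigid transform mapping tile A's frame onto tile B's.

    Phase correlation on downsampled grayscale recovers translation for
    each candidate rotation; the rotation grid is searched coarse-to-fine
    by normalized cross-correlation, then translation is refined at full
    resolution with subpixel precision.  The returned transform follows
    the generator's convention (apply it to A to obtain B); a score below
    the confidence floor sets ``low_confidence`` rather than raising.
    """
    ha, wa = tile_a.shape
    hb, wb = tile_b.shape
    if abs(ha - hb) > 0.1 * ha or abs(wa - wb) > 0.1 * wa:
        raise ParameterError("tiles must share dimensions within 10%")

    ga, gb = _gray(tile_a), _gray(tile_b)
    factor = max(1, int(np.ceil(max(ha, wa) / max_dim)))
    ga_ds = downscale_local_mean(ga, (factor, factor))
    gb_ds = downscale_local_mean(gb, (factor, factor))

    def search(angles: np.ndarray) -> tuple[float, float]:
        best = (-np.inf, 0.0)
        for ang in angles:
            tf = _translation_at_rotation(ga_ds, gb_ds, ang, upsample=4)
            sc = _score_transform(ga_ds, gb_ds, tf)
            if sc > best[0]:
                best = (sc, ang)
        return best

    if rotation_range > 0:
        _, best_ang = search(np.arange(-rotation_range, rotation_range + 1e-9, coarse_step))
        lo = best_ang - coarse_step
        hi = best_ang + coarse_step
        _, best_ang = search(np.arange(lo, hi + 1e-9, fine_step))
    else:
        best_ang = 0.0

    # full-resolution subpixel translation at the chosen rotation
    tf_full = _translation_at_rotation(ga, gb, best_ang, upsample=20)
    score = _score_transform(ga_ds, gb_ds, tf_full)
    tf_full.score = score
    tf_full.low_confidence = score < SCORE_FLOOR
    return tf_full


# ---------------------------------------------------------------------------
# grid alignment and fusion


def resample_grid(grid_b: IntensityGrid, transform: RigidTransform, tile_shape: tuple[int, int]) -> IntensityGrid:
    """Resample grid B onto A's patch grid under the section transform.

    Each A-patch centre is mapped forward into B's frame and the nearest
    B patch supplies its value (nearest-neighbour keeps classes crisp).
    Patches landing outside B become background.
    """
    ps = grid_b.patch_size
    hp, wp = grid_b.shape
    ii, jj = np.mgrid[0:hp, 0:wp]
    cx = (jj + 0.5) * ps
    cy = (ii + 0.5) * ps
    pts = np.column_stack([cx.ravel(), cy.ravel()])
    moved = transform.apply_points(pts, tile_shape)
    jb = np.floor(moved[:, 0] / ps).astype(int).reshape(hp, wp)
    ib = np.floor(moved[:, 1] / ps).astype(int).reshape(hp, wp)
    valid = (ib >= 0) & (ib < hp) & (jb >= 0) & (jb < wp)

    values = np.full((hp, wp), np.nan)
    tissue = np.zeros((hp, wp))
    values[valid] = grid_b.values[ib[valid], jb[valid]]
    tissue[valid] = grid_b.tissue_fraction[ib[valid], jb[valid]]
    return IntensityGrid(
        values=values,
        patch_size=ps,
        tissue_fraction=tissue,
        value_range=grid_b.value_range,
    )


def binarize_grid(grid: IntensityGrid, high_threshold: float = 0.75) -> np.ndarray:
    """High-expression patches: value at/above the per-grid quantile.

    The quantile is taken over tissue patches only; background patches
    are never high, and neither are patches with zero signal — an
    all-zero grid has no high expression anywhere.  Ties at the
    threshold are included.
    """
    if not 0.0 < high_threshold < 1.0:
        raise ParameterError("high_threshold must lie in (0, 1)")
    tv = grid.tissue_values()
    out = np.zeros(grid.shape, dtype=bool)
    if len(tv) == 0:
        return out
    thr = np.quantile(tv, high_threshold)
    with np.errstate(invalid="ignore"):
        out = np.where(
            np.isnan(grid.values), False, (grid.values >= thr) & (grid.values > 0)
        )
    return out


def render_fusion(classes: np.ndarray) -> np.ndarray:
    rgb = np.zeros((*classes.shape, 3), dtype=np.uint8)
    for cls, col in FUSION_COLORS.items():
        rgb[classes == cls] = col
    return rgb


def fuse_heatmaps(
    grid_a: IntensityGrid,
    grid_b_aligned: IntensityGrid,
    high_threshold: float = 0.75,
) -> FusionMap:
    """Conditional fusion of two aligned patch grids.

    Both markers high -> concordant (red); exactly one high -> discordant
    (white); both low -> concordant-low (turquoise); any patch lacking
    tissue in either grid -> background.  The rule is symmetric in the
    two grids.
    """
    if grid_a.shape != grid_b_aligned.shape:
        raise ParameterError("grids must share shape; resample B onto A first")
    high_a = binarize_grid(grid_a, high_threshold)
    high_b = binarize_grid(grid_b_aligned, high_threshold)
    background = grid_a.background | grid_b_aligned.background

    classes = np.full(grid_a.shape, int(FusionClass.CONCORDANT_LOW), dtype=np.int8)
    classes[high_a & high_b] = int(FusionClass.CONCORDANT_HIGH)
    classes[high_a ^ high_b] = int(FusionClass.DISCORDANT)
    classes[background] = int(FusionClass.BACKGROUND)
    return FusionMap(
        classes=classes, rendered=render_fusion(classes), high_threshold=high_threshold
    )
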