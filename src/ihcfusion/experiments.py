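"""Recovery experiments on ground-truthed synthetic tiles.

Each function plants a known quantity with the synthetic generator, runs
the analysis, and measures how well it was recovered.  These are the
computations behind the analysis drivers and the acceptance script; the
test suite exercises the same functions at its own problem sizes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .config import PipelineConfig, default_demo_config
from .extraction import ExtractionConfig, extract_brown_mask, select_k
from .fusion import fuse_heatmaps, register_pair, resample_grid
from .heatmap import aggregate_patch_intensity
from .pipeline import run_pipeline, strip_timestamps
from .stats import heatmap_correlation, region_summary
from .synthetic import MarkerStainModel, TissueModel, generate_tile, generate_tile_pair
from .types import RgbTile, RigidTransform


def dab_fraction_recovery(
    fraction: float, n_seeds: int, tile_size: int = 1024, seed0: int = 0
) -> dict:
    """Plant a DAB area fraction as diffuse deposition and re-estimate it.

    Returns per-seed absolute errors |estimated - true positive fraction|
    and their median.  Truth is read from the generator's own masks, so a
    generator that misses its nominal target is still scored fairly.
    """
    errors, estimates, truths = [], [], []
    for i in range(n_seeds):
        tm = TissueModel(
            tile_size=tile_size, necrosis_fraction=0.0, glass_fraction=0.1,
            cell_density=1.5, rng_seed=seed0 + i,
        )
        marker = MarkerStainModel(
            marker_name="M", cellular_fraction=0.0, diffuse_in_tissue=fraction
        )
        tile, truth = generate_tile(tm, marker)
        true_frac = truth.dab_mask_per_marker["M"].sum() / truth.tissue_mask.sum()
        sm = extract_brown_mask(tile, ExtractionConfig(seed=seed0 + i))
        errors.append(abs(sm.positive_fraction - true_frac))
        estimates.append(sm.positive_fraction)
        truths.append(float(true_frac))
    return {
        "fraction": fraction,
        "errors": errors,
        "median_abs_error": float(np.median(errors)),
        "estimates": estimates,
        "truths": truths,
    }


def _planted_color_tile(
    n_colors: int, seed: int, tile_size: int = 256, noise_sigma: float = 6.0
) -> RgbTile:
    """Tile of n well-separated colors in random blobs plus RGB noise."""
    palette = np.array(
        [[245, 245, 245], [110, 70, 40], [70, 70, 160], [200, 60, 60]], dtype=float
    )[:n_colors]
    rng = np.random.default_rng(seed)
    from scipy import ndimage

    fields = np.stack(
        [ndimage.gaussian_filter(rng.standard_normal((tile_size, tile_size)), tile_size / 8)
         for _ in range(n_colors)]
    )
    labels = np.argmax(fields, axis=0)
    img = palette[labels] + rng.normal(0, noise_sigma, (tile_size, tile_size, 3))
    return RgbTile(np.clip(np.round(img), 0, 255).astype(np.uint8))


def k_selection_accuracy(
    n_colors: int, n_seeds: int, seed0: int = 0, tile_size: int = 256
) -> dict:
    """How often the silhouette criterion recovers the planted color count."""
    chosen = []
    for i in range(n_seeds):
        tile = _planted_color_tile(n_colors, seed0 + i, tile_size)
        k, _ = select_k(tile, (2, 6), seed=seed0 + i)
        chosen.append(k)
    return {
        "planted_k": n_colors,
        "chosen": chosen,
        "n_correct": int(sum(k == n_colors for k in chosen)),
        "n_seeds": n_seeds,
    }


def _standard_pair(seed: int, tile_size: int, transform: RigidTransform):
    tm = TissueModel(
        tile_size=tile_size, necrosis_fraction=0.25, glass_fraction=0.1,
        cell_density=1.5, rng_seed=seed,
    )
    ma = MarkerStainModel(marker_name="IBA1", cellular_fraction=0.6, rim_intensity=0.5)
    mb = MarkerStainModel(
        marker_name="CD163", cellular_fraction=0.15, diffuse_in_necrosis=0.6,
        rim_intensity=0.1,
    )
    return generate_tile_pair(tm, ma, mb, transform)


def registration_recovery(
    n_seeds: int, seed0: int = 0, tile_size: int = 512,
    shift_range: float = 20.0, rot_range: float = 3.0,
) -> dict:
    """Recover planted rigid transforms; report worst-case errors."""
    rng = np.random.default_rng(seed0)
    shift_errs, rot_errs = [], []
    for i in range(n_seeds):
        dx, dy = rng.uniform(-shift_range, shift_range, 2)
        rot = rng.uniform(-rot_range, rot_range)
        planted = RigidTransform(dx=float(dx), dy=float(dy), rotation=float(rot))
        tile_a, tile_b, _ = _standard_pair(seed0 + i, tile_size, planted)
        est = register_pair(tile_a, tile_b)
        shift_errs.append(max(abs(est.dx - dx), abs(est.dy - dy)))
        rot_errs.append(abs(est.rotation - rot))
    return {
        "max_shift_error_px": float(max(shift_errs)),
        "max_rotation_error_deg": float(max(rot_errs)),
        "shift_errors": shift_errs,
        "rotation_errors": rot_errs,
    }


def fusion_overlap_recovery(seed: int = 0, tile_size: int = 1024) -> dict:
    """Plant two hotspot regions with Jaccard overlap 0.5 and fuse.

    Marker A deposits in X u Y, marker B in Y u Z, with |X| = |Z| = |Y|/2,
    so the planted overlap |AnB| / |AuB| is exactly one half and the fused
    map's concordant-high share among high patches should recover 0.50.
    """
    size = tile_size
    y_region = np.zeros((size, size), dtype=bool)
    x_region = np.zeros_like(y_region)
    z_region = np.zeros_like(y_region)
    # rectangles on patch-aligned bounds; |X| = |Z| = |Y|/2
    s = size // 1024 if size >= 1024 else 1
    y_region[size // 4 : size // 4 + 192 * s, size // 4 : size // 4 + 384 * s] = True
    x_region[size // 16 : size // 16 + 96 * s, size // 4 : size // 4 + 384 * s] = True
    z_region[size - 160 * s : size - 64 * s, size // 4 : size // 4 + 384 * s] = True

    tm = TissueModel(
        tile_size=size, necrosis_fraction=0.0, glass_fraction=0.0,
        cell_density=1.5, rng_seed=seed,
    )
    ma = MarkerStainModel(marker_name="A", cellular_fraction=0.0,
                          diffuse_region=x_region | y_region)
    mb = MarkerStainModel(marker_name="B", cellular_fraction=0.0,
                          diffuse_region=y_region | z_region)
    # patch-aligned section offset: isolates the fusion semantics from
    # patch-grid quantization of the planted regions' boundaries
    planted = RigidTransform(dx=16.0, dy=-16.0, rotation=0.0)
    tile_a, tile_b, truth = generate_tile_pair(tm, ma, mb, planted)

    cfg = ExtractionConfig(seed=seed)
    grid_a = aggregate_patch_intensity(tile_a, extract_brown_mask(tile_a, cfg))
    grid_b = aggregate_patch_intensity(tile_b, extract_brown_mask(tile_b, cfg))
    est = register_pair(tile_a, tile_b)
    aligned = resample_grid(grid_b, est, tile_a.shape)

    region_frac = (x_region | y_region).sum() / truth.tissue_mask.sum()
    fmap = fuse_heatmaps(grid_a, aligned, high_threshold=1.0 - float(region_frac))
    counts = fmap.counts()
    ch, disc = counts["concordant_high"], counts["discordant"]
    share = ch / (ch + disc) if (ch + disc) else float("nan")
    return {"concordant_high_share": float(share), "counts": counts}


def correlation_recovery(rho: float = 0.8, n_patches: int = 4096, seed: int = 0) -> dict:
    """Simulate bivariate-correlated patch intensity fields and re-estimate rho."""
    rng = np.random.default_rng(seed)
    side = int(np.sqrt(n_patches))
    z1 = rng.standard_normal((side, side))
    z2 = rho * z1 + np.sqrt(1 - rho**2) * rng.standard_normal((side, side))

    def to_grid(z):
        v = (z - z.min()) / (z.max() - z.min())
        from .heatmap import IntensityGrid

        return IntensityGrid(values=v, patch_size=16,
                             tissue_fraction=np.ones_like(v), value_range=(0.0, 1.0))

    rep = heatmap_correlation(to_grid(z1), to_grid(z2))
    return {"planted_rho": rho, "pearson_r": rep.pearson_r,
            "spearman_rho": rep.spearman_rho, "n_patches": rep.n_patches}


def necrosis_direction(n_seeds: int, seed0: int = 0, tile_size: int = 512) -> dict:
    """The headline contrast: diffuse marker B exceeds cellular marker A in
    necrosis while A at least matches B in viable hypercellular tissue."""
    nec_ok = via_ok = 0
    diffs = []
    for i in range(n_seeds):
        planted = RigidTransform(dx=6.0, dy=-4.0, rotation=1.0)
        tile_a, tile_b, truth = _standard_pair(seed0 + i, tile_size, planted)
        cfg = ExtractionConfig(seed=seed0 + i)
        grid_a = aggregate_patch_intensity(tile_a, extract_brown_mask(tile_a, cfg))
        grid_b = aggregate_patch_intensity(tile_b, extract_brown_mask(tile_b, cfg))
        est = register_pair(tile_a, tile_b)
        aligned = resample_grid(grid_b, est, tile_a.shape)
        regions = {
            "necrosis": truth.necrosis_mask,
            "palisade": truth.palisade_mask,
            "viable": truth.tissue_mask & ~truth.necrosis_mask & ~truth.palisade_mask,
        }
        tab = region_summary(grid_a, aligned, regions).set_index("region")
        nec = tab.loc["necrosis", "diff_b_minus_a"]
        via = tab.loc["viable", "diff_b_minus_a"]
        nec_ok += int(nec > 0)
        via_ok += int(via <= 0)
        diffs.append({"necrosis": float(nec), "viable": float(via)})
    return {"n_seeds": n_seeds, "necrosis_b_gt_a": nec_ok,
            "viable_a_ge_b": via_ok, "diffs": diffs}


def identical_marker_discordance(
    seed: int = 0, tile_size: int = 512, section_resample: float = 0.05
) -> dict:
    """Noise floor of the fusion map: same stain model on both sections,
    identity placement — discordance then reflects only section-to-section
    cell resampling (set ``section_resample=0`` for pure chromogen noise)."""
    tm = TissueModel(
        tile_size=tile_size, necrosis_fraction=0.25, glass_fraction=0.1,
        cell_density=1.5, section_resample=section_resample, rng_seed=seed,
    )
    kw = dict(cellular_fraction=0.5, diffuse_in_necrosis=0.4, rim_intensity=0.4)
    tile_a, tile_b, _ = generate_tile_pair(
        tm,
        MarkerStainModel(marker_name="A", **kw),
        MarkerStainModel(marker_name="B", **kw),
        RigidTransform(),
    )
    cfg = ExtractionConfig(seed=seed)
    grid_a = aggregate_patch_intensity(tile_a, extract_brown_mask(tile_a, cfg))
    grid_b = aggregate_patch_intensity(tile_b, extract_brown_mask(tile_b, cfg))
    est = register_pair(tile_a, tile_b)
    aligned = resample_grid(grid_b, est, tile_a.shape)
    fmap = fuse_heatmaps(grid_a, aligned)
    counts = fmap.counts()
    tissue_patches = sum(v for k, v in counts.items() if k != "background")
    return {
        "discordant_fraction": counts["discordant"] / tissue_patches,
        "counts": counts,
    }


def pipeline_determinism(out_root: str | Path, seed: int = 0, tile_size: int = 512) -> dict:
    """Run the demo pipeline twice; compare rasters and manifests."""
    import imageio.v3 as iio

    cfg = default_demo_config()
    cfg.seed = seed
    cfg.simulate.tile_size = tile_size
    out_root = Path(out_root)
    m1 = run_pipeline(cfg, out_root / "run1")
    m2 = run_pipeline(cfg, out_root / "run2")
    rasters_equal = True
    for p1 in sorted((out_root / "run1").glob("*.png")):
        p2 = out_root / "run2" / p1.name
        if not np.array_equal(iio.imread(p1), iio.imread(p2)):
            rasters_equal = False
    s1 = json.dumps(strip_timestamps(m1)).replace("run1", "runX")
    s2 = json.dumps(strip_timestamps(m2)).replace("run2", "runX")
    return {"rasters_identical": rasters_equal, "manifests_identical": s1 == s2}
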