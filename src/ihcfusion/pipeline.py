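"""End-to-end orchestration: simulate -> extract -> heatmap -> fuse -> stats.

Each run writes every artifact under an output directory plus a manifest
JSON recording the package version, seeds, configuration hash, chosen
parameters (including the automatically selected k per tile — a result in
its own right), and the paths of every file written.  Runs are idempotent
for a fixed seed: re-running yields bitwise-identical rasters and an
identical manifest apart from timestamps.
"""

from __future__ import annotations

import logging
import sys
import time
from pathlib import Path

from . import __version__, io
from .config import PipelineConfig
from .extraction import extract_brown_mask
from .fusion import fuse_heatmaps, register_pair, resample_grid
from .heatmap import aggregate_patch_intensity, render_heatmap
from .stats import compare_markers
from .synthetic import generate_tile_pair
from .types import StageError

log = logging.getLogger("ihcfusion")

TIMESTAMP_KEYS = {"started_at", "finished_at", "elapsed_s"}


def _setup_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    if not any(isinstance(h, logging.StreamHandler) for h in log.handlers):
        log.addHandler(logging.StreamHandler(sys.stderr))
    log.setLevel(logging.INFO)
    return handler


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute the full analysis and return the manifest dictionary.

    Stages run in order; a failure halts the run with a stage-tagged
    error, leaving partial outputs and a failure marker in the manifest.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = _setup_logging(out)
    manifest: dict = {
        "package_version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "started_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
    }
    (out / "config.json").write_text(config.to_json())
    manifest["config_path"] = str(out / "config.json")

    stage = "simulate"
    try:
        t0 = time.time()
        if config.input_a and config.input_b:
            tile_a = io.read_tile(config.input_a, marker_name="A")
            tile_b = io.read_tile(config.input_b, marker_name="B")
            truth = None
            outputs: list[Path] = []
        elif config.simulate is not None:
            sim = config.simulate
            tissue = sim.to_tissue_model(config.seed)
            tile_a, tile_b, truth = generate_tile_pair(
                tissue,
                sim.marker_a.to_model(),
                sim.marker_b.to_model(),
                sim.transform.to_transform(),
            )
            outputs = [
                io.write_tile(out / f"tile_{tile_a.marker_name}.png", tile_a),
                io.write_tile(out / f"tile_{tile_b.marker_name}.png", tile_b),
            ]
            outputs += list(io.write_ground_truth(out / "truth", truth,
                                                  config.model_dump(mode="json")["simulate"]))
        else:
            raise FileNotFoundError("no inputs: set input_a/input_b or a simulate section")
        _record(manifest, stage, outputs, t0)
        log.info("simulate: tiles %s / %s", tile_a.marker_name, tile_b.marker_name)

        stage = "extract"
        t0 = time.time()
        ecfg = config.extract.to_extraction_config(config.seed)
        mask_a = extract_brown_mask(tile_a, ecfg)
        mask_b = extract_brown_mask(tile_b, ecfg)
        outputs = [
            io.write_mask(out / f"dab_{tile_a.marker_name}.png", mask_a.dab_mask),
            io.write_mask(out / f"dab_{tile_b.marker_name}.png", mask_b.dab_mask),
            io.write_mask(out / f"tissue_{tile_a.marker_name}.png", mask_a.tissue_mask),
            io.write_mask(out / f"tissue_{tile_b.marker_name}.png", mask_b.tissue_mask),
        ]
        import pandas as pd

        metrics = pd.DataFrame(
            [
                {"tile": tile_a.marker_name, "k": mask_a.k_used,
                 "positive_fraction": mask_a.positive_fraction,
                 "darkness_threshold": ecfg.darkness_threshold},
                {"tile": tile_b.marker_name, "k": mask_b.k_used,
                 "positive_fraction": mask_b.positive_fraction,
                 "darkness_threshold": ecfg.darkness_threshold},
            ]
        )
        metrics.to_csv(out / "extraction_metrics.csv", index=False)
        outputs.append(out / "extraction_metrics.csv")
        _record(manifest, stage, outputs, t0,
                extra={"k_a": mask_a.k_used, "k_b": mask_b.k_used,
                       "positive_fraction_a": mask_a.positive_fraction,
                       "positive_fraction_b": mask_b.positive_fraction})
        log.info("extract: k=%s/%s positive=%.4f/%.4f", mask_a.k_used, mask_b.k_used,
                 mask_a.positive_fraction, mask_b.positive_fraction)

        stage = "heatmap"
        t0 = time.time()
        ps = config.heatmap.patch_size
        grid_a = aggregate_patch_intensity(tile_a, mask_a, ps)
        grid_b = aggregate_patch_intensity(tile_b, mask_b, ps)
        outputs = io.write_grid(out, grid_a, f"heatmap_{tile_a.marker_name}")
        outputs += io.write_grid(out, grid_b, f"heatmap_{tile_b.marker_name}")
        outputs.append(io.write_rgb(out / f"heatmap_{tile_a.marker_name}.png",
                                    render_heatmap(grid_a).rgb))
        outputs.append(io.write_rgb(out / f"heatmap_{tile_b.marker_name}.png",
                                    render_heatmap(grid_b).rgb))
        _record(manifest, stage, outputs, t0)

        stage = "fuse"
        t0 = time.time()
        transform = register_pair(tile_a, tile_b,
                                  rotation_range=config.fusion.rotation_range)
        grid_b_aligned = resample_grid(grid_b, transform, tile_a.shape)
        fmap = fuse_heatmaps(grid_a, grid_b_aligned, config.fusion.high_threshold)
        outputs = [io.write_transform(out / "transform.json", transform)]
        outputs += io.write_grid(out, grid_b_aligned, "heatmap_b_aligned")
        import numpy as np
        import pandas as pd

        hp, wp = fmap.classes.shape
        ii, jj = np.mgrid[0:hp, 0:wp]
        pd.DataFrame({"row": ii.ravel(), "col": jj.ravel(),
                      "class": fmap.classes.ravel()}).to_csv(out / "fusion_classes.csv",
                                                             index=False)
        outputs.append(out / "fusion_classes.csv")
        outputs.append(io.write_rgb(out / "fusion.png", fmap.rendered))
        _record(manifest, stage, outputs, t0,
                extra={"transform": transform.to_dict(), "counts": fmap.counts()})
        log.info("fuse: transform %s counts %s", transform.to_dict(), fmap.counts())

        stage = "stats"
        t0 = time.time()
        regions = None
        if truth is not None:
            regions = {
                "necrosis": truth.necrosis_mask,
                "palisade": truth.palisade_mask,
                "viable": truth.tissue_mask & ~truth.necrosis_mask & ~truth.palisade_mask,
            }
        report = compare_markers(grid_a, grid_b_aligned, regions,
                                 config.fusion.high_threshold)
        outputs = [io.write_json(out / "correlation_report.json", report.to_dict())]
        if report.by_region is not None:
            report.by_region.to_csv(out / "region_summary.csv", index=False,
                                    float_format="%.6g")
            outputs.append(out / "region_summary.csv")
        _record(manifest, stage, outputs, t0,
                extra={"pearson_r": None if report.pearson_r != report.pearson_r
                       else report.pearson_r,
                       "n_patches": report.n_patches})
        log.info("stats: r=%s over %d patches", report.pearson_r, report.n_patches)

    except Exception as exc:
        manifest["stages"].setdefault(stage, {})["status"] = "failed"
        manifest["stages"][stage]["error"] = str(exc)
        manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
        io.write_json(out / "manifest.json", manifest)
        log.removeHandler(handler)
        handler.close()
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, str(exc)) from exc

    manifest["finished_at"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    manifest["run_log"] = str(out / "run.log")
    io.write_json(out / "manifest.json", manifest)
    log.removeHandler(handler)
    handler.close()
    return manifest


def _record(manifest: dict, stage: str, outputs: list[Path], t0: float,
            extra: dict | None = None) -> None:
    entry = {
        "status": "ok",
        "outputs": sorted(str(p) for p in outputs),
        "elapsed_s": round(time.time() - t0, 3),
    }
    if extra:
        entry.update(extra)
    manifest["stages"][stage] = entry


def strip_timestamps(manifest: dict) -> dict:
    """Manifest with volatile timing fields removed, for comparisons."""
    out = {k: v for k, v in manifest.items() if k not in TIMESTAMP_KEYS}
    out["stages"] = {
        s: {k: v for k, v in entry.items() if k not in TIMESTAMP_KEYS}
        for s, entry in manifest.get("stages", {}).items()
    }
    return out
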