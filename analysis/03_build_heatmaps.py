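"""Patch-intensity heatmaps (16x16 px patches, turquoise -> red scale).

Per patch: mean chromogen darkness over DAB-positive pixels, normalized
by the tile maximum.  Writes grids (CSV + float TIFF) and rendered PNGs
to results/heatmaps/.
"""

import argparse
from pathlib import Path

import numpy as np

from ihcfusion import io
from ihcfusion.config import PipelineConfig
from ihcfusion.extraction import StainMask
from ihcfusion.heatmap import aggregate_patch_intensity, render_heatmap


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--tiles", type=Path, default=Path("results/tiles"))
    ap.add_argument("--masks", type=Path, default=Path("results/extract"))
    ap.add_argument("--out", type=Path, default=Path("results/heatmaps"))
    args = ap.parse_args()

    cfg = PipelineConfig.from_file(args.tiles / "config.json")
    args.out.mkdir(parents=True, exist_ok=True)
    for marker in (cfg.simulate.marker_a.name, cfg.simulate.marker_b.name):
        tile = io.read_tile(args.tiles / f"tile_{marker}.png", marker_name=marker)
        dab = io.read_mask(args.masks / f"dab_{marker}.png")
        tissue = io.read_mask(args.masks / f"tissue_{marker}.png")
        sm = StainMask(dab & tissue, tissue, float(dab.sum() / tissue.sum()))
        grid = aggregate_patch_intensity(tile, sm, cfg.heatmap.patch_size)
        io.write_grid(args.out, grid, f"heatmap_{marker}")
        io.write_rgb(args.out / f"heatmap_{marker}.png", render_heatmap(grid).rgb)
        tv = grid.tissue_values()
        print(f"{marker:6s} grid {grid.shape[0]}x{grid.shape[1]}  "
              f"raw max {grid.value_range[1]:.4f}  "
              f"mean {np.mean(tv):.4f}  hot(>=0.75q) {np.mean(tv >= np.quantile(tv, 0.75)):.3f}")


if __name__ == "__main__":
    main()
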