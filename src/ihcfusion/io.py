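"""Reading and writing of the pipeline's raster and tabular artifacts.

Rasters travel as PNG/TIFF (tifffile/imageio), patch grids as CSV plus
float TIFF with a JSON sidecar, transforms and reports as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .heatmap import IntensityGrid
from .types import RgbTile, RigidTransform


def write_tile(path: str | Path, tile: RgbTile) -> Path:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, tile.pixels, photometric="rgb")
    else:
        iio.imwrite(path, tile.pixels)
    return path


def read_tile(path: str | Path, marker_name: str | None = None) -> RgbTile:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    if px.ndim == 3 and px.shape[2] == 4:  # drop alpha
        px = px[..., :3]
    return RgbTile(np.asarray(px, dtype=np.uint8), marker_name=marker_name)


def write_mask(path: str | Path, mask: np.ndarray) -> Path:
    path = Path(path)
    img = (mask.astype(np.uint8)) * 255
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, img)
    else:
        iio.imwrite(path, img)
    return path


def read_mask(path: str | Path) -> np.ndarray:
    path = Path(path)
    img = tifffile.imread(path) if path.suffix.lower() in (".tif", ".tiff") else iio.imread(path)
    if img.ndim == 3:
        img = img[..., 0]
    return img > 127


def write_ground_truth(dir_path: str | Path, truth, config: dict | None = None) -> tuple[Path, Path]:
    """Ground truth as one multi-page boolean-mask TIFF + JSON sidecar.

    The sidecar lists each page's role, the inter-section transform, and
    the generator configuration, so the truth is self-describing.
    """
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    pages: list[tuple[str, np.ndarray]] = [
        ("tissue_mask", truth.tissue_mask),
        ("necrosis_mask", truth.necrosis_mask),
        ("palisade_mask", truth.palisade_mask),
        ("tissue_mask_b", truth.tissue_mask_b),
        ("necrosis_mask_b", truth.necrosis_mask_b),
        ("palisade_mask_b", truth.palisade_mask_b),
    ]
    for name, mask in truth.dab_mask_per_marker.items():
        pages.append((f"dab_mask_{name}", mask))
    tiff_path = dir_path / "ground_truth.tif"
    tifffile.imwrite(tiff_path, np.stack([m.astype(np.uint8) * 255 for _, m in pages]))
    sidecar = {
        "pages": [name for name, _ in pages],
        "intersection_transform": truth.intersection_transform.to_dict(),
        "cell_counts": truth.cell_counts,
        "config": config,
    }
    json_path = dir_path / "ground_truth.json"
    json_path.write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return tiff_path, json_path


def grid_to_frame(grid: IntensityGrid) -> pd.DataFrame:
    hp, wp = grid.shape
    ii, jj = np.mgrid[0:hp, 0:wp]
    return pd.DataFrame(
        {
            "row": ii.ravel(),
            "col": jj.ravel(),
            "value": grid.values.ravel(),
            "tissue_fraction": grid.tissue_fraction.ravel(),
        }
    )


def write_grid(dir_path: str | Path, grid: IntensityGrid, stem: str) -> list[Path]:
    """Grid as CSV + float32 TIFF + JSON sidecar with the value range."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    csv_path = dir_path / f"{stem}.csv"
    grid_to_frame(grid).to_csv(csv_path, index=False, float_format="%.6g")
    tif_path = dir_path / f"{stem}.tif"
    tifffile.imwrite(tif_path, grid.values.astype(np.float32))
    meta_path = dir_path / f"{stem}.json"
    meta_path.write_text(
        json.dumps(
            {
                "patch_size": grid.patch_size,
                "value_range": list(grid.value_range),
                "shape": list(grid.shape),
            },
            indent=2,
        )
    )
    return [csv_path, tif_path, meta_path]


def read_grid(dir_path: str | Path, stem: str) -> IntensityGrid:
    dir_path = Path(dir_path)
    meta = json.loads((dir_path / f"{stem}.json").read_text())
    values = tifffile.imread(dir_path / f"{stem}.tif").astype(np.float64)
    frame = pd.read_csv(dir_path / f"{stem}.csv")
    hp, wp = meta["shape"]
    tissue = np.zeros((hp, wp))
    tissue[frame["row"], frame["col"]] = frame["tissue_fraction"]
    return IntensityGrid(
        values=values,
        patch_size=int(meta["patch_size"]),
        tissue_fraction=tissue,
        value_range=tuple(meta["value_range"]),
    )


def write_rgb(path: str | Path, rgb: np.ndarray) -> Path:
    path = Path(path)
    iio.imwrite(path, rgb)
    return path


def write_transform(path: str | Path, transform: RigidTransform) -> Path:
    path = Path(path)
    path.write_text(json.dumps(transform.to_dict(), indent=2))
    return path


def read_transform(path: str | Path) -> RigidTransform:
    return RigidTransform.from_dict(json.loads(Path(path).read_text()))


def write_json(path: str | Path, obj: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default))
    return path


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
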