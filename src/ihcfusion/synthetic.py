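"""Ground-truthed synthetic brightfield IHC tiles.

Generates pairs of pseudo-adjacent tissue sections immunostained for two
microglia/macrophage markers, with the staining geometries seen in
glioblastoma: hematoxylin-counterstained nucleated tissue, DAB chromogen
deposited on cell somata and processes (IBA1-like cellular labeling),
diffuse extracellular DAB in hypocellular necrotic zones (CD163-like),
and band-like pseudopalisading rims of densely packed positive cells
around necrotic cores.  Every painted structure is recorded in a
:class:`TileGroundTruth` so downstream stages can be scored against a
recoverable truth.

Rendering follows Beer-Lambert absorbance mixing: per-pixel optical
densities for hematoxylin and DAB are combined along fixed stain color
vectors and attenuated exponentially to 8-bit RGB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as draw_line

from .types import ParameterError, RgbTile, RigidTransform, warp_image

# Stain absorbance color vectors (unit-norm RGB absorbances), in the style
# of published hematoxylin/DAB deconvolution vectors.
HEMATOXYLIN_VEC = np.array([0.651, 0.701, 0.290])
DAB_VEC = np.array([0.269, 0.568, 0.778])

#: cell density multiplier inside the pseudopalisading rim relative to
#: viable tissue (rims are hypercellular demarcation lines).
RIM_DENSITY_FACTOR = 2.5

#: fraction of cell positions resampled between adjacent sections —
#: sections share tissue structure but not the exact same cells.
SECTION_CELL_RESAMPLE = 0.05

NUCLEUS_RADIUS = 3
SOMA_RADIUS = 4
N_PROCESSES = 4
PROCESS_LENGTH = 10

HEMATOXYLIN_BASE_OD = 0.25
NUCLEUS_EXTRA_OD = 0.5
#: hematoxylin attenuation under DAB deposits — dense chromogen masks the
#: counterstain, keeping mixed pixels in the brown hue range as in real DAB.
DAB_BLOCKS_HEMATOXYLIN = 0.5


@dataclass
class TissueModel:
    """Geometry and cellularity of one synthetic tissue section.

    Parameters
    ----------
    tile_size
        Side length of the square tile in pixels (>= 128).
    necrosis_fraction
        Target necrotic area as a fraction of *tissue* area, in [0, 1].
    n_necrotic_foci
        Number of necrotic cores to keep (largest connected blobs).
    palisade_width
        Width in pixels of the hypercellular rim hugging the necrosis
        boundary on the viable side.
    cell_density
        Cells per 1000 px^2 in viable tissue.
    hypocellular_factor
        Multiplier in [0, 1] on cell density inside necrosis.
    glass_fraction
        Fraction of the tile that is bare glass (no tissue).
    od_noise_sigma
        Std-dev of Gaussian noise added to each stain's optical density.
    rng_seed
        Seed for all randomness; identical seeds give bitwise-identical
        tiles.
    """

    tile_size: int = 512
    necrosis_fraction: float = 0.25
    n_necrotic_foci: int = 1
    palisade_width: int = 12
    cell_density: float = 2.0
    hypocellular_factor: float = 0.1
    glass_fraction: float = 0.0
    od_noise_sigma: float = 0.05
    section_resample: float = SECTION_CELL_RESAMPLE
    rng_seed: int = 0

    def validate(self) -> None:
        if self.tile_size < 128:
            raise ParameterError("tile_size must be >= 128")
        for name in ("necrosis_fraction", "hypocellular_factor", "glass_fraction",
                     "section_resample"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.cell_density < 0:
            raise ParameterError("cell_density must be >= 0")
        if self.n_necrotic_foci < 1:
            raise ParameterError("n_necrotic_foci must be >= 1")


@dataclass
class MarkerStainModel:
    """How one immunomarker deposits DAB on the tissue.

    ``cellular_fraction`` is the share of viable-tissue cells whose soma
    and processes are DAB positive.  ``diffuse_in_necrosis`` is the target
    DAB coverage fraction inside the necrotic mask (extracellular
    deposition).  ``rim_intensity`` adds positivity probability and
    chromogen weight on pseudopalisading rim cells.  ``dab_od`` is the
    mean chromogen optical density of positive structures.

    ``diffuse_in_tissue`` plants blob-like extracellular deposition over
    viable tissue (large-area labeling); ``diffuse_region`` overrides the
    coverage-based diffuse placement with an explicit mask (tile-A frame)
    for scripted experiments.
    """

    marker_name: str = "marker"
    cellular_fraction: float = 0.5
    diffuse_in_necrosis: float = 0.0
    rim_intensity: float = 0.0
    dab_od: float = 1.2
    diffuse_in_tissue: float = 0.0
    diffuse_region: np.ndarray | None = None

    def validate(self) -> None:
        for name in (
            "cellular_fraction",
            "diffuse_in_necrosis",
            "rim_intensity",
            "diffuse_in_tissue",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.dab_od <= 0:
            raise ParameterError("dab_od must be > 0")


@dataclass
class CellPopulation:
    """Planted cells of one compartment.

    Besides positions and painted nucleus/soma rasters, each cell carries
    persistent attributes that survive into the adjacent section: a
    marker-affinity quantile in [0, 1) (a cell is positive for a marker
    when its affinity falls below the marker's positive fraction — the
    same cell is then positive on both sections) and its process
    morphology (angles/lengths of the radiating processes).
    """

    centers: np.ndarray  # (N, 2) as (x, y)
    nucleus_mask: np.ndarray
    soma_mask: np.ndarray
    affinity: np.ndarray = field(default_factory=lambda: np.empty(0))
    proc_angles: np.ndarray = field(default_factory=lambda: np.empty((0, N_PROCESSES)))
    proc_lengths: np.ndarray = field(default_factory=lambda: np.empty((0, N_PROCESSES)))

    @property
    def count(self) -> int:
        return len(self.centers)


@dataclass
class TileGroundTruth:
    """Everything the generator planted, for scoring downstream stages.

    Masks without suffix live in tile A's frame; ``*_b`` masks are the
    same structures after the inter-section transform (tile B's frame).
    ``dab_mask_per_marker`` maps marker name to its full DAB truth mask in
    the frame of the tile it stains (A for the first marker, B for the
    second).  ``dab_components_per_marker`` decomposes each truth mask
    into its cellular / rim / diffuse parts.
    """

    tissue_mask: np.ndarray
    necrosis_mask: np.ndarray
    palisade_mask: np.ndarray
    dab_mask_per_marker: dict[str, np.ndarray]
    dab_components_per_marker: dict[str, dict[str, np.ndarray]]
    intersection_transform: RigidTransform
    tissue_mask_b: np.ndarray
    necrosis_mask_b: np.ndarray
    palisade_mask_b: np.ndarray
    cell_counts: dict[str, int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# geometry


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Standardized low-frequency Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


def make_tissue_mask(rng: np.random.Generator, size: int, glass_fraction: float) -> np.ndarray:
    """Tissue blob occupying (1 - glass_fraction) of the tile, glass at edges."""
    if glass_fraction <= 0:
        return np.ones((size, size), dtype=bool)
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    edge = np.maximum(np.abs(xx - c), np.abs(yy - c)) / (size / 2.0)
    fld = 0.25 * _smooth_field(rng, (size, size), size / 8.0) - edge
    thr = np.quantile(fld, glass_fraction)
    return fld >= thr


def make_necrosis_mask(
    rng: np.random.Generator,
    tissue: np.ndarray,
    fraction: float,
    n_foci: int,
) -> np.ndarray:
    """Smoothed random necrotic blobs covering ``fraction`` of tissue area.

    Thresholded low-frequency noise, keeping the ``n_foci`` largest
    connected components; the threshold is found by bisection so the
    realized area matches the target closely.
    """
    size = tissue.shape[0]
    tissue_area = int(tissue.sum())
    if fraction <= 0 or tissue_area == 0:
        return np.zeros_like(tissue)
    fld = _smooth_field(rng, tissue.shape, size / 10.0)
    fld = np.where(tissue, fld, -np.inf)
    target = fraction * tissue_area

    def realized(thr: float) -> np.ndarray:
        m = fld > thr
        if not m.any():
            return m
        lab, n = ndimage.label(m)
        if n > n_foci:
            sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
            keep = np.argsort(sizes)[::-1][:n_foci] + 1
            m = np.isin(lab, keep)
        return m

    finite = fld[np.isfinite(fld)]
    lo, hi = float(finite.min()), float(finite.max())
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if realized(mid).sum() > target:
            lo = mid
        else:
            hi = mid
    mask = realized(0.5 * (lo + hi))
    return mask


def make_palisade_mask(necrosis: np.ndarray, tissue: np.ndarray, width: int) -> np.ndarray:
    """Ring of ``width`` pixels hugging the necrosis boundary, outside it."""
    if width <= 0 or not necrosis.any():
        return np.zeros_like(necrosis)
    dil = ndimage.binary_dilation(necrosis, ndimage.generate_binary_structure(2, 1), iterations=width)
    return dil & ~necrosis & tissue


# ---------------------------------------------------------------------------
# cells


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    keep = yy**2 + xx**2 <= r**2
    return yy[keep], xx[keep]


def _paint_disks(shape: tuple[int, int], centers: np.ndarray, radius: int) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    if len(centers) == 0:
        return mask
    dy, dx = _disk_offsets(radius)
    h, w = shape
    for x, y in centers:
        ys = np.round(y + dy).astype(int)
        xs = np.round(x + dx).astype(int)
        keep = (ys >= 0) & (ys < h) & (xs >= 0) & (xs < w)
        mask[ys[keep], xs[keep]] = True
    return mask


def plant_cells(
    region_mask: np.ndarray,
    density: float,
    rng: np.random.Generator,
    nucleus_radius: int = NUCLEUS_RADIUS,
    soma_radius: int = SOMA_RADIUS,
) -> CellPopulation:
    """Plant Poisson-distributed cells uniformly inside ``region_mask``.

    ``density`` is cells per 1000 px^2 of the region.  Each cell carries a
    nucleus disc and a slightly larger soma disc.  An empty region (or
    zero density) yields zero cells, not an error.
    """
    if density < 0:
        raise ParameterError("density must be >= 0")
    shape = region_mask.shape
    area = int(region_mask.sum())
    n = int(rng.poisson(density * area / 1000.0)) if area > 0 and density > 0 else 0
    if n == 0:
        empty = np.zeros(shape, dtype=bool)
        return CellPopulation(np.empty((0, 2)), empty, empty.copy())
    flat = np.flatnonzero(region_mask)
    picks = rng.choice(flat, size=n, replace=True)
    ys, xs = np.unravel_index(picks, shape)
    centers = np.column_stack([xs, ys]).astype(float)
    nucleus = _paint_disks(shape, centers, nucleus_radius)
    soma = _paint_disks(shape, centers, soma_radius)
    return CellPopulation(
        centers, nucleus, soma,
        affinity=rng.random(n),
        proc_angles=rng.uniform(0, 2 * np.pi, (n, N_PROCESSES)),
        proc_lengths=rng.uniform(0.6 * PROCESS_LENGTH, 1.4 * PROCESS_LENGTH,
                                 (n, N_PROCESSES)),
    )


def _paint_positive_cells(
    shape: tuple[int, int],
    pop: CellPopulation,
    select: np.ndarray,
    soma_radius: int = SOMA_RADIUS,
) -> np.ndarray | None:
    """Soma discs plus radiating processes for the selected cells.

    Process geometry comes from the cells' stored morphology so the same
    cell looks the same on both sections of a pair.
    """
    if pop.count == 0 or not select.any():
        return None
    centers = pop.centers[select]
    mask = _paint_disks(shape, centers, soma_radius)
    h, w = shape
    for (x, y), angles, lens in zip(centers, pop.proc_angles[select],
                                    pop.proc_lengths[select]):
        for ang, ln in zip(angles, lens):
            x1 = int(round(x + ln * np.cos(ang)))
            y1 = int(round(y + ln * np.sin(ang)))
            rr, cc = draw_line(int(round(y)), int(round(x)), y1, x1)
            keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
            mask[rr[keep], cc[keep]] = True
    return mask


# ---------------------------------------------------------------------------
# staining and rendering


def _coverage_blob(
    rng: np.random.Generator, region: np.ndarray, coverage: float, sigma: float
) -> np.ndarray:
    """Blob-like submask of ``region`` covering exactly ``coverage`` of it."""
    out = np.zeros_like(region)
    n = int(region.sum())
    if coverage <= 0 or n == 0:
        return out
    if coverage >= 1:
        return region.copy()
    fld = _smooth_field(rng, region.shape, sigma)
    vals = fld[region]
    thr = np.quantile(vals, 1.0 - coverage)
    out[region] = vals > thr
    return out


def render_tile(od_hema: np.ndarray, od_dab: np.ndarray) -> np.ndarray:
    """Beer-Lambert attenuation of white light through the two stains."""
    od = od_hema[..., None] * HEMATOXYLIN_VEC + od_dab[..., None] * DAB_VEC
    rgb = 255.0 * np.exp(-np.clip(od, 0.0, None))
    return np.clip(np.round(rgb), 0, 255).astype(np.uint8)


def _marker_field_rng(tissue_seed: int, marker: MarkerStainModel, salt: int) -> np.random.Generator:
    """Generator for a marker's deposition fields.

    Extracellular deposits are a property of the tissue block, revealed by
    whichever section is stained for that marker: the field depends on the
    tissue seed and the marker's deposition parameters, so two sections
    stained with identical models show the same deposits (modulo the
    section transform), while markers with different parameters get
    independent fields.
    """
    return np.random.default_rng(
        [
            int(tissue_seed) & 0x7FFFFFFF,
            salt,
            int(round(marker.diffuse_in_necrosis * 1e6)),
            int(round(marker.diffuse_in_tissue * 1e6)),
            int(round(marker.dab_od * 1e6)),
        ]
    )


def _marker_diffuse(
    tissue_model: TissueModel,
    marker: MarkerStainModel,
    tissue: np.ndarray,
    necrosis: np.ndarray,
    palisade: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """A-frame diffuse deposition mask and OD modulation field."""
    size = tissue.shape[0]
    if marker.diffuse_region is not None:
        diffuse = marker.diffuse_region.astype(bool) & tissue
    else:
        frng = _marker_field_rng(tissue_model.rng_seed, marker, 11)
        viable = tissue & ~necrosis
        diffuse = _coverage_blob(frng, necrosis, marker.diffuse_in_necrosis, size / 24.0)
        diffuse |= _coverage_blob(frng, viable & ~palisade, marker.diffuse_in_tissue, size / 16.0)
    mrng = _marker_field_rng(tissue_model.rng_seed, marker, 13)
    mod = np.clip(1.0 + 0.15 * _smooth_field(mrng, tissue.shape, size / 24.0), 0.7, 1.3)
    return diffuse, mod


def _stain_section(
    noise_rng: np.random.Generator,
    tissue: np.ndarray,
    pops: dict[str, CellPopulation],
    nucleus_mask: np.ndarray,
    marker: MarkerStainModel,
    diffuse: np.ndarray,
    diffuse_mod: np.ndarray,
    od_noise_sigma: float,
    base_field: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Paint hematoxylin + DAB OD rasters for one section and one marker.

    ``pops`` holds the section's cell populations (viable / rim /
    necrosis) with their persistent affinities; ``diffuse`` is the
    marker's extracellular deposition mask in this section's frame;
    ``base_field`` the block-intrinsic counterstain baseline (shared by
    adjacent sections).  Returns (od_hema, od_dab, dab_components); the
    truth DAB mask is the union of the components, all inside tissue.
    """
    shape = tissue.shape

    # hematoxylin: smooth cytoplasmic/neuropil baseline plus dark nuclei
    od_h = np.where(tissue, np.clip(base_field, 0.1, None), 0.0)
    od_h = od_h + np.where(nucleus_mask, NUCLEUS_EXTRA_OD, 0.0)

    od_d = np.zeros(shape)
    components: dict[str, np.ndarray] = {}

    diffuse = diffuse & tissue
    if diffuse.any():
        od_d = np.where(diffuse, marker.dab_od * diffuse_mod, od_d)
        components["diffuse"] = diffuse

    def paint(pop: CellPopulation, prob: float, od: float) -> np.ndarray | None:
        if pop.count == 0 or prob <= 0:
            return None
        stamps = _paint_positive_cells(shape, pop, pop.affinity < prob)
        if stamps is None:
            return None
        stamps &= tissue
        if not stamps.any():
            return None
        np.copyto(od_d, np.maximum(od_d, od), where=stamps)
        return stamps

    cellular = paint(pops["viable"], marker.cellular_fraction, marker.dab_od)
    if cellular is not None:
        components["cellular"] = cellular
    rim_prob = float(np.clip(marker.cellular_fraction + marker.rim_intensity, 0.0, 1.0))
    rim = paint(pops["rim"], rim_prob, marker.dab_od * (1.0 + 0.3 * marker.rim_intensity))
    if rim is not None:
        components["rim"] = rim
    # necrotic remnant cells stain weakly, and only for cellular markers
    remnant = paint(pops["necrosis"], 0.5 * marker.cellular_fraction, 0.6 * marker.dab_od)
    if remnant is not None:
        components["remnant"] = remnant

    dab_any = _union(components, shape)
    od_h = np.where(dab_any, DAB_BLOCKS_HEMATOXYLIN * od_h, od_h)

    if od_noise_sigma > 0:
        od_h = np.clip(od_h + noise_rng.normal(0.0, od_noise_sigma, shape), 0.0, None)
        od_d = np.clip(od_d + noise_rng.normal(0.0, od_noise_sigma, shape), 0.0, None)
    return od_h, od_d, components


def _union(components: dict[str, np.ndarray], shape: tuple[int, int]) -> np.ndarray:
    out = np.zeros(shape, dtype=bool)
    for m in components.values():
        out |= m
    return out


def _plant_geometry_and_cells(tissue: TissueModel, rng: np.random.Generator):
    """Shared first half of tile generation (A frame)."""
    size = tissue.tile_size
    tissue_mask = make_tissue_mask(rng, size, tissue.glass_fraction)
    necrosis = make_necrosis_mask(rng, tissue_mask, tissue.necrosis_fraction,
                                  tissue.n_necrotic_foci)
    palisade = make_palisade_mask(necrosis, tissue_mask, tissue.palisade_width)
    viable = tissue_mask & ~necrosis
    pops = {
        "viable": plant_cells(viable & ~palisade, tissue.cell_density, rng),
        "rim": plant_cells(palisade, tissue.cell_density * RIM_DENSITY_FACTOR, rng),
        "necrosis": plant_cells(necrosis,
                                tissue.cell_density * tissue.hypocellular_factor, rng),
    }
    nucleus = (pops["viable"].nucleus_mask | pops["rim"].nucleus_mask
               | pops["necrosis"].nucleus_mask)
    # block-intrinsic counterstain baseline, shared by adjacent sections
    base_field = HEMATOXYLIN_BASE_OD * (
        1.0 + 0.15 * _smooth_field(rng, (size, size), size / 16.0)
    )
    return tissue_mask, necrosis, palisade, pops, nucleus, base_field


# ---------------------------------------------------------------------------
# tile generation


def generate_tile(
    tissue: TissueModel, marker: MarkerStainModel
) -> tuple[RgbTile, TileGroundTruth]:
    """Generate a single stained section (no adjacent pair).

    Equivalent to tile A of :func:`generate_tile_pair`; the ground truth's
    B-frame masks simply duplicate the A-frame ones under the identity
    transform.
    """
    tissue.validate()
    marker.validate()
    size = tissue.tile_size
    rng = np.random.default_rng(tissue.rng_seed)
    tissue_mask, necrosis, palisade, pops, nucleus, base_field = _plant_geometry_and_cells(tissue, rng)
    diffuse, mod = _marker_diffuse(tissue, marker, tissue_mask, necrosis, palisade)
    od_h, od_d, comps = _stain_section(
        rng, tissue_mask, pops, nucleus, marker, diffuse, mod,
        tissue.od_noise_sigma, base_field,
    )
    tile = RgbTile(render_tile(od_h, od_d), marker_name=marker.marker_name)
    truth = TileGroundTruth(
        tissue_mask=tissue_mask,
        necrosis_mask=necrosis,
        palisade_mask=palisade,
        dab_mask_per_marker={marker.marker_name: _union(comps, (size, size))},
        dab_components_per_marker={marker.marker_name: comps},
        intersection_transform=RigidTransform(),
        tissue_mask_b=tissue_mask,
        necrosis_mask_b=necrosis,
        palisade_mask_b=palisade,
        cell_counts={name: pop.count for name, pop in pops.items()},
    )
    return tile, truth


def _carry_population(
    pop: CellPopulation,
    transform: RigidTransform,
    size: int,
    region_b: np.ndarray,
    rng: np.random.Generator,
    resample: float = SECTION_CELL_RESAMPLE,
) -> CellPopulation:
    """Move a population into B's frame, resampling a small share of cells.

    Carried cells keep their affinity and morphology (the same physical
    cell truncated by the next section); resampled cells are new draws.
    """
    if pop.count == 0:
        return pop
    moved = transform.apply_points(pop.centers, (size, size))
    inside = (
        (moved[:, 0] >= 0) & (moved[:, 0] < size)
        & (moved[:, 1] >= 0) & (moved[:, 1] < size)
    )
    centers = moved[inside]
    aff = pop.affinity[inside]
    ang = pop.proc_angles[inside]
    length = pop.proc_lengths[inside]
    n_res = int(round(resample * len(centers)))
    if n_res > 0 and region_b.any():
        drop = rng.choice(len(centers), size=n_res, replace=False)
        keep = np.ones(len(centers), dtype=bool)
        keep[drop] = False
        flat = np.flatnonzero(region_b)
        picks = rng.choice(flat, size=n_res, replace=True)
        ys, xs = np.unravel_index(picks, region_b.shape)
        centers = np.vstack([centers[keep], np.column_stack([xs, ys]).astype(float)])
        aff = np.concatenate([aff[keep], rng.random(n_res)])
        ang = np.vstack([ang[keep], rng.uniform(0, 2 * np.pi, (n_res, N_PROCESSES))])
        length = np.vstack([length[keep],
                            rng.uniform(0.6 * PROCESS_LENGTH, 1.4 * PROCESS_LENGTH,
                                        (n_res, N_PROCESSES))])
    nucleus = _paint_disks((size, size), centers, NUCLEUS_RADIUS)
    soma = _paint_disks((size, size), centers, SOMA_RADIUS)
    return CellPopulation(centers, nucleus, soma, aff, ang, length)


def generate_tile_pair(
    tissue: TissueModel,
    marker_a: MarkerStainModel,
    marker_b: MarkerStainModel,
    transform: RigidTransform | None = None,
) -> tuple[RgbTile, RgbTile, TileGroundTruth]:
    """Generate two pseudo-adjacent sections sharing one tissue geometry.

    Tile A is stained for ``marker_a``.  Tile B is tile A's geometry under
    the rigid ``transform`` (section placement difference), stained for
    ``marker_b``; a small fraction of cell positions is resampled because
    adjacent sections share structure but not exact cells.  Cells keep
    their marker affinities across sections and deposition fields are
    tied to the tissue block, so identical stain models on the two
    sections produce near-identical staining.

    Returns the two rendered tiles plus the full planted ground truth.
    """
    tissue.validate()
    marker_a.validate()
    marker_b.validate()
    if transform is None:
        transform = RigidTransform()
    size = tissue.tile_size
    if transform.magnitude() >= size / 4.0:
        raise ParameterError(
            f"transform translation {transform.magnitude():.1f}px exceeds tile_size/4"
        )
    if marker_a.marker_name == marker_b.marker_name:
        raise ParameterError("markers must have distinct names")

    rng = np.random.default_rng(tissue.rng_seed)
    (tissue_mask, necrosis, palisade, pops, nucleus_a,
     base_field) = _plant_geometry_and_cells(tissue, rng)

    # tissue leaving the frame under the transform
    t_area = int(tissue_mask.sum())
    if t_area > 0:
        moved = warp_image(tissue_mask, transform, order=0)
        lost = 1.0 - moved.sum() / t_area
        if lost > 0.25:
            raise ParameterError(f"transform moves {lost:.0%} of tissue out of frame")

    diffuse_a, mod_a = _marker_diffuse(tissue, marker_a, tissue_mask, necrosis, palisade)
    od_h_a, od_d_a, comps_a = _stain_section(
        rng, tissue_mask, pops, nucleus_a, marker_a, diffuse_a, mod_a,
        tissue.od_noise_sigma, base_field,
    )

    # --- section B: same geometry under the rigid transform
    tissue_b = warp_image(tissue_mask, transform, order=0)
    necrosis_b = warp_image(necrosis, transform, order=0)
    palisade_b = warp_image(palisade, transform, order=0)
    viable_b = tissue_b & ~necrosis_b

    pops_b = {
        "viable": _carry_population(pops["viable"], transform, size,
                                    viable_b & ~palisade_b, rng,
                                    tissue.section_resample),
        "rim": _carry_population(pops["rim"], transform, size, palisade_b, rng,
                                 tissue.section_resample),
        "necrosis": _carry_population(pops["necrosis"], transform, size,
                                      necrosis_b, rng, tissue.section_resample),
    }
    nucleus_b = (pops_b["viable"].nucleus_mask | pops_b["rim"].nucleus_mask
                 | pops_b["necrosis"].nucleus_mask)

    diffuse_b, mod_b = _marker_diffuse(tissue, marker_b, tissue_mask, necrosis, palisade)
    diffuse_b = warp_image(diffuse_b, transform, order=0)
    mod_b = warp_image(mod_b, transform, order=1, cval=1.0)
    base_field_b = warp_image(base_field, transform, order=1,
                              cval=HEMATOXYLIN_BASE_OD)

    od_h_b, od_d_b, comps_b = _stain_section(
        rng, tissue_b, pops_b, nucleus_b, marker_b, diffuse_b, mod_b,
        tissue.od_noise_sigma, base_field_b,
    )

    tile_a = RgbTile(render_tile(od_h_a, od_d_a), marker_name=marker_a.marker_name)
    tile_b = RgbTile(render_tile(od_h_b, od_d_b), marker_name=marker_b.marker_name)

    truth = TileGroundTruth(
        tissue_mask=tissue_mask,
        necrosis_mask=necrosis,
        palisade_mask=palisade,
        dab_mask_per_marker={
            marker_a.marker_name: _union(comps_a, (size, size)),
            marker_b.marker_name: _union(comps_b, (size, size)),
        },
        dab_components_per_marker={
            marker_a.marker_name: comps_a,
            marker_b.marker_name: comps_b,
        },
        intersection_transform=transform,
        tissue_mask_b=tissue_b,
        necrosis_mask_b=necrosis_b,
        palisade_mask_b=palisade_b,
        cell_counts={name: pop.count for name, pop in pops.items()},
    )
    return tile_a, tile_b, truth
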