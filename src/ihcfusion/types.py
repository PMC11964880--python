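"""Shared domain types for tile-based brightfield IHC analysis.

A tile is an 8-bit RGB raster standing in for a region of a whole-slide
image (WSI).  Rigid transforms model the placement difference between
adjacent paraffin sections mounted on separate slides.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np


class ParameterError(ValueError):
    """A configuration or argument violates an operation's preconditions."""


class InsufficientDataError(ValueError):
    """Too few observations to compute the requested statistic."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RgbTile:
    """8-bit RGB raster with optional physical and marker metadata."""

    pixels: np.ndarray  # H x W x 3, uint8
    microns_per_pixel: float | None = None
    marker_name: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ParameterError(f"tile must be HxWx3, got shape {px.shape}")
        if px.shape[0] < 16 or px.shape[1] < 16:
            raise ParameterError("tile must be at least 16x16 pixels")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ParameterError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        self.pixels = px

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]

    def as_float(self) -> np.ndarray:
        """Pixels as float in [0, 1]."""
        return self.pixels.astype(np.float64) / 255.0


@dataclass
class RigidTransform:
    """In-plane rigid motion: rotation about the tile centre, then translation.

    The forward map sends a coordinate ``(x, y)`` (column, row) in the
    reference frame A to its location in frame B:

        ``p_B = R(rotation) @ (p_A - c) + c + (dx, dy)``

    with ``c`` the tile centre.  ``score`` holds the alignment metric when
    the transform was estimated rather than planted; ``low_confidence`` is
    set when that score fell below the configured floor.
    """

    dx: float = 0.0
    dy: float = 0.0
    rotation: float = 0.0  # degrees, counter-clockwise
    score: float | None = None
    low_confidence: bool = False

    def matrix(self, shape: tuple[int, int]) -> np.ndarray:
        """3x3 homogeneous forward matrix (xy convention) for a tile shape."""
        h, w = shape
        cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
        pre = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
        post = np.array(
            [[1, 0, cx + self.dx], [0, 1, cy + self.dy], [0, 0, 1]], dtype=float
        )
        return post @ rot @ pre

    def inverse(self) -> "RigidTransform":
        """Transform undoing this one (translation expressed in A's frame)."""
        th = math.radians(self.rotation)
        c, s = math.cos(th), math.sin(th)
        # inverse: rotate by -theta about centre, translate by -R^-1 t
        inv_dx = -(c * self.dx + s * self.dy)
        inv_dy = -(-s * self.dx + c * self.dy)
        return RigidTransform(dx=inv_dx, dy=inv_dy, rotation=-self.rotation)

    def apply_points(self, xy: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
        """Map an (N, 2) array of (x, y) points from frame A to frame B."""
        m = self.matrix(shape)
        pts = np.column_stack([xy, np.ones(len(xy))])
        return (pts @ m.T)[:, :2]

    def magnitude(self) -> float:
        return math.hypot(self.dx, self.dy)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RigidTransform":
        return cls(**d)


def warp_image(
    image: np.ndarray, transform: RigidTransform, order: int = 1, cval: float = 0.0
) -> np.ndarray:
    """Apply the forward rigid transform to an image (A frame -> B frame).

    Output pixel x_B samples the input at ``T^{-1}(x_B)``.  ``order=0`` for
    masks, ``order=1`` for intensity rasters.  Fill value ``cval`` outside.
    """
    from scipy import ndimage

    shape = image.shape[:2]
    inv = np.linalg.inv(transform.matrix(shape))
    # affine_transform works in (row, col); convert the xy matrix.
    swap = np.array([[0.0, 1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
    m = swap @ inv @ swap
    out_dtype = image.dtype

    def _warp_channel(ch: np.ndarray) -> np.ndarray:
        return ndimage.affine_transform(
            ch.astype(np.float64),
            m[:2, :2],
            offset=m[:2, 2],
            order=order,
            mode="constant",
            cval=cval,
        )

    if image.ndim == 2:
        out = _warp_channel(image)
    else:
        out = np.stack(
            [_warp_channel(image[..., i]) for i in range(image.shape[2])], axis=-1
        )
    if out_dtype == bool:
        return out > 0.5
    if np.issubdtype(out_dtype, np.integer):
        return np.clip(np.round(out), np.iinfo(out_dtype).min, np.iinfo(out_dtype).max).astype(out_dtype)
    return out.astype(out_dtype)
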