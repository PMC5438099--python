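"""Bregma-anchored coordinate system, RoI import and masking.

Anatomical coordinates are given in microns relative to the skull landmark
bregma: x is mediolateral (positive = animal's right), y is anteroposterior
(positive = anterior). Pixel coordinates are 0-based with x = column
increasing rightward and y = row increasing downward, so anterior maps to
*smaller* row indices (the sign flip in :func:`um_to_px`).

RoIs come in two shapes, as in the widefield-imaging workflow this package
supports: square seeds specified in a CSV of micron offsets from bregma
(used for seed-pixel correlation maps and correlation matrices), and
hand-drawn polygons used to crop away non-cortical tissue and the midline
sinus.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from matplotlib.path import Path as _MplPath
from scipy import ndimage

from .stack import UNDEFINED, ImageStack


@dataclass
class CoordinateSystem:
    """Bregma origin (pixels) plus the micron width of one pixel."""

    origin: tuple[float, float]  # (x_px, y_px) of bregma
    um_per_px: float

    def __post_init__(self) -> None:
        if self.origin is None or len(self.origin) != 2:
            raise ValueError("origin must be an (x, y) pixel pair")
        if not (self.um_per_px > 0):
            raise ValueError(f"um_per_px must be positive, got {self.um_per_px}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))
        self.um_per_px = float(self.um_per_px)


@dataclass
class SeedRoI:
    """Named square seed: center in microns from bregma, side length in pixels."""

    name: str
    x_um: float
    y_um: float
    length: int = 1

    def __post_init__(self) -> None:
        if int(self.length) < 1:
            raise ValueError(f"RoI {self.name!r}: length must be >= 1, got {self.length}")
        self.length = int(self.length)
        self.x_um = float(self.x_um)
        self.y_um = float(self.y_um)


@dataclass
class PolygonRoI:
    """Named polygon in pixel coordinates; at least three vertices, simple."""

    name: str
    vertices: Sequence[tuple[float, float]]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon {self.name!r} needs >= 3 vertices, got {len(self.vertices)}"
            )
        self.vertices = [(float(x), float(y)) for x, y in self.vertices]


def um_per_px_from_fov(fov_mm: float, sensor_px: int) -> float:
    """Pixel width in microns from field-of-view size and sensor width.

    A 10.5 mm field imaged onto a 256-pixel-wide sensor gives 41 μm/pixel
    (after rounding to the nearest micron).
    """
    if not (fov_mm > 0) or sensor_px < 1:
        raise ValueError("fov_mm must be positive and sensor_px >= 1")
    return fov_mm * 1000.0 / sensor_px


def set_origin(clicks: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Average several clicked bregma positions into one origin.

    Averaging reduces the human error of any single click; a single click is
    accepted as-is.
    """
    if len(clicks) == 0:
        raise ValueError("at least one click is required to set the origin")
    arr = np.asarray(clicks, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("clicks must be (x, y) pairs")
    mean = arr.mean(axis=0)
    return float(mean[0]), float(mean[1])


def um_to_px(p_um: tuple[float, float], cs: CoordinateSystem) -> tuple[float, float]:
    """Micron offset from bregma → pixel position (x right, y down)."""
    x_um, y_um = p_um
    return (
        cs.origin[0] + x_um / cs.um_per_px,
        cs.origin[1] - y_um / cs.um_per_px,
    )


def px_to_um(p_px: tuple[float, float], cs: CoordinateSystem) -> tuple[float, float]:
    """Exact algebraic inverse of :func:`um_to_px`."""
    x_px, y_px = p_px
    return (
        (x_px - cs.origin[0]) * cs.um_per_px,
        (cs.origin[1] - y_px) * cs.um_per_px,
    )


#: Single-pixel seed coordinates (microns from bregma) for seven standard
#: cortical areas per hemisphere, Allen-atlas-derived: visual (V1), barrel
#: (BC), hindlimb (HL), primary/secondary motor (M1/M2), retrosplenial (RS)
#: and anterior cingulate (AC) cortex. Layout matches the RoI CSV format.
CORTICAL_ROIS_UM: tuple[tuple[str, int, float, float], ...] = (
    ("L-V1", 1, -2516.8, -4267.8),
    ("L-BC", 1, -4300.0, -760.0),
    ("L-HL", 1, -1694.2, -1145.7),
    ("L-M1", 1, -1500.0, 2000.0),
    ("L-M2", 1, -870.02, 1420.5),
    ("L-RS", 1, -620.43, -2885.8),
    ("L-AC", 1, -260.0, 270.0),
    ("R-V1", 1, 2516.8, -4267.8),
    ("R-BC", 1, 4300.0, -760.0),
    ("R-HL", 1, 1694.2, -1145.7),
    ("R-M1", 1, 1500.0, 2000.0),
    ("R-M2", 1, 870.02, 1420.5),
    ("R-RS", 1, 620.43, -2885.8),
    ("R-AC", 1, 260.0, 270.0),
)


def cortical_rois(length: int = 1) -> list["SeedRoI"]:
    """The standard 14-area bilateral seed set as :class:`SeedRoI` objects."""
    return [SeedRoI(n, x, y, length) for n, _, x, y in CORTICAL_ROIS_UM]


def write_cortical_roi_csv(path: str | os.PathLike) -> str:
    """Write the standard seed table as a name,length,x,y CSV."""
    df = pd.DataFrame(CORTICAL_ROIS_UM, columns=["name", "length", "x", "y"])
    df.to_csv(path, index=False)
    return os.fspath(path)


_ROI_COLUMNS = ("name", "length", "x", "y")


def import_roi_csv(path: str | os.PathLike) -> list[SeedRoI]:
    """Import square seed RoIs from a CSV with columns name,length,x,y.

    Coordinates are microns relative to bregma; row order is preserved.
    Duplicate names, missing columns and non-numeric coordinates are errors.
    """
    df = pd.read_csv(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    missing = [c for c in _ROI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing RoI column(s) {missing}")
    if df.empty:
        return []
    for col in ("length", "x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            bad = df.loc[vals.isna(), col].iloc[0]
            raise ValueError(f"{path}: non-numeric value {bad!r} in column {col!r}")
        df[col] = vals
    names = df["name"].astype(str)
    if names.duplicated().any():
        dup = names[names.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate RoI name {dup!r}")
    return [
        SeedRoI(name=row["name"], x_um=row["x"], y_um=row["y"], length=int(row["length"]))
        for _, row in df.iterrows()
    ]


def _round_half_away(v: float) -> int:
    return int(math.copysign(math.floor(abs(v) + 0.5), v))


def seed_pixels(
    roi: SeedRoI,
    cs: CoordinateSystem,
    frame_shape: tuple[int, int] | None = None,
) -> set[tuple[int, int]]:
    """Integer pixel block covered by a square seed RoI.

    The block is ``length × length``, centered on the rounded pixel position
    of the RoI center (fractional centers round half-away-from-zero). With a
    ``frame_shape`` (rows, cols) the block is clipped to the frame and the
    center itself must be in-bounds.
    """
    cx, cy = um_to_px((roi.x_um, roi.y_um), cs)
    icx, icy = _round_half_away(cx), _round_half_away(cy)
    if frame_shape is not None:
        n_rows, n_cols = frame_shape
        if not (0 <= icx < n_cols and 0 <= icy < n_rows):
            raise ValueError(
                f"RoI {roi.name!r} center ({icx}, {icy}) lies outside a "
                f"{n_rows}×{n_cols} frame"
            )
    half = roi.length // 2
    xs = range(icx - half, icx - half + roi.length)
    ys = range(icy - half, icy - half + roi.length)
    pixels = {(x, y) for x in xs for y in ys}
    if frame_shape is not None:
        n_rows, n_cols = frame_shape
        pixels = {(x, y) for x, y in pixels if 0 <= x < n_cols and 0 <= y < n_rows}
    return pixels


def polygon_pixel_mask(
    polygons: Iterable[PolygonRoI], frame_shape: tuple[int, int]
) -> np.ndarray:
    """2-D boolean mask: True where a pixel center falls inside any polygon.

    Pixel centers are tested with the even–odd rule; boundary pixels count as
    inside.
    """
    n_rows, n_cols = frame_shape
    mask = np.zeros((n_rows, n_cols), dtype=bool)
    yy, xx = np.mgrid[0:n_rows, 0:n_cols]
    points = np.column_stack([xx.ravel(), yy.ravel()]).astype(np.float64)
    for poly in polygons:
        path = _MplPath(np.asarray(poly.vertices, dtype=np.float64))
        # tiny positive radius pulls exact-boundary centers inside
        inside = path.contains_points(points, radius=1e-9)
        inside |= path.contains_points(points, radius=-1e-9)
        mask |= inside.reshape(n_rows, n_cols)
    return mask


def polygon_mask(stack: ImageStack, polygons: Sequence[PolygonRoI]) -> ImageStack:
    """Crop a stack to polygon RoIs: pixels outside every polygon become
    undefined in every frame. An empty polygon list yields a fully undefined
    stack. Idempotent."""
    mask = polygon_pixel_mask(polygons, stack.frame_shape)
    data = stack.data.copy()
    data[:, ~mask] = UNDEFINED
    return stack.with_data(data)


def shift_to_common_origin(
    stack: ImageStack,
    own_origin: tuple[float, float],
    target_origin: tuple[float, float],
) -> ImageStack:
    """Translate a stack so its bregma lands on a shared origin.

    Used to pool stacks from different animals onto one coordinate system:
    the stack is shifted by ``target − own`` (bilinear resampling); pixels
    exposed at the border become undefined.
    """
    dx = float(target_origin[0]) - float(own_origin[0])
    dy = float(target_origin[1]) - float(own_origin[1])
    if dx == 0.0 and dy == 0.0:
        return stack.copy()
    out = np.empty_like(stack.data)
    for i in range(stack.n_frames):
        # shift in (row, col) order; order=1 bilinear, exposed pixels NaN
        out[i] = ndimage.shift(
            stack.data[i], (dy, dx), order=1, mode="constant", cval=UNDEFINED
        )
    return stack.with_data(out)
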