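"""Image, ROI and tile I/O.

Coordinate conventions used throughout the package: arrays are indexed
``[row, col]`` (0-based, row-major); pixel ``(r, c)`` covers the half-open
square ``[r, r+1) x [c, c+1)`` with its center at ``(r + 0.5, c + 0.5)``.
Polygon coordinates are ``(x, y) = (col, row)`` in pixel units, matching
GeoJSON written in image space.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import imageio.v3 as iio
import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

__all__ = [
    "CalibrationParams",
    "RoiMask",
    "Tile",
    "read_image",
    "write_image",
    "load_roi",
    "roi_from_polygons",
    "full_image_roi",
    "iter_tiles",
]


@dataclass(frozen=True)
class CalibrationParams:
    """Physical calibration of the image grid and the scoring field size.

    Parameters
    ----------
    microns_per_pixel
        Physical edge length of one pixel in micrometers. Scanner dependent;
        must be supplied for real slides (typical 40x scans run 0.12-0.5).
    tile_width_um, tile_height_um
        Dimensions of one high-power field (HPF), the unit area over which
        TMEM doorways are counted and ranked. Default 300 x 400 um; the
        manual-scoring field of 439 x 330 um is available as a preset.
    """

    microns_per_pixel: float = 0.357
    tile_width_um: float = 300.0
    tile_height_um: float = 400.0

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError("microns_per_pixel must be positive")
        if self.tile_width_um <= 0 or self.tile_height_um <= 0:
            raise ValueError("tile dimensions must be positive")

    @property
    def um2_per_pixel(self) -> float:
        return self.microns_per_pixel ** 2

    def um_to_px(self, um: float) -> int:
        """Convert a physical length to a whole number of pixels (rounded)."""
        return int(round(um / self.microns_per_pixel))

    def area_px_to_um2(self, n_pixels: int) -> float:
        return n_pixels * self.um2_per_pixel

    @classmethod
    def manual_hpf_preset(cls, microns_per_pixel: float = 0.357) -> "CalibrationParams":
        """Field size matching the manual-microscopy HPF (439 x 330 um)."""
        return cls(microns_per_pixel, tile_width_um=439.0, tile_height_um=330.0)


@dataclass
class RoiMask:
    """Binary region-of-interest mask on the image grid.

    ``provenance`` records whether the mask was drawn (loaded from a file)
    or defaults to the full image.
    """

    mask: np.ndarray
    provenance: str = "drawn"

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("ROI mask must be 2-D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def bounding_box(self) -> tuple[int, int, int, int]:
        """(row0, col0, row1, col1), half-open, of the True region."""
        if self.is_empty:
            raise ValueError("ROI mask is empty")
        rows = np.flatnonzero(self.mask.any(axis=1))
        cols = np.flatnonzero(self.mask.any(axis=0))
        return int(rows[0]), int(cols[0]), int(rows[-1]) + 1, int(cols[-1]) + 1


def read_image(path: str | Path) -> np.ndarray:
    """Read an 8-bit RGB image (PNG or TIFF) as an (H, W, 3) uint8 array.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ValueError
        For non-RGB or non-8-bit input.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:  # drop alpha if fully opaque
        if np.all(arr[:, :, 3] == 255):
            arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected 3 channels, got array of shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"expected 8-bit image, got dtype {arr.dtype}")
    return arr


def write_image(path: str | Path, raster: np.ndarray) -> None:
    """Write a uint8 raster to PNG or TIFF, chosen by file suffix."""
    path = Path(path)
    raster = np.ascontiguousarray(raster)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, raster)
    else:
        iio.imwrite(path, raster)


def roi_from_polygons(
    polygons: Sequence[Sequence[tuple[float, float]]],
    image_shape: tuple[int, int],
) -> RoiMask:
    """Rasterize closed polygons (pixel (x, y) coordinates) to a binary mask.

    A pixel belongs to the ROI when its center lies strictly inside any
    polygon (pixel-center inclusion). Polygons must be simple.
    """
    if len(polygons) == 0:
        raise ValueError("empty polygon list")
    h, w = image_shape[:2]
    mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    cx = xx + 0.5
    cy = yy + 0.5
    for coords in polygons:
        poly = Polygon(coords)
        if not poly.is_valid:
            raise ValueError("polygon is not simple (self-intersecting or degenerate)")
        # restrict the point test to the polygon bounding box
        minx, miny, maxx, maxy = poly.bounds
        sel = (cx >= minx) & (cx <= maxx) & (cy >= miny) & (cy <= maxy)
        if not sel.any():
            continue
        inside = shapely.contains_xy(poly, cx[sel], cy[sel])
        mask[yy[sel][inside], xx[sel][inside]] = True
    if not mask.any():
        raise ValueError("polygons rasterize to an empty mask")
    return RoiMask(mask, provenance="drawn")


def full_image_roi(image_shape: tuple[int, int]) -> RoiMask:
    return RoiMask(np.ones(image_shape[:2], dtype=bool), provenance="full-image")


def load_roi(path: str | Path, image_shape: tuple[int, int]) -> RoiMask:
    """Load an ROI from an 8-bit mask image (nonzero = inside) or a GeoJSON
    file of polygons in pixel coordinates.

    Raises on grid mismatch, out-of-bounds polygons, or an empty result.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    h, w = image_shape[:2]
    if path.suffix.lower() in (".json", ".geojson"):
        data = json.loads(path.read_text())
        polygons = _geojson_polygons(data)
        for coords in polygons:
            arr = np.asarray(coords, dtype=float)
            if (arr[:, 0] < 0).any() or (arr[:, 0] > w).any() or (
                arr[:, 1] < 0
            ).any() or (arr[:, 1] > h).any():
                raise ValueError("polygon coordinates outside image bounds")
        return roi_from_polygons(polygons, (h, w))
    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.shape != (h, w):
        raise ValueError(f"ROI mask shape {arr.shape} does not match image {(h, w)}")
    roi = RoiMask(arr > 0, provenance="drawn")
    if roi.is_empty:
        raise ValueError("ROI mask is empty")
    return roi


def _geojson_polygons(data: dict) -> list[list[tuple[float, float]]]:
    polygons: list[list[tuple[float, float]]] = []

    def collect(geom: dict) -> None:
        gtype = geom.get("type")
        if gtype == "Polygon":
            polygons.append([tuple(p) for p in geom["coordinates"][0]])
        elif gtype == "MultiPolygon":
            for poly in geom["coordinates"]:
                polygons.append([tuple(p) for p in poly[0]])
        else:
            raise ValueError(f"unsupported GeoJSON geometry type: {gtype}")

    if data.get("type") == "FeatureCollection":
        for feat in data["features"]:
            collect(feat["geometry"])
    elif data.get("type") == "Feature":
        collect(data["geometry"])
    else:
        collect(data)
    if not polygons:
        raise ValueError("no polygons found in GeoJSON")
    return polygons


@dataclass(frozen=True)
class Tile:
    """One high-power-field tile of the scoring grid.

    ``row``/``col`` index the tile within the grid; ``y0``/``x0`` are the
    top-left pixel, ``height``/``width`` the nominal tile size in pixels
    (the raster slice is clipped at the image edge). ``roi_overlap`` is the
    fraction of the *nominal* tile area covered by the ROI, so edge-clipped
    tiles are penalized.
    """

    row: int
    col: int
    y0: int
    x0: int
    height: int
    width: int
    roi_overlap: float

    @property
    def index(self) -> tuple[int, int]:
        return (self.row, self.col)

    def contains_point(self, y: float, x: float) -> bool:
        """Half-open containment: [y0, y0+h) x [x0, x0+w)."""
        return (
            self.y0 <= y < self.y0 + self.height
            and self.x0 <= x < self.x0 + self.width
        )


def iter_tiles(
    image_shape: tuple[int, int],
    roi: RoiMask,
    calibration: CalibrationParams,
) -> Iterator[Tile]:
    """Yield the non-overlapping HPF tile grid covering the ROI bounding box.

    Tiles are anchored at the bounding-box origin and emitted in row-major
    order; each carries its ROI-overlap fraction. Deterministic.
    """
    h, w = image_shape[:2]
    if roi.shape != (h, w):
        raise ValueError("ROI grid does not match image grid")
    tile_w = calibration.um_to_px(calibration.tile_width_um)
    tile_h = calibration.um_to_px(calibration.tile_height_um)
    if tile_w < 1 or tile_h < 1:
        raise ValueError("tile smaller than 1 px at this calibration")
    r0, c0, r1, c1 = roi.bounding_box()
    n_rows = int(np.ceil((r1 - r0) / tile_h))
    n_cols = int(np.ceil((c1 - c0) / tile_w))
    nominal_area = tile_h * tile_w
    for tr in range(n_rows):
        for tc in range(n_cols):
            y0 = r0 + tr * tile_h
            x0 = c0 + tc * tile_w
            ye = min(y0 + tile_h, h)
            xe = min(x0 + tile_w, w)
            inside = int(roi.mask[y0:ye, x0:xe].sum())
            yield Tile(
                row=tr,
                col=tc,
                y0=y0,
                x0=x0,
                height=tile_h,
                width=tile_w,
                roi_overlap=inside / nominal_area,
            )
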