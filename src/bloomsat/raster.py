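"""Georeferenced raster containers and GeoTIFF I/O.

A :class:`SpectralImage` holds a multiband reflectance raster together with
an affine geotransform (north-up, square pixels — the only case this package
needs). Rasters are written as plain GeoTIFFs via :mod:`tifffile`, carrying
the standard ``ModelPixelScale`` / ``ModelTiepoint`` tags so any GIS can read
them; band names travel in the image description.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import tifffile

# GeoTIFF tag codes
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922

DEFAULT_BAND_NAMES = ("blue", "green", "red", "nir")


@dataclass(frozen=True)
class GeoTransform:
    """North-up geotransform with square pixels.

    Map x increases eastward with column index; map y increases northward,
    so it *decreases* with row index. ``origin_x``/``origin_y`` are the map
    coordinates of the top-left corner of pixel (row=0, col=0).
    """

    origin_x: float
    origin_y: float
    pixel_size: float

    def __post_init__(self) -> None:
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    def rowcol_to_xy(self, row, col):
        """Map coordinates of the *center* of pixel (row, col)."""
        x = self.origin_x + (np.asarray(col, dtype=float) + 0.5) * self.pixel_size
        y = self.origin_y - (np.asarray(row, dtype=float) + 0.5) * self.pixel_size
        return x, y

    def xy_to_rowcol(self, x, y):
        """Integer pixel indices containing map point (x, y)."""
        col = np.floor((np.asarray(x, dtype=float) - self.origin_x) / self.pixel_size)
        row = np.floor((self.origin_y - np.asarray(y, dtype=float)) / self.pixel_size)
        return row.astype(int), col.astype(int)


@dataclass
class SpectralImage:
    """Multiband raster: ``values`` indexed (band, row, col), reflectance in [0, 1]."""

    values: np.ndarray
    transform: GeoTransform
    band_names: tuple[str, ...] = DEFAULT_BAND_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[np.newaxis]
        if self.values.ndim != 3:
            raise ValueError("values must be (band, row, col)")
        if len(self.band_names) != self.values.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for {self.values.shape[0]} bands"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("raster contains non-finite values")

    @property
    def n_bands(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols)."""
        return self.values.shape[1:]

    def pixels(self) -> np.ndarray:
        """Flattened (n_pixels, n_bands) view in row-major pixel order."""
        b, h, w = self.values.shape
        return self.values.reshape(b, h * w).T

    def same_grid(self, other: "SpectralImage") -> bool:
        return self.shape == other.shape and self.transform == other.transform

    def save(self, path) -> None:
        write_geotiff(path, self.values, self.transform, band_names=self.band_names)

    @classmethod
    def load(cls, path) -> "SpectralImage":
        values, transform, band_names = read_geotiff(path)
        if band_names is None:
            band_names = tuple(f"band_{i + 1}" for i in range(values.shape[0]))
        return cls(values=values, transform=transform, band_names=tuple(band_names))


def write_geotiff(path, values, transform: GeoTransform, band_names=None) -> None:
    """Write a (band, row, col) or (row, col) array as a georeferenced TIFF."""
    arr = np.asarray(values)
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    desc = {}
    if band_names is not None:
        desc["band_names"] = list(band_names)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, (transform.pixel_size, transform.pixel_size, 0.0)),
        (
            _MODEL_TIEPOINT,
            "d",
            6,
            (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0),
        ),
    ]
    tifffile.imwrite(
        path,
        arr,
        photometric="minisblack",
        planarconfig="separate" if arr.shape[0] > 1 else None,
        description=json.dumps(desc),
        extratags=extratags,
    )


def read_geotiff(path):
    """Read a TIFF written by :func:`write_geotiff`.

    Returns ``(values, transform, band_names)``; ``band_names`` is None when
    the file carries no band metadata.
    """
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        page = tif.pages[0]
        scale = page.tags.get(_MODEL_PIXEL_SCALE)
        tiepoint = page.tags.get(_MODEL_TIEPOINT)
        if scale is None or tiepoint is None:
            raise ValueError(f"{path}: missing GeoTIFF georeferencing tags")
        px = float(scale.value[0])
        origin_x = float(tiepoint.value[3])
        origin_y = float(tiepoint.value[4])
        band_names = None
        desc_tag = page.tags.get("ImageDescription")
        if desc_tag is not None:
            try:
                meta = json.loads(desc_tag.value)
                if isinstance(meta, dict) and "band_names" in meta:
                    band_names = tuple(meta["band_names"])
            except (json.JSONDecodeError, TypeError):
                pass
    if arr.ndim == 2:
        arr = arr[np.newaxis]
    return arr, GeoTransform(origin_x=origin_x, origin_y=origin_y, pixel_size=px), band_names
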