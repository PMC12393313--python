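"""Calibrated images, polygon ROIs and region statistics.

Conventions
-----------
Pixel coordinates are 0-based ``(x, y)`` with ``x`` the column index and
``y`` the row index.  A pixel occupies the unit square centered on its
integer index, and polygon membership is decided at pixel *centers*,
boundary inclusive.  Physical calibration is a single isotropic pixel
edge length with an explicit unit string (``"um"`` or ``"nm"``).
"""

from __future__ import annotations

import hashlib
import json
import logging
import struct
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import shapely
import tifffile
from shapely.geometry import Polygon

from .errors import DimensionError, EmptyRegionError, GeometryError

logger = logging.getLogger("centmorph")

ROI_KINDS = {"torus_outer", "torus_inner", "background", "spindle_exclusion", "freehand"}


@dataclass
class CalibratedImage:
    """A 2-D intensity raster with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of finite, non-negative intensities.
    pixel_size : float
        Physical length of one pixel edge, in ``unit``.
    unit : str
        Length unit carried through all physical outputs ("um" or "nm").
    channel : str
        Free-text fluorophore/marker label, e.g. ``"mCherry::SP12"``.
    """

    pixels: np.ndarray
    pixel_size: float
    unit: str = "um"
    channel: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise DimensionError(f"expected a 2-D raster, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 8:
            raise DimensionError(f"raster must be at least 8x8, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("intensities must be finite")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")

    @property
    def shape(self):
        return self.pixels.shape

    @property
    def pixel_area(self) -> float:
        """Physical area of one pixel (unit squared)."""
        return self.pixel_size ** 2


@dataclass
class PolygonROI:
    """A simple polygon in pixel coordinates with a semantic kind label."""

    vertices: np.ndarray  # (n, 2) array of (x, y)
    kind: str = "freehand"

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise GeometryError("vertices must be an (n, 2) array of (x, y)")
        if len(self.vertices) < 3:
            raise GeometryError("a polygon ROI needs at least 3 vertices")
        if self.kind not in ROI_KINDS:
            raise ValueError(f"unknown ROI kind {self.kind!r}; expected one of {sorted(ROI_KINDS)}")
        if not self.polygon.is_simple:
            raise GeometryError("polygon ROI must be simple (non-self-intersecting)")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    def contains_mask(self, shape: tuple[int, int]) -> np.ndarray:
        """Boolean raster of pixels whose centers lie in the polygon (boundary inclusive)."""
        poly = self.polygon
        minx, miny, maxx, maxy = poly.bounds
        h, w = shape
        x0 = max(int(np.floor(minx)), 0)
        x1 = min(int(np.ceil(maxx)), w - 1)
        y0 = max(int(np.floor(miny)), 0)
        y1 = min(int(np.ceil(maxy)), h - 1)
        mask = np.zeros(shape, dtype=bool)
        if x1 < x0 or y1 < y0:
            return mask
        xs, ys = np.meshgrid(np.arange(x0, x1 + 1), np.arange(y0, y1 + 1))
        inside = shapely.intersects_xy(poly, xs.ravel(), ys.ravel())
        mask[y0:y1 + 1, x0:x1 + 1] = inside.reshape(ys.shape)
        return mask

    def digest(self) -> str:
        """Short content hash used to tag measurements in the provenance log."""
        payload = self.kind.encode() + self.vertices.tobytes()
        return hashlib.sha1(payload).hexdigest()[:12]


@dataclass
class RegionStats:
    """Mean/min/max intensity and area of an ROI.

    ``max`` is the quantity the original ImageJ workflow calls "Maxthr"
    and reuses as the upper threshold of every segmentation formula.
    """

    mean: float
    min: float
    max: float
    area_px: int
    area_units: float

    def __post_init__(self):
        if not (self.min <= self.mean <= self.max):
            raise ValueError("require min <= mean <= max")
        if self.area_px < 1:
            raise ValueError("area_px must be >= 1")


def load_image(path, pixel_size: float, unit: str = "um", channel: str = "",
               page: int | None = None) -> CalibratedImage:
    """Read a TIFF or PNG raster and attach physical calibration.

    Multi-page TIFFs require an explicit ``page`` index; reading one
    without it raises :class:`DimensionError` rather than guessing.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read image: {path}")
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            n_pages = len(tf.pages)
            if page is None:
                if n_pages != 1:
                    raise DimensionError(
                        f"{path.name} has {n_pages} pages; pass an explicit page index")
                data = tf.pages[0].asarray()
            else:
                if not 0 <= page < n_pages:
                    raise DimensionError(f"page {page} out of range for {n_pages}-page TIFF")
                data = tf.pages[page].asarray()
    else:
        data = np.asarray(iio.imread(path))
        if data.ndim == 3 and page is not None:
            data = data[..., page]
        elif data.ndim == 3:
            raise DimensionError(f"{path.name} is not a single-channel 2-D image")
    return CalibratedImage(data, pixel_size=pixel_size, unit=unit, channel=channel)


def save_image(image: CalibratedImage, path) -> None:
    """Write the raster to TIFF (float32) or PNG (uint8/uint16 as-is)."""
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image.pixels.astype(np.float32))
    else:
        arr = image.pixels
        if arr.max() <= 255 and np.allclose(arr, np.round(arr)):
            iio.imwrite(path, arr.astype(np.uint8))
        else:
            iio.imwrite(path, arr.astype(np.uint16))


def region_stats(image: CalibratedImage, roi: PolygonROI) -> RegionStats:
    """Intensity statistics over pixels whose centers fall inside ``roi``.

    Mirrors the measure step of the original workflow: the mean and
    minimum of a traced torus feed the (mean+min)/2 lower threshold and
    the region maximum ("Maxthr") the upper threshold.
    """
    verts = roi.vertices
    h, w = image.shape
    if np.any(verts[:, 0] < -0.5) or np.any(verts[:, 0] > w - 0.5) or \
       np.any(verts[:, 1] < -0.5) or np.any(verts[:, 1] > h - 0.5):
        raise GeometryError("ROI vertices fall outside the raster")
    mask = roi.contains_mask(image.shape)
    n = int(mask.sum())
    if n == 0:
        raise EmptyRegionError("ROI encloses no pixel centers")
    vals = image.pixels[mask]
    stats = RegionStats(
        mean=float(vals.mean()), min=float(vals.min()), max=float(vals.max()),
        area_px=n, area_units=n * image.pixel_area,
    )
    logger.info("region_stats roi=%s kind=%s n_px=%d mean=%.6g min=%.6g max=%.6g",
                roi.digest(), roi.kind, n, stats.mean, stats.min, stats.max)
    return stats


def mask_for(image: CalibratedImage, roi: PolygonROI) -> np.ndarray:
    """Boolean membership raster of ``roi`` on ``image``'s grid."""
    return roi.contains_mask(image.shape)


def pixel_size_from_scalebar(n_pixels: int, physical_length: float) -> float:
    """Calibration from a marked scale bar: length per pixel.

    The FIB-SEM screenshots are calibrated by marking a known run of
    pixels as a known physical length (e.g. 11 px = 100 nm).
    """
    if n_pixels < 1:
        raise ValueError("n_pixels must be >= 1")
    if not physical_length > 0:
        raise ValueError("physical_length must be positive")
    return physical_length / n_pixels


# --------------------------------------------------------------------------
# ROI serialization

def roi_to_json(roi: PolygonROI, path) -> None:
    with open(path, "w") as fh:
        json.dump({"kind": roi.kind, "vertices": roi.vertices.tolist()}, fh)


def roi_from_json(path) -> PolygonROI:
    with open(path) as fh:
        doc = json.load(fh)
    return PolygonROI(np.asarray(doc["vertices"], dtype=float), kind=doc["kind"])


def read_imagej_roi(path) -> PolygonROI:
    """Minimal reader for ImageJ binary ``.roi`` files (polygon/freehand only).

    Parses the fixed 64-byte header ("Iout" magic) followed by relative
    16-bit x then y coordinate blocks.
    """
    raw = Path(path).read_bytes()
    if raw[:4] != b"Iout":
        raise IOError(f"{path} is not an ImageJ .roi file")
    roi_type = raw[6]
    # 0 = polygon, 7 = freehand
    if roi_type not in (0, 7):
        raise IOError(f"unsupported ImageJ ROI type {roi_type}; only polygon/freehand")
    top, left, _bottom, _right, n = struct.unpack(">5h", raw[8:18])
    xs = np.frombuffer(raw, dtype=">i2", count=n, offset=64).astype(float) + left
    ys = np.frombuffer(raw, dtype=">i2", count=n, offset=64 + 2 * n).astype(float) + top
    kind = "freehand"
    return PolygonROI(np.column_stack([xs, ys]), kind=kind)


def write_imagej_roi(roi: PolygonROI, path) -> None:
    """Write a polygon as an ImageJ ``.roi`` file (integer coordinates)."""
    verts = np.round(roi.vertices).astype(int)
    left, top = verts.min(axis=0)
    right, bottom = verts.max(axis=0)
    n = len(verts)
    header = bytearray(64)
    header[0:4] = b"Iout"
    struct.pack_into(">h", header, 4, 227)  # format version
    header[6] = 0  # polygon
    struct.pack_into(">5h", header, 8, top, left, bottom, right, n)
    xs = (verts[:, 0] - left).astype(">i2").tobytes()
    ys = (verts[:, 1] - top).astype(">i2").tobytes()
    Path(path).write_bytes(bytes(header) + xs + ys)
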