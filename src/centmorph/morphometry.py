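"""Fluorescence morphometry of the centriculum, PCM and tubulin ring.

Implements the annular measurements used to size the membrane reticulum
around *C. elegans* embryonic centrosomes and the structures nested in
it:

* diameter from two perpendicular line scans (peak-to-peak distance,
  averaged as (d1+d2)/2);
* intensity-threshold masks built from region statistics — lower
  threshold (mean+min)/2 of a traced torus, (mean+max)/2 of a traced
  void, or background mean+max for the PCM; upper threshold always the
  region maximum ("Maxthr");
* the centriculum *void area* (the space enclosed by the inner edge of
  the thresholded ring) and the *gap area* (void minus PCM area);
* two independent tubulin-ring-width estimators: circle-equivalent
  radii of the outer and inner thresholded areas (R1 - R2), and the
  mean width of the four line-scan peaks at 90% of each peak's maximum.

All thresholds are closed intervals [lower, upper].  Void extraction
uses 4-connectivity for background and 8-connectivity for foreground so
a diagonal chain of ring pixels still closes the ring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.signal import find_peaks
from skimage.morphology import convex_hull_image

from .errors import (EmptyRegionError, GeometryError, OpenRingError,
                     PeakDetectionError, ThresholdInversionError,
                     TruncatedPeakError)
from .io import CalibratedImage, PolygonROI, RegionStats, mask_for, region_stats


@dataclass
class IntensityProfile:
    """Intensity along a scan line, averaged across its width.

    positions are physical distances along the scan (uniformly spaced,
    strictly increasing, centered on the scan midpoint); values are the
    width-averaged interpolated intensities.
    """

    positions: np.ndarray
    values: np.ndarray
    line_width: float
    unit: str = "um"

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) < 16:
            raise ValueError("profile needs at least 16 samples")
        d = np.diff(self.positions)
        if not (np.all(d > 0) and np.allclose(d, d[0])):
            raise ValueError("positions must be strictly increasing and uniform")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("profile values must be finite and non-negative")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.positions[0] + self.positions[-1])

    @property
    def spacing(self) -> float:
        return float(self.positions[1] - self.positions[0])


@dataclass
class DiameterMeasurement:
    d1: float
    d2: float

    @property
    def average(self) -> float:
        return 0.5 * (self.d1 + self.d2)


@dataclass
class ThresholdMask:
    """Binary raster plus the [lower, upper] rule that produced it."""

    mask: np.ndarray
    lower: float
    upper: float
    rule: str  # torus_mean_min | void_mean_max | background_mean_plus_max

    def __post_init__(self):
        if self.lower > self.upper:
            raise ThresholdInversionError(
                f"lower threshold {self.lower} exceeds upper {self.upper}")


@dataclass
class RingWidthResult:
    """Tubulin ring width by one or both estimators.

    R1/R2 are circle-equivalent radii sqrt(area/pi) of the outer and
    inner (void) thresholded areas; the line-scan width is the mean of
    the four per-peak widths at 90% of each peak's own maximum.
    """

    R1: float | None = None
    R2: float | None = None
    width_threshold: float | None = None
    width_linescan: float | None = None
    peak_widths: list[float] = field(default_factory=list)


@dataclass
class AreaIntensity:
    """Area, total raw intensity ("RawInt") and intensity density of a mask."""

    area: float
    total_intensity: float

    @property
    def density(self) -> float:
        return self.total_intensity / self.area


@dataclass
class GapArea:
    """Centriculum void area minus PCM area; negative means overlap."""

    void_area: float
    pcm_area: float

    @property
    def gap(self) -> float:
        return self.void_area - self.pcm_area

    @property
    def overlap(self) -> bool:
        return self.gap < 0


# --------------------------------------------------------------------------
# Line scans and diameters

def line_scan(image: CalibratedImage, center: tuple[float, float], angle: float,
              length: float, line_width: float) -> IntensityProfile:
    """Width-averaged intensity profile along a straight scan line.

    The scan of physical ``length`` is centered on ``center`` (pixel
    coordinates) at ``angle`` degrees from the +x axis.  Samples are
    spaced 0.5 pixel apart along the scan; at each sample the intensity
    is the mean of bilinearly interpolated values across ``line_width``
    perpendicular to the scan direction.
    """
    px = image.pixel_size
    theta = math.radians(angle)
    u = np.array([math.cos(theta), math.sin(theta)])   # along scan
    v = np.array([-math.sin(theta), math.cos(theta)])  # across scan
    step = 0.5 * px
    n_along = int(round(length / step)) + 1
    s = (np.arange(n_along) - (n_along - 1) / 2) * step
    n_across = max(1, int(round(line_width / step)) + 1)
    t = (np.arange(n_across) - (n_across - 1) / 2) * (line_width / max(n_across - 1, 1)
                                                      if n_across > 1 else 1.0)
    cx, cy = center
    # pixel displacement = physical / pixel_size
    X = cx + (s[:, None] * u[0] + t[None, :] * v[0]) / px
    Y = cy + (s[:, None] * u[1] + t[None, :] * v[1]) / px
    h, w = image.shape
    if X.min() < 0 or X.max() > w - 1 or Y.min() < 0 or Y.max() > h - 1:
        raise GeometryError("scan line (with its width) exits the raster")
    vals = ndimage.map_coordinates(image.pixels, [Y.ravel(), X.ravel()], order=1)
    profile = vals.reshape(X.shape).mean(axis=1)
    return IntensityProfile(positions=s, values=profile, line_width=line_width,
                            unit=image.unit)


def _side_peak(profile: IntensityProfile, side: str, smooth: bool = False):
    """Highest local maximum on one side of the profile midpoint.

    Plateaus count as single peaks (plateau middle).  Ties break toward
    the sample farthest from the midpoint.  Returns (position, index) or
    None.
    """
    vals = profile.values
    if smooth:
        vals = np.convolve(vals, np.ones(3) / 3, mode="same")
    idx, props = find_peaks(vals, plateau_size=1)
    mid = profile.midpoint
    pos = profile.positions[idx]
    sel = pos < mid if side == "left" else pos > mid
    idx, pos = idx[sel], pos[sel]
    if len(idx) == 0:
        return None
    heights = vals[idx]
    best = heights == heights.max()
    cand_pos = pos[best]
    cand_idx = idx[best]
    far = np.argmax(np.abs(cand_pos - mid))
    return float(cand_pos[far]), int(cand_idx[far])


def diameter_from_profiles(p1: IntensityProfile, p2: IntensityProfile,
                           smooth: bool = False) -> DiameterMeasurement:
    """Peak-to-peak diameters d1, d2 from two perpendicular profiles.

    Per profile the diameter is the distance between the highest local
    maximum left of the midpoint and the highest right of it; the
    reported centriculum diameter is the average (d1+d2)/2.
    """
    ds = []
    for p in (p1, p2):
        left = _side_peak(p, "left", smooth)
        right = _side_peak(p, "right", smooth)
        if left is None or right is None:
            raise PeakDetectionError(
                "profile lacks a qualifying peak on each side of its midpoint",
                profile=p)
        ds.append(right[0] - left[0])
    return DiameterMeasurement(d1=ds[0], d2=ds[1])


# --------------------------------------------------------------------------
# Threshold masks

def torus_threshold(image: CalibratedImage, outer: PolygonROI,
                    inner: PolygonROI) -> ThresholdMask:
    """(mean+min)/2 lower threshold from a traced torus region.

    The torus (outer polygon minus inner polygon) supplies the region
    statistics; lower = (mean+min)/2, upper = region max.  The mask
    keeps torus-ROI pixels whose intensity lies in [lower, upper].
    """
    torus = mask_for(image, outer) & ~mask_for(image, inner)
    if not torus.any():
        raise EmptyRegionError("torus region (outer minus inner) is empty")
    vals = image.pixels[torus]
    lower = 0.5 * (vals.mean() + vals.min())
    upper = float(vals.max())
    mask = torus & (image.pixels >= lower) & (image.pixels <= upper)
    return ThresholdMask(mask=mask, lower=float(lower), upper=upper,
                         rule="torus_mean_min")


def void_threshold(image: CalibratedImage, void_roi: PolygonROI) -> ThresholdMask:
    """(mean+max)/2 lower threshold from a traced void region.

    Used to locate the inner edge of the tubulin ring: the rough void
    trace overlaps the bright inner flank of the ring, so (mean+max)/2
    selects ring pixels within the trace and the enclosed sub-threshold
    region is the ring void.
    """
    roi_mask = mask_for(image, void_roi)
    if not roi_mask.any():
        raise EmptyRegionError("void ROI encloses no pixels")
    vals = image.pixels[roi_mask]
    lower = 0.5 * (vals.mean() + vals.max())
    upper = float(vals.max())
    mask = roi_mask & (image.pixels >= lower) & (image.pixels <= upper)
    return ThresholdMask(mask=mask, lower=float(lower), upper=upper,
                         rule="void_mean_max")


def pcm_threshold(image: CalibratedImage, background: PolygonROI,
                  seed_point: tuple[int, int] | None = None) -> ThresholdMask:
    """Background (mean + max) lower threshold, wand-style selection.

    lower = mean + max of a background region outside the PCM; upper =
    the image maximum.  Of the pixels in range, only the 8-connected
    component containing the seed (by default the location of the image
    maximum) is kept — the automated stand-in for ImageJ's wand tool.
    """
    bg = region_stats(image, background)
    lower = bg.mean + bg.max
    upper = float(image.pixels.max())
    if lower > upper:
        raise ThresholdInversionError(
            f"background-derived lower threshold {lower:.4g} exceeds image max {upper:.4g}")
    inrange = (image.pixels >= lower) & (image.pixels <= upper)
    labels, _ = ndimage.label(inrange, structure=np.ones((3, 3), dtype=int))
    if seed_point is None:
        seed_idx = np.unravel_index(np.argmax(image.pixels), image.shape)
    else:
        seed_idx = (int(round(seed_point[1])), int(round(seed_point[0])))
    lab = labels[seed_idx]
    if lab == 0:
        raise EmptyRegionError("seed point is not inside the thresholded region")
    return ThresholdMask(mask=labels == lab, lower=float(lower), upper=upper,
                         rule="background_mean_plus_max")


# --------------------------------------------------------------------------
# Areas and intensities

def void_area(mask: ThresholdMask, center: tuple[float, float],
              pixel_size: float) -> float:
    """Area of the void enclosed by the thresholded ring, physical units.

    The void is the 4-connected background component containing
    ``center``.  If that component reaches the raster border the ring
    is not closed and an :class:`OpenRingError` is raised.
    """
    bg = ~mask.mask
    labels, _ = ndimage.label(bg)  # 4-connected background
    cidx = (int(round(center[1])), int(round(center[0])))
    lab = labels[cidx]
    if lab == 0:
        raise OpenRingError("declared center lies on the thresholded ring itself")
    comp = labels == lab
    if comp[0, :].any() or comp[-1, :].any() or comp[:, 0].any() or comp[:, -1].any():
        raise OpenRingError("thresholded ring is not closed around the center")
    return float(comp.sum()) * pixel_size ** 2


def area_intensity(mask: ThresholdMask | np.ndarray,
                   image: CalibratedImage) -> AreaIntensity:
    """Area, summed raw intensity and density of the masked pixels."""
    m = mask.mask if isinstance(mask, ThresholdMask) else np.asarray(mask, bool)
    n = int(m.sum())
    if n == 0:
        raise EmptyRegionError("mask selects no pixels")
    total = float(image.pixels[m].sum())
    return AreaIntensity(area=n * image.pixel_area, total_intensity=total)


def intensity_within_outline(outline: PolygonROI,
                             other: CalibratedImage) -> AreaIntensity:
    """Total raw intensity of a co-registered channel inside an outline.

    The outline is typically the outer edge of the centriculum traced
    on one channel; ``other`` is the tubulin channel measured in place.
    """
    h, w = other.shape
    verts = outline.vertices
    if np.any(verts[:, 0] < -0.5) or np.any(verts[:, 0] > w - 0.5) or \
       np.any(verts[:, 1] < -0.5) or np.any(verts[:, 1] > h - 0.5):
        raise GeometryError("outline falls outside the raster")
    m = mask_for(other, outline)
    if not m.any():
        raise EmptyRegionError("outline encloses no pixels")
    return AreaIntensity(area=int(m.sum()) * other.pixel_area,
                         total_intensity=float(other.pixels[m].sum()))


def mt_ring_area(image: CalibratedImage, outer: PolygonROI, inner: PolygonROI,
                 spindle_exclusion: PolygonROI | None = None) -> float:
    """Area enclosed by the outer edge of the peri-centrosomal MT ring.

    Tubulin-ring thresholding as in :func:`torus_threshold`; pixels in
    the spindle-exclusion polygon are removed before measurement so
    spindle signal is never picked up.  The outer edge is reconstructed
    across the excluded wedge by the convex closure of the surviving
    mask, and its enclosed area returned in physical units.
    """
    tm = torus_threshold(image, outer, inner)
    mask = tm.mask
    if spindle_exclusion is not None:
        mask = mask & ~mask_for(image, spindle_exclusion)
    if not mask.any():
        raise EmptyRegionError("no ring pixels survive the spindle exclusion")
    hull = convex_hull_image(mask)
    return float(hull.sum()) * image.pixel_area


# --------------------------------------------------------------------------
# Ring width estimators

def ring_width_threshold(outer_area: float, void_area: float) -> RingWidthResult:
    """Ring width from circle-equivalent radii of outer and void areas.

    Both areas are treated as perfect circles: R1 = sqrt(outer/pi),
    R2 = sqrt(void/pi), width = R1 - R2.  Applied as stated even to
    non-circular masks (a documented bias source; no ellipse fitting).
    """
    if outer_area < void_area:
        raise ValueError("outer_area must be >= void_area (check argument order)")
    if void_area < 0:
        raise ValueError("areas must be non-negative")
    r1 = math.sqrt(outer_area / math.pi)
    r2 = math.sqrt(void_area / math.pi)
    return RingWidthResult(R1=r1, R2=r2, width_threshold=r1 - r2)


def _peak_width_at_fraction(profile: IntensityProfile, peak_idx: int,
                            fraction: float = 0.9) -> float:
    """Width of one peak at ``fraction`` of its own maximum.

    Walks outward from the peak sample in both directions to the first
    samples below the level and locates the crossings by linear
    interpolation.  The peak is normalized to its own maximum.
    """
    vals = profile.values
    pos = profile.positions
    level = fraction * vals[peak_idx]
    xs = []
    for stepdir in (-1, +1):
        i = peak_idx
        while 0 <= i + stepdir < len(vals) and vals[i + stepdir] >= level:
            i += stepdir
        j = i + stepdir
        if j < 0 or j >= len(vals):
            raise TruncatedPeakError(
                f"{int(fraction*100)}%-of-max level never crossed on one side of the peak")
        # linear interpolation between samples i (>= level) and j (< level)
        frac = (vals[i] - level) / (vals[i] - vals[j])
        xs.append(pos[i] + frac * (pos[j] - pos[i]))
    return float(abs(xs[1] - xs[0]))


def ring_width_linescan(p1: IntensityProfile, p2: IntensityProfile,
                        fraction: float = 0.9) -> RingWidthResult:
    """Ring width as the mean of the four 90%-of-max peak widths.

    Each profile crosses the ring twice, giving four peaks in total;
    each peak is normalized to its own maximum and its width read at
    90% of that maximum (chosen because the trough between the two
    peaks of a tubulin-ring scan typically sits near 85% of max).
    """
    widths = []
    for p in (p1, p2):
        for side in ("left", "right"):
            found = _side_peak(p, side)
            if found is None:
                raise PeakDetectionError(
                    "profile lacks the two peaks needed for line-scan widths",
                    profile=p)
            widths.append(_peak_width_at_fraction(p, found[1], fraction))
    return RingWidthResult(width_linescan=float(np.mean(widths)),
                           peak_widths=widths)


def gap_area(void: float, pcm: float) -> GapArea:
    """Gap between centriculum void and PCM: void area minus PCM area.

    Negative values are permitted and flagged — they arise when the
    PCM signal overlaps the centriculum ring.
    """
    if void < 0 or pcm < 0:
        raise ValueError("areas must be non-negative")
    return GapArea(void_area=void, pcm_area=pcm)
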