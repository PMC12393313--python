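"""End-to-end measurement recipes combining the low-level operations.

These are the unattended equivalents of the manual workflows: given a
scene's channels and rough ROI traces, measure centriculum diameter,
void area, PCM area/intensity, tubulin-ring widths by both estimators,
and the void/PCM gap.
"""

from __future__ import annotations

import math

from . import morphometry as mm
from .io import CalibratedImage, PolygonROI


def measure_diameter(image: CalibratedImage, center: tuple[float, float],
                     length: float, line_width: float = 1.0,
                     angle: float = 0.0) -> mm.DiameterMeasurement:
    """Diameter from two perpendicular line scans through ``center``."""
    p1 = mm.line_scan(image, center, angle, length, line_width)
    p2 = mm.line_scan(image, center, angle + 90.0, length, line_width)
    return mm.diameter_from_profiles(p1, p2)


def measure_void(image: CalibratedImage, outer: PolygonROI, inner: PolygonROI,
                 center: tuple[float, float]) -> float:
    """Centriculum void area via the torus (mean+min)/2 threshold."""
    tm = mm.torus_threshold(image, outer, inner)
    return mm.void_area(tm, center, image.pixel_size)


def measure_pcm(image: CalibratedImage, background: PolygonROI,
                seed_point=None) -> mm.AreaIntensity:
    """PCM area and total intensity via the background mean+max threshold."""
    tm = mm.pcm_threshold(image, background, seed_point=seed_point)
    return mm.area_intensity(tm, image)


def measure_gap(centriculum: CalibratedImage, pcm: CalibratedImage,
                torus_outer: PolygonROI, torus_inner: PolygonROI,
                background: PolygonROI,
                center: tuple[float, float]) -> mm.GapArea:
    """Gap area: centriculum void minus PCM area, from two channels."""
    void = measure_void(centriculum, torus_outer, torus_inner, center)
    pcm_ai = measure_pcm(pcm, background)
    return mm.gap_area(void, pcm_ai.area)


def measure_ring_width(tubulin: CalibratedImage, torus_outer: PolygonROI,
                       torus_inner: PolygonROI, void_roi: PolygonROI,
                       center: tuple[float, float], scan_length: float,
                       line_width: float = 1.0,
                       spindle_exclusion: PolygonROI | None = None) -> mm.RingWidthResult:
    """Tubulin ring width by both estimators on one channel.

    Threshold route: R1 from the area enclosed by the outer edge of the
    thresholded ring (spindle excluded if given), R2 from the
    (mean+max)/2 void threshold.  Line-scan route: mean of the four
    90%-of-max peak widths from two perpendicular scans.
    """
    outer_area = mm.mt_ring_area(tubulin, torus_outer, torus_inner,
                                 spindle_exclusion)
    vt = mm.void_threshold(tubulin, void_roi)
    inner_area = mm.void_area(vt, center, tubulin.pixel_size)
    thr = mm.ring_width_threshold(outer_area, inner_area)

    p1 = mm.line_scan(tubulin, center, 0.0, scan_length, line_width)
    p2 = mm.line_scan(tubulin, center, 90.0, scan_length, line_width)
    ls = mm.ring_width_linescan(p1, p2)
    return mm.RingWidthResult(R1=thr.R1, R2=thr.R2,
                              width_threshold=thr.width_threshold,
                              width_linescan=ls.width_linescan,
                              peak_widths=ls.peak_widths)
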