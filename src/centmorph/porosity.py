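"""Porosity of segmented centriculum membrane panels.

A panel is a binary projection of FIB-SEM-segmented membrane viewed
from inside the centrosome: foreground = membrane, background =
openings ("holes") through which a microtubule could pass.  This
module measures each hole's area, the open-area fraction of the panel,
the passability cutoff for a 25-nm microtubule, the binned hole-size
distribution, and the en-face viewing-angle restriction applied when
the panels were captured.

Holes are 4-connected and the membrane 8-connected, so two openings
meeting only at a pixel corner stay distinct.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.segmentation import clear_border

from .errors import DegeneratePanelError, EmptyRegionError, GeometryError

# Bin edges of the hole-size frequency distribution (nm^2):
# 500-wide up to 1000, then 1000-wide up to 10000, then overflow.
BIN_EDGES = [0.0, 500.0, 1000.0] + [float(e) for e in range(2000, 10001, 1000)] + [math.inf]


@dataclass
class MembranePanel:
    """Binary membrane raster with nm/px calibration and metadata labels.

    ``side`` and ``phase`` (cortical/pronuclear, prometaphase/metaphase)
    are carried to reports but never used in computation.
    """

    mask: np.ndarray  # True = membrane, False = opening
    pixel_size: float  # nm per pixel
    side: str = "cortical"
    phase: str = "metaphase"

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise GeometryError("panel mask must be 2-D")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.mask.all() or not self.mask.any():
            raise DegeneratePanelError("panel must contain both membrane and openings")

    @property
    def panel_area(self) -> float:
        """Total imaged area in nm^2."""
        return self.mask.size * self.pixel_size ** 2


@dataclass
class HoleSet:
    """Per-hole areas (nm^2) on one panel."""

    areas: np.ndarray
    panel_area: float
    side: str = "cortical"
    phase: str = "metaphase"

    def __post_init__(self):
        self.areas = np.asarray(self.areas, dtype=float)
        if np.any(self.areas <= 0):
            raise ValueError("hole areas must be positive")
        if self.areas.sum() > self.panel_area:
            raise ValueError("total hole area cannot exceed the panel area")

    @property
    def n(self) -> int:
        return len(self.areas)

    @property
    def open_fraction(self) -> float:
        """Percent of the panel that is open (sum of hole areas / panel area)."""
        return 100.0 * float(self.areas.sum()) / self.panel_area


@dataclass
class BinnedDistribution:
    """Hole-size histogram on the fixed nm^2 bin scheme.

    counts_percent: % of holes falling in each bin; area_percent: % of
    the total open area contributed by each bin.  Bins are right-closed,
    (0,500], (500,1000], (1000,2000], ..., (9000,10000], (10000, inf).
    """

    bin_edges: list[float] = field(default_factory=lambda: list(BIN_EDGES))
    counts: np.ndarray = None
    bin_areas: np.ndarray = None

    @property
    def counts_percent(self) -> np.ndarray:
        return 100.0 * self.counts / self.counts.sum()

    @property
    def area_percent(self) -> np.ndarray:
        return 100.0 * self.bin_areas / self.bin_areas.sum()

    @property
    def labels(self) -> list[str]:
        out = []
        for lo, hi in zip(self.bin_edges[:-1], self.bin_edges[1:]):
            out.append(f">{lo:.0f}" if math.isinf(hi) else f"{lo:.0f}-{hi:.0f}")
        return out


@dataclass
class ViewingAngleCheck:
    """En-face check: angle between the center plane and a panel edge."""

    angle: float
    limit: float = 30.0

    @property
    def passed(self) -> bool:
        return self.angle < self.limit


def extract_holes(panel: MembranePanel, border_policy: str = "exclude") -> HoleSet:
    """Detect and measure every hole on a membrane panel.

    Holes are 4-connected background components.  With the default
    ``border_policy="exclude"`` components touching the raster border
    are dropped (their true extent is unknown in a cropped panel).
    No minimum-size floor is applied: single-pixel holes are retained
    so the binned distribution sees the full size range.
    """
    if border_policy not in {"exclude", "include"}:
        raise ValueError("border_policy must be 'exclude' or 'include'")
    openings = ~panel.mask
    labels, _ = ndimage.label(openings)  # 4-connected
    if border_policy == "exclude":
        labels = clear_border(labels)
    counts = np.bincount(labels.ravel())
    areas = counts[1:][counts[1:] > 0].astype(float) * panel.pixel_size ** 2
    return HoleSet(areas=np.sort(areas), panel_area=panel.panel_area,
                   side=panel.side, phase=panel.phase)


def min_passable_area(mt_diameter: float = 25.0) -> float:
    """Smallest circular hole a microtubule of given diameter fits through.

    pi * (d/2)^2; for the canonical 25-nm microtubule this is
    ~490.87 nm^2 (reported truncated to 490 nm^2), and in practice a
    lower bound since real holes are not perfect circles.
    """
    if not mt_diameter > 0:
        raise ValueError("mt_diameter must be positive")
    return math.pi * (mt_diameter / 2.0) ** 2


def as_printed(area: float) -> int:
    """Truncate an area to the integer nm^2 used in reported text."""
    return int(area)


def passable_holes(holes: HoleSet, cutoff: float) -> HoleSet:
    """Holes at least ``cutoff`` nm^2, open fraction over the same panel."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    keep = holes.areas[holes.areas >= cutoff]
    return HoleSet(areas=keep, panel_area=holes.panel_area,
                   side=holes.side, phase=holes.phase)


def bin_distribution(holes: HoleSet) -> BinnedDistribution:
    """Bin hole areas on the fixed scheme and express as percentages."""
    if holes.n == 0:
        raise EmptyRegionError("cannot bin an empty hole set")
    inner = np.asarray(BIN_EDGES[1:-1])
    # bin i holds areas a with edges[i] < a <= edges[i+1]
    idx = np.searchsorted(inner, holes.areas, side="left")
    nbins = len(BIN_EDGES) - 1
    counts = np.bincount(idx, minlength=nbins).astype(float)
    bin_areas = np.bincount(idx, weights=holes.areas, minlength=nbins)
    return BinnedDistribution(counts=counts, bin_areas=bin_areas)


def viewing_angle(center_fiducial, edge_fiducial, plane_normal,
                  limit: float = 30.0) -> ViewingAngleCheck:
    """Angle between the center-to-edge fiducial line and the center plane.

    The panels must be captured close to en face: the line from the
    central fiducial to a fiducial on the top or bottom edge of the
    image may deviate from the central plane by less than ``limit``
    degrees (default 30).
    """
    c = np.asarray(center_fiducial, dtype=float)
    e = np.asarray(edge_fiducial, dtype=float)
    n = np.asarray(plane_normal, dtype=float)
    d = e - c
    if np.linalg.norm(d) == 0:
        raise GeometryError("center and edge fiducials coincide")
    if np.linalg.norm(n) == 0:
        raise GeometryError("plane normal must be non-zero")
    sin_phi = abs(np.dot(d, n)) / (np.linalg.norm(d) * np.linalg.norm(n))
    angle = math.degrees(math.asin(min(1.0, sin_phi)))
    return ViewingAngleCheck(angle=angle, limit=limit)
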