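"""Synthetic microscopy scenes with exact ground truth.

Every input class the measurement stages consume can be generated
here with a known truth record, so the full pipeline is testable
without any acquired data:

* annular fluorescent rings (rectangular or Gaussian radial profile)
  with optional Poisson shot noise followed by Gaussian read noise;
* three-channel centrosome scenes — centriculum ring, nested PCM disk
  and tubulin ring — with a designed void/PCM gap, plus the torus,
  background and void ROIs needed to run the measurements unattended;
* binary membrane panels whose holes are non-overlapping discs drawn
  from a lognormal area distribution until a target open fraction is
  reached, with exact rasterized per-hole areas as truth;
* microtubule slab fields with stopped/continuing mixtures and
  half-normal angular spread about the radial vector.

All generators are seed-deterministic: same spec + seed, same bits.
Defaults emulate the metaphase 1-cell C. elegans geometry: a ~3.4 um
centriculum ring (void radius 1.5 um) at 0.05-0.1 um/px, panels at
100/11 nm/px with ~7.85% open area on the cortical side, and slabs of
106 stopped / 21 continuing microtubules about 1 um thick.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import GeometryError, PackingError
from .io import CalibratedImage, PolygonROI
from .mt_angles import BoundaryLine, MicrotubuleTrace
from .porosity import MembranePanel, HoleSet


# --------------------------------------------------------------------------
# Specs

@dataclass
class RingSpec:
    """Designed annulus: diameter measured peak-to-peak (ring centerline)."""

    diameter: float = 3.4        # um
    radial_profile: str = "rectangular"  # or "gaussian"
    width_param: float = 0.4     # full width (rectangular) or sd (gaussian), um
    peak_intensity: float = 100.0
    background: float = 5.0
    noise: str = "none"          # none | gaussian | poisson | poisson+gaussian
    noise_sd: float = 2.0        # read-noise sd, used by gaussian noise

    def __post_init__(self):
        if self.radial_profile not in {"rectangular", "gaussian"}:
            raise ValueError("radial_profile must be rectangular or gaussian")
        if not self.diameter > self.width_param:
            raise ValueError("diameter must exceed width_param")
        if not self.peak_intensity > self.background >= 0:
            raise ValueError("require peak_intensity > background >= 0")


@dataclass
class SceneSpec:
    """Three-channel centrosome scene with a designed void/PCM gap."""

    centriculum: RingSpec = field(default_factory=RingSpec)
    pcm_radius: float = 1.27     # um; < void radius leaves a positive gap
    pcm_intensity: float = 80.0
    tubulin: RingSpec = field(
        default_factory=lambda: RingSpec(diameter=2.6, width_param=0.5,
                                         peak_intensity=90.0))
    seed: int = 0

    @property
    def void_radius(self) -> float:
        """Inner radius of the centriculum ring (edge of the void)."""
        c = self.centriculum
        if c.radial_profile == "rectangular":
            return c.diameter / 2 - c.width_param / 2
        return c.diameter / 2  # gaussian ring: void bounded by the centerline

    @property
    def gap_truth(self) -> float:
        """Designed gap area: pi (r_void^2 - r_pcm^2), um^2 (may be < 0)."""
        return math.pi * (self.void_radius ** 2 - self.pcm_radius ** 2)


@dataclass
class PanelSpec:
    """Membrane panel with lognormal hole areas and a target open fraction.

    Defaults emulate the cortical side at metaphase: ~7.85% open, most
    holes below the 500 nm^2 passability scale.
    """

    panel_size: tuple[int, int] = (2000, 2000)  # nm (height, width)
    pixel_size: float = 100.0 / 11.0            # nm/px, scale-bar calibration
    hole_areas: str = "lognormal"               # or "fixed"
    fixed_areas: tuple = ()                     # nm^2, used when hole_areas="fixed"
    lognormal_median: float = 400.0             # nm^2
    lognormal_sigma: float = 1.2                # sd of log area
    target_open_fraction: float = 7.85          # percent
    side: str = "cortical"
    phase: str = "metaphase"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.target_open_fraction <= 60:
            raise ValueError("target_open_fraction must be in (0, 60] percent")

    @classmethod
    def for_side(cls, side: str, seed: int = 0) -> "PanelSpec":
        """Conditions emulating one side of the metaphase centriculum.

        Cortical: ~7.85% open, mostly sub-500 nm^2 holes.  Pronuclear:
        ~20.66% open with much larger holes (most of the open area in
        holes over 10,000 nm^2) — large holes are also what makes a 20%
        open fraction packable at all.
        """
        if side == "cortical":
            return cls(side="cortical", seed=seed)
        if side == "pronuclear":
            return cls(panel_size=(3000, 3000), lognormal_median=2500.0,
                       lognormal_sigma=1.5, target_open_fraction=20.66,
                       side="pronuclear", seed=seed)
        raise ValueError("side must be 'cortical' or 'pronuclear'")


@dataclass
class SlabSpec:
    """Microtubule slab field; counts default to the cortical-side data."""

    n_stopped: int = 106
    n_continuing: int = 21
    stopped_angle_sd: float = 25.0    # degrees
    continuing_angle_sd: float = 8.0  # degrees
    slab_width: float = 1000.0        # nm between interior and exterior edges
    seed: int = 0

    def __post_init__(self):
        if self.n_stopped < 0 or self.n_continuing < 0:
            raise ValueError("counts must be non-negative")
        if not (self.stopped_angle_sd > 0 and self.continuing_angle_sd > 0):
            raise ValueError("angle sds must be positive")


# --------------------------------------------------------------------------
# Ring images and scenes

def _radial_grid(image_size: int, center: tuple[float, float],
                 pixel_size: float) -> np.ndarray:
    y, x = np.mgrid[0:image_size, 0:image_size]
    return np.hypot(x - center[0], y - center[1]) * pixel_size


def _apply_noise(img: np.ndarray, spec: RingSpec, rng: np.random.Generator) -> np.ndarray:
    out = img
    if "poisson" in spec.noise:
        out = rng.poisson(out).astype(float)
    if "gaussian" in spec.noise:
        out = out + rng.normal(0.0, spec.noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def make_ring_image(spec: RingSpec, image_size: int = 128, pixel_size: float = 0.1,
                    seed: int = 0, center: tuple[float, float] | None = None):
    """Render a radially symmetric annulus; returns (image, truth dict).

    The default center sits slightly off the pixel lattice so that
    rasterization artifacts of exactly centered circles never flatter
    the downstream measurements.
    """
    if center is None:
        c = (image_size - 1) / 2
        center = (c + 0.17, c - 0.23)
    if spec.radial_profile == "rectangular":
        r_outer = spec.diameter / 2 + spec.width_param / 2
    else:
        r_outer = spec.diameter / 2 + 4 * spec.width_param
    extent = min(center[0], center[1],
                 image_size - 1 - center[0], image_size - 1 - center[1]) * pixel_size
    if r_outer > extent - 5 * pixel_size:
        raise GeometryError("ring does not fit in the image with a 5-pixel margin")
    r = _radial_grid(image_size, center, pixel_size)
    if spec.radial_profile == "rectangular":
        band = np.abs(r - spec.diameter / 2) <= spec.width_param / 2
        img = np.where(band, spec.peak_intensity, spec.background).astype(float)
        r_inner = spec.diameter / 2 - spec.width_param / 2
    else:
        img = spec.background + (spec.peak_intensity - spec.background) * np.exp(
            -0.5 * ((r - spec.diameter / 2) / spec.width_param) ** 2)
        r_inner = None
    rng = np.random.default_rng(seed)
    if spec.noise != "none":
        img = _apply_noise(img, spec, rng)
    image = CalibratedImage(img, pixel_size=pixel_size, unit="um", channel="ring")
    truth = {
        "center": center,
        "diameter": spec.diameter,
        "width": spec.width_param,
        "profile": spec.radial_profile,
        "r_inner": r_inner,
        "r_outer": spec.diameter / 2 + spec.width_param / 2
        if spec.radial_profile == "rectangular" else None,
        "void_area": math.pi * r_inner ** 2 if r_inner is not None else None,
    }
    return image, truth


def _circle_roi(center, radius_px, kind, n_vertices=64) -> PolygonROI:
    ang = np.linspace(0, 2 * math.pi, n_vertices, endpoint=False)
    verts = np.column_stack([center[0] + radius_px * np.cos(ang),
                             center[1] + radius_px * np.sin(ang)])
    return PolygonROI(verts, kind=kind)


def make_scene(spec: SceneSpec, image_size: int = 160, pixel_size: float = 0.05):
    """Render the co-registered centriculum / PCM / tubulin channels.

    Returns ``(channels, rois, truth)``: channels is a dict with keys
    ``"centriculum"``, ``"pcm"``, ``"tubulin"``; rois holds the rough
    traces a user of the real workflow would draw (centriculum torus
    outer/inner, background patch, tubulin void trace); truth records
    the designed void area, PCM area, gap and ring geometry.
    """
    c = (image_size - 1) / 2
    center = (c + 0.17, c - 0.23)
    cent_img, cent_truth = make_ring_image(spec.centriculum, image_size,
                                           pixel_size, spec.seed, center)
    cent_img.channel = "mCherry::SP12"

    r = _radial_grid(image_size, center, pixel_size)
    pcm = np.where(r <= spec.pcm_radius, spec.pcm_intensity, 2.0).astype(float)
    pcm_img = CalibratedImage(pcm, pixel_size=pixel_size, unit="um",
                              channel="GFP::SPD-5")

    tub_img, tub_truth = make_ring_image(spec.tubulin, image_size, pixel_size,
                                         spec.seed + 1, center)
    tub_img.channel = "GFP::TBA-2"

    px = pixel_size
    r_inner_px = cent_truth["r_inner"] / px
    r_outer_px = cent_truth["r_outer"] / px
    rois = {
        "torus_outer": _circle_roi(center, r_outer_px + 4, "torus_outer"),
        "torus_inner": _circle_roi(center, max(2.0, r_inner_px - 4), "torus_inner"),
        "background": PolygonROI(
            [[2, 2], [14, 2], [14, 14], [2, 14]], kind="background"),
        "tubulin_void": _circle_roi(
            center, (spec.tubulin.diameter / 2) / px, "freehand"),
        "tubulin_torus_outer": _circle_roi(
            center, (spec.tubulin.diameter / 2 + spec.tubulin.width_param / 2) / px + 4,
            "torus_outer"),
        "tubulin_torus_inner": _circle_roi(
            center, max(2.0, (spec.tubulin.diameter / 2 - spec.tubulin.width_param / 2) / px - 4),
            "torus_inner"),
    }
    truth = {
        "center": center,
        "void_radius": spec.void_radius,
        "void_area": math.pi * spec.void_radius ** 2,
        "pcm_radius": spec.pcm_radius,
        "pcm_area": math.pi * spec.pcm_radius ** 2,
        "gap": spec.gap_truth,
        "centriculum": cent_truth,
        "tubulin": tub_truth,
    }
    channels = {"centriculum": cent_img, "pcm": pcm_img, "tubulin": tub_img}
    return channels, rois, truth


# --------------------------------------------------------------------------
# Membrane panels

def make_panel(spec: PanelSpec, max_attempts: int = 10_000):
    """Pack non-overlapping disc holes into a membrane panel.

    Hole areas are drawn from the spec's distribution and rasterized as
    discs until the rasterized open fraction is within 0.5 percentage
    points of the target.  Hole centers keep a separation of the two
    radii plus 1.5 px, which guarantees at least one full membrane
    pixel between any two holes, so 4-connected labeling recovers each
    one exactly.  ``max_attempts`` bounds *rejected* placements.
    Returns ``(panel, truth_holes)`` where the truth areas are the
    exact rasterized areas in nm^2.

    High open fractions need correspondingly large holes (or panels):
    the separation overhead scales with hole perimeter, so packing 20%
    open area out of sub-500 nm^2 holes is geometrically infeasible —
    mirroring the real panels, where the high-porosity pronuclear side
    is dominated by holes over 10,000 nm^2.
    """
    rng = np.random.default_rng(spec.seed)
    px = spec.pixel_size
    h = int(round(spec.panel_size[0] / px))
    w = int(round(spec.panel_size[1] / px))
    mask = np.ones((h, w), dtype=bool)  # all membrane
    panel_area = h * w * px ** 2
    target = spec.target_open_fraction

    if spec.hole_areas == "fixed":
        queue = list(spec.fixed_areas)

    placed = []  # (cx, cy, r_px)
    truth_areas = []
    open_area = 0.0
    attempts = 0
    margin = 3
    while True:
        frac = 100.0 * open_area / panel_area
        if frac >= target - 0.5:
            break
        if attempts >= max_attempts:
            raise PackingError(
                f"could not reach {target}% open after {max_attempts} rejections",
                achieved_fraction=frac)
        if spec.hole_areas == "fixed":
            if not queue:
                break
            area = queue[0]
        else:
            area = float(rng.lognormal(math.log(spec.lognormal_median),
                                       spec.lognormal_sigma))
        r_px = math.sqrt(area / math.pi) / px
        cx = rng.uniform(margin + r_px, w - 1 - margin - r_px)
        cy = rng.uniform(margin + r_px, h - 1 - margin - r_px)
        if any(math.hypot(cx - ox, cy - oy) < r_px + orr + 1.5
               for ox, oy, orr in placed):
            attempts += 1
            continue
        lo_y, hi_y = max(0, int(cy - r_px) - 1), min(h, int(cy + r_px) + 2)
        lo_x, hi_x = max(0, int(cx - r_px) - 1), min(w, int(cx + r_px) + 2)
        yy, xx = np.mgrid[lo_y:hi_y, lo_x:hi_x]
        disc_local = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px ** 2
        disc = np.zeros((h, w), bool)
        disc[lo_y:hi_y, lo_x:hi_x] = disc_local
        n_px = int(disc.sum())
        if n_px == 0:  # sub-pixel hole: carve the nearest single pixel
            disc[int(round(cy)), int(round(cx))] = True
            n_px = 1
        rast_area = n_px * px ** 2
        if frac + 100.0 * rast_area / panel_area > target + 0.5:
            attempts += 1
            continue  # would overshoot; try a different (smaller) hole
        mask[disc] = False
        placed.append((cx, cy, r_px))
        truth_areas.append(rast_area)
        open_area += rast_area
        if spec.hole_areas == "fixed":
            queue.pop(0)

    panel = MembranePanel(mask=mask, pixel_size=px, side=spec.side, phase=spec.phase)
    truth = HoleSet(areas=np.sort(np.asarray(truth_areas)), panel_area=panel_area,
                    side=spec.side, phase=spec.phase)
    return panel, truth


# --------------------------------------------------------------------------
# Microtubule slabs

def make_slab(spec: SlabSpec):
    """Generate a slab of microtubule traces with known truth.

    The interior edge is the x-axis (also the tangent line) and the
    exterior edge is parallel at ``slab_width``; the radial vector is
    +y.  Angles to the radial vector are drawn as |Normal(0, sd)|
    resampled to stay below 90 deg.  Stopped traces terminate uniformly
    within the central 10-90% of the slab; continuing traces cross the
    exterior edge by a random margin.

    Returns ``(traces, interior, exterior, truth)`` where truth is a
    list of ``(category, angle)`` tuples aligned with the traces.
    """
    rng = np.random.default_rng(spec.seed)
    interior = BoundaryLine(point=(0.0, 0.0), direction=(1.0, 0.0),
                            role="interior_edge")
    exterior = BoundaryLine(point=(0.0, spec.slab_width), direction=(1.0, 0.0),
                            role="exterior_edge")
    traces, truth = [], []
    plan = [("stopped", spec.stopped_angle_sd)] * spec.n_stopped + \
           [("continuing", spec.continuing_angle_sd)] * spec.n_continuing
    for category, sd in plan:
        angle = abs(rng.normal(0.0, sd))
        while angle >= 90.0:
            angle = abs(rng.normal(0.0, sd))
        sign = rng.choice([-1.0, 1.0])
        th = math.radians(angle)
        d = np.array([sign * math.sin(th), math.cos(th)])  # unit, +y radial
        x0 = rng.uniform(-2000.0, 2000.0)
        y0 = -rng.uniform(50.0, 200.0)
        start = np.array([x0, y0])
        if category == "continuing":
            y_end = spec.slab_width + rng.uniform(50.0, 300.0)
        else:
            y_end = rng.uniform(0.1, 0.9) * spec.slab_width
        t = (y_end - y0) / d[1]
        end = start + t * d
        traces.append(MicrotubuleTrace(start=tuple(start), end=tuple(end)))
        truth.append((category, angle))
    return traces, interior, exterior, truth
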