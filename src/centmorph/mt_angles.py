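"""Stopped-vs-continuing classification of microtubule traces.

Each trace is a straight line segment crossing the interior edge of
the centriculum, annotated with whether the same microtubule is seen
in the slabs above or below the analysed one.  Two straight boundary
lines approximate the (locally flat) interior and exterior edges of
the centriculum; the interior line doubles as the local tangent.

A trace that reaches or crosses the exterior line is *continuing*; one
that terminates strictly between the lines and is absent from the
adjacent slabs is *stopped*; one that reappears in an adjacent slab is
*excluded* from the angle statistics.

The reported angle is measured to the radial vector (the normal of the
tangent line): 0 deg is the shortest path through the centriculum,
90 deg runs parallel to the membrane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import GeometryError, IneligibleTraceError, InsufficientDataError

_TOL = 1e-9


@dataclass
class BoundaryLine:
    """An infinite line: a point on it plus a unit direction vector."""

    point: tuple[float, float]
    direction: tuple[float, float]
    role: str = "interior_edge"  # or exterior_edge

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise GeometryError("boundary line direction must be non-zero")
        self.direction = tuple(d / norm)
        self.point = tuple(float(c) for c in self.point)

    def signed_offset(self, p) -> float:
        """Signed distance of a point from the line (left of direction > 0)."""
        dx, dy = self.direction
        px, py = self.point
        return (p[0] - px) * (-dy) + (p[1] - py) * dx


@dataclass
class MicrotubuleTrace:
    start: tuple[float, float]
    end: tuple[float, float]
    slab_id: str = ""
    present_above: bool = False
    present_below: bool = False

    def __post_init__(self):
        s = np.asarray(self.start, float)
        e = np.asarray(self.end, float)
        if not (np.all(np.isfinite(s)) and np.all(np.isfinite(e))):
            raise GeometryError("trace endpoints must be finite")
        if np.allclose(s, e):
            raise GeometryError("trace must have distinct endpoints")


@dataclass
class MTClassification:
    category: str  # stopped | continuing | excluded
    angle_to_radial: float | None = None


def angle_to_radial(trace: MicrotubuleTrace, tangent: BoundaryLine) -> float:
    """Angle between the trace and the radial vector, in [0, 90] degrees.

    The acute angle between the trace and the tangent line is taken and
    subtracted from 90, so the result is the angle to the normal of the
    centriculum edge.  Invariant to reversing either direction vector.
    """
    d = np.asarray(trace.end, float) - np.asarray(trace.start, float)
    nd = np.linalg.norm(d)
    if nd == 0:
        raise GeometryError("zero-length trace has no direction")
    t = np.asarray(tangent.direction, float)
    cos_t = min(1.0, abs(float(np.dot(d, t))) / nd)
    theta_tangent = math.degrees(math.acos(cos_t))
    return 90.0 - theta_tangent


def classify_trace(trace: MicrotubuleTrace, interior: BoundaryLine,
                   exterior: BoundaryLine) -> MTClassification:
    """Classify one trace as stopped, continuing or excluded.

    The trace must cross the interior edge.  It is *continuing* if it
    reaches or crosses the exterior line on the side away from the
    interior (an endpoint exactly on the exterior line, within 1e-9,
    counts as continuing).  Otherwise it is *excluded* if flagged
    present in an adjacent slab, else *stopped*.
    """
    s_i = interior.signed_offset(trace.start)
    e_i = interior.signed_offset(trace.end)
    crosses = min(s_i, e_i) <= _TOL and max(s_i, e_i) >= -_TOL
    if not crosses:
        raise IneligibleTraceError("trace does not cross the interior edge")

    # side of the exterior line away from the interior line
    interior_side = exterior.signed_offset(interior.point)
    if abs(interior_side) <= _TOL:
        raise GeometryError("interior and exterior edges coincide")
    far_sign = -math.copysign(1.0, interior_side)
    reach = max(far_sign * exterior.signed_offset(trace.start),
                far_sign * exterior.signed_offset(trace.end))
    if reach >= -_TOL:
        category = "continuing"
    elif trace.present_above or trace.present_below:
        category = "excluded"
    else:
        category = "stopped"
    return MTClassification(category=category,
                            angle_to_radial=round(angle_to_radial(trace, interior), 10))


def angle_summary(classifications: list[MTClassification], compare: bool = True):
    """Per-category angle statistics, with a stopped-vs-continuing test.

    Excluded traces are omitted.  Returns a dict with ``"stopped"`` and
    ``"continuing"`` entries (mean, sd, n, angles) and, when both
    categories have at least two traces and ``compare`` is True, a
    ``"comparison"`` entry from the two-group auto test.
    """
    from .stats import GroupSample, compare_two

    groups = {}
    for cat in ("stopped", "continuing"):
        angles = np.array([c.angle_to_radial for c in classifications
                           if c.category == cat], dtype=float)
        if len(angles) < 2:
            raise InsufficientDataError(
                f"need at least 2 '{cat}' traces, got {len(angles)}")
        groups[cat] = {
            "n": len(angles),
            "mean": float(angles.mean()),
            "sd": float(angles.std(ddof=1)),
            "angles": angles,
        }
    out = dict(groups)
    if compare:
        out["comparison"] = compare_two(
            GroupSample("stopped", groups["stopped"]["angles"]),
            GroupSample("continuing", groups["continuing"]["angles"]))
    return out
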