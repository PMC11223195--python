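"""Small geometric helpers shared across modules."""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation


def angle_between(v1: np.ndarray, v2: np.ndarray) -> float:
    """Angle between two 3-vectors in degrees, in [0, 180]."""
    n1 = np.linalg.norm(v1)
    n2 = np.linalg.norm(v2)
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("angle undefined for zero-length vector")
    c = float(np.dot(v1, v2) / (n1 * n2))
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


def rotation_about_axis(axis: np.ndarray, angle_deg: float) -> Rotation:
    """Right-handed rotation by ``angle_deg`` about (non-unit) ``axis``."""
    a = np.asarray(axis, dtype=float)
    n = np.linalg.norm(a)
    if n == 0.0:
        raise ValueError("rotation axis must be non-zero")
    return Rotation.from_rotvec(np.deg2rad(angle_deg) * a / n)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal round-half-up (0.5 always rounds away from zero).

    Plain ``round`` uses banker's rounding, which disagrees with the
    convention used for reported occupancy tables (e.g. 71.35 -> 71.4).
    """
    q = Decimal(1).scaleb(-ndigits)
    # go through a short repr to strip float noise such as 71.35000000000001
    return float(Decimal(f"{x:.10g}").quantize(q, rounding=ROUND_HALF_UP))


def fit_cylinder_axis(points: np.ndarray) -> np.ndarray:
    """Least-squares cylinder axis through a set of points.

    Minimises the variance of point-to-axis distances over axis direction
    and position.  For points sampled from an ideal helix this recovers the
    helix axis essentially exactly (zero residual at the optimum), which is
    what makes it a usable ground-truth oracle for segment orientations.
    Returns a unit vector oriented from the first toward the last point.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[0] < 5:
        raise ValueError("need at least 5 points to fit a cylinder axis")
    center = pts.mean(axis=0)
    centered = pts - center

    # initial direction: principal component
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    d0 = vt[0]

    def spherical(d):
        theta = np.arccos(np.clip(d[2], -1, 1))
        phi = np.arctan2(d[1], d[0])
        return np.array([theta, phi])

    def direction(tp):
        t, p = tp
        return np.array([np.sin(t) * np.cos(p), np.sin(t) * np.sin(p), np.cos(t)])

    def residuals(params):
        t, p, ox, oy = params
        d = direction((t, p))
        # offset restricted to the plane perpendicular to d
        e1, e2 = _plane_basis(d)
        origin = ox * e1 + oy * e2
        rel = centered - origin
        radial = rel - np.outer(rel @ d, d)
        r = np.linalg.norm(radial, axis=1)
        return r - r.mean()

    t0, p0 = spherical(d0)
    sol = least_squares(residuals, x0=[t0, p0, 0.0, 0.0], method="lm")
    d = direction(sol.x[:2])
    if np.dot(d, pts[-1] - pts[0]) < 0:
        d = -d
    return d


def _plane_basis(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, d)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    return e1, e2


def segment_axis_angle(ca_coords: np.ndarray, hinge_position: int) -> float:
    """Angle in degrees between the cylinder axes fitted to the Cα
    coordinates at/below the hinge and strictly beyond it.

    ``hinge_position`` counts residues from the start of the array
    (1-based), matching a kink that leaves residues up to and including
    the hinge unmoved.
    """
    ca = np.asarray(ca_coords, dtype=float)
    a1 = fit_cylinder_axis(ca[:hinge_position])
    a2 = fit_cylinder_axis(ca[hinge_position:])
    return angle_between(a1, a2)
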