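"""Shared geometric primitives: the angle convention, contour helpers.

Angle convention (used everywhere in the package): the angle of pixel ``p``
about origin ``o`` is ``theta = atan2(o_row - p_row, p_col - o_col)`` mapped
to [0, 360).  With the image displayed row-down, 0 deg points toward
increasing column ("3 o'clock") and angles increase counterclockwise.
"""
from __future__ import annotations

import numpy as np
from skimage.draw import polygon2mask


def pixel_angles_deg(rows, cols, origin) -> np.ndarray:
    """Angles (degrees, [0, 360)) of pixel coordinates about ``origin``."""
    rows = np.asarray(rows, dtype=float)
    cols = np.asarray(cols, dtype=float)
    o_r, o_c = origin
    theta = np.degrees(np.arctan2(o_r - rows, cols - o_c))
    return np.mod(theta, 360.0)


def polar_to_cartesian(theta_deg, radius, origin):
    """(row, col) of points at polar coordinates about ``origin``."""
    t = np.radians(np.asarray(theta_deg, dtype=float))
    r = np.asarray(radius, dtype=float)
    o_r, o_c = origin
    return o_r - r * np.sin(t), o_c + r * np.cos(t)


def normalize_angle_deg(a: float) -> float:
    return float(np.mod(a, 360.0))


def contour_mask(points: np.ndarray, shape) -> np.ndarray:
    """Rasterize a closed (row, col) polyline into a binary mask."""
    return polygon2mask(shape, np.asarray(points, dtype=float))


def polygon_area(points: np.ndarray) -> float:
    """Unsigned shoelace area of a closed (row, col) polyline."""
    p = np.asarray(points, dtype=float)
    r, c = p[:, 0], p[:, 1]
    return 0.5 * abs(np.dot(r, np.roll(c, -1)) - np.dot(c, np.roll(r, -1)))


def is_simple(points: np.ndarray) -> bool:
    """True if the closed polyline does not self-intersect."""
    from shapely.geometry import LinearRing

    p = np.asarray(points, dtype=float)
    if len(p) < 3:
        return False
    try:
        return LinearRing(p).is_simple
    except Exception:
        return False


def resample_closed(points: np.ndarray, spacing: float | None = None,
                    n_points: int | None = None) -> np.ndarray:
    """Resample a closed polyline to uniform arc-length spacing.

    Exactly one of ``spacing`` (max distance between successive samples,
    in the polyline's coordinate units) or ``n_points`` must be given.
    """
    p = np.asarray(points, dtype=float)
    closed = np.vstack([p, p[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    total = arc[-1]
    if total == 0:
        return p[:1].repeat(n_points or 1, axis=0)
    if n_points is None:
        n_points = max(int(np.ceil(total / spacing)), 8)
    s = np.linspace(0.0, total, n_points, endpoint=False)
    rows = np.interp(s, arc, closed[:, 0])
    cols = np.interp(s, arc, closed[:, 1])
    return np.column_stack([rows, cols])


def mask_boundary_contour(mask: np.ndarray) -> np.ndarray:
    """Longest iso-contour of a binary mask as a closed (row, col) polyline."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        raise ValueError("empty mask has no boundary")
    c = max(contours, key=len)
    # find_contours returns first == last for closed curves; drop duplicate
    if np.allclose(c[0], c[-1]):
        c = c[:-1]
    return c


def disk_contour(center, radius: float, n_points: int = 120) -> np.ndarray:
    """Closed circular contour (ccw in the package angle convention)."""
    theta = np.linspace(0.0, 360.0, n_points, endpoint=False)
    r, c = polar_to_cartesian(theta, radius, center)
    return np.column_stack([r, c])
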