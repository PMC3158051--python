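"""Low-level 3D curve utilities shared by the generator and the scorers.

All coordinates are physical (µm), ordered ``(z, y, x)`` to match voxel-array
axis order.  A centerline is an ``(n, 3)`` float array of ordered points.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "arclength",
    "cumulative_arclength",
    "resample_polyline",
    "random_rotation",
    "circular_arc",
    "min_point_distance",
    "point_to_polyline",
    "analytic_edge_distance",
    "pairwise_coordinate_distances",
]


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    """Cumulative arclength, starting at 0, one entry per point."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 2:
        raise ValueError("centerline must be an (n>=2, 3) array")
    steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
    if np.any(steps == 0):
        raise ValueError("centerline has duplicate consecutive points")
    return np.concatenate([[0.0], np.cumsum(steps)])


def arclength(points: np.ndarray) -> float:
    return float(cumulative_arclength(points)[-1])


def resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a polyline to ``n`` points uniformly spaced in arclength."""
    s = cumulative_arclength(points)
    t = np.linspace(0.0, s[-1], n)
    out = np.empty((n, 3))
    for k in range(3):
        out[:, k] = np.interp(t, s, np.asarray(points)[:, k])
    return out


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (via QR of a Gaussian matrix)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def circular_arc(length: float, circle_radius: float, n: int = 256) -> np.ndarray:
    """Planar circular arc of given arclength in the (y, x) plane.

    The arc starts at angle 0 and is centered on the origin of its circle;
    callers rotate/translate it into place.  ``circle_radius=inf`` gives a
    straight segment along x.
    """
    if length <= 0:
        raise ValueError("arc length must be positive")
    t = np.linspace(0.0, 1.0, n)
    if not np.isfinite(circle_radius):
        pts = np.zeros((n, 3))
        pts[:, 2] = length * t
        return pts
    theta = length / circle_radius
    ang = theta * t
    pts = np.zeros((n, 3))
    pts[:, 1] = circle_radius * np.sin(ang)
    pts[:, 2] = circle_radius * (np.cos(ang) - 1.0)
    return pts


def min_point_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Minimum pairwise distance between two point sets (brute force)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def point_to_polyline(points: np.ndarray, polyline: np.ndarray):
    """Distance from each query point to a polyline, with projection arclength.

    Exact point-to-segment distances (not sample-to-sample).  Returns
    ``(dist, s)`` where ``s`` is the arclength of the closest point on the
    polyline.  Vectorized over segments; chunked over query points by callers
    if memory matters.
    """
    p = np.asarray(points, dtype=float)
    c = np.asarray(polyline, dtype=float)
    seg0 = c[:-1]
    dvec = c[1:] - seg0
    seglen2 = (dvec**2).sum(axis=1)
    cum = cumulative_arclength(c)
    # (npts, nseg, 3)
    w = p[:, None, :] - seg0[None, :, :]
    t = (w * dvec[None, :, :]).sum(axis=2) / seglen2[None, :]
    t = np.clip(t, 0.0, 1.0)
    proj = seg0[None, :, :] + t[:, :, None] * dvec[None, :, :]
    d2 = ((p[:, None, :] - proj) ** 2).sum(axis=2)
    iseg = d2.argmin(axis=1)
    rows = np.arange(len(p))
    dist = np.sqrt(d2[rows, iseg])
    s = cum[iseg] + t[rows, iseg] * np.sqrt(seglen2[iseg])
    return dist, s


def analytic_edge_distance(curve_a: np.ndarray, radius_a: float,
                           curve_b: np.ndarray, radius_b: float,
                           n_samples: int = 400) -> float:
    """Shortest tube-surface-to-surface distance between two territory models.

    Computed from the continuous geometry (dense centerline samples), clipped
    at zero when the tubes overlap.
    """
    a = resample_polyline(curve_a, n_samples)
    b = resample_polyline(curve_b, n_samples)
    d = min_point_distance(a, b) - radius_a - radius_b
    return max(0.0, float(d))


def pairwise_coordinate_distances(curve_a: np.ndarray, curve_b: np.ndarray,
                                  n: int = 200) -> np.ndarray:
    """Distance between same-coordinate points of two homolog centerlines.

    Both curves are resampled to ``n`` points uniform in arclength; entry ``i``
    is ``|A(t_i) - B(t_i)|`` with ``t_i = i/(n-1)`` the chromosome coordinate.
    """
    a = resample_polyline(curve_a, n)
    b = resample_polyline(curve_b, n)
    return np.linalg.norm(a - b, axis=1)
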