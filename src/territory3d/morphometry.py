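"""Territory morphometry: centerline, width D, length L, slenderness S = L/D,
the "highly extended" call (strictly S > 6), and painted-segment counts.

Conventions:

* the centerline is the longest geodesic path through the 3D skeleton of the
  mask, lightly smoothed to suppress voxel staircase inflation;
* width is twice the *median* of the medial (locally maximal) Euclidean
  distance transform sampled along the centerline — the median is robust to
  the thinning of the mask at bead troughs;
* length is the geodesic centerline length (a traced path, not a chord);
* a painted segment is an intensity peak along the centerline whose flanking
  minima drop below ``gap_fraction`` of the peak, or an abutting block of a
  different dominant fluorophore.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from territory3d import skeleton as sk
from territory3d.geometry import cumulative_arclength
from territory3d.io import VoxelImage
from territory3d.paint import PaintScheme
from territory3d.segmentation import TerritoryMask

__all__ = [
    "Centerline",
    "MorphometryRecord",
    "extract_centerline",
    "estimate_width",
    "slenderness",
    "classify_extension",
    "count_painted_segments",
    "count_segments_profile",
    "measure_territory",
]

EXTENSION_THRESHOLD = 6.0  # strict: highly extended iff S > 6

DEFAULT_GAP_FRACTION = 0.5
DEFAULT_MIN_PROMINENCE_FRACTION = 0.1
DEFAULT_MIN_SEPARATION = 0.3  # µm
SMOOTH_WINDOW = 3  # odd; centerline coordinate smoothing, voxels


@dataclass
class Centerline:
    """Ordered centerline points (µm) with arclength parametrization.

    ``pc_at_start`` records the orientation: True if point 0 is the
    pairing-center end, False if point -1 is, None when the terminal paint
    colors could not distinguish the ends.
    """

    points: np.ndarray
    pc_at_start: bool | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("centerline needs >= 2 3D points")

    @property
    def arclength(self) -> np.ndarray:
        return cumulative_arclength(self.points)

    @property
    def length(self) -> float:
        return float(self.arclength[-1])

    def coordinates(self) -> np.ndarray:
        """Chromosome coordinate per point, oriented PC end -> non-PC end
        (unoriented centerlines are parametrized from point 0)."""
        s = self.arclength
        t = s / s[-1]
        if self.pc_at_start is False:
            t = 1.0 - t
        return t


@dataclass
class MorphometryRecord:
    territory_id: str
    width_d: float
    length_l: float
    slenderness_s: float
    segment_count_k: int
    highly_extended: bool

    def __post_init__(self) -> None:
        if self.width_d <= 0:
            raise ValueError("width must be positive")
        if self.segment_count_k < 1:
            raise ValueError("segment count must be >= 1")
        if abs(self.slenderness_s - self.length_l / self.width_d) > 1e-6:
            raise ValueError("slenderness must equal L/D")


def _smooth_path(points: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    """Moving-average smoothing with shrinking windows at the ends."""
    n = len(points)
    if n <= 2 or window <= 1:
        return points
    out = np.empty_like(points)
    half = window // 2
    for i in range(n):
        h = min(half, i, n - 1 - i)
        out[i] = points[i - h:i + h + 1].mean(axis=0)
    return out


def extract_centerline(mask_or_territory, voxel_size=None,
                       smooth_window: int = SMOOTH_WINDOW) -> Centerline:
    """Longest geodesic skeleton path of a territory mask, as physical points.

    Masks thinner than two voxels everywhere (skeleton degenerate) fall back
    to the principal-axis segment through the mask centroid.
    """
    if isinstance(mask_or_territory, TerritoryMask):
        mask = mask_or_territory.mask
        voxel_size = mask_or_territory.voxel_size
    else:
        mask = np.asarray(mask_or_territory, dtype=bool)
        if voxel_size is None:
            raise ValueError("voxel_size required with a raw mask")
    vs = np.asarray(voxel_size, dtype=float)
    g = sk.skeleton_voxel_graph(mask, vs)
    path = sk.longest_geodesic_path(g)
    if len(path) >= 2:
        pts = (np.asarray(path, dtype=float) + 0.5) * vs
        pts = _smooth_path(pts, smooth_window)
        pts = _dedupe(pts)
        if len(pts) >= 2:
            return Centerline(points=pts)
    # degenerate (thinning can fully erode small or perfectly symmetric
    # masks): principal-axis segment through the centroid, finely sampled so
    # the radius estimators can still sample along it
    coords = (np.argwhere(mask) + 0.5) * vs
    c = coords.mean(axis=0)
    centered = coords - c
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    proj = centered @ axis
    a = c + proj.min() * axis
    b = c + proj.max() * axis
    n = max(int(np.linalg.norm(b - a) / (0.5 * vs.min())), 1) + 1
    return Centerline(points=np.linspace(a, b, n))


def _dedupe(points: np.ndarray) -> np.ndarray:
    keep = [0]
    for i in range(1, len(points)):
        if np.linalg.norm(points[i] - points[keep[-1]]) > 1e-9:
            keep.append(i)
    return points[keep]


def estimate_width(mask_or_territory, centerline: Centerline,
                   voxel_size=None, method: str = "volume") -> float:
    """Territory width D (µm).

    ``method="volume"`` (default) refines the EDT-based medial radius under
    the tube-volume constraint ``V = pi r^2 L + 4/3 pi r^3`` (the mask volume
    is known to sub-percent accuracy, so this removes the lattice
    quantization jitter of the distance transform); ``method="edt"`` is the
    plain estimator, twice the median of the medial distance transform along
    the centerline.  Both carry a quarter-voxel partial-volume allowance on
    the diameter (the physical surface lies beyond the outermost foreground
    voxel centers; constant verified on analytic tubes of known radius).
    """
    if isinstance(mask_or_territory, TerritoryMask):
        mask = mask_or_territory.mask
        voxel_size = mask_or_territory.voxel_size
    else:
        mask = np.asarray(mask_or_territory, dtype=bool)
        if voxel_size is None:
            raise ValueError("voxel_size required with a raw mask")
    vs = np.asarray(voxel_size, dtype=float)
    r = medial_radius(mask, centerline, vs)
    if method == "volume":
        r = refine_radius(mask, centerline, r, vs)
    elif method != "edt":
        raise ValueError(f"unknown width method {method!r}")
    return max(2.0 * r + 0.25 * float(vs.min()), float(vs.min()))


def refine_radius(mask: np.ndarray, centerline: Centerline, r0: float,
                  vs) -> float:
    """Tube radius consistent with the mask volume under a capsule model.

    Iterates ``L = completed centerline length at radius r`` and
    ``pi r^2 L + 4/3 pi r^3 = V`` to a fixed point (three rounds suffice).
    Assumes a single tube: for merged homolog pairs the returned radius
    absorbs the doubled cross-section, which only makes the extension call
    more conservative.
    """
    vs = np.asarray(vs, dtype=float)
    vol = float(mask.sum()) * float(np.prod(vs))
    r = max(r0, 1e-3)
    for _ in range(3):
        length = corrected_length(mask, centerline, r, tuple(vs))
        # positive root of pi r^2 L + 4/3 pi r^3 = V
        coeffs = [4.0 / 3.0 * np.pi, np.pi * length, 0.0, -vol]
        roots = np.roots(coeffs)
        real = roots[np.isreal(roots)].real
        pos = real[real > 0]
        if pos.size == 0:
            return r
        r = float(pos.min())
    return r


def medial_radius(mask: np.ndarray, centerline: Centerline, vs) -> float:
    """Robust medial tube radius along the centerline (µm).

    The skeleton jitters off the true medial axis by up to a voxel, so each
    sample takes the local maximum of the EDT over a 3^3 neighborhood; the
    estimate is the mean of samples within one voxel of their median —
    median-robust against bead-trough thinning, but without the median's
    quantization jitter.
    """
    vs = np.asarray(vs, dtype=float)
    edt = ndimage.distance_transform_edt(mask, sampling=vs)
    edt_max = ndimage.maximum_filter(edt, size=3)
    idx = np.clip(np.round(centerline.points / vs - 0.5).astype(int), 0,
                  np.array(mask.shape) - 1)
    radii = edt_max[idx[:, 0], idx[:, 1], idx[:, 2]]
    radii = radii[radii > 0]
    if radii.size == 0:
        raise ValueError("centerline does not intersect the mask")
    med = float(np.median(radii))
    near = radii[np.abs(radii - med) <= float(vs.max())]
    return float(near.mean())


def corrected_length(mask_or_territory, centerline: Centerline,
                     radius: float, voxel_size=None) -> float:
    """Centerline length trimmed and completed to the tube ends.

    The true centerline ends where the end cap begins: there the distance
    transform still equals the full tube ``radius``.  Thinning can either
    overshoot into the cap (EDT below the radius) or retract from it, so
    the path is first trimmed back to full-radius territory and then
    extended by the cap overhang — the farthest mask voxel's projection onto
    the outward tangent minus ``radius``, clipped at zero.
    """
    if isinstance(mask_or_territory, TerritoryMask):
        mask = mask_or_territory.mask
        voxel_size = mask_or_territory.voxel_size
    else:
        mask = np.asarray(mask_or_territory, dtype=bool)
        if voxel_size is None:
            raise ValueError("voxel_size required with a raw mask")
    vs = np.asarray(voxel_size, dtype=float)
    coords = (np.argwhere(mask) + 0.5) * vs
    pts, overshoot = _trim_to_full_radius(mask, centerline.points, radius, vs)
    if len(pts) < 2:
        # quasi-spherical mask: all interior, no tube stretch at full radius
        return float(vs.min())
    total = float(cumulative_arclength(pts)[-1]) - overshoot
    for end, inner in ((pts[0], pts[min(3, len(pts) - 1)]),
                       (pts[-1], pts[max(-4, -len(pts))])):
        u = end - inner
        nu = np.linalg.norm(u)
        if nu < 1e-9:
            continue
        u /= nu
        rel = coords - end
        proj = rel @ u
        perp2 = (rel**2).sum(axis=1) - proj**2
        near = (proj > 0) & (perp2 <= radius**2)
        if near.any():
            ext = float(proj[near].max()) - radius
            total += max(0.0, ext)
    return max(total, float(vs.min()))


def _trim_to_full_radius(mask: np.ndarray, points: np.ndarray,
                         radius: float, vs: np.ndarray):
    """Drop path ends that have slid into the end caps (EDT below the full
    tube radius).

    Trimming stops where the EDT reaches ``radius - margin``, a point still
    ``margin`` beyond the true centerline endpoint; that residual is
    returned as ``overshoot`` and subtracted from the length by the caller.
    """
    edt = ndimage.distance_transform_edt(mask, sampling=vs)
    idx = np.clip(np.round(points / vs - 0.5).astype(int), 0,
                  np.array(mask.shape) - 1)
    vals = edt[idx[:, 0], idx[:, 1], idx[:, 2]]
    margin = 0.75 * float(vs.min())
    thr = radius - margin
    n = len(points)
    i0 = 0
    while i0 < n - 1 and vals[i0] < thr:
        i0 += 1
    i1 = n - 1
    while i1 > i0 and vals[i1] < thr:
        i1 -= 1
    overshoot = margin * ((i0 > 0) + (i1 < n - 1))
    return points[i0:i1 + 1], overshoot


def slenderness(length_l: float, width_d: float) -> float:
    if length_l <= 0 or width_d <= 0:
        raise ValueError("length and width must be positive")
    return length_l / width_d


def classify_extension(slenderness_s: float) -> bool:
    """Strictly greater than the printed threshold of 6."""
    return slenderness_s > EXTENSION_THRESHOLD


def arclength_profiles(image: VoxelImage, centerline: Centerline,
                       channels) -> tuple[np.ndarray, np.ndarray]:
    """Per-channel intensity sampled along the centerline (trilinear).

    Returns ``(s, profiles)`` with ``profiles`` of shape
    ``(n_channels, n_samples)`` in the order of ``channels``.
    """
    vs = np.asarray(image.voxel_size, dtype=float)
    s = centerline.arclength
    # resample at ~half-voxel steps for a stable profile
    step = float(vs.min()) / 2.0
    n = max(int(np.ceil(s[-1] / step)) + 1, 8)
    si = np.linspace(0.0, s[-1], n)
    pts = np.empty((n, 3))
    for k in range(3):
        pts[:, k] = np.interp(si, s, centerline.points[:, k])
    idx = (pts / vs - 0.5).T  # fractional voxel coordinates
    profs = np.stack([
        ndimage.map_coordinates(image.channel(c), idx, order=1, mode="nearest")
        for c in channels
    ])
    return si, profs


def count_segments_profile(s: np.ndarray, profiles: np.ndarray,
                           gap_fraction: float = DEFAULT_GAP_FRACTION,
                           min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE_FRACTION,
                           min_separation: float = DEFAULT_MIN_SEPARATION) -> int:
    """Painted-segment count from per-channel arclength profiles.

    Peaks of the summed profile count as segments when their flanking minima
    fall below ``gap_fraction`` of the lower adjacent peak; peaks closer than
    ``min_separation`` (µm) merge.  A change of dominant channel *within* an
    intensity block adds one segment per change (spatially resolved colors
    without an intensity gap).
    """
    total = profiles.sum(axis=0)
    if total.max() <= 0:
        raise ValueError("empty intensity profile")
    peaks = _merged_peaks(s, total, gap_fraction, min_prominence_fraction,
                          min_separation)
    # split into blocks at the valleys between retained peaks
    boundaries = []
    for (_, pa), (pb, _) in zip(peaks, peaks[1:]):
        seg = np.arange(pa, pb + 1)
        boundaries.append(seg[np.argmin(total[pa:pb + 1])])
    blocks = np.split(np.arange(len(s)), boundaries)
    color_changes = 0
    for block in blocks:
        color_changes += _dominant_changes(s[block], profiles[:, block],
                                           min_separation)
    return max(len(peaks) + color_changes, 1)


def _merged_peaks(s, total, gap_fraction, min_prom_frac, min_separation):
    """Indices (left, right bounds) of retained peaks, in order."""
    from scipy.signal import find_peaks

    floor = min_prom_frac * float(total.max())
    pk, _ = find_peaks(total, height=floor, prominence=floor, plateau_size=1)
    if len(pk) == 0:
        pk = np.array([int(np.argmax(total))])
    peaks = [(int(p), int(p)) for p in pk]
    # iteratively merge the pair with the shallowest valley
    while len(peaks) > 1:
        best = None
        for i, ((a0, a1), (b0, b1)) in enumerate(zip(peaks, peaks[1:])):
            valley = total[a1:b0 + 1].min()
            ha = total[a0:a1 + 1].max()
            hb = total[b0:b1 + 1].max()
            lower = min(ha, hb)
            sep = s[b0] - s[a1]
            relative = valley / lower if lower > 0 else 1.0
            if sep < min_separation or relative >= gap_fraction:
                score = relative
                if best is None or score > best[0]:
                    best = (score, i)
        if best is None:
            break
        i = best[1]
        a, b = peaks[i], peaks[i + 1]
        peaks[i:i + 2] = [(a[0], b[1])]
    return peaks


def _dominant_changes(s, profiles, min_separation):
    """Count changes of dominant channel between stable runs within a block."""
    if profiles.shape[0] < 2 or len(s) == 0:
        return 0
    total = profiles.sum(axis=0)
    floor = 0.2 * float(total.max()) if total.max() > 0 else 0.0
    live = total > floor
    if not live.any():
        return 0
    dom = profiles.argmax(axis=0)
    dom = dom[live]
    ss = s[live]
    # collapse to runs, drop runs shorter than min_separation
    runs = []
    start = 0
    for i in range(1, len(dom) + 1):
        if i == len(dom) or dom[i] != dom[start]:
            if ss[i - 1] - ss[start] >= min_separation:
                if not runs or runs[-1] != dom[start]:
                    runs.append(dom[start])
            start = i
    return max(len(runs) - 1, 0)


def count_painted_segments(image: VoxelImage, centerline: Centerline,
                           paint: PaintScheme,
                           gap_fraction: float = DEFAULT_GAP_FRACTION,
                           min_prominence_fraction: float = DEFAULT_MIN_PROMINENCE_FRACTION,
                           min_separation: float = DEFAULT_MIN_SEPARATION) -> int:
    """Painted-segment count k along one centerline (see module docstring)."""
    s, profs = arclength_profiles(image, centerline, paint.channels)
    return count_segments_profile(s, profs, gap_fraction,
                                  min_prominence_fraction, min_separation)


def measure_territory(image: VoxelImage, territory: TerritoryMask,
                      paint: PaintScheme, **segment_params) -> MorphometryRecord:
    """Full morphometry of one segmented territory."""
    cl = extract_centerline(territory)
    vs = np.asarray(territory.voxel_size, dtype=float)
    r0 = medial_radius(territory.mask, cl, vs)
    r = refine_radius(territory.mask, cl, r0, vs)
    d = max(2.0 * r + 0.25 * float(vs.min()), float(vs.min()))
    length = corrected_length(territory, cl, r)
    s = slenderness(length, d)
    k = count_painted_segments(image, cl, paint, **segment_params)
    return MorphometryRecord(
        territory_id=f"{territory.nucleus_id}/{territory.chromosome_id}",
        width_d=d,
        length_l=length,
        slenderness_s=s,
        segment_count_k=k,
        highly_extended=classify_extension(s),
    )
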