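"""Nucleus-level ground truth: homolog pairs in planted configurations.

Pairing configurations follow the visual taxonomy used for scoring painted
homolog pairs: V (associated only at one end), Y (aligned from one end partway
along the length), X (associated only in the middle), O (associated at both
ends but not the middle), full (aligned along the entire length), plus
no-alignment (territories in contact without any same-coordinate association)
and no-contact.  V and Y come in PC and non-PC flavors depending on which
chromosome end carries the pairing center.

Geometry: homolog A is a random smooth thread; homolog B is A displaced along
the normal of A's best-fit plane by a smoothly varying offset delta(t) --
small (tubes overlapping, "associated") over the planted paired intervals of
chromosome coordinate t, large (well beyond the pairing distance) elsewhere.
The pair is recentered so both homologs fit the nuclear sphere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from territory3d import geometry
from territory3d.paint import PaintScheme
from territory3d.synth.territory import TerritoryModel, generate_territory

__all__ = [
    "CONFIGURATIONS",
    "PairSpec",
    "NucleusSpec",
    "generate_nucleus",
    "paired_intervals",
    "planted_association_profile",
    "planted_edge_distance",
]

#: planted paired intervals per configuration, in PC-anchored coordinate
#: (0 = pairing-center end)
CONFIGURATIONS: dict[str, tuple[tuple[float, float], ...]] = {
    "V-PC": ((0.0, 0.10),),
    "Y-PC": ((0.0, 0.50),),
    "V-NPC": ((0.90, 1.0),),
    "Y-NPC": ((0.50, 1.0),),
    "X": ((0.40, 0.60),),
    "O": ((0.0, 0.10), (0.90, 1.0)),
    "full": ((0.0, 1.0),),
    "no_alignment": (),
    "no_contact": (),
}

PROXIMITY_CATEGORIES = ("touching", "close", "intermediate", "far")

#: offset between paired homolog centerlines, in units of tube radius
#: (tubes overlap strongly and render as one thicker thread)
PAIR_OFFSET = 1.0
#: tighter offset used for fully aligned (synapsed) pairs, whose colors stay
#: in register; homolog axes in a synaptonemal complex sit ~100 nm apart
FULL_OFFSET = 0.3
#: offset between unpaired stretches, µm (well beyond the pairing distance)
FAR_OFFSET = 1.2
#: half-width of the cosine ramp between paired and unpaired offsets,
#: in chromosome-coordinate units
RAMP_WIDTH = 0.06


def paired_intervals(configuration: str, pc_end: str) -> tuple[tuple[float, float], ...]:
    """Planted paired intervals in *left-anchored* chromosome coordinate."""
    if configuration not in CONFIGURATIONS:
        raise ValueError(f"unknown configuration {configuration!r}")
    ivals = CONFIGURATIONS[configuration]
    if pc_end == "right":
        ivals = tuple(sorted((1.0 - b, 1.0 - a) for a, b in ivals))
    return ivals


@dataclass
class PairSpec:
    """Request for one homolog pair within a nucleus."""

    paint: PaintScheme
    stage_label: str = "compact"
    configuration: str | None = None
    target_slenderness: float = 1.5
    bead_count: int = 1
    proximity: str | None = None  # targeted placement for unpaired compact pairs

    def __post_init__(self) -> None:
        if self.configuration is not None and self.configuration not in CONFIGURATIONS:
            raise ValueError(f"unknown configuration {self.configuration!r}")
        if self.proximity is not None and self.proximity not in PROXIMITY_CATEGORIES:
            raise ValueError(f"unknown proximity {self.proximity!r}")
        if self.configuration is not None and self.proximity is not None:
            raise ValueError("specify either a configuration or a proximity, not both")


@dataclass
class NucleusSpec:
    """One nucleus: requested pair specs plus (after generation) the geometry."""

    pairs: list[PairSpec]
    nucleus_id: str = "n0"
    nuclear_radius: float = 2.0
    clustered: bool = False
    row: int | None = None
    zone_label: str | None = None
    territories: dict[str, tuple[TerritoryModel, TerritoryModel]] = field(default_factory=dict)

    @property
    def realized(self) -> bool:
        return bool(self.territories)

    def configuration_of(self, chromosome_id: str) -> str | None:
        for p in self.pairs:
            if p.paint.chromosome_id == chromosome_id:
                return p.configuration
        return None


def _offset_profile(t: np.ndarray, intervals, radius: float) -> np.ndarray:
    """delta(t): PAIR_OFFSET*radius inside paired intervals, FAR_OFFSET outside,
    cosine-ramped over RAMP_WIDTH."""
    if not intervals:
        return np.full_like(t, FAR_OFFSET)
    dist = np.full_like(t, np.inf)
    for a, b in intervals:
        d = np.maximum(0.0, np.maximum(a - t, t - b))
        dist = np.minimum(dist, d)
    x = np.clip(dist / RAMP_WIDTH, 0.0, 1.0)
    ramp = 0.5 - 0.5 * np.cos(np.pi * x)
    near = PAIR_OFFSET * radius
    return near + (FAR_OFFSET - near) * ramp


def _plane_normal(points: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane (smallest principal axis)."""
    c = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    return vt[-1]


def _fit_shift(points: np.ndarray, radius: float, nuclear_radius: float,
               rng: np.random.Generator, cluster_dir: np.ndarray | None,
               cluster_frac: float = 0.35) -> np.ndarray | None:
    """Translation keeping a centerline inside the nucleus, optionally biased
    toward a clustering direction.  Returns None if even centering fails."""
    center = points.mean(axis=0)
    extent = np.linalg.norm(points - center, axis=1).max() + radius
    slack = nuclear_radius - extent
    if slack < 0:
        return None
    if cluster_dir is not None:
        shift = min(slack * 0.9, cluster_frac * nuclear_radius) * cluster_dir
    else:
        # uniform center in the slack ball
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        shift = v * slack * rng.uniform(0.0, 0.95) ** (1.0 / 3.0)
    return shift - center


def _paired_pair(spec: PairSpec, nuc: NucleusSpec, rng: np.random.Generator):
    """Homolog pair realizing an association configuration (V/Y/X/O/full)."""
    intervals = paired_intervals(spec.configuration, spec.paint.pc_end)
    if spec.configuration == "full":
        fit_radius = nuc.nuclear_radius - 0.38
    else:
        # reserve room for the out-of-plane displacement of unpaired stretches
        margin = FAR_OFFSET / 2.0 + 0.55
        fit_radius = float(np.sqrt(max(nuc.nuclear_radius**2 - margin**2, 0.25)))
    a = None
    for _ in range(24):
        try:
            # planar arcs only: helical pitch runs along the plane normal,
            # where it would alias with the homolog displacement
            a = generate_territory(
                stage_label=spec.stage_label,
                target_slenderness=spec.target_slenderness,
                bead_count=spec.bead_count,
                paint=spec.paint,
                seed=rng,
                nuclear_radius=fit_radius,
                allow_helix=False,
            )
            break
        except ValueError:
            continue
    if a is None:
        raise ValueError(
            f"cannot fit a paired {spec.configuration} thread of slenderness "
            f"{spec.target_slenderness} in a nucleus of radius {nuc.nuclear_radius} µm"
        )
    t = a.coordinates()
    if spec.configuration == "full":
        delta = np.full_like(t, FULL_OFFSET * a.tube_radius)
    else:
        delta = _offset_profile(t, intervals, a.tube_radius)
    u = _plane_normal(a.centerline)
    half = (delta[:, None] / 2.0) * u[None, :]
    ca = a.centerline - half
    cb = a.centerline + half
    b = TerritoryModel(
        centerline=cb,
        tube_radius=a.tube_radius,
        bead_profile=a.bead_profile.copy(),
        planted_bead_count=a.planted_bead_count,
        paint=spec.paint,
        stage_label=spec.stage_label,
    )
    a.centerline = ca
    return a, b


def _contact_pair(spec: PairSpec, nuc: NucleusSpec, rng: np.random.Generator):
    """no_alignment: territories touch end-to-side at unrelated coordinates.

    Homolog B's non-PC tip is brought into contact with a point one fifth of
    the way along homolog A, with B extending away from A, so the only contact
    is between regions of different chromosome coordinate.
    """
    fit_radius = 0.65 * nuc.nuclear_radius
    for _ in range(200):
        a = generate_territory(spec.stage_label, spec.target_slenderness,
                               spec.bead_count, paint=spec.paint, seed=rng,
                               nuclear_radius=fit_radius)
        b = generate_territory(spec.stage_label, spec.target_slenderness,
                               spec.bead_count, paint=spec.paint, seed=rng,
                               nuclear_radius=fit_radius)
        ta = a.coordinates()
        ia = int(np.argmin(np.abs(ta - 0.2)))
        anchor = a.centerline[ia]
        # push B away from A along the local normal of A at the anchor
        tang = a.centerline[min(ia + 1, len(ta) - 1)] - a.centerline[ia - 1]
        tang /= np.linalg.norm(tang)
        v = rng.normal(size=3)
        v -= v.dot(tang) * tang
        v /= np.linalg.norm(v)
        contact = anchor + 1.6 * a.tube_radius * v
        # orient B so its far (non-PC) end sits at the contact point and its
        # body extends outward along v
        tip = b.centerline[-1]
        shifted = b.centerline - tip + contact
        # rotate B about the contact point so its centroid heads along +v
        cvec = shifted.mean(axis=0) - contact
        if np.linalg.norm(cvec) < 1e-9:
            continue
        cvec /= np.linalg.norm(cvec)
        rot = _rotation_between(cvec, v)
        bpts = (shifted - contact) @ rot.T + contact
        b = TerritoryModel(bpts, b.tube_radius, b.bead_profile,
                           b.planted_bead_count, spec.paint, spec.stage_label)
        ens = np.vstack([a.centerline, b.centerline])
        sh = _fit_shift(ens, max(a.tube_radius, b.tube_radius),
                        nuc.nuclear_radius, rng, None)
        if sh is None:
            continue
        rr = a.tube_radius + b.tube_radius
        same = geometry.pairwise_coordinate_distances(a.centerline, b.centerline)
        if same.min() <= 1.25 * 2.0 * a.tube_radius:
            continue  # would register as paired somewhere
        # contact at the planted point; elsewhere the centerlines keep a
        # clearance well beyond the pairing distance
        da, sa = geometry.point_to_polyline(
            geometry.resample_polyline(b.centerline, 150), a.centerline)
        touch = da <= rr
        if not touch.any():
            continue
        sb = np.linspace(0, b.length, 150)
        if touch[sb <= 0.9 * b.length].any():
            continue
        if (da[sb <= 0.7 * b.length] < 1.0).any():
            continue
        return a.transformed(translation=sh), b.transformed(translation=sh)
    raise RuntimeError("could not realize a no_alignment contact geometry")


def _rotation_between(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Rotation matrix taking unit vector u onto unit vector v."""
    c = float(np.dot(u, v))
    w = np.cross(u, v)
    s = np.linalg.norm(w)
    if s < 1e-12:
        return np.eye(3) if c > 0 else -np.eye(3)
    k = np.array([[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]])
    return np.eye(3) + k + k @ k * ((1 - c) / s**2)


def _slab_place(m: TerritoryModel, w: np.ndarray, offset: float) -> TerritoryModel:
    """Rotate a thread so its best-fit plane is normal to ``w`` and shift it
    ``offset`` along ``w`` (used to keep two long threads apart)."""
    c = m.centerline.mean(axis=0)
    rot = _rotation_between(_plane_normal(m.centerline), w)
    pts = (m.centerline - c) @ rot.T + offset * w
    return TerritoryModel(pts, m.tube_radius, m.bead_profile.copy(),
                          m.planted_bead_count, m.paint, m.stage_label)


def _separate_pair(spec: PairSpec, nuc: NucleusSpec, rng: np.random.Generator,
                   cluster_dir: np.ndarray | None):
    """no_contact configuration or targeted/uniform proximity placement."""
    target = spec.proximity
    if spec.configuration == "no_contact":
        target = "no_contact"
    extended = spec.stage_label == "extended"
    fit = 0.8 * nuc.nuclear_radius if extended else 0.62 * nuc.nuclear_radius
    helix_ok = not (extended and target == "no_contact")
    for _ in range(400):
        try:
            a = generate_territory(spec.stage_label, spec.target_slenderness,
                                   spec.bead_count, paint=spec.paint, seed=rng,
                                   nuclear_radius=fit, allow_helix=helix_ok)
            b = generate_territory(spec.stage_label, spec.target_slenderness,
                                   spec.bead_count, paint=spec.paint, seed=rng,
                                   nuclear_radius=fit, allow_helix=helix_ok)
        except ValueError:
            continue
        if extended and target == "no_contact":
            # long threads cannot be separated by rejection alone: stack
            # their best-fit planes along a random normal
            w = rng.normal(size=3)
            w /= np.linalg.norm(w)
            off = rng.uniform(0.34, 0.38) * nuc.nuclear_radius
            a2, b2 = _slab_place(a, w, -off), _slab_place(b, w, +off)
            r = max(a2.tube_radius, b2.tube_radius)
            if any(np.linalg.norm(m.centerline, axis=1).max() + r
                   > nuc.nuclear_radius for m in (a2, b2)):
                continue
        else:
            models = []
            ok = True
            for m in (a, b):
                sh = _fit_shift(m.centerline, m.tube_radius, nuc.nuclear_radius,
                                rng, cluster_dir)
                if sh is None:
                    ok = False
                    break
                models.append(m.transformed(translation=sh))
            if not ok:
                continue
            a2, b2 = models
        d = geometry.analytic_edge_distance(a2.centerline, a2.tube_radius,
                                            b2.centerline, b2.tube_radius,
                                            n_samples=120)
        dd = a2.width  # D of this pair
        if target is None:
            return a2, b2
        if target == "no_contact" and d > 0.65:
            return a2, b2
        if target == "touching" and d == 0.0:
            return a2, b2
        if target == "close" and 0.05 * dd < d <= 0.95 * dd:
            return a2, b2
        if target == "intermediate" and 1.05 * dd < d <= 1.95 * dd:
            return a2, b2
        if target == "far" and d > 2.1 * dd:
            return a2, b2
    raise RuntimeError(
        f"could not place a pair with target proximity {target!r} in a "
        f"nucleus of radius {nuc.nuclear_radius} µm"
    )


def generate_nucleus(spec: NucleusSpec, seed: int | np.random.Generator = 0) -> NucleusSpec:
    """Realize the geometry of a nucleus in place (and return it).

    Each requested homolog pair is generated according to its configuration
    (or placed independently, optionally targeting a proximity category);
    clustered nuclei have their chromatin biased toward one side of the
    nucleus, the transition-zone hallmark.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cluster_dir = None
    if spec.clustered:
        v = rng.normal(size=3)
        cluster_dir = v / np.linalg.norm(v)
    spec.territories = {}
    occupied: list[TerritoryModel] = []
    for pair in spec.pairs:
        cfg = pair.configuration
        if cfg is None or cfg == "no_contact":
            a, b = _separate_pair(pair, spec, rng, cluster_dir)
        elif cfg == "no_alignment":
            a, b = _contact_pair(pair, spec, rng)
            a, b = _recenter(spec, rng, a, b, cluster_dir)
        else:
            a, b = _paired_pair(pair, spec, rng)
            a, b = _recenter(spec, rng, a, b, cluster_dir)
        _check_configuration(pair, a, b)
        spec.territories[pair.paint.chromosome_id] = (a, b)
        occupied.extend((a, b))
    return spec


def _recenter(spec: NucleusSpec, rng: np.random.Generator,
              a: TerritoryModel, b: TerritoryModel,
              cluster_dir: np.ndarray | None):
    """Shift a rigid homolog-pair ensemble into the nuclear sphere."""
    pts = np.vstack([a.centerline, b.centerline])
    r = max(a.tube_radius, b.tube_radius)
    sh = _fit_shift(pts, r, spec.nuclear_radius, rng, cluster_dir,
                    cluster_frac=0.2)
    if sh is None:
        raise ValueError("pair geometry does not fit the nuclear sphere")
    return a.transformed(translation=sh), b.transformed(translation=sh)


def _check_configuration(pair: PairSpec, a: TerritoryModel, b: TerritoryModel) -> None:
    """Planted-truth consistency of the realized geometry."""
    if pair.configuration is None:
        return
    dd = geometry.pairwise_coordinate_distances(a.centerline, b.centerline)
    within = dd <= 2.0 * a.tube_radius
    if pair.configuration == "full" and within.mean() < 0.95:
        raise AssertionError("full configuration not aligned over >=95% of length")
    if pair.configuration == "no_contact":
        d = geometry.analytic_edge_distance(a.centerline, a.tube_radius,
                                            b.centerline, b.tube_radius,
                                            n_samples=120)
        if d <= 0.0:
            raise AssertionError("no_contact pair is touching")


def planted_association_profile(a: TerritoryModel, b: TerritoryModel,
                                epsilon: float | None = None,
                                bins: int = 20) -> np.ndarray:
    """Ground-truth paired/unpaired profile from the analytic centerlines.

    A chromosome-coordinate bin is paired iff the same-coordinate centerline
    separation at the bin center is within ``epsilon`` (default 1 territory
    width).
    """
    if epsilon is None:
        epsilon = 2.0 * a.tube_radius  # 1 * D
    n = 10 * bins
    d = geometry.pairwise_coordinate_distances(a.centerline, b.centerline, n=n)
    prof = np.zeros(bins, dtype=bool)
    edges = np.linspace(0, n, bins + 1).astype(int)
    for i in range(bins):
        prof[i] = d[edges[i]:edges[i + 1]].mean() <= epsilon
    return prof


def planted_edge_distance(a: TerritoryModel, b: TerritoryModel,
                          n_samples: int = 300) -> float:
    return geometry.analytic_edge_distance(a.centerline, a.tube_radius,
                                           b.centerline, b.tube_radius,
                                           n_samples=n_samples)
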