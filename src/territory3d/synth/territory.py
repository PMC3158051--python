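"""Generation of single chromosome-territory models.

A territory is modeled as a tube: a smooth 3D centerline of controlled
arclength, a constant tube radius (half the territory width), and a
"beads-on-a-string" intensity profile along arclength.  Premeiotic territories
are compact ovoids (slenderness near 1); transition-zone territories are
extended threads (slenderness well above 6).

The analytic slenderness of a model is ``centerline arclength / (2 * radius)``
and is exact by construction: curves are rescaled to the requested arclength
after shaping, so the planted slenderness carries no sampling error.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from territory3d import geometry
from territory3d.paint import PaintScheme

__all__ = ["TerritoryModel", "generate_territory", "bead_profile"]

#: arclength discretization step of stored centerlines, µm
DS = 0.02

#: default territory width distribution (µm): compact wild-type premeiotic
WIDTH_MEAN = 0.67
WIDTH_SD = 0.05

#: bead trough intensity as a fraction of peak
BEAD_FLOOR = 0.1


def bead_profile(n: int, bead_count: int, floor: float = BEAD_FLOOR) -> np.ndarray:
    """Raised-cosine intensity modulation with exactly ``bead_count`` maxima.

    ``p(t) = floor + (1-floor) * (1 - cos(2 pi k t)) / 2`` on t in [0, 1]:
    maxima at t = (2i+1)/(2k), troughs (value = floor) at the bead boundaries.
    """
    if bead_count < 1:
        raise ValueError("bead_count must be >= 1")
    if not (0.0 <= floor < 1.0):
        raise ValueError("bead floor must be in [0, 1)")
    t = np.linspace(0.0, 1.0, n)
    return floor + (1.0 - floor) * 0.5 * (1.0 - np.cos(2.0 * np.pi * bead_count * t))


@dataclass
class TerritoryModel:
    """Ground-truth geometric description of one chromosome territory.

    Attributes
    ----------
    centerline:
        ``(n, 3)`` ordered points in µm, axis order (z, y, x).  Index 0 is
        chromosome coordinate 0 (the PC end when the paint scheme's
        ``pc_end`` is ``"left"``).
    tube_radius:
        µm; territory width D = 2 * tube_radius.
    bead_profile:
        Per-point intensity multiplier in (0, 1].
    """

    centerline: np.ndarray
    tube_radius: float
    bead_profile: np.ndarray
    planted_bead_count: int
    paint: PaintScheme
    stage_label: str

    def __post_init__(self) -> None:
        self.centerline = np.asarray(self.centerline, dtype=float)
        self.bead_profile = np.asarray(self.bead_profile, dtype=float)
        if self.tube_radius <= 0:
            raise ValueError("tube_radius must be positive")
        if self.planted_bead_count < 1:
            raise ValueError("planted_bead_count must be >= 1")
        if len(self.bead_profile) != len(self.centerline):
            raise ValueError("bead_profile length must match the centerline")
        geometry.cumulative_arclength(self.centerline)  # validates shape
        if self.stage_label not in ("compact", "extended"):
            raise ValueError("stage_label must be 'compact' or 'extended'")

    @property
    def width(self) -> float:
        """Territory width D (µm)."""
        return 2.0 * self.tube_radius

    @property
    def length(self) -> float:
        """Geodesic centerline length L (µm)."""
        return geometry.arclength(self.centerline)

    @property
    def slenderness(self) -> float:
        """Analytic slenderness S = L / D."""
        return self.length / self.width

    def coordinates(self) -> np.ndarray:
        """Chromosome coordinate of each centerline point (arclength / L)."""
        s = geometry.cumulative_arclength(self.centerline)
        return s / s[-1]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TerritoryModel":
        """Rigidly transformed copy (rotation about the centerline centroid)."""
        pts = self.centerline
        if rotation is not None:
            c = pts.mean(axis=0)
            pts = (pts - c) @ rotation.T + c
        if translation is not None:
            pts = pts + np.asarray(translation, dtype=float)
        return replace(self, centerline=pts,
                       bead_profile=self.bead_profile.copy())


def _shaped_curve(length: float, stage_label: str, rng: np.random.Generator,
                  wiggle: float = 0.1, tighten: float = 0.0,
                  allow_helix: bool = True) -> np.ndarray:
    """Random smooth curve of the given arclength, centered on the origin.

    Compact territories are gentle near-straight arcs; extended ones are
    strongly curved arcs (so long threads curl inside the nucleus), both with
    a small smooth out-of-plane sinusoidal perturbation.  The curve is
    rescaled to the exact requested arclength.  ``tighten`` in [0, 1] biases
    extended threads toward maximal curl (used when fitting small nuclei);
    curl is capped so the tube cannot close on itself.
    """
    cap = 7.8 if allow_helix else 5.2
    if stage_label == "compact":
        theta = rng.uniform(0.2, 1.0)
    else:
        lo = min(2.5 + 4.5 * tighten, cap - 0.8)
        hi = min(4.5 + 3.3 * tighten, cap)
        theta = rng.uniform(lo, hi)
    base = geometry.circular_arc(length, length / theta, n=256)
    t = np.linspace(0.0, 1.0, len(base))
    if theta > 5.2:
        # long tightly curled threads pick up a helical pitch (~1 µm/turn)
        # so successive passes cannot touch
        ang = theta * t
        base[:, 0] += (ang - theta / 2.0) / (2.0 * np.pi)
    amp = wiggle * length / max(4.0, length / 0.5)
    freq = rng.integers(1, 3)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    base[:, 0] += amp * np.sin(2.0 * np.pi * freq * t + phase)
    # rescale to the exact arclength so planted slenderness is analytic
    cur = geometry.arclength(base)
    base *= length / cur
    base -= base.mean(axis=0)
    return base @ geometry.random_rotation(rng).T


def generate_territory(stage_label: str = "compact",
                       target_slenderness: float = 1.5,
                       bead_count: int = 1,
                       width_mean: float = WIDTH_MEAN,
                       width_sd: float = WIDTH_SD,
                       paint: PaintScheme | None = None,
                       seed: int | np.random.Generator = 0,
                       nuclear_radius: float | None = None,
                       wiggle: float = 0.1,
                       allow_helix: bool = True) -> TerritoryModel:
    """Draw one territory model.

    The width is drawn from the stated territory-width distribution
    (default mean 0.67 µm, SD 0.05 µm) and the centerline arclength is set to
    ``target_slenderness * width`` exactly.

    Parameters
    ----------
    nuclear_radius:
        If given, reject geometries whose extent (plus tube radius) cannot fit
        inside a nucleus of this radius centered at the origin; raises
        ``ValueError`` if no fitting shape is found.
    """
    if target_slenderness < 1.0:
        raise ValueError("target_slenderness must be >= 1")
    if bead_count < 1:
        raise ValueError("bead_count must be >= 1")
    if width_mean <= 0:
        raise ValueError("width_mean must be positive")
    if paint is None:
        from territory3d.paint import two_color_scheme
        paint = two_color_scheme("I")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    width = 0.0
    while width <= 0.1 * width_mean:
        width = rng.normal(width_mean, width_sd)
    radius = width / 2.0
    length = target_slenderness * width

    for attempt in range(64):
        curve = _shaped_curve(length, stage_label, rng, wiggle=wiggle,
                              tighten=attempt / 24.0, allow_helix=allow_helix)
        if nuclear_radius is None:
            break
        extent = np.linalg.norm(curve, axis=1).max() + radius
        if extent <= nuclear_radius:
            break
    else:
        raise ValueError(
            f"territory of length {length:.2f} µm cannot fit a nucleus of "
            f"radius {nuclear_radius} µm"
        )

    n = max(33, int(round(length / DS)) + 1)
    curve = geometry.resample_polyline(curve, n)
    # resampling perturbs arclength at the 1e-4 level; rescale once more
    curve *= length / geometry.arclength(curve)
    profile = bead_profile(n, bead_count)
    return TerritoryModel(
        centerline=curve,
        tube_radius=radius,
        bead_profile=profile,
        planted_bead_count=bead_count,
        paint=paint,
        stage_label=stage_label,
    )
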