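"""Spatial relationships between two chromosome territories.

Two families of scores:

* **proximity** — the shortest edge-to-edge distance ``d`` between two
  territories, expressed in units of the territory width ``D`` and
  classified as touching (mask contact), close (0 < d ≤ D), intermediate
  (D < d ≤ 2D) or far (d > 2D).  The printed category bounds overlap at
  exactly d = 2D ("intermediate (D<d≤2D) or far (2D≤d)"); the default
  resolves the boundary to intermediate (the strict reading of D<d≤2D) and
  a flag flips it.
* **alignment** — a per-chromosome-coordinate association profile between
  two homolog centerlines (a coordinate bin is paired when the two
  same-coordinate points lie within ``epsilon``, one territory width by
  default), summarized as an alignment state (unaligned / partial / full)
  and a configuration label (V-PC, Y-PC, V-NPC, Y-NPC, X, O, full, other,
  no_alignment, no_contact).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from territory3d.geometry import resample_polyline
from territory3d.morphometry import Centerline
from territory3d.segmentation import STRUCT26, TerritoryMask

__all__ = [
    "PairRecord",
    "edge_distance",
    "masks_touching",
    "classify_proximity",
    "association_profile",
    "classify_alignment_state",
    "classify_configuration",
]

PROXIMITY_CATEGORIES = ("touching", "close", "intermediate", "far")
CONFIGURATION_LABELS = ("V-PC", "Y-PC", "V-NPC", "Y-NPC", "X", "O", "full",
                        "other", "no_alignment", "no_contact")

DEFAULT_BINS = 20
#: single paired run confined to the terminal 15% of coordinate => V shape
TERMINAL_RUN_FRACTION = 0.15
FULL_PAIRED_FRACTION = 0.9
UNALIGNED_PAIRED_FRACTION = 0.05


@dataclass
class PairRecord:
    """Scored relationship of one territory pair in one nucleus."""

    nucleus_id: str
    chromosome_a: str
    chromosome_b: str
    kind: str  # "homologous" | "heterologous"
    edge_distance_d: float
    scale_d: float
    proximity: str
    alignment_state: str | None = None
    configuration: str | None = None
    paired_fraction: float | None = None
    association_profile: np.ndarray | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.edge_distance_d < 0:
            raise ValueError("edge distance must be >= 0")
        if self.proximity not in PROXIMITY_CATEGORIES:
            raise ValueError(f"unknown proximity {self.proximity!r}")
        if self.configuration is not None and self.configuration not in CONFIGURATION_LABELS:
            raise ValueError(f"unknown configuration {self.configuration!r}")


def masks_touching(mask_a: np.ndarray, mask_b: np.ndarray) -> bool:
    """True when the masks overlap or meet under 26-connectivity."""
    if (mask_a & mask_b).any():
        return True
    dil = ndimage.binary_dilation(mask_a, structure=STRUCT26)
    return bool((dil & mask_b).any())


def edge_distance(a: TerritoryMask | np.ndarray, b: TerritoryMask | np.ndarray,
                  voxel_size=None) -> float:
    """Shortest edge-to-edge distance (µm); 0 for touching/overlapping masks."""
    if isinstance(a, TerritoryMask):
        voxel_size = a.voxel_size
        mask_a, mask_b = a.mask, b.mask if isinstance(b, TerritoryMask) else b
    else:
        mask_a, mask_b = np.asarray(a, bool), np.asarray(b, bool)
        if voxel_size is None:
            raise ValueError("voxel_size required with raw masks")
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both masks must be non-empty")
    if masks_touching(mask_a, mask_b):
        return 0.0
    vs = np.asarray(voxel_size, dtype=float)
    ca = (np.argwhere(mask_a) + 0.5) * vs
    cb = (np.argwhere(mask_b) + 0.5) * vs
    d, _ = cKDTree(ca).query(cb, k=1)
    # voxel centers sit ~half a voxel inside each surface: correct one voxel
    return max(float(d.min()) - float(vs.min()), 0.0)


def classify_proximity(d: float, scale_d: float, touching: bool = False,
                       boundary_2d: str = "intermediate") -> str:
    """Proximity category of an edge distance ``d`` at width scale ``D``."""
    if d < 0:
        raise ValueError("edge distance must be >= 0")
    if scale_d <= 0:
        raise ValueError("width scale D must be positive")
    if boundary_2d not in ("intermediate", "far"):
        raise ValueError("boundary_2d must be 'intermediate' or 'far'")
    if touching or d == 0:
        return "touching"
    if d <= scale_d:
        return "close"
    if d < 2 * scale_d:
        return "intermediate"
    if d == 2 * scale_d:
        return boundary_2d
    return "far"


def association_profile(centerline_a: Centerline, centerline_b: Centerline,
                        epsilon: float, bins: int = DEFAULT_BINS) -> np.ndarray:
    """Paired/unpaired boolean profile over chromosome coordinate.

    Both centerlines must be oriented the same way (PC end first); bin ``i``
    is paired when the same-coordinate points at the bin center lie within
    ``epsilon`` µm.  Swapping the homologs leaves the profile unchanged.
    """
    if bins < 2:
        raise ValueError("need at least 2 bins")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    pa = _oriented_points(centerline_a, bins)
    pb = _oriented_points(centerline_b, bins)
    return np.linalg.norm(pa - pb, axis=1) <= epsilon


def _oriented_points(cl: Centerline, bins: int) -> np.ndarray:
    pts = resample_polyline(cl.points, 2 * bins + 1)[1::2]  # bin centers
    if cl.pc_at_start is False:
        pts = pts[::-1]
    return pts


def _runs(profile: np.ndarray) -> list[tuple[int, int]]:
    """Inclusive (start, stop) index ranges of True runs."""
    runs = []
    start = None
    for i, v in enumerate(profile):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(profile) - 1))
    return runs


def classify_alignment_state(profile: np.ndarray,
                             full_fraction: float = FULL_PAIRED_FRACTION,
                             unaligned_fraction: float = UNALIGNED_PAIRED_FRACTION) -> str:
    """unaligned / partial / full from a paired-bin profile.

    Full requires both terminal bins paired plus at least ``full_fraction``
    of bins overall (tolerating one unpaired interior bin from segmentation
    noise); unaligned means at most ``unaligned_fraction`` of bins paired.
    """
    profile = np.asarray(profile, dtype=bool)
    frac = profile.mean()
    if frac >= full_fraction and profile[0] and profile[-1]:
        return "full"
    if frac <= unaligned_fraction:
        return "unaligned"
    return "partial"


def classify_configuration(profile: np.ndarray, touching: bool,
                           pc_at_start: bool = True,
                           terminal_fraction: float = TERMINAL_RUN_FRACTION,
                           full_fraction: float = FULL_PAIRED_FRACTION) -> str:
    """Configuration label from an association profile.

    Decision order: no_contact (nothing paired, not touching); no_alignment
    (touching without any paired bin); full; V at either end (single run
    confined to the terminal ``terminal_fraction`` of coordinate); Y at
    either end (single run from an end, beyond terminal but below full); X
    (single interior run); O (runs at both ends, unpaired interior); other.
    """
    profile = np.asarray(profile, dtype=bool)
    if not pc_at_start:
        profile = profile[::-1]
    n = len(profile)
    runs = _runs(profile)
    if not runs:
        return "no_alignment" if touching else "no_contact"
    if classify_alignment_state(profile, full_fraction) == "full":
        return "full"
    term = max(int(np.ceil(terminal_fraction * n)), 1)
    if len(runs) == 1:
        (a, b) = runs[0]
        if a == 0 and b == n - 1:
            return "full"  # single run spanning everything
        if a == 0:
            return "V-PC" if b < term else "Y-PC"
        if b == n - 1:
            return "V-NPC" if (n - a) <= term else "Y-NPC"
        return "X"
    if len(runs) == 2:
        (a0, b0), (a1, b1) = runs
        if a0 == 0 and b1 == n - 1:
            return "O"
    return "other"
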