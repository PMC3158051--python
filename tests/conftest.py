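import logging

import numpy as np
import pytest

from territory3d.io import VoxelImage
from territory3d.paint import PaintScheme, PaintSegment, three_color_scheme, two_color_scheme

logging.getLogger("territory3d").setLevel(logging.ERROR)

VOX = (0.1, 0.1, 0.1)


@pytest.fixture(scope="session")
def mono_paint():
    return PaintScheme("mono", (PaintSegment(0.0, 1.0, 0),), "left")


@pytest.fixture(scope="session")
def halves_paint():
    return two_color_scheme("I", (0, 1))


@pytest.fixture(scope="session")
def thirds_paint():
    return three_color_scheme("I")


def straight_tube(radius=0.3, length=4.0, n=201, center=(0.0, 0.0, 0.0)):
    """Straight-tube territory model along x through ``center``."""
    from territory3d.paint import PaintScheme, PaintSegment
    from territory3d.synth.territory import TerritoryModel

    pts = np.zeros((n, 3))
    pts[:, 2] = np.linspace(-length / 2, length / 2, n)
    pts += np.asarray(center)
    paint = PaintScheme("T", (PaintSegment(0.0, 1.0, 0),), "left")
    return TerritoryModel(pts, radius, np.ones(n), 1, paint, "extended")


def analytic_capsule_mask(shape, voxel_size, origin, p0, p1, radius):
    """Brute-force voxel indicator of a capsule (tube + hemispherical caps)."""
    vs = np.asarray(voxel_size)
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * vs[i] for i in range(3)]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    p = np.stack([zz, yy, xx], axis=-1)
    a = np.asarray(p0, float)
    b = np.asarray(p1, float)
    ab = b - a
    t = np.clip(((p - a) @ ab) / (ab @ ab), 0.0, 1.0)
    proj = a + t[..., None] * ab
    dist = np.linalg.norm(p - proj, axis=-1)
    return dist <= radius


def render_model(model, voxel_size=VOX, pad=0.5, n_channels=None):
    """Tight noise-free render of a model, returning (VoxelImage, origin)."""
    from territory3d.synth.optics import render_territory_channels

    vs = np.asarray(voxel_size)
    lo = model.centerline.min(axis=0) - model.tube_radius - pad
    hi = model.centerline.max(axis=0) + model.tube_radius + pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / vs[k])) for k in range(3))
    if n_channels is None:
        n_channels = max(model.paint.channels) + 1
    img = render_territory_channels(model, shape, vs, lo, n_channels)
    vi = VoxelImage(img, tuple(vs), {c: f"paint{c}" for c in range(n_channels)})
    return vi, lo
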