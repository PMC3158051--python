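"""Recovery panels: scripted synthetic experiments with known ground truth.

Each panel generates territory models, renders them, runs the measurement
pipeline, and returns a tidy DataFrame of planted vs. recovered values.
They are the package's standard self-checks (used by the test suite and by
``scripts/acceptance.py``) and convenient starting points for sensitivity
analyses.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd

from territory3d import morphometry as mm
from territory3d import segmentation as seg
from territory3d.io import VoxelImage
from territory3d.paint import PaintScheme, PaintSegment, three_color_scheme
from territory3d.pairing import score_homolog_pair
from territory3d.synth.nucleus import (
    CONFIGURATIONS,
    NucleusSpec,
    PairSpec,
    generate_nucleus,
)
from territory3d.synth.optics import (
    OpticsParams,
    default_noisy_optics,
    render_territory_channels,
    render_voxels,
)
from territory3d.synth.territory import TerritoryModel, generate_territory

__all__ = [
    "render_single_territory",
    "width_recovery_panel",
    "slenderness_sweep",
    "configuration_recovery_panel",
    "segment_count_panel",
]

MONO_PAINT = PaintScheme("mono", (PaintSegment(0.0, 1.0, 0),), "left")


def render_single_territory(model: TerritoryModel,
                            voxel_size=(0.1, 0.1, 0.1),
                            pad: float = 0.5,
                            n_channels: int | None = None,
                            optics: OpticsParams | None = None) -> VoxelImage:
    """Render one territory model into a tight noise-free (or custom) stack."""
    vs = np.asarray(voxel_size, dtype=float)
    lo = model.centerline.min(axis=0) - model.tube_radius - pad
    hi = model.centerline.max(axis=0) + model.tube_radius + pad
    shape = tuple(int(np.ceil((hi[k] - lo[k]) / vs[k])) for k in range(3))
    if n_channels is None:
        n_channels = max(model.paint.channels) + 1
    img = render_territory_channels(model, shape, vs, lo, n_channels)
    if optics is not None:
        from scipy import ndimage

        img = img * optics.photon_scale + optics.background
        if any(s > 0 for s in optics.psf_sigma):
            sig = [optics.psf_sigma[i] / vs[i] for i in range(3)]
            for c in range(n_channels):
                img[c] = ndimage.gaussian_filter(img[c], sig)
        if optics.noise_model != "none":
            rng = np.random.default_rng(optics.rng_seed)
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
    return VoxelImage(img, tuple(vs), {c: f"paint{c}" for c in range(n_channels)})


def _measure_clean(model: TerritoryModel, voxel_size=(0.1, 0.1, 0.1)):
    """Noise-free render -> exact segmentation -> morphometry."""
    image = render_single_territory(model, voxel_size)
    mask = seg.segment_channel(image, model.paint.channels[0], "positive")
    cl = mm.extract_centerline(mask, voxel_size)
    vs = np.asarray(voxel_size, dtype=float)
    r0 = mm.medial_radius(mask, cl, vs)
    r = mm.refine_radius(mask, cl, r0, vs)
    d = max(2.0 * r + 0.25 * float(vs.min()), float(vs.min()))
    length = mm.corrected_length(mask, cl, r, voxel_size)
    return d, length


def width_recovery_panel(n: int = 100, seed: int = 0,
                         width_mean: float = 0.67,
                         width_sd: float = 0.05) -> pd.DataFrame:
    """Compact premeiotic territories at the wild-type width distribution.

    Renders each noise-free at 0.1 µm voxels, segments it exactly, and runs
    the width estimator; columns ``width_true`` / ``width_est`` (µm).
    """
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n):
        m = generate_territory("compact", target_slenderness=1.5, bead_count=1,
                               width_mean=width_mean, width_sd=width_sd,
                               paint=MONO_PAINT, seed=rng,
                               nuclear_radius=1.8)
        m.bead_profile[:] = 1.0
        d, _ = _measure_clean(m)
        rows.append({"width_true": m.width, "width_est": d})
    return pd.DataFrame(rows)


def slenderness_sweep(s_values=None, reps: int = 3, seed: int = 0,
                      width: float = 0.67) -> pd.DataFrame:
    """Noise-free tubes of known analytic slenderness, 1-12 by default.

    The sweep geometry is a gently curved planar tube of fixed width: the
    cleanest probe of the strict S > 6 decision boundary.  Columns:
    ``s_true``, ``s_est``, ``highly_extended``.
    """
    if s_values is None:
        s_values = np.arange(1.0, 12.01, 0.5)
    rows = []
    for s in s_values:
        rng = np.random.default_rng([seed, int(round(s * 10))])
        for _ in range(reps):
            m = generate_territory("compact", target_slenderness=float(s),
                                   bead_count=1, width_mean=width,
                                   width_sd=0.0, paint=MONO_PAINT, seed=rng,
                                   wiggle=0.0)
            m.bead_profile[:] = 1.0
            d, length = _measure_clean(m)
            s_est = mm.slenderness(length, d)
            rows.append({"s_true": float(s), "s_est": s_est,
                         "highly_extended": mm.classify_extension(s_est)})
    return pd.DataFrame(rows)


def configuration_recovery_panel(per_label: int = 20, seed: int = 0,
                                 noisy: bool = False,
                                 labels=None) -> pd.DataFrame:
    """Planted homolog-pair configurations -> image route -> recovered label."""
    paint = three_color_scheme("I")
    labels = list(labels or CONFIGURATIONS)
    rows = []
    for cfg in labels:
        for k in range(per_label):
            s = 5.0 if cfg == "no_alignment" else 8.0
            nuc = NucleusSpec(pairs=[PairSpec(
                paint=paint, stage_label="extended", configuration=cfg,
                target_slenderness=s, bead_count=3)])
            generate_nucleus(nuc, seed=np.random.default_rng([seed, zlib.crc32(cfg.encode()), k]))
            if noisy:
                optics = default_noisy_optics(seed=int(
                    np.random.default_rng([seed, 7, zlib.crc32(cfg.encode()), k]).integers(2**31)))
                policy = "background"
            else:
                optics = OpticsParams(photon_scale=100.0)
                policy = "positive"
            img, _ = render_voxels(nuc, optics)
            vi = VoxelImage(img, optics.voxel_size)
            masks = {c: seg.segment_channel(vi, c, policy)
                     for c in paint.channels}
            ters = seg.assemble_territories(vi, masks, paint)
            if not ters:
                rows.append({"planted": cfg, "recovered": "none"})
                continue
            rec = score_homolog_pair(vi, ters[:2], paint)
            rows.append({"planted": cfg, "recovered": rec.configuration})
    return pd.DataFrame(rows)


def segment_count_panel(bead_counts=range(1, 7), reps: int = 8, seed: int = 0,
                        noisy: bool = False) -> pd.DataFrame:
    """Beaded single territories: planted vs recovered painted-segment count."""
    rows = []
    for k in bead_counts:
        rng = np.random.default_rng([seed, k])
        for _ in range(reps):
            m = generate_territory("extended", target_slenderness=8.0,
                                   bead_count=int(k), paint=MONO_PAINT,
                                   seed=rng, nuclear_radius=1.6)
            if noisy:
                optics = default_noisy_optics(seed=int(rng.integers(2**31)))
                image = render_single_territory(m, optics=optics)
                mask = seg.segment_channel(image, 0, "background")
            else:
                image = render_single_territory(m)
                mask = seg.segment_channel(image, 0, "positive")
            cl = mm.extract_centerline(mask, image.voxel_size)
            got = mm.count_painted_segments(image, cl, m.paint)
            rows.append({"planted": int(k), "recovered": int(got)})
    return pd.DataFrame(rows)
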