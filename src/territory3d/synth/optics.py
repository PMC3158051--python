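"""Voxel rendering of nucleus geometry into multi-channel image stacks.

The imaging model is deliberately simple: each territory is a hard tube around
its centerline whose emission is the bead profile times a global photon scale;
the microscope contributes an isotropic-or-not Gaussian PSF, a constant
background, and Poisson (optionally plus Gaussian read) noise.  With the PSF
and noise switched off, a voxel's value in a paint channel is *exactly* the
analytic tube indicator x bead profile x photon scale, which is what makes
noise-free renders usable as segmentation ground truth.

Axis order is (channel, z, y, x); voxel sizes are (z, y, x) in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from territory3d import geometry
from territory3d.paint import PaintScheme
from territory3d.synth.nucleus import NucleusSpec
from territory3d.synth.territory import TerritoryModel

__all__ = ["OpticsParams", "render_voxels", "render_territory_channels"]

#: DAPI haze intensity (fraction of photon_scale) inside the nuclear sphere
DAPI_HAZE = 0.3
#: extra DAPI haze on the clustered side of a clustered nucleus
DAPI_CLUSTER_BOOST = 0.4
#: DAPI intensity of chromatin tubes
DAPI_CHROMATIN = 1.0


@dataclass(frozen=True)
class OpticsParams:
    """Rendering/optics parameters.

    noise_model is one of ``"none"``, ``"poisson"``, ``"poisson+gaussian"``.
    """

    voxel_size: tuple[float, float, float] = (0.1, 0.1, 0.1)
    psf_sigma: tuple[float, float, float] = (0.0, 0.0, 0.0)
    photon_scale: float = 1.0
    background: float = 0.0
    noise_model: str = "none"
    read_noise_sd: float = 2.0
    rng_seed: int = 0
    n_channels: int = 5
    dapi_channel: int | None = 4
    pad: float = 0.35  # µm of empty margin around the nucleus

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if any(s < 0 for s in self.psf_sigma):
            raise ValueError("psf_sigma must be non-negative")
        if self.photon_scale <= 0:
            raise ValueError("photon_scale must be positive")
        if self.noise_model not in ("none", "poisson", "poisson+gaussian"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")


def default_noisy_optics(seed: int = 0) -> OpticsParams:
    """Default realistic imaging conditions.

    Emulates a deconvolved wide-field z-stack (the acquisition mode used for
    chromosome-paint scoring): Poisson shot noise on a bright paint signal
    over a small camera background, with the *residual* blur left after
    deconvolution rather than a raw wide-field PSF.
    """
    return OpticsParams(
        psf_sigma=(0.08, 0.05, 0.05),
        photon_scale=300.0,
        background=5.0,
        noise_model="poisson",
        rng_seed=seed,
    )


def _voxel_centers(shape, voxel_size, origin):
    axes = [origin[i] + (np.arange(shape[i]) + 0.5) * voxel_size[i] for i in range(3)]
    return axes


def render_territory_channels(model: TerritoryModel, shape, voxel_size, origin,
                              n_channels: int) -> np.ndarray:
    """Expected (noise-free, PSF-free, unit-scale) channel stack of one tube.

    For every voxel center within ``tube_radius`` of the centerline (exact
    point-to-segment distance), intensity is the bead profile at the closest
    arclength, written into every channel painting the local chromosome
    coordinate.
    """
    az, ay, ax = _voxel_centers(shape, voxel_size, origin)
    out = np.zeros((n_channels,) + tuple(shape))
    r = model.tube_radius
    lo = model.centerline.min(axis=0) - r - 1e-9
    hi = model.centerline.max(axis=0) + r + 1e-9
    zi = np.where((az >= lo[0]) & (az <= hi[0]))[0]
    yi = np.where((ay >= lo[1]) & (ay <= hi[1]))[0]
    xi = np.where((ax >= lo[2]) & (ax <= hi[2]))[0]
    if zi.size == 0 or yi.size == 0 or xi.size == 0:
        raise ValueError("territory lies outside the rendered field of view")
    zz, yy, xx = np.meshgrid(az[zi], ay[yi], ax[xi], indexing="ij")
    pts = np.stack([zz.ravel(), yy.ravel(), xx.ravel()], axis=1)
    total_len = model.length
    cum = geometry.cumulative_arclength(model.centerline)
    prof_s = cum
    nch_scheme = model.paint.channel_weights(np.array([0.0])).shape[1]
    if nch_scheme > n_channels:
        raise ValueError("paint scheme uses more channels than rendered")
    # chunk the exact point-to-polyline distance computation
    chunk = max(1, int(4e5 / max(len(model.centerline), 1)))
    inside_idx = []
    inten = []
    svals = []
    for start in range(0, len(pts), chunk):
        d, s = geometry.point_to_polyline(pts[start:start + chunk], model.centerline)
        sel = d <= r
        if sel.any():
            inside_idx.append(start + np.where(sel)[0])
            svals.append(s[sel])
    if inside_idx:
        inside_idx = np.concatenate(inside_idx)
        svals = np.concatenate(svals)
        prof = np.interp(svals, prof_s, model.bead_profile)
        coords = svals / total_len
        w = model.paint.channel_weights(coords)  # (n, nch_scheme)
        sub = np.zeros((n_channels, len(pts)))
        for ch in range(nch_scheme):
            mask_ch = w[:, ch] > 0
            if mask_ch.any():
                sub[ch, inside_idx[mask_ch]] += prof[mask_ch]
        sub = sub.reshape((n_channels, len(zi), len(yi), len(xi)))
        out[:, zi[0]:zi[-1] + 1, yi[0]:yi[-1] + 1, xi[0]:xi[-1] + 1] += sub
    return out


def render_voxels(nucleus: NucleusSpec, optics: OpticsParams):
    """Render a realized nucleus into a multi-channel voxel stack.

    Returns ``(image, ground_truth)`` where ``image`` is a float array of
    shape ``(n_channels, nz, ny, nx)`` and ``ground_truth`` is a JSON-able
    dict recording the planted geometry (see :mod:`territory3d.synth.gonad`).
    """
    if not nucleus.realized:
        raise ValueError("nucleus geometry not realized; call generate_nucleus first")
    vz, vy, vx = optics.voxel_size
    R = nucleus.nuclear_radius + optics.pad
    shape = tuple(int(np.ceil(2 * R / v)) for v in optics.voxel_size)
    origin = (-R, -R, -R)

    expected = np.zeros((optics.n_channels,) + shape)
    for chrom, (a, b) in nucleus.territories.items():
        for m in (a, b):
            expected += render_territory_channels(
                m, shape, optics.voxel_size, origin, optics.n_channels) * optics.photon_scale

    if optics.dapi_channel is not None:
        az, ay, ax = _voxel_centers(shape, optics.voxel_size, origin)
        zz, yy, xx = np.meshgrid(az, ay, ax, indexing="ij")
        r2 = zz**2 + yy**2 + xx**2
        sphere = r2 <= nucleus.nuclear_radius**2
        haze = DAPI_HAZE * sphere.astype(float)
        if nucleus.clustered:
            # chromatin crowds one side: brighter hemisphere around the
            # centroid of the planted territories
            cent = np.mean([m.centerline.mean(axis=0)
                            for pair in nucleus.territories.values()
                            for m in pair], axis=0)
            nrm = np.linalg.norm(cent)
            if nrm > 1e-9:
                u = cent / nrm
                side = (zz * u[0] + yy * u[1] + xx * u[2]) > 0
                haze += DAPI_CLUSTER_BOOST * (sphere & side)
        chromatin = expected.sum(axis=0) > 0
        dapi = np.maximum(haze, DAPI_CHROMATIN * chromatin)
        expected[optics.dapi_channel] = dapi * optics.photon_scale

    expected += optics.background

    if any(s > 0 for s in optics.psf_sigma):
        sig_vox = [optics.psf_sigma[i] / optics.voxel_size[i] for i in range(3)]
        for c in range(optics.n_channels):
            expected[c] = ndimage.gaussian_filter(expected[c], sigma=sig_vox)

    if optics.noise_model == "none":
        image = expected
    else:
        rng = np.random.default_rng(optics.rng_seed)
        image = rng.poisson(np.clip(expected, 0, None)).astype(float)
        if optics.noise_model == "poisson+gaussian":
            image += rng.normal(0.0, optics.read_noise_sd, size=image.shape)
            image = np.clip(image, 0.0, None)

    truth = nucleus_ground_truth(nucleus)
    truth["optics"] = {
        "voxel_size": list(optics.voxel_size),
        "origin": list(origin),
        "psf_sigma": list(optics.psf_sigma),
        "photon_scale": optics.photon_scale,
        "background": optics.background,
        "noise_model": optics.noise_model,
    }
    return image, truth


def nucleus_ground_truth(nucleus: NucleusSpec) -> dict:
    """JSON-able planted truth for one nucleus."""
    from territory3d.synth.nucleus import (
        planted_association_profile,
        planted_edge_distance,
    )

    territories = {}
    pairs = {}
    for p in nucleus.pairs:
        chrom = p.paint.chromosome_id
        a, b = nucleus.territories[chrom]
        territories[chrom] = [
            {
                "centerline": m.centerline.tolist(),
                "tube_radius": m.tube_radius,
                "width": m.width,
                "length": m.length,
                "slenderness": m.slenderness,
                "bead_count": m.planted_bead_count,
                "stage": m.stage_label,
            }
            for m in (a, b)
        ]
        d = planted_edge_distance(a, b)
        pairs[chrom] = {
            "configuration": p.configuration,
            "proximity": p.proximity,
            "edge_distance": d,
            "association_profile": planted_association_profile(a, b).tolist(),
        }
    return {
        "nucleus_id": nucleus.nucleus_id,
        "nuclear_radius": nucleus.nuclear_radius,
        "clustered": nucleus.clustered,
        "row": nucleus.row,
        "zone": nucleus.zone_label,
        "territories": territories,
        "pairs": pairs,
    }
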