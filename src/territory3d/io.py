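"""Reading and writing multi-channel voxel stacks (OME-TIFF) and sidecars.

Stacks are stored channel-major, axes ``CZYX``, with the physical voxel size
in the OME pixel metadata.  Ground truth travels as a JSON sidecar next to
the stack.  Voxel indexing throughout the package is 0-based and z-major.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["VoxelImage", "write_stack", "read_stack", "write_truth",
           "read_truth", "mask_to_rle", "rle_to_mask"]

#: channel roles of the default 5-channel layout: 4 paint dyes + DAPI
DEFAULT_ROLES = {0: "paint0", 1: "paint1", 2: "paint2", 3: "paint3", 4: "dapi"}


@dataclass
class VoxelImage:
    """Multi-channel 3D intensity stack with physical voxel dimensions."""

    data: np.ndarray  # (C, Z, Y, X), non-negative
    voxel_size: tuple[float, float, float]  # (z, y, x) µm
    channel_roles: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_ROLES))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("expected a (C, Z, Y, X) array")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[1:]

    @property
    def dapi_channel(self) -> int | None:
        for c, role in self.channel_roles.items():
            if role == "dapi":
                return c
        return None

    def channel(self, c: int) -> np.ndarray:
        if not 0 <= c < self.n_channels:
            raise ValueError(f"channel {c} out of range")
        return self.data[c]


def write_stack(path: str | Path, image: VoxelImage) -> Path:
    """Write a stack as OME-TIFF with voxel size in the pixel metadata."""
    path = Path(path)
    vz, vy, vx = image.voxel_size
    payload = image.data.astype(np.float32)
    # content-derived UUID keeps rewrites bit-identical (reproducible runs)
    import hashlib
    import uuid as uuidlib

    digest = hashlib.sha256(payload.tobytes()).digest()[:16]
    stable_uuid = str(uuidlib.UUID(bytes=digest))
    tifffile.imwrite(
        path,
        payload,
        ome=True,
        photometric="minisblack",
        metadata={
            "UUID": f"urn:uuid:{stable_uuid}",
            "axes": "CZYX",
            "PhysicalSizeZ": vz,
            "PhysicalSizeY": vy,
            "PhysicalSizeX": vx,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeXUnit": "µm",
            "Channel": {"Name": [image.channel_roles.get(c, f"ch{c}")
                                 for c in range(image.n_channels)]},
        },
    )
    return path


def read_stack(path: str | Path,
               expected_channel_roles: dict[int, str] | None = None,
               voxel_size_override: tuple[float, float, float] | None = None,
               ) -> VoxelImage:
    """Read an OME-TIFF stack written by this package or a microscope.

    Voxel size comes from the OME metadata; if absent, ``voxel_size_override``
    is required.  If ``expected_channel_roles`` is given, the channel count
    must match.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    stored_names: list[str] = []
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        axes = tf.series[0].axes
        vsize = voxel_size_override
        if tf.ome_metadata is not None:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            ns = {"ome": root.tag.split("}")[0].strip("{")}
            px = root.find(".//ome:Pixels", ns)
            if px is not None and vsize is None and all(
                f"PhysicalSize{a}" in px.attrib for a in "ZYX"
            ):
                vsize = tuple(float(px.attrib[f"PhysicalSize{a}"]) for a in "ZYX")
            stored_names = [c.attrib.get("Name", "")
                            for c in root.findall(".//ome:Channel", ns)]
    if vsize is None:
        raise ValueError(
            f"{path}: no voxel-size metadata; pass voxel_size_override=(z,y,x)"
        )
    axes = axes.replace("Q", "Z")  # unlabeled stack axis
    if data.ndim == 3:  # single channel
        data = data[None]
        axes = "C" + axes
    if axes not in ("CZYX", "ZCYX"):
        raise ValueError(f"unsupported axis order {axes!r}")
    if axes == "ZCYX":
        data = np.moveaxis(data, 1, 0)
    if expected_channel_roles is not None:
        roles = expected_channel_roles
    elif len(stored_names) == data.shape[0] and all(stored_names):
        roles = dict(enumerate(stored_names))
    else:
        roles = {c: ("dapi" if c == data.shape[0] - 1 else f"paint{c}")
                 for c in range(data.shape[0])}
    if expected_channel_roles is not None and len(expected_channel_roles) != data.shape[0]:
        raise ValueError(
            f"{path}: {data.shape[0]} channels but {len(expected_channel_roles)} "
            "expected channel roles"
        )
    return VoxelImage(data=np.asarray(data, dtype=float), voxel_size=tuple(vsize),
                      channel_roles=dict(roles))


def mask_to_rle(mask: np.ndarray) -> dict:
    """Run-length encode a boolean volume (z-major raveling, 0-based).

    JSON-able: ``{"shape": [...], "starts": [...], "lengths": [...]}``.
    """
    mask = np.asarray(mask, dtype=bool)
    flat = mask.ravel()
    edges = np.flatnonzero(np.diff(np.concatenate([[0], flat.view(np.int8), [0]])))
    starts = edges[0::2]
    lengths = edges[1::2] - starts
    return {"shape": list(mask.shape), "starts": starts.tolist(),
            "lengths": lengths.tolist()}


def rle_to_mask(rle: dict) -> np.ndarray:
    """Inverse of :func:`mask_to_rle`."""
    shape = tuple(rle["shape"])
    flat = np.zeros(int(np.prod(shape)), dtype=bool)
    for s, l in zip(rle["starts"], rle["lengths"]):
        flat[s:s + l] = True
    return flat.reshape(shape)


def write_truth(path: str | Path, truth: dict) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth))
    return path


def read_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
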