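"""Calibrated image stacks and TIFF round-tripping.

An :class:`ImageStack` is the raw input of every imaging stage: a
``(C, Z, Y, X)`` voxel grid with named channels, an in-plane pixel size and a
z-step (both in micrometres).  Stacks are written as multi-page TIFF with the
calibration and channel names embedded as JSON metadata, so a write/read
round trip restores the object bit-for-bit.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import tifffile

log = logging.getLogger("gastrulaquant")

DEFAULT_PIXEL_SIZE_UM = 1.0
DEFAULT_Z_STEP_UM = 2.0

__all__ = ["ImageStack", "read_stack", "write_stack"]


@dataclass
class ImageStack:
    """Multi-channel 3-D voxel grid with physical calibration."""

    data: np.ndarray                      # (C, Z, Y, X), float32
    channels: tuple[str, ...]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float = DEFAULT_Z_STEP_UM

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim == 3:          # single channel
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError(f"stack must be (C, Z, Y, X), got shape {self.data.shape}")
        if len(self.channels) != self.data.shape[0]:
            raise ValueError(
                f"channel-count mismatch: {len(self.channels)} names for "
                f"{self.data.shape[0]} channels"
            )
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("calibration must be > 0")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]

    def channel(self, name: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(name)]
        except ValueError:
            raise KeyError(f"no channel named {name!r}; have {self.channels}") from None

    def content_hash(self) -> str:
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.data).tobytes())
        h.update(repr((self.channels, self.pixel_size_um, self.z_step_um)).encode())
        return h.hexdigest()[:16]


def write_stack(path, stack: ImageStack) -> None:
    tifffile.imwrite(
        str(path),
        stack.data.astype(np.float32),
        photometric="minisblack",
        metadata={
            "axes": "CZYX",
            "channels": list(stack.channels),
            "pixel_size_um": stack.pixel_size_um,
            "z_step_um": stack.z_step_um,
        },
    )


def read_stack(path, channels: tuple[str, ...] | None = None) -> ImageStack:
    """Read a multi-page TIFF written by :func:`write_stack` (or any grayscale
    stack); missing calibration falls back to defaults with a warning.

    If ``channels`` is given it must match the file's channel count.
    """
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    axes = meta.get("axes", "")
    if data.ndim == 2:
        data = data[None, None]
    elif data.ndim == 3:
        data = data[None] if axes.startswith("Z") else data[:, None]
    px = meta.get("pixel_size_um")
    pz = meta.get("z_step_um")
    if px is None or pz is None:
        warnings.warn(
            f"{path}: missing calibration metadata; defaulting to "
            f"{DEFAULT_PIXEL_SIZE_UM} um/px, {DEFAULT_Z_STEP_UM} um z-step"
        )
        px = px or DEFAULT_PIXEL_SIZE_UM
        pz = pz or DEFAULT_Z_STEP_UM
    names = tuple(meta.get("channels", [f"ch{i}" for i in range(data.shape[0])]))
    if channels is not None:
        if len(channels) != data.shape[0]:
            raise ValueError(
                f"channel-count mismatch: config names {len(channels)} channels, "
                f"file has {data.shape[0]}"
            )
        names = tuple(channels)
    return ImageStack(data=data, channels=names, pixel_size_um=float(px), z_step_um=float(pz))
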