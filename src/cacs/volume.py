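"""3D image volumes with physical voxel pitch.

The package works on grayscale stacks ordered (z, y, x), with z the
light-sheet scan axis (TIFF page index).  Voxel centers sit at
``(i + 0.5) * pitch`` along each axis; all physical coordinates are in
micrometers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile


@dataclass
class ImageVolume:
    """A 3D intensity array with per-axis voxel pitch.

    Parameters
    ----------
    data : ndarray, shape (nz, ny, nx)
        Intensity values.  Any real dtype.
    pitch : tuple of float
        Voxel pitch (z, y, x) in micrometers.
    value_range : tuple of float, optional
        Nominal (min, max) of the encoding, e.g. (0, 65535) for a 16-bit
        camera.  Defaults to the data min/max on first access.
    """

    data: np.ndarray
    pitch: tuple[float, float, float]
    value_range: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        self.pitch = tuple(float(p) for p in self.pitch)
        if len(self.pitch) != 3 or any(p <= 0 for p in self.pitch):
            raise ValueError(f"pitch must be three positive floats, got {self.pitch}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent(self) -> tuple[float, float, float]:
        """Physical size (z, y, x) in micrometers."""
        return tuple(n * p for n, p in zip(self.data.shape, self.pitch))

    def range(self) -> tuple[float, float]:
        if self.value_range is not None:
            return self.value_range
        return float(self.data.min()), float(self.data.max())

    def astype(self, dtype) -> "ImageVolume":
        return ImageVolume(self.data.astype(dtype), self.pitch, self.value_range)

    def save(self, path) -> None:
        """Write as a multi-page TIFF with ImageJ-style pitch metadata."""
        write_tiff(path, self)

    @classmethod
    def load(cls, path, pitch: tuple[float, float, float] | None = None) -> "ImageVolume":
        return read_tiff(path, pitch=pitch)


def write_tiff(path, vol: ImageVolume) -> None:
    data = vol.data
    if data.dtype not in (np.uint8, np.uint16, np.float32):
        data = data.astype(np.float32)
    pz, py, px = vol.pitch
    tifffile.imwrite(
        path,
        data,
        imagej=True,
        resolution=(1.0 / px, 1.0 / py),
        metadata={"spacing": pz, "unit": "um", "axes": "ZYX"},
    )


def read_tiff(path, pitch=None) -> ImageVolume:
    """Read a multi-page grayscale TIFF; pitch from ImageJ tags unless given."""
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if data.ndim == 2:
            data = data[None]
        if pitch is None:
            pz = py = px = 1.0
            ij = tf.imagej_metadata or {}
            if "spacing" in ij:
                pz = float(ij["spacing"])
            page = tf.pages[0]
            xres = page.tags.get("XResolution")
            yres = page.tags.get("YResolution")
            if xres is not None:
                num, den = xres.value
                if num:
                    px = den / num
            if yres is not None:
                num, den = yres.value
                if num:
                    py = den / num
            pitch = (pz, py, px)
    return ImageVolume(np.asarray(data), pitch)


def scale_to_uint16(data: np.ndarray, lo: float | None = None, hi: float | None = None):
    """Map ``data`` linearly onto [0, 65535]; returns (array, (lo, hi, scale))."""
    lo = float(data.min()) if lo is None else float(lo)
    hi = float(data.max()) if hi is None else float(hi)
    span = hi - lo
    if span <= 0:
        return np.zeros(data.shape, np.uint16), (lo, hi, 0.0)
    scale = 65535.0 / span
    out = np.clip((data - lo) * scale, 0, 65535).astype(np.uint16)
    return out, (lo, hi, scale)
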