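"""Raster image container and TIFF/PNG I/O.

Every analysis stage consumes :class:`RasterImage`: a 2-D scalar intensity
array tagged with a physical pixel size in micrometres and a channel role
(actin cytoskeleton, nuclei, bright-field, or other).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


class ChannelRole(str, enum.Enum):
    ACTIN = "actin"
    NUCLEI = "nuclei"
    BRIGHTFIELD = "brightfield"
    OTHER = "other"


@dataclass(frozen=True)
class RasterImage:
    """2-D scalar image with physical pixel size.

    Parameters
    ----------
    pixels : ndarray
        2-D array of intensities (any real dtype); finite values only.
    pixel_size_um : float
        Edge length of one pixel in micrometres; must be positive.
    channel_role : ChannelRole
        Which fluorescence/bright-field channel this image represents.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_role: ChannelRole = ChannelRole.OTHER

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise ValueError(f"expected a 2-D image, got shape {px.shape}")
        if px.shape[0] < 8 or px.shape[1] < 8:
            raise ValueError(f"image must be at least 8x8, got {px.shape}")
        if not np.all(np.isfinite(px.astype(np.float64, copy=False))):
            raise ValueError("image contains non-finite values")
        if not (self.pixel_size_um > 0):
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def extent_um(self) -> tuple[float, float]:
        """(width, height) of the frame in micrometres."""
        h, w = self.pixels.shape
        return (w * self.pixel_size_um, h * self.pixel_size_um)

    def as_float(self) -> np.ndarray:
        return self.pixels.astype(np.float64, copy=False)

    def with_pixels(self, pixels: np.ndarray) -> "RasterImage":
        return replace(self, pixels=pixels)


def read_image(
    path: str | Path,
    channel_role: ChannelRole | str = ChannelRole.OTHER,
    pixel_size_um: float = 1.0,
) -> RasterImage | list[RasterImage]:
    """Read a TIFF or PNG image (8/16-bit integer or float).

    Multi-page TIFFs return one :class:`RasterImage` per page; pass a list of
    roles (one per page) to tag them.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        data = tifffile.imread(path)
    else:
        data = iio.imread(path)
    if data.ndim == 2:
        role = ChannelRole(channel_role) if not isinstance(channel_role, (list, tuple)) else ChannelRole(channel_role[0])
        return RasterImage(data, pixel_size_um, role)
    if data.ndim == 3:
        # multi-page stack: smallest axis is the page axis
        page_axis = int(np.argmin(data.shape))
        pages = np.moveaxis(data, page_axis, 0)
        if isinstance(channel_role, (list, tuple)):
            roles = [ChannelRole(r) for r in channel_role]
        else:
            roles = [ChannelRole(channel_role)] * pages.shape[0]
        if len(roles) != pages.shape[0]:
            raise ValueError("number of channel roles does not match page count")
        return [RasterImage(p, pixel_size_um, r) for p, r in zip(pages, roles)]
    raise ValueError(f"unsupported image dimensionality: {data.shape}")


def write_raster(array: np.ndarray, path: str | Path, dtype: str | None = None) -> Path:
    """Write an array as TIFF (float maps go to 32-bit) or PNG (8/16-bit).

    Round-trip safe: integer dtypes are reproduced exactly; float maps are
    stored as float32.
    """
    path = Path(path)
    arr = np.asarray(array)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(np.float32)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, arr)
    elif path.suffix.lower() == ".png":
        if np.issubdtype(arr.dtype, np.floating):
            raise ValueError("PNG output requires an integer dtype")
        iio.imwrite(path, arr)
    else:
        raise ValueError(f"unsupported output format: {path.suffix}")
    return path
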