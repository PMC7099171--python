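"""Reading and writing calibrated microscopy images.

Fluorescence channels (endothelial markers such as CD31 or lectin, mural-cell
markers such as CD13 or PDGFR-beta) are handled as independent single-channel
rasters carrying an explicit physical calibration in micrometres per pixel.
The calibration is always supplied by the caller; embedded TIFF resolution
tags are ignored unless explicitly trusted, because metadata dialects vary
between acquisition systems and a silently wrong pixel size corrupts every
downstream density.

Coordinate convention: row-major arrays, origin at the top-left corner,
0-based indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import imageio.v3 as iio
import tifffile

from vasquant.errors import ConfigurationError, FormatError

_SUPPORTED_DTYPES = ("uint8", "uint16", "float32")


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel 2D intensity image with physical pixel size.

    Parameters
    ----------
    pixels
        2D array of non-negative intensities.
    pixel_size_um
        Physical edge length of one pixel, in micrometres. Must be positive.
    channel_label
        Free-text marker name, e.g. ``"CD31"`` or ``"PDGFRB"``.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel_label: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError(f"pixels must be a non-empty 2D array, got shape {px.shape}")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")
        if px.size and float(px.min()) < 0:
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "pixels", px)

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def _check_dtype(arr: np.ndarray, path: Path) -> np.ndarray:
    if arr.dtype == np.float64:
        arr = arr.astype(np.float32)
    if arr.dtype.name not in _SUPPORTED_DTYPES:
        raise FormatError(
            f"{path}: unsupported bit depth {arr.dtype}; "
            "supported: 8-bit/16-bit integer, 32-bit float"
        )
    return arr


def _select_channel(arr: np.ndarray, channel_index: int, path: Path) -> np.ndarray:
    """Reduce an array read from disk to the requested 2D channel.

    3D arrays are interpreted as (channel, H, W) when the leading axis is
    small, or as (H, W, channel) for interleaved RGB(A) data.  RGB channels
    map by index (0=R, 1=G, 2=B) with no luminance conversion — fluorescence
    channels are independent markers.
    """
    if arr.ndim == 2:
        if channel_index != 0:
            raise ConfigurationError(
                f"{path}: channel_index {channel_index} out of range for single-channel image"
            )
        return arr
    if arr.ndim == 3:
        # interleaved (H, W, C) — typical of PNG RGB(A)
        if arr.shape[-1] in (3, 4) and arr.shape[0] > 4 and arr.shape[1] > 4:
            n = arr.shape[-1]
            if not 0 <= channel_index < n:
                raise ConfigurationError(
                    f"{path}: channel_index {channel_index} out of range (file has {n} channels)"
                )
            return arr[..., channel_index]
        # planar (C, H, W) — typical of multi-channel TIFF
        n = arr.shape[0]
        if not 0 <= channel_index < n:
            raise ConfigurationError(
                f"{path}: channel_index {channel_index} out of range (file has {n} channels)"
            )
        return arr[channel_index]
    raise FormatError(f"{path}: cannot interpret array of shape {arr.shape} as 2D channels")


def load_image(
    path: str | Path,
    pixel_size_um: float,
    channel_index: int = 0,
    channel_label: str = "",
) -> CalibratedImage:
    """Load one channel of a TIFF or PNG image as a :class:`CalibratedImage`.

    Multi-channel TIFFs keep their stored channel order.  A multi-page TIFF
    is treated as a z-stack only by :func:`load_stack`; here the first page's
    channels are addressed.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ConfigurationError
        If ``channel_index`` is outside the file's channel count.
    FormatError
        For unsupported bit depths or layouts.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    arr = _check_dtype(arr, path)
    chan = _select_channel(arr, channel_index, path)
    return CalibratedImage(chan, pixel_size_um, channel_label)


def load_stack(
    path: str | Path,
    pixel_size_um: float,
    channel_index: int = 0,
    channel_label: str = "",
) -> list[CalibratedImage]:
    """Load a multi-page TIFF as a list of slices (a z-stack).

    Each page may itself be multi-channel; ``channel_index`` selects within
    each page.  Single-page files yield a one-element list.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    arr = np.asarray(tifffile.imread(path))
    arr = _check_dtype(arr, path)
    if arr.ndim == 2:
        pages = [arr]
    elif arr.ndim == 3:
        pages = list(arr)
    elif arr.ndim == 4:  # (Z, C, H, W)
        pages = [_select_channel(p, channel_index, path) for p in arr]
        return [CalibratedImage(p, pixel_size_um, channel_label) for p in pages]
    else:
        raise FormatError(f"{path}: cannot interpret shape {arr.shape} as a z-stack")
    out = []
    for p in pages:
        if p.ndim == 3:
            p = _select_channel(p, channel_index, path)
        out.append(CalibratedImage(p, pixel_size_um, channel_label))
    return out


def max_project(stack: Sequence[CalibratedImage]) -> CalibratedImage:
    """Maximum-intensity projection of a z-stack into a single 2D image.

    All slices must share shape and calibration.  Projection is opt-in in
    the pipeline: single optical sections are analyzed as-is.
    """
    if len(stack) == 0:
        raise ValueError("max_project requires at least one slice")
    first = stack[0]
    for s in stack[1:]:
        if s.shape != first.shape:
            raise ValueError(f"slice shape mismatch: {s.shape} vs {first.shape}")
        if s.pixel_size_um != first.pixel_size_um:
            raise ValueError("slice calibration mismatch")
    proj = np.maximum.reduce([s.pixels for s in stack])
    return CalibratedImage(proj, first.pixel_size_um, first.channel_label)


def save_mask(mask, path: str | Path) -> None:
    """Write a binary mask as an 8-bit TIFF (foreground=255, background=0)."""
    path = Path(path)
    arr = (np.asarray(mask.pixels, dtype=bool).astype(np.uint8)) * 255
    tifffile.imwrite(path, arr)


def save_image(img: CalibratedImage, path: str | Path) -> None:
    """Write a calibrated image's raw pixels to TIFF (dtype preserved)."""
    tifffile.imwrite(Path(path), np.asarray(img.pixels))
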