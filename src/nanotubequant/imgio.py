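"""Calibrated micrograph input/output.

Every downstream measurement in this package is stated in physical units
(µm, µm²), so each raster carries a mandatory ``pixel_size`` in µm per
pixel edge.  Calibration is always supplied by the caller — TIFF metadata
is never trusted silently: when a TIFF resolution tag is present and
disagrees with the supplied value by more than 1 % a warning is emitted
and the supplied value wins.

Coordinate convention: row-major, origin at the top-left corner, 0-based
indices.  Intensities are used only via thresholding; no illumination or
flat-field correction is applied anywhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile


class ChannelTag(str, Enum):
    DONOR = "donor"
    RECIPIENT = "recipient"
    CELL = "cell"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class CalibratedImage:
    """Single-channel 2-D intensity raster with a physical pixel size.

    Parameters
    ----------
    pixels:
        2-D array of finite, non-negative intensities (arbitrary units).
    pixel_size:
        µm per pixel edge; strictly positive.
    channel_tag:
        Which biological channel this raster represents.
    """

    pixels: np.ndarray
    pixel_size: float
    channel_tag: ChannelTag = ChannelTag.UNASSIGNED

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D raster")
        if not np.issubdtype(px.dtype, np.number):
            raise TypeError("pixels must be numeric")
        if not np.all(np.isfinite(px)):
            raise ValueError("intensities must be finite")
        if px.min() < 0:
            raise ValueError("intensities must be non-negative")
        if not (np.isscalar(self.pixel_size) or np.ndim(self.pixel_size) == 0):
            raise TypeError("pixel_size must be a scalar")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_size", float(self.pixel_size))
        object.__setattr__(self, "channel_tag", ChannelTag(self.channel_tag))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    def with_tag(self, tag: ChannelTag | str) -> "CalibratedImage":
        return CalibratedImage(self.pixels, self.pixel_size, ChannelTag(tag))


@dataclass(frozen=True)
class ChannelPair:
    """Donor / recipient channel pair sharing shape and calibration."""

    donor: CalibratedImage
    recipient: CalibratedImage

    def __post_init__(self) -> None:
        if self.donor.shape != self.recipient.shape:
            raise ValueError("donor and recipient rasters differ in shape")
        if self.donor.pixel_size != self.recipient.pixel_size:
            raise ValueError("donor and recipient pixel sizes differ")


@dataclass(frozen=True)
class BinaryMask:
    """Boolean raster with the same shape/calibration contract as its source."""

    pixels: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=bool)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("mask must be a non-empty 2-D raster")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be > 0")
        object.__setattr__(self, "pixels", px)
        object.__setattr__(self, "pixel_size", float(self.pixel_size))

    @property
    def area_um2(self) -> float:
        return float(self.pixels.sum()) * self.pixel_size**2


def um2_to_px(area_um2: float, pixel_size: float) -> float:
    """Convert an area in µm² to a (real-valued) pixel count."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    return area_um2 / pixel_size**2


def px_to_um2(n_pixels: float, pixel_size: float) -> float:
    """Inverse of :func:`um2_to_px`."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    return n_pixels * pixel_size**2


def um_to_px(length_um: float, pixel_size: float) -> float:
    """Convert a length in µm to pixels."""
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    return length_um / pixel_size


def _tiff_metadata_pixel_size(path: Path) -> float | None:
    """µm/px recorded in TIFF resolution tags, if any (best effort)."""
    try:
        with tifffile.TiffFile(path) as tf:
            page = tf.pages[0]
            res = page.tags.get("XResolution")
            unit = page.tags.get("ResolutionUnit")
            if res is None:
                return None
            num, den = res.value
            if num == 0 or den == 0:
                return None
            per_unit = num / den  # pixels per unit
            if unit is not None and getattr(unit.value, "name", str(unit.value)) in ("CENTIMETER", "3", "RESUNIT.CENTIMETER"):
                return 1e4 / per_unit
            # inch or unspecified: cannot interpret reliably
            return None
    except Exception:
        return None


def _squeeze_single_channel(arr: np.ndarray, path: Path) -> np.ndarray:
    """Reduce a (H, W, C) or (C, H, W) array to its single non-empty channel."""
    if arr.ndim == 2:
        return arr
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a 2-D or 3-channel raster, got shape {arr.shape}")
    # channel axis = the small one
    axis = int(np.argmin(arr.shape))
    arr = np.moveaxis(arr, axis, 0)
    nonempty = [i for i in range(arr.shape[0]) if arr[i].any()]
    if len(nonempty) == 0:
        return arr[0]
    if len(nonempty) > 1:
        raise ValueError(
            f"{path}: {len(nonempty)} non-empty channels; use split_channels or a channel selector"
        )
    return arr[nonempty[0]]


def load_image(
    path: str | Path,
    pixel_size: float,
    channel_tag: ChannelTag | str = ChannelTag.UNASSIGNED,
    channel: int | None = None,
) -> CalibratedImage:
    """Read a single-channel 8/16-bit TIFF or PNG as a :class:`CalibratedImage`.

    An RGB/multi-channel file is accepted when exactly one channel is
    non-empty (it is reduced to that channel) or when ``channel`` selects
    one explicitly.  Intensities are preserved bit-exactly.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if not pixel_size > 0:
        raise ValueError("pixel_size must be > 0")
    arr = np.asarray(iio.imread(path))
    if channel is not None:
        if arr.ndim != 3:
            raise ValueError(f"{path}: channel selector given for a single-channel file")
        axis = int(np.argmin(arr.shape))
        arr = np.moveaxis(arr, axis, 0)
        if not 0 <= channel < arr.shape[0]:
            raise IndexError(f"channel {channel} out of range for {arr.shape[0]} channels")
        arr = arr[channel]
    else:
        arr = _squeeze_single_channel(arr, path)

    if path.suffix.lower() in (".tif", ".tiff"):
        meta_px = _tiff_metadata_pixel_size(path)
        if meta_px is not None and abs(meta_px - pixel_size) / pixel_size > 0.01:
            warnings.warn(
                f"{path}: TIFF metadata pixel size {meta_px:.4g} µm/px differs from "
                f"configured {pixel_size:.4g} µm/px by >1%; using configured value",
                stacklevel=2,
            )
    return CalibratedImage(arr, pixel_size, ChannelTag(channel_tag))


def save_image(path: str | Path, image: CalibratedImage) -> None:
    """Write a calibrated image as TIFF or PNG, preserving dtype bit-exactly."""
    path = Path(path)
    arr = image.pixels
    if path.suffix.lower() in (".tif", ".tiff"):
        # record calibration in the resolution tags (pixels per cm)
        per_cm = 1e4 / image.pixel_size
        tifffile.imwrite(path, arr, resolution=(per_cm, per_cm), resolutionunit="CENTIMETER")
    else:
        iio.imwrite(path, arr)


def split_channels(
    path: str | Path,
    donor_channel: int,
    recipient_channel: int,
    pixel_size: float,
) -> ChannelPair:
    """Split a multi-channel file into donor and recipient calibrated channels."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if donor_channel == recipient_channel:
        raise ValueError("donor and recipient channel indices must differ")
    arr = np.asarray(iio.imread(path))
    if arr.ndim != 3:
        raise ValueError(f"{path}: expected a multi-channel file")
    axis = int(np.argmin(arr.shape))
    arr = np.moveaxis(arr, axis, 0)
    n = arr.shape[0]
    for idx in (donor_channel, recipient_channel):
        if not 0 <= idx < n:
            raise IndexError(f"channel index {idx} out of range for {n} channels")
    donor = CalibratedImage(arr[donor_channel], pixel_size, ChannelTag.DONOR)
    recipient = CalibratedImage(arr[recipient_channel], pixel_size, ChannelTag.RECIPIENT)
    return ChannelPair(donor, recipient)
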