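"""Image containers, TIFF I/O, line sampling, 1-D peak finding, and marker masks.

Conventions
-----------
Coordinates are ``(x, y)`` with the origin at the top-left pixel, 0-based,
and pixel centers at integer positions.  Arrays are indexed ``pixels[y, x]``.
Lines are sampled on the half-open interval ``[p0, p1)`` at uniform spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile
from scipy import ndimage, signal
from skimage.filters import threshold_otsu

__all__ = [
    "ChannelImage",
    "TimeSeriesStack",
    "LineProfile",
    "read_tiff",
    "write_tiff",
    "sample_line",
    "find_profile_peaks",
    "robust_noise_sd",
    "pm_mask_from_marker",
]


@dataclass
class ChannelImage:
    """A single 2-D fluorescence channel.

    Parameters
    ----------
    pixels : ndarray
        2-D array of non-negative intensities (counts).
    channel_label : str
        Name of the channel (e.g. ``"reporter"``, ``"marker"``, ``"er"``).
    bit_depth : int
        Acquisition bit depth, 8 or 16.  Pixel values are stored as float64
        internally; the bit depth controls TIFF export.
    pixel_size : float
        Physical pixel size in µm/px (metadata only).
    """

    pixels: np.ndarray
    channel_label: str = ""
    bit_depth: int = 16
    pixel_size: float = 0.1

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("ChannelImage requires a 2-D array")
        if self.pixels.shape[0] < 8 or self.pixels.shape[1] < 8:
            raise ValueError("image must be at least 8x8 pixels")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("image contains non-finite values")
        if np.any(self.pixels < 0):
            raise ValueError("image contains negative intensities")
        if self.bit_depth not in (8, 16):
            raise ValueError("bit_depth must be 8 or 16")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class TimeSeriesStack:
    """An ordered 2-D+time stack of frames from one channel.

    ``bleach_frame_index`` marks the first frame acquired after the
    photobleach event (None for stacks without a bleach).
    """

    frames: list[ChannelImage]
    timestamps: np.ndarray
    bleach_frame_index: int | None = None

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        if len(self.frames) != self.timestamps.size:
            raise ValueError("one timestamp per frame required")
        if len(self.frames) == 0:
            raise ValueError("empty stack")
        shape = self.frames[0].shape
        if any(f.shape != shape for f in self.frames):
            raise ValueError("all frames must share a shape")
        if np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.bleach_frame_index is not None and not (
            1 <= self.bleach_frame_index < len(self.frames)
        ):
            raise ValueError("bleach_frame_index out of range")

    def __len__(self) -> int:
        return len(self.frames)

    def as_array(self) -> np.ndarray:
        """Return the stack as a (t, y, x) float array."""
        return np.stack([f.pixels for f in self.frames])


@dataclass
class LineProfile:
    """Intensity profile(s) sampled along a straight line.

    ``positions`` are distances (px) from ``p0`` along the line;
    ``values`` maps channel label -> sampled intensities.
    """

    positions: np.ndarray
    values: dict[str, np.ndarray]
    endpoints: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        d = np.diff(self.positions)
        if self.positions.size and (np.any(d <= 0) or np.any(d > 1 + 1e-9)):
            raise ValueError("positions must be strictly increasing with spacing <= 1 px")


# ---------------------------------------------------------------------------
# TIFF I/O
# ---------------------------------------------------------------------------

def write_tiff(path: str | Path, data: ChannelImage | TimeSeriesStack) -> None:
    """Write a channel image (single page) or stack (multi-page) grayscale TIFF.

    Values are rounded and clipped to the container's bit depth.
    """
    if isinstance(data, ChannelImage):
        pages = [data.pixels]
        depth = data.bit_depth
    else:
        pages = [f.pixels for f in data.frames]
        depth = data.frames[0].bit_depth
    dtype = np.uint8 if depth == 8 else np.uint16
    lim = np.iinfo(dtype).max
    arr = np.stack([np.clip(np.rint(p), 0, lim).astype(dtype) for p in pages])
    tifffile.imwrite(str(path), arr if len(pages) > 1 else arr[0])


def read_tiff(path: str | Path, pixel_size: float = 0.1,
              frame_interval: float = 1.0) -> ChannelImage | TimeSeriesStack:
    """Read a grayscale TIFF; multi-page files become a :class:`TimeSeriesStack`.

    Timestamps for stacks are synthesized as ``frame_interval * page_index``
    (plain TIFFs exported here carry no timing metadata).

    Raises
    ------
    ValueError
        For RGB or float-typed pages (unsupported formats).
    """
    arr = tifffile.imread(str(path))
    if arr.dtype.kind == "f":
        raise ValueError(f"unsupported TIFF sample format (float): {path}")
    if arr.ndim == 2:
        depth = 8 if arr.dtype.itemsize == 1 else 16
        return ChannelImage(arr.astype(np.float64), channel_label=Path(path).stem,
                            bit_depth=depth, pixel_size=pixel_size)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[-1] != arr.shape[-2]:
        raise ValueError(f"unsupported RGB TIFF: {path}")
    if arr.ndim != 3:
        raise ValueError(f"unsupported TIFF layout with shape {arr.shape}: {path}")
    depth = 8 if arr.dtype.itemsize == 1 else 16
    frames = [
        ChannelImage(p.astype(np.float64), channel_label=Path(path).stem,
                     bit_depth=depth, pixel_size=pixel_size)
        for p in arr
    ]
    ts = frame_interval * np.arange(len(frames))
    return TimeSeriesStack(frames, ts)


# ---------------------------------------------------------------------------
# Line profiles
# ---------------------------------------------------------------------------

def sample_line(img: ChannelImage | dict[str, ChannelImage],
                p0: tuple[float, float], p1: tuple[float, float],
                spacing: float = 0.5) -> LineProfile:
    """Sample intensities along the segment ``[p0, p1)`` by bilinear interpolation.

    Accepts a single channel or a dict of channels sharing a shape; samples
    are taken every ``spacing`` px starting at ``p0``.
    """
    channels = {img.channel_label or "ch": img} if isinstance(img, ChannelImage) else img
    if not channels:
        raise ValueError("no channels to sample")
    shape = next(iter(channels.values())).shape
    x0, y0 = p0
    x1, y1 = p1
    length = float(np.hypot(x1 - x0, y1 - y0))
    if length == 0:
        raise ValueError("zero-length line")
    if not (0 < spacing <= 1):
        raise ValueError("spacing must be in (0, 1] px")
    for x, y in (p0, p1):
        if not (0 <= x <= shape[1] - 1 and 0 <= y <= shape[0] - 1):
            raise ValueError(f"line endpoint ({x}, {y}) outside image")
    positions = np.arange(0.0, length, spacing)
    t = positions / length
    xs = x0 + t * (x1 - x0)
    ys = y0 + t * (y1 - y0)
    values = {
        label: ndimage.map_coordinates(ch.pixels, [ys, xs], order=1, mode="nearest")
        for label, ch in channels.items()
    }
    return LineProfile(positions, values, (p0, p1))


def robust_noise_sd(values: np.ndarray) -> float:
    """Robust noise SD of a signal: 1.4826·MAD of first differences / √2.

    First-differencing removes slowly varying structure so the estimate
    reflects pixel noise, not signal; the √2 undoes the variance doubling
    of differencing.
    """
    values = np.asarray(values, dtype=np.float64).ravel()
    d = np.diff(values)
    if d.size == 0:
        return 0.0
    return 1.4826 * float(np.median(np.abs(d - np.median(d)))) / np.sqrt(2.0)


def find_profile_peaks(profile: LineProfile, channel: str,
                       min_prominence: float | None = None) -> list[tuple[float, float]]:
    """Local maxima of a profile channel with topographic prominence filtering.

    Returns ``(position, value)`` pairs sorted by position.  Plateau maxima
    are reported at the integer-rounded plateau centroid.  When
    ``min_prominence`` is None it defaults to 3x the robust noise SD of the
    profile (see :func:`robust_noise_sd`).
    """
    if channel not in profile.values:
        raise KeyError(f"channel {channel!r} not in profile")
    v = np.asarray(profile.values[channel], dtype=np.float64)
    if v.size == 0:
        return []
    if min_prominence is None:
        min_prominence = 3.0 * robust_noise_sd(v)
    idx, props = signal.find_peaks(v, prominence=max(min_prominence, np.finfo(float).tiny),
                                   plateau_size=(None, None))
    out = []
    for k in range(idx.size):
        center = int(round(0.5 * (props["left_edges"][k] + props["right_edges"][k])))
        out.append((float(profile.positions[center]), float(v[center])))
    return out


# ---------------------------------------------------------------------------
# Masks
# ---------------------------------------------------------------------------

def pm_mask_from_marker(marker: ChannelImage, method: str = "halfmax",
                        threshold: float | None = None) -> np.ndarray:
    """Binary mask of marker-positive (cortical) pixels.

    The default ``'halfmax'`` method seeds a coarse foreground separation
    with Otsu's threshold, then refines the mask to the half-maximum
    contour (background level + half of the peak-over-background), the
    standard convention for membrane profiles whose intensity falls off
    smoothly; plain ``'otsu'`` tends to include the dim fringe of such
    profiles.  ``method='fixed'`` uses the supplied ``threshold``.  A blank
    (constant) image cannot define a mask.
    """
    px = marker.pixels
    if np.ptp(px) == 0:
        raise ValueError("marker image is constant; cannot derive a mask")
    if method in ("halfmax", "otsu"):
        thr = threshold_otsu(px)
        if method == "halfmax":
            fg = px > thr
            bg_level = float(np.median(px[~fg])) if (~fg).any() else 0.0
            peak = float(np.percentile(px[fg], 95))  # robust peak estimate
            thr = bg_level + 0.5 * (peak - bg_level)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown masking method {method!r}")
    return px > thr
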