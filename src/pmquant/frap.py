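"""FRAP pipeline: bias correction, template ROIs, photobleach normalization,
exponential recovery fitting, and cohort aggregation.

The corrected, normalized trace of a bleached ROI is fitted with a single
exponential recovery,

    F(t) = F∞ − (F∞ − F_post)·exp(−k·(t − t_bleach)),

and the mobile fraction is (F∞ − F_post)/(F_pre − F_post) with F_pre = 1 on
the normalized scale; the immobile fraction is its complement.  A model-free
endpoint mode (plateau = mean of the final 20% of frames) is available as a
cross-check.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .imgcore import ChannelImage, TimeSeriesStack

__all__ = ["FrapSeries", "FrapFit", "correct_bias", "build_bleach_rois",
           "extract_series", "normalize_trace", "fit_recovery", "cohort_curve"]


@dataclass
class FrapSeries:
    """Per-ROI mean-intensity traces plus the unbleached reference trace."""

    roi_traces: dict[str, np.ndarray]
    reference_trace: np.ndarray
    timestamps: np.ndarray
    bleach_frame_index: int
    pre_bleach_means: dict[str, float]


@dataclass
class FrapFit:
    """Fitted recovery of one normalized ROI trace."""

    F_post: float
    F_inf: float
    k: float
    mobile_fraction: float
    immobile_fraction: float
    rss: float
    flag: str | None = None

    @property
    def valid(self) -> bool:
        return self.flag is None


def correct_bias(stack: TimeSeriesStack, background: TimeSeriesStack,
                 background_frames: int = 100) -> TimeSeriesStack:
    """Subtract the camera bias / illumination background from every frame.

    The per-pixel background is the mean of up to ``background_frames`` dark
    frames (averaging reduces read noise); corrected values are clipped at
    zero.  Warns and uses what is available if fewer frames exist.
    """
    n_avail = len(background)
    if n_avail < background_frames:
        warnings.warn(
            f"only {n_avail} background frames available "
            f"(requested {background_frames}); using all of them",
            stacklevel=2)
        background_frames = n_avail
    bg = background.as_array()[:background_frames].mean(axis=0)
    frames = [
        ChannelImage(np.clip(f.pixels - bg, 0.0, None), f.channel_label,
                     f.bit_depth, f.pixel_size)
        for f in stack.frames
    ]
    return TimeSeriesStack(frames, stack.timestamps, stack.bleach_frame_index)


def build_bleach_rois(template_points: list[tuple[int, int]],
                      image_shape: tuple[int, int],
                      dilate_to: int = 5) -> list[np.ndarray]:
    """Dilate single-pixel template points to square ROI masks.

    Each ROI is the ``dilate_to`` x ``dilate_to`` square centered on its
    point, cropped at image borders.  Duplicate points are merged with a
    warning; overlapping ROIs from distinct points are kept separate.
    """
    h, w = image_shape
    half = dilate_to // 2
    seen: list[tuple[int, int]] = []
    for pt in template_points:
        x, y = pt
        if not (0 <= x < w and 0 <= y < h):
            raise ValueError(f"template point {pt} outside image")
        if pt in seen:
            warnings.warn(f"duplicate template point {pt} merged", stacklevel=2)
        else:
            seen.append(pt)
    rois = []
    for x, y in seen:
        mask = np.zeros((h, w), dtype=bool)
        mask[max(y - half, 0):y + half + 1, max(x - half, 0):x + half + 1] = True
        rois.append(mask)
    return rois


def extract_series(stack: TimeSeriesStack, rois: list[np.ndarray],
                   reference_mask: np.ndarray | None = None) -> FrapSeries:
    """Mean-intensity traces for each ROI plus the reference region.

    Without an explicit reference mask, the reference is chosen
    automatically as the brightest quartile of above-threshold pixels (Otsu
    threshold of the mean pre-bleach frame) that belong to no bleach ROI —
    i.e. bright, never-bleached fluorescence.  Dim background pixels are
    excluded because their zero-clipped noise decays differently from the
    fluorescent signal and would distort the normalization.
    """
    from skimage.filters import threshold_otsu

    if stack.bleach_frame_index is None:
        raise ValueError("stack has no bleach_frame_index")
    arr = stack.as_array()
    bleach = stack.bleach_frame_index
    if reference_mask is None:
        pre_mean = arr[:bleach].mean(axis=0)
        in_roi = np.zeros(pre_mean.shape, dtype=bool)
        for m in rois:
            in_roi |= m
        candidates = ~in_roi & (pre_mean > threshold_otsu(pre_mean))
        if not candidates.any():
            raise ValueError("no candidate reference pixels found")
        cutoff = np.percentile(pre_mean[candidates], 75)
        reference_mask = candidates & (pre_mean >= cutoff)
    traces = {f"roi{i}": arr[:, m].mean(axis=1) for i, m in enumerate(rois)}
    ref = arr[:, np.asarray(reference_mask, dtype=bool)].mean(axis=1)
    pre = {k: float(v[:bleach].mean()) for k, v in traces.items()}
    return FrapSeries(traces, ref, stack.timestamps, bleach, pre)


def normalize_trace(roi_trace: np.ndarray, reference_trace: np.ndarray,
                    pre_frames: int) -> np.ndarray:
    """Double normalization: divide out incidental photobleaching and scale
    so the pre-bleach mean equals 1.

    N(t) = [roi(t)/ref(t)] · [mean(ref_pre)/mean(roi_pre)].
    """
    roi = np.asarray(roi_trace, dtype=np.float64)
    ref = np.asarray(reference_trace, dtype=np.float64)
    if roi.shape != ref.shape:
        raise ValueError("traces must have equal length")
    if pre_frames < 1 or pre_frames >= roi.size:
        raise ValueError("pre_frames out of range")
    if np.any(ref <= 0):
        raise ValueError("reference trace must be strictly positive")
    ratio = roi / ref
    pre_mean = ratio[:pre_frames].mean()
    if pre_mean <= 0:
        raise ValueError("non-positive pre-bleach ROI signal")
    return ratio / pre_mean


def _model(t: np.ndarray, f_inf: float, k: float, f_post: float) -> np.ndarray:
    return f_inf - (f_inf - f_post) * np.exp(-k * t)


def fit_recovery(normalized_trace: np.ndarray, timestamps: np.ndarray,
                 bleach_frame_index: int, mode: str = "fit") -> FrapFit:
    """Estimate the mobile fraction of a normalized FRAP trace.

    ``mode='fit'`` performs the least-squares single-exponential fit;
    ``mode='endpoint'`` is the model-free cross-check that takes the plateau
    as the mean of the final 20% of post-bleach frames.  Non-convergent fits
    are returned flagged (excluded from cohort means) instead of raising.
    Mobile fractions outside [0, 1] are clipped with a warning.

    When the fitted rate implies a recovery much slower than the observation
    window (k·T_post < 1), the exponential plateau is an extrapolation far
    beyond the data and is numerically degenerate (k → 0 trades off against
    F∞ → ∞); the plateau then falls back to the endpoint estimate.
    """
    y = np.asarray(normalized_trace, dtype=np.float64)
    t = np.asarray(timestamps, dtype=np.float64)
    post_y = y[bleach_frame_index:]
    post_t = t[bleach_frame_index:] - t[bleach_frame_index]
    if post_y.size < 3:
        raise ValueError("at least 3 post-bleach points required")

    f_post0 = float(post_y[0])
    if mode == "endpoint":
        tail = max(1, int(round(0.2 * post_y.size)))
        f_inf = float(post_y[-tail:].mean())
        k = np.nan
        rss = float(np.sum((post_y - f_inf) ** 2))
        f_post = f_post0
    elif mode == "fit":
        f_inf0 = float(post_y[-3:].mean())
        k0 = np.log(2.0) / max(post_t[-1] / 2.0, np.finfo(float).tiny)
        try:
            popt, _ = curve_fit(
                _model, post_t, post_y,
                p0=[np.clip(f_inf0, f_post0, 1.5), k0, f_post0],
                bounds=([f_post0 - 0.5, 1e-9, -0.5], [1.5, np.inf, 1.5]),
                maxfev=10_000)
        except RuntimeError as exc:
            return FrapFit(f_post0, np.nan, np.nan, np.nan, np.nan, np.nan,
                           flag=f"fit failed: {exc}")
        f_inf, k, f_post = (float(v) for v in popt)
        rss = float(np.sum((post_y - _model(post_t, *popt)) ** 2))
        if k * post_t[-1] < 1.0:       # plateau not reached: extrapolation unsafe
            tail = max(1, int(round(0.2 * post_y.size)))
            f_inf = float(post_y[-tail:].mean())
    else:
        raise ValueError(f"unknown mode {mode!r}")

    f_pre = 1.0   # normalized
    denom = f_pre - f_post
    mobile = (f_inf - f_post) / denom if denom > 0 else np.nan
    flag = None
    if not np.isfinite(mobile):
        flag = "degenerate trace: no bleach depth"
    elif not 0.0 <= mobile <= 1.0:
        warnings.warn(f"mobile fraction {mobile:.3f} clipped to [0, 1]",
                      stacklevel=2)
        mobile = float(np.clip(mobile, 0.0, 1.0))
    return FrapFit(f_post, f_inf, k, mobile,
                   1.0 - mobile if flag is None else np.nan, rss, flag)


def cohort_curve(traces: list[np.ndarray], fits: list[FrapFit] | None = None
                 ) -> dict:
    """Pointwise mean ± SD of a cohort of normalized traces, plus mean
    mobile/immobile fractions over unflagged fits."""
    if len(traces) < 2:
        raise ValueError("at least two traces required for a cohort curve")
    arr = np.vstack(traces)
    out = {
        "mean_trace": arr.mean(axis=0),
        "sd_trace": arr.std(axis=0, ddof=1),
        "n": arr.shape[0],
    }
    if fits is not None:
        valid = [f for f in fits if f.valid]
        out["n_fits"] = len(valid)
        out["mean_mobile_fraction"] = (
            float(np.mean([f.mobile_fraction for f in valid])) if valid else np.nan)
        out["mean_immobile_fraction"] = (
            1.0 - out["mean_mobile_fraction"] if valid else np.nan)
    return out
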