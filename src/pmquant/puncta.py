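"""Intensity-maxima detection, ER-association classification, and colocalization.

``find_maxima`` implements the noise-tolerance (topographic prominence)
criterion of ImageJ's Find Maxima tool: a pixel ``p`` is an accepted maximum
iff there is no path from ``p`` to any strictly higher pixel along which the
intensity stays above ``value(p) − noise_tolerance``.  Equivalently, in the
connected component of ``{q : value(q) > value(p) − tolerance}`` containing
``p``, the maximum value equals ``value(p)``.  The implementation activates
pixels in descending intensity order into a union-find structure that tracks
each component's maximum, and evaluates the criterion for every pixel at the
moment its tolerance threshold is crossed.  Plateaus (connected equal-valued
accepted pixels) yield one point at the rounded plateau centroid.  Image
borders behave as −∞ neighbors, so edge pixels are eligible maxima.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .imgcore import ChannelImage, robust_noise_sd

__all__ = [
    "MaximaSet",
    "AssociationResult",
    "ColocResult",
    "find_maxima",
    "derive_binary_threshold",
    "classify_association",
    "coloc_overlap",
    "roi_mean_intensity",
]

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class MaximaSet:
    """Detected intensity maxima of one channel."""

    points: list[tuple[int, int]]          # (x, y), one per plateau
    values: np.ndarray                     # plateau intensity per point
    noise_tolerance: float
    source_channel: str = ""

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class AssociationResult:
    """Binary ER-association classification of a maxima set."""

    n_total: int
    n_associated: int
    fraction: float
    threshold_used: float
    min_specific: float | None = None
    background_max: float | None = None


@dataclass
class ColocResult:
    """Thresholded pixel-overlap colocalization fractions.

    A fraction is None when the corresponding denominator channel has no
    above-threshold pixels (undefined, reported as missing rather than 0).
    """

    frac_A_in_B: float | None
    frac_B_in_A: float | None
    thr_A: float
    thr_B: float


def find_maxima(img: ChannelImage, noise_tolerance: float | None = None) -> MaximaSet:
    """Accepted intensity maxima under the noise-tolerance path criterion.

    ``noise_tolerance`` defaults to 3x the robust noise SD of the image.
    Returns an empty set for constant images (no pixel has a neighborhood
    drop, but also no strictly higher terrain — a constant plateau spanning
    the whole image is not a punctum).
    """
    px = img.pixels
    if noise_tolerance is None:
        noise_tolerance = 3.0 * robust_noise_sd(px)
    if noise_tolerance <= 0:
        raise ValueError("noise_tolerance must be > 0")
    if np.ptp(px) == 0:
        return MaximaSet([], np.array([]), noise_tolerance, img.channel_label)

    h, w = px.shape
    flat = px.ravel()
    n = flat.size
    order = np.argsort(-flat, kind="stable")
    svals = flat[order]

    parent = np.arange(n, dtype=np.int64)
    comp_max = flat.copy()
    active = np.zeros(n, dtype=bool)
    accepted = np.zeros(n, dtype=bool)

    def find(a: int) -> int:
        root = a
        while parent[root] != root:
            root = parent[root]
        while parent[a] != root:            # path compression
            parent[a], a = root, parent[a]
        return root

    tol = float(noise_tolerance)
    k = 0           # check pointer over `order`
    i = 0           # activation pointer over `order`
    while i < n:
        wv = svals[i]
        # evaluate every pixel whose tolerance threshold is crossed now
        while k < n and svals[k] - tol >= wv:
            p = int(order[k])
            accepted[p] = comp_max[find(p)] == flat[p]
            k += 1
        # activate the whole tie group of value wv
        j = i
        while j < n and svals[j] == wv:
            p = int(order[j])
            active[p] = True
            py, pxx = divmod(p, w)
            for dy, dx in _NEIGHBORS:
                ny, nx = py + dy, pxx + dx
                if 0 <= ny < h and 0 <= nx < w:
                    q = ny * w + nx
                    if active[q]:
                        rp, rq = find(p), find(q)
                        if rp != rq:
                            parent[rq] = rp
                            if comp_max[rq] > comp_max[rp]:
                                comp_max[rp] = comp_max[rq]
            j += 1
        i = j
    while k < n:
        p = int(order[k])
        accepted[p] = comp_max[find(p)] == flat[p]
        k += 1

    # adjacent accepted pixels always share a value, so connected components
    # of the accepted mask are exactly the plateaus
    mask = accepted.reshape(h, w)
    labels, n_lab = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    points: list[tuple[int, int]] = []
    values = []
    for lab in range(1, n_lab + 1):
        ys, xs = np.nonzero(labels == lab)
        points.append((int(round(xs.mean())), int(round(ys.mean()))))
        values.append(px[ys[0], xs[0]])
    order_pts = np.lexsort(([p[0] for p in points], [p[1] for p in points]))
    points = [points[o] for o in order_pts]
    values = np.array(values)[order_pts] if values else np.array([])
    return MaximaSet(points, values, tol, img.channel_label)


def derive_binary_threshold(er_img: ChannelImage, er_mask: np.ndarray,
                            free_mask: np.ndarray,
                            low_percentile: float = 1.0,
                            high_percentile: float = 99.0,
                            interpolation: float = 0.5
                            ) -> tuple[float, float, float]:
    """Derive the binary ER/no-ER threshold from marker intensity ranges.

    ``min_specific`` is a low percentile of the intensities inside the ER
    mask (the minimal specific ER signal); ``background_max`` is a high
    percentile of intensities in ER-free regions.  Percentile endpoints
    rather than strict extrema resist single-pixel outliers.  The threshold
    sits at ``background_max + interpolation·(min_specific − background_max)``
    (midpoint by default).

    Returns ``(threshold, min_specific, background_max)``; raises if the two
    intensity ranges are not separable.
    """
    er_mask = np.asarray(er_mask, dtype=bool)
    free_mask = np.asarray(free_mask, dtype=bool)
    if not er_mask.any() or not free_mask.any():
        raise ValueError("both masks must be nonempty")
    if (er_mask & free_mask).any():
        raise ValueError("ER and ER-free masks must be disjoint")
    min_specific = float(np.percentile(er_img.pixels[er_mask], low_percentile))
    background_max = float(np.percentile(er_img.pixels[free_mask], high_percentile))
    if min_specific <= background_max:
        raise ValueError(
            f"ER and background intensity ranges are not separable "
            f"(min specific {min_specific:.1f} <= background max {background_max:.1f})")
    threshold = background_max + interpolation * (min_specific - background_max)
    return threshold, min_specific, background_max


def classify_association(maxima: MaximaSet, er_img: ChannelImage,
                         threshold: float,
                         min_specific: float | None = None,
                         background_max: float | None = None
                         ) -> AssociationResult:
    """Score each maximum as ER-associated iff the ER intensity at its
    coordinate is at least ``threshold`` (inclusive)."""
    if len(maxima) == 0:
        raise ValueError("empty maxima set")
    px = er_img.pixels
    assoc = sum(1 for x, y in maxima.points if px[y, x] >= threshold)
    return AssociationResult(
        n_total=len(maxima), n_associated=assoc,
        fraction=assoc / len(maxima), threshold_used=threshold,
        min_specific=min_specific, background_max=background_max)


def coloc_overlap(img_a: ChannelImage, img_b: ChannelImage,
                  thr_a: float, thr_b: float) -> ColocResult:
    """Fraction of above-threshold pixel area of each channel that overlaps
    the other channel's above-threshold area."""
    if img_a.shape != img_b.shape:
        raise ValueError("images must share a shape")
    pos_a = img_a.pixels >= thr_a
    pos_b = img_b.pixels >= thr_b
    both = int((pos_a & pos_b).sum())
    na, nb = int(pos_a.sum()), int(pos_b.sum())
    return ColocResult(
        frac_A_in_B=both / na if na else None,
        frac_B_in_A=both / nb if nb else None,
        thr_A=thr_a, thr_B=thr_b)


def roi_mean_intensity(img: ChannelImage, roi_mask: np.ndarray) -> float:
    """Mean intensity of the image over a binary region of interest."""
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != img.shape:
        raise ValueError("mask shape must match image")
    if not roi_mask.any():
        raise ValueError("empty ROI mask")
    return float(img.pixels[roi_mask].mean())
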