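"""Independent brute-force oracles used to validate the fast implementations.

These deliberately use naive per-element graph searches and scans rather
than the union-find / scipy routines in the package, so agreement is a
meaningful check.
"""

from __future__ import annotations

import numpy as np

_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def maxima_oracle(arr: np.ndarray, tol: float) -> list[tuple[int, int]]:
    """Exhaustive evaluation of the noise-tolerance path criterion.

    A pixel is accepted iff no breadth-first path through pixels with value
    strictly above ``value(p) − tol`` reaches a pixel strictly higher than
    ``value(p)``.  Accepted pixels are grouped into equal-valued connected
    plateaus; one rounded centroid per plateau is returned, sorted by (y, x).
    """
    arr = np.asarray(arr, dtype=np.float64)
    if np.ptp(arr) == 0:
        # contract: a constant image has no puncta (a plateau spanning the
        # whole image is not a maximum)
        return []
    h, w = arr.shape
    accepted = np.zeros((h, w), dtype=bool)
    for y0 in range(h):
        for x0 in range(w):
            v = arr[y0, x0]
            seen = {(y0, x0)}
            stack = [(y0, x0)]
            ok = True
            while stack and ok:
                cy, cx = stack.pop()
                for dy, dx in _NEIGHBORS:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and (ny, nx) not in seen:
                        if arr[ny, nx] > v - tol:
                            if arr[ny, nx] > v:
                                ok = False
                                break
                            seen.add((ny, nx))
                            stack.append((ny, nx))
            accepted[y0, x0] = ok

    # group accepted pixels into equal-valued plateaus by flood fill
    visited = np.zeros((h, w), dtype=bool)
    points = []
    for y0 in range(h):
        for x0 in range(w):
            if accepted[y0, x0] and not visited[y0, x0]:
                v = arr[y0, x0]
                plateau = [(y0, x0)]
                visited[y0, x0] = True
                stack = [(y0, x0)]
                while stack:
                    cy, cx = stack.pop()
                    for dy, dx in _NEIGHBORS:
                        ny, nx = cy + dy, cx + dx
                        if (0 <= ny < h and 0 <= nx < w and accepted[ny, nx]
                                and not visited[ny, nx] and arr[ny, nx] == v):
                            visited[ny, nx] = True
                            plateau.append((ny, nx))
                            stack.append((ny, nx))
                ys = [p[0] for p in plateau]
                xs = [p[1] for p in plateau]
                points.append((int(round(np.mean(xs))), int(round(np.mean(ys)))))
    return sorted(points, key=lambda p: (p[1], p[0]))


def prominence_peaks_1d(values: np.ndarray, min_prominence: float
                        ) -> list[int]:
    """O(n²) topographic-prominence peak finder for 1-D signals.

    For each local maximum (plateau apex), scan outward on each side to the
    first strictly higher sample (or the signal edge), tracking the minimum
    en route; the prominence is the apex minus the higher of the two minima.
    Returns rounded plateau-centroid indices of peaks with prominence at
    least ``min_prominence``, in position order.
    """
    v = np.asarray(values, dtype=np.float64)
    n = v.size
    peaks = []
    i = 1
    while i < n - 1:
        if v[i - 1] < v[i]:
            j = i
            while j < n - 1 and v[j + 1] == v[i]:
                j += 1
            if j < n - 1 and v[j + 1] < v[i]:       # plateau [i, j] is a peak
                left_min = v[i]
                k = i - 1
                while k >= 0 and v[k] <= v[i]:
                    left_min = min(left_min, v[k])
                    k -= 1
                right_min = v[j]
                k = j + 1
                while k < n and v[k] <= v[i]:
                    right_min = min(right_min, v[k])
                    k += 1
                prom = v[i] - max(left_min, right_min)
                if prom >= min_prominence:
                    peaks.append(int(round((i + j) / 2)))
            i = j + 1
        else:
            i += 1
    return peaks
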