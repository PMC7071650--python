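"""Synthetic-data generators with known ground truth for every pipeline stage.

Each generator emulates one class of input the measurement modules consume:

* two-channel budding-yeast cell pairs (PM reporter + PM marker) with a
  controllable daughter:mother reporter intensity ratio, for the line-scan
  polarity estimator;
* cortical sections with an ER-network channel and a puncta channel with a
  controllable ER-association fraction, for the maxima/threshold classifier;
* FRAP time-lapses with controllable mobile fraction, bleach depth, camera
  bias and incidental whole-field photobleaching;
* pellet/supernatant densitometry tables.

Ground truth is always returned alongside the data and is never consumed by
the measurement modules; seeds are explicit fields, never global state.

Noise model: Poisson shot noise on the signal (with a gain chosen so the
relative shot noise at ``base_intensity`` is ``1/(√2·snr)``) plus additive
Gaussian read noise of matching variance, so the total SD at the base
intensity is ``base_intensity/snr``; ``snr = inf`` disables noise entirely
and yields the deterministic mean image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .imgcore import ChannelImage, TimeSeriesStack

__all__ = [
    "CellPairParams",
    "CellPairGeometry",
    "FieldParams",
    "FieldTruth",
    "FrapSimParams",
    "FrapTruth",
    "generate_cell_pair",
    "generate_field",
    "generate_frap_series",
    "generate_densitometry",
    "generate_aggregation_cell",
]


def _apply_noise(mean_img: np.ndarray, snr: float, base_intensity: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson shot + Gaussian read noise calibrated to ``snr`` at base intensity."""
    if not np.isfinite(snr):
        return mean_img.copy()
    if snr <= 0:
        raise ValueError("snr must be positive")
    gain = 2.0 * snr**2 / base_intensity          # photons per count
    shot = rng.poisson(np.clip(mean_img, 0, None) * gain) / gain
    read_sd = base_intensity / (np.sqrt(2.0) * snr)
    out = shot + rng.normal(0.0, read_sd, size=mean_img.shape)
    return np.clip(out, 0.0, None)


# ---------------------------------------------------------------------------
# Cell pairs for polarity line scans
# ---------------------------------------------------------------------------

@dataclass
class CellPairParams:
    """Ground-truth parameters of a synthetic mother/daughter cell pair.

    ``ratio_true`` is the daughter:mother PM reporter intensity ratio
    (the quantity the line-scan estimator recovers as Fd/Fm).
    ``neck_offset`` is the gap (px) between the two membranes at the neck;
    it must be positive so a line through both centers crosses four distinct
    membranes (two per cell).
    """

    mother_axes: tuple[float, float] = (45.0, 36.0)
    daughter_axes: tuple[float, float] = (24.0, 20.0)
    neck_offset: float = 4.0
    pm_thickness: float = 2.0
    ratio_true: float = 7.5
    base_intensity: float = 1000.0
    background: float = 20.0
    snr: float = 10.0
    image_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.ratio_true <= 0:
            raise ValueError("ratio_true must be > 0")
        if self.pm_thickness < 1:
            raise ValueError("pm_thickness must be >= 1 px")
        if not (self.daughter_axes[0] < self.mother_axes[0]
                and self.daughter_axes[1] < self.mother_axes[1]):
            raise ValueError("daughter axes must be smaller than mother axes")
        if self.neck_offset <= 0:
            raise ValueError(
                "degenerate geometry: ellipses overlap at the neck "
                "(neck_offset must be > 0)")
        h, w = self.image_shape
        extent = (self.mother_axes[0] * 2 + self.daughter_axes[0] * 2
                  + self.neck_offset)
        if extent + 20 > w or 2 * self.mother_axes[1] + 20 > h:
            raise ValueError("cell pair does not fit the image with margins")


@dataclass
class CellPairGeometry:
    """Rendered geometry plus ground truth of a synthetic cell pair.

    ``line`` runs horizontally through both cell centers; the mother and
    daughter intervals partition it (in line-position units, px from p0)
    at the mid-point of the neck gap.
    """

    mother_center: tuple[float, float]
    mother_axes: tuple[float, float]
    daughter_center: tuple[float, float]
    daughter_axes: tuple[float, float]
    line: tuple[tuple[float, float], tuple[float, float]]
    mother_interval: tuple[float, float]
    daughter_interval: tuple[float, float]
    pm_mask: np.ndarray
    params: CellPairParams

    @property
    def ratio_true(self) -> float:
        return self.params.ratio_true


def _ring_distance(shape: tuple[int, int], center: tuple[float, float],
                   axes: tuple[float, float]) -> np.ndarray:
    """Approximate signed distance (px) to an axis-aligned ellipse boundary.

    Uses the gradient-normalized level set F/|∇F| with
    F = ((x-cx)/a)² + ((y-cy)/b)² − 1, accurate near the boundary, which is
    all the Gaussian membrane profile ever samples.
    """
    h, w = shape
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    cx, cy = center
    a, b = axes
    fx = (x - cx) / a
    fy = (y - cy) / b
    f = fx**2 + fy**2 - 1.0
    grad = 2.0 * np.hypot(fx / a, fy / b)
    return f / np.maximum(grad, 1e-9)


def generate_cell_pair(params: CellPairParams
                       ) -> tuple[dict[str, ChannelImage], CellPairGeometry]:
    """Render a two-channel mother/daughter cell pair with known Fd/Fm truth.

    Returns ``{"reporter": ..., "marker": ...}`` and the geometry.  The
    marker channel carries uniform PM intensity on both cells; the reporter
    PM intensity on the daughter contour is ``ratio_true`` times the mother
    contour intensity.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    am, bm = params.mother_axes
    ad, bd = params.daughter_axes

    cy = h / 2.0
    cx_m = (w - (2 * am + 2 * ad + params.neck_offset)) / 2.0 + am
    cx_d = cx_m + am + params.neck_offset + ad

    sigma = params.pm_thickness / 2.355          # FWHM = pm_thickness
    dm = _ring_distance((h, w), (cx_m, cy), (am, bm))
    dd = _ring_distance((h, w), (cx_d, cy), (ad, bd))
    ring_m = np.exp(-dm**2 / (2 * sigma**2))
    ring_d = np.exp(-dd**2 / (2 * sigma**2))

    base = params.base_intensity
    reporter_mean = params.background + base * ring_m + params.ratio_true * base * ring_d
    marker_mean = params.background + base * (ring_m + ring_d)

    reporter = ChannelImage(_apply_noise(reporter_mean, params.snr, base, rng),
                            "reporter", pixel_size=params.pixel_size)
    marker = ChannelImage(_apply_noise(marker_mean, params.snr, base, rng),
                          "marker", pixel_size=params.pixel_size)

    margin = 8.0
    x_start = cx_m - am - margin
    x_end = cx_d + ad + margin
    line = ((x_start, cy), (x_end, cy))
    mid_gap = cx_m + am + params.neck_offset / 2.0
    mother_iv = (0.0, mid_gap - x_start)
    daughter_iv = (mid_gap - x_start, x_end - x_start)
    pm_mask = (ring_m + ring_d) > 0.5

    geom = CellPairGeometry(
        mother_center=(cx_m, cy), mother_axes=(am, bm),
        daughter_center=(cx_d, cy), daughter_axes=(ad, bd),
        line=line, mother_interval=mother_iv, daughter_interval=daughter_iv,
        pm_mask=pm_mask, params=params)
    return {"reporter": reporter, "marker": marker}, geom


# ---------------------------------------------------------------------------
# Cortical fields: ER network + puncta
# ---------------------------------------------------------------------------

@dataclass
class FieldParams:
    """Parameters of a synthetic cortical field (ER network + puncta channel)."""

    n_maxima: int = 1000
    assoc_fraction_true: float = 0.8
    er_coverage: float = 0.30
    er_intensity_range: tuple[float, float] = (200.0, 400.0)
    background_max: float = 100.0
    puncta_amplitude: float = 500.0
    image_shape: tuple[int, int] = (512, 512)
    spot_sigma: float = 1.5
    min_separation: float = 6.0
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.assoc_fraction_true <= 1.0:
            raise ValueError("assoc_fraction_true must be in [0, 1]")
        if self.er_intensity_range[0] <= self.background_max:
            raise ValueError("min specific ER intensity must exceed background_max")
        if not 0.0 < self.er_coverage < 1.0:
            raise ValueError("er_coverage must be in (0, 1)")
        if self.n_maxima < 1:
            raise ValueError("need at least one spot")


@dataclass
class FieldTruth:
    """Per-spot ground truth of a synthetic field."""

    centers: np.ndarray            # (n, 2) int pixel coordinates (x, y)
    associated: np.ndarray         # (n,) bool labels
    er_mask: np.ndarray            # bool, ER-on pixels
    params: FieldParams

    @property
    def assoc_fraction(self) -> float:
        return float(np.mean(self.associated))


def _er_network_mask(shape: tuple[int, int], coverage: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Reticulated ER mask: random-walk tubules plus elliptical patches.

    Walks are grown until the pixel coverage reaches the target; only the
    coverage statistics matter to the downstream classifier.
    """
    from scipy import ndimage as ndi

    h, w = shape
    mask = np.zeros((h, w), dtype=bool)
    n_steps = max(h, w) * 2
    for _ in range(10_000):
        dilated = ndi.binary_dilation(mask, iterations=1)
        if dilated.mean() >= coverage:
            return dilated
        x = rng.uniform(0, w)
        y = rng.uniform(0, h)
        theta = rng.uniform(0, 2 * np.pi)
        for _ in range(n_steps):
            theta += rng.normal(0, 0.35)
            x = np.clip(x + np.cos(theta), 0, w - 1)
            y = np.clip(y + np.sin(theta), 0, h - 1)
            mask[int(y), int(x)] = True
        if rng.random() < 0.3:                   # occasional patch (sheet)
            py, px = rng.integers(0, h), rng.integers(0, w)
            ry, rx = rng.integers(3, 8), rng.integers(3, 8)
            yy, xx = np.ogrid[0:h, 0:w]
            mask |= ((yy - py) / ry)**2 + ((xx - px) / rx)**2 <= 1.0
    return ndi.binary_dilation(mask, iterations=1)


def generate_field(params: FieldParams
                   ) -> tuple[dict[str, ChannelImage], FieldTruth]:
    """Generate an ER-network channel plus a puncta channel with known labels.

    Exactly ``round(assoc_fraction_true · n_maxima)`` spot centers fall on
    ER-on pixels; the rest fall on pixels whose ER intensity is at most
    ``background_max``.  Raises if the requested spot count cannot be placed
    without violating the minimum separation.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape

    er_mask = _er_network_mask((h, w), params.er_coverage, rng)
    lo, hi = params.er_intensity_range
    er_img = rng.uniform(0.0, params.background_max, size=(h, w))
    er_img[er_mask] = rng.uniform(lo, hi, size=int(er_mask.sum()))

    n_assoc = int(round(params.assoc_fraction_true * params.n_maxima))
    margin = int(np.ceil(4 * params.spot_sigma)) + 1
    interior = np.zeros((h, w), dtype=bool)
    interior[margin:h - margin, margin:w - margin] = True

    def _place(n: int, allowed: np.ndarray, occupied: list[tuple[int, int]]
               ) -> list[tuple[int, int]]:
        ys, xs = np.nonzero(allowed & interior)
        if ys.size == 0 and n > 0:
            raise ValueError("no pixels available for spot placement")
        placed: list[tuple[int, int]] = []
        min_sep2 = params.min_separation**2
        attempts = 0
        occ = occupied + placed
        while len(placed) < n:
            attempts += 1
            if attempts > 200 * n + 1000:
                raise ValueError(
                    f"could not place {n} spots with min separation "
                    f"{params.min_separation} px; field too crowded")
            i = rng.integers(0, ys.size)
            x, y = int(xs[i]), int(ys[i])
            if all((x - ox)**2 + (y - oy)**2 >= min_sep2 for ox, oy in occ):
                placed.append((x, y))
                occ = occupied + placed
        return placed

    assoc_pts = _place(n_assoc, er_mask, [])
    free_pts = _place(params.n_maxima - n_assoc, ~er_mask, assoc_pts)

    centers = np.array(assoc_pts + free_pts, dtype=int)
    labels = np.zeros(params.n_maxima, dtype=bool)
    labels[:n_assoc] = True

    puncta = np.zeros((h, w))
    half = int(np.ceil(4 * params.spot_sigma))
    yy, xx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    kernel = np.exp(-(xx**2 + yy**2) / (2 * params.spot_sigma**2))
    for x, y in centers:
        puncta[y - half:y + half + 1, x - half:x + half + 1] += \
            params.puncta_amplitude * kernel
    if params.noise_sd > 0:
        puncta = np.clip(puncta + rng.normal(0, params.noise_sd, (h, w)), 0, None)

    channels = {
        "puncta": ChannelImage(puncta, "puncta"),
        "er": ChannelImage(er_img, "er"),
    }
    return channels, FieldTruth(centers, labels, er_mask, params)


# ---------------------------------------------------------------------------
# FRAP time-lapses
# ---------------------------------------------------------------------------

@dataclass
class FrapSimParams:
    """Ground-truth parameters of a simulated FRAP time-lapse.

    The bleached ROI recovers as F(t) = F∞ − (F∞ − F_post)·e^(−k·(t−t_bleach))
    with F_post = 1 − bleach_depth and
    F∞ = F_post + mobile_fraction_true·bleach_depth (normalized units).
    Incidental photobleaching multiplies the whole-field signal by
    e^(−incidental_rate·frame); the camera adds ``bias_level`` (plus an
    optional horizontal gradient) to every pixel.
    """

    mobile_fraction_true: float = 0.2
    rate_k: float = 0.2
    bleach_depth: float = 0.8
    incidental_rate: float = 0.01
    pre_frames: int = 10
    post_frames: int = 50
    frame_interval: float = 0.5
    noise_sd: float = 50.0
    bias_level: float = 100.0
    bias_gradient: float = 0.0
    base_intensity: float = 1000.0
    image_shape: tuple[int, int] = (48, 48)
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.mobile_fraction_true <= 1.0:
            raise ValueError("mobile_fraction_true must be in [0, 1]")
        if self.rate_k <= 0:
            raise ValueError("rate_k must be > 0")
        if not 0.0 < self.bleach_depth <= 1.0:
            raise ValueError("bleach_depth must be in (0, 1]")
        if self.post_frames < 3:
            raise ValueError("at least 3 post-bleach frames required for a fit")
        if self.pre_frames < 1:
            raise ValueError("at least one pre-bleach frame required")


@dataclass
class FrapTruth:
    """Ground truth and auxiliary inputs for a simulated FRAP stack."""

    bleach_point: tuple[int, int]          # (x, y) punctum center, bleached
    reference_points: list[tuple[int, int]]
    background_stack: TimeSeriesStack      # dark frames (bias only)
    bias_image: np.ndarray                 # noiseless per-pixel bias
    params: FrapSimParams

    @property
    def mobile_fraction(self) -> float:
        return self.params.mobile_fraction_true


def generate_frap_series(params: FrapSimParams
                         ) -> tuple[TimeSeriesStack, FrapTruth]:
    """Simulate a FRAP time-lapse of one bleached punctum plus references.

    The stack contains a bleached 5×5 punctum at the image center and two
    never-bleached reference puncta; a 100-frame dark stack (camera bias
    only) is included in the truth object for bias correction.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    h, w = params.image_shape
    n = params.pre_frames + params.post_frames
    t = params.frame_interval * np.arange(n)
    t_bleach = t[params.pre_frames]

    f_post = 1.0 - params.bleach_depth
    f_inf = f_post + params.mobile_fraction_true * params.bleach_depth
    f = np.ones(n)
    post = t[params.pre_frames:] - t_bleach
    f[params.pre_frames:] = f_inf - (f_inf - f_post) * np.exp(-params.rate_k * post)

    bleach_pt = (w // 2, h // 2)
    ref_pts = [(w // 4, h // 4), (3 * w // 4, 3 * h // 4)]

    def _block(img: np.ndarray, pt: tuple[int, int], value: float) -> None:
        x, y = pt
        img[y - 2:y + 3, x - 2:x + 3] = value

    yx = np.arange(w, dtype=np.float64)
    bias = params.bias_level + params.bias_gradient * yx[None, :] * np.ones((h, 1))

    frames = []
    base = params.base_intensity
    for i in range(n):
        signal = np.full((h, w), 0.05 * base)          # dim diffuse background
        for pt in ref_pts:
            _block(signal, pt, base)
        _block(signal, bleach_pt, base * f[i])
        signal *= np.exp(-params.incidental_rate * i)
        mean = bias + signal
        if params.noise_sd > 0:
            mean = np.clip(mean + rng.normal(0, params.noise_sd, (h, w)), 0, None)
        frames.append(ChannelImage(mean, "frap"))

    stack = TimeSeriesStack(frames, t, bleach_frame_index=params.pre_frames)

    bg_frames = []
    for i in range(100):
        dark = bias.copy()
        if params.noise_sd > 0:
            dark = np.clip(dark + rng.normal(0, params.noise_sd, (h, w)), 0, None)
        bg_frames.append(ChannelImage(dark, "dark"))
    bg_stack = TimeSeriesStack(bg_frames, np.arange(100, dtype=float))

    return stack, FrapTruth(bleach_pt, ref_pts, bg_stack, bias, params)


# ---------------------------------------------------------------------------
# Densitometry tables
# ---------------------------------------------------------------------------

def generate_densitometry(n: int, pellet_fraction_true: dict[float, float],
                          noise_cv: float = 0.1, total_intensity: float = 10_000.0,
                          seed: int = 0) -> pd.DataFrame:
    """Simulate a pellet/supernatant band-intensity table.

    ``pellet_fraction_true`` maps temperature (°C) to the true pellet
    fraction P/(P+S); ``n`` replicate rows are drawn per condition with
    multiplicative noise of coefficient of variation ``noise_cv`` applied
    independently to the two bands.

    Returns a DataFrame with columns
    ``sample_id, temperature_C, pellet, supernatant``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for temp, frac in pellet_fraction_true.items():
        if not 0.0 <= frac <= 1.0:
            raise ValueError("pellet fractions must be in [0, 1]")
        for i in range(n):
            p = total_intensity * frac
            s = total_intensity * (1.0 - frac)
            if noise_cv > 0:
                p = max(p * (1.0 + noise_cv * rng.standard_normal()), 0.0)
                s = max(s * (1.0 + noise_cv * rng.standard_normal()), 0.0)
            rows.append({"sample_id": f"T{temp:g}_r{i}", "temperature_C": temp,
                         "pellet": p, "supernatant": s})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Single cells for aggregation scoring
# ---------------------------------------------------------------------------

def generate_aggregation_cell(interior_spots: int, cortical_spots: int = 0,
                              radius: float = 20.0, amplitude: float = 400.0,
                              diffuse: float = 100.0, noise_sd: float = 5.0,
                              image_shape: tuple[int, int] = (64, 64),
                              seed: int = 0
                              ) -> tuple[ChannelImage, np.ndarray, bool]:
    """Render a single round cell with optional interior/cortical puncta.

    Returns the image, the cell mask, and the ground-truth flag
    (True iff the cell has interior aggregates).  Cortical spots sit on the
    cell rim and must never flip the aggregation call.
    """
    rng = np.random.default_rng(seed)
    h, w = image_shape
    cy, cx = h / 2.0, w / 2.0
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    r = np.hypot(xx - cx, yy - cy)
    cell_mask = r <= radius

    img = np.zeros((h, w))
    img[cell_mask] = diffuse

    sigma = 1.2
    half = 5
    gy, gx = np.mgrid[-half:half + 1, -half:half + 1].astype(np.float64)
    kernel = np.exp(-(gx**2 + gy**2) / (2 * sigma**2))

    def _add_spot(x: int, y: int) -> None:
        img[y - half:y + half + 1, x - half:x + half + 1] += amplitude * kernel

    for _ in range(interior_spots):
        rho = rng.uniform(0, radius * 0.55)
        th = rng.uniform(0, 2 * np.pi)
        _add_spot(int(cx + rho * np.cos(th)), int(cy + rho * np.sin(th)))
    for _ in range(cortical_spots):
        th = rng.uniform(0, 2 * np.pi)
        _add_spot(int(cx + radius * np.cos(th)), int(cy + radius * np.sin(th)))

    if noise_sd > 0:
        img = np.clip(img + rng.normal(0, noise_sd, (h, w)), 0, None)
    return ChannelImage(img, "aggregation"), cell_mask, interior_spots > 0
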