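"""End-to-end simulated experiments: generate inputs with known truth, run
the measurement pipeline, and summarize the cohort.

These are the building blocks the analysis drivers and the reproduction
script share.  Each experiment takes explicit ground-truth parameters and a
base seed; per-replicate seeds are derived deterministically from it.
"""

from __future__ import annotations

import numpy as np

from . import frap as frap_mod
from . import polarity as pol_mod
from . import puncta as pun_mod
from . import synthgen as gen_mod

__all__ = ["polarity_cohort", "er_association_fraction", "frap_mobile_fraction"]


def polarity_cohort(ratio_true: float, n_cells: int, snr: float = 10.0,
                    base_seed: int = 0) -> pol_mod.CohortSummary:
    """Simulate ``n_cells`` cell pairs at a fixed Fd/Fm truth and measure them."""
    measurements = []
    for i in range(n_cells):
        params = gen_mod.CellPairParams(ratio_true=ratio_true, snr=snr,
                                        seed=(base_seed + i) % 2**31)
        channels, geom = gen_mod.generate_cell_pair(params)
        measurements.append(pol_mod.measure_cell_polarity(
            channels["reporter"], channels["marker"], geom.line,
            (geom.daughter_interval, geom.mother_interval),
            cell_id=f"cell{i}"))
    return pol_mod.cohort_polarity(measurements)


def er_association_fraction(assoc_fraction_true: float, n_spots: int = 1000,
                            n_fields: int = 3, base_seed: int = 0) -> float:
    """Simulate cortical fields and recover the ER-associated spot fraction.

    For each field the binary threshold is derived from the ER and ER-free
    intensity ranges, puncta maxima are detected, and each maximum is scored
    against the ER channel; the mean fraction over fields is returned.
    """
    fracs = []
    for j in range(n_fields):
        params = gen_mod.FieldParams(n_maxima=n_spots,
                                     assoc_fraction_true=assoc_fraction_true,
                                     seed=(base_seed + j) % 2**31)
        channels, truth = gen_mod.generate_field(params)
        thr, mn, bg = pun_mod.derive_binary_threshold(
            channels["er"], truth.er_mask, ~truth.er_mask)
        maxima = pun_mod.find_maxima(channels["puncta"],
                                     noise_tolerance=params.puncta_amplitude / 2)
        res = pun_mod.classify_association(maxima, channels["er"], thr, mn, bg)
        fracs.append(res.fraction)
    return float(np.mean(fracs))


def frap_mobile_fraction(mobile_fraction_true: float, n_rois: int = 22,
                         rate_k: float = 0.2, incidental_rate: float = 0.01,
                         noise_frac: float = 0.05, base_seed: int = 0) -> dict:
    """Simulate FRAP time-lapses and recover the cohort mean mobile fraction.

    Each ROI runs the full pipeline: camera-bias correction against the dark
    stack, 5×5 template ROI, double normalization against the unbleached
    reference, and the single-exponential recovery fit.
    """
    fits, traces = [], []
    for i in range(n_rois):
        params = gen_mod.FrapSimParams(
            mobile_fraction_true=mobile_fraction_true, rate_k=rate_k,
            incidental_rate=incidental_rate,
            noise_sd=noise_frac * 1000.0, seed=(base_seed + i) % 2**31)
        stack, truth = gen_mod.generate_frap_series(params)
        corrected = frap_mod.correct_bias(stack, truth.background_stack)
        rois = frap_mod.build_bleach_rois([truth.bleach_point],
                                          stack.frames[0].shape)
        series = frap_mod.extract_series(corrected, rois)
        norm = frap_mod.normalize_trace(series.roi_traces["roi0"],
                                        series.reference_trace,
                                        series.bleach_frame_index)
        fits.append(frap_mod.fit_recovery(norm, series.timestamps,
                                          series.bleach_frame_index))
        traces.append(norm)
    return frap_mod.cohort_curve(traces, fits)
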