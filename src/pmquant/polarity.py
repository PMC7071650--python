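"""Daughter/mother PM polarity ratios (Fd/Fm) from two-channel line scans.

The estimator follows the line-scan protocol used for PM lipid-reporter
quantitation: a line is drawn through both cells, peaks of the PM-marker
profile define where the membrane is, and within each cell's stretch of the
line the two highest reporter peaks that coincide with marker peaks are
averaged to give Fd (daughter) and Fm (mother); the polarity ratio is Fd/Fm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .imgcore import ChannelImage, LineProfile, find_profile_peaks, sample_line

__all__ = ["PolarityMeasurement", "CohortSummary", "measure_cell_polarity",
           "cohort_polarity"]


@dataclass
class PolarityMeasurement:
    """Per-cell polarity result.

    ``flag`` is None for a valid measurement, otherwise a short reason the
    cell was excluded from cohort statistics (e.g. too few coincident peaks).
    """

    cell_id: str
    Fd: float
    Fm: float
    ratio: float
    peaks_used: dict[str, list[float]]
    flag: str | None = None

    @property
    def valid(self) -> bool:
        return self.flag is None


@dataclass
class CohortSummary:
    n: int
    mean_Fd: float
    mean_Fm: float
    mean_ratio: float
    sd_ratio: float
    n_flagged: int = 0


def _segment_peaks(profile: LineProfile, interval: tuple[float, float],
                   channel: str, min_prominence: float | None
                   ) -> list[tuple[float, float]]:
    lo, hi = interval
    return [(p, v) for p, v in find_profile_peaks(profile, channel, min_prominence)
            if lo <= p < hi]


def _coincident_candidates(reporter_peaks: list[tuple[float, float]],
                           marker_peaks: list[tuple[float, float]],
                           window: float) -> list[tuple[float, float]]:
    mpos = np.array([p for p, _ in marker_peaks])
    if mpos.size == 0:
        return []
    return [(p, v) for p, v in reporter_peaks
            if np.min(np.abs(mpos - p)) <= window]


def measure_cell_polarity(reporter: ChannelImage, marker: ChannelImage,
                          line: tuple[tuple[float, float], tuple[float, float]],
                          cell_segments: tuple[tuple[float, float], tuple[float, float]],
                          coincidence_window: float = 2.0,
                          cell_id: str = "cell",
                          spacing: float = 0.5,
                          min_prominence: float | None = None
                          ) -> PolarityMeasurement:
    """Measure Fd/Fm for one cell pair along a line through both cells.

    Parameters
    ----------
    reporter, marker : ChannelImage
        Reporter channel to quantify and PM-marker channel defining where
        the membrane is.
    line : ((x0, y0), (x1, y1))
        Scan line in pixel coordinates; must cross both cells.
    cell_segments : (daughter_interval, mother_interval)
        Half-open intervals in line-position units (px from p0) assigning
        stretches of the profile to the daughter and mother cell.
    coincidence_window : float
        Maximum |reporter peak − marker peak| distance (px) for a reporter
        peak to count as a PM peak.
    min_prominence : float, optional
        Peak prominence threshold; defaults to 3x the robust noise SD of
        each profile.

    Cells with fewer than two coincident reporter peaks in either segment
    are flagged rather than raising, so cohorts keep their per-cell counts.
    """
    daughter_iv, mother_iv = cell_segments
    profile = sample_line({"reporter": reporter, "marker": marker},
                          line[0], line[1], spacing=spacing)

    values: dict[str, float] = {}
    peaks_used: dict[str, list[float]] = {}
    flag = None
    for label, interval in (("daughter", daughter_iv), ("mother", mother_iv)):
        marker_pk = _segment_peaks(profile, interval, "marker", min_prominence)
        reporter_pk = _segment_peaks(profile, interval, "reporter", min_prominence)
        candidates = _coincident_candidates(reporter_pk, marker_pk,
                                            coincidence_window)
        if len(candidates) < 2:
            flag = f"fewer than two coincident reporter peaks in {label} segment"
            values[label] = np.nan
            peaks_used[label] = []
            continue
        top2 = sorted(candidates, key=lambda pv: pv[1], reverse=True)[:2]
        values[label] = float(np.mean([v for _, v in top2]))
        peaks_used[label] = [p for p, _ in top2]

    fd, fm = values["daughter"], values["mother"]
    ratio = fd / fm if flag is None else np.nan
    return PolarityMeasurement(cell_id, fd, fm, ratio, peaks_used, flag)


def cohort_polarity(measurements: list[PolarityMeasurement]) -> CohortSummary:
    """Arithmetic cohort summary over unflagged measurements.

    SD is the sample standard deviation (ddof=1); a single-cell cohort has
    SD 0 by convention.
    """
    valid = [m for m in measurements if m.valid]
    if not valid:
        raise ValueError("no unflagged measurements in cohort")
    ratios = np.array([m.ratio for m in valid])
    sd = float(np.std(ratios, ddof=1)) if ratios.size > 1 else 0.0
    return CohortSummary(
        n=len(valid),
        mean_Fd=float(np.mean([m.Fd for m in valid])),
        mean_Fm=float(np.mean([m.Fm for m in valid])),
        mean_ratio=float(np.mean(ratios)),
        sd_ratio=sd,
        n_flagged=len(measurements) - len(valid),
    )
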