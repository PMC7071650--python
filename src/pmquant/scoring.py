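"""Aggregation-state scoring and sedimentation densitometry fractions.

A cell "has cytosolic aggregates" iff at least one intensity maximum lies in
its interior after the cortical band is eroded away; cells with only
cortical puncta (normal cortical assemblies) score as aggregate-free.  The
strict rule — a single interior punctum counts as aggregated — is a stated
re-operationalization of a visual criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .imgcore import ChannelImage
from .puncta import find_maxima

__all__ = ["AggregationScore", "SedimentationResult", "score_cell_aggregation",
           "aggregation_timecourse", "sedimentation_fractions"]


@dataclass
class AggregationScore:
    timepoint: float                   # minutes
    n_cells: int
    n_without_aggregates: int
    percent_without: float


@dataclass
class SedimentationResult:
    sample_id: str
    temperature: float
    pellet_fraction: float
    supernatant_fraction: float


def score_cell_aggregation(img: ChannelImage, cell_mask: np.ndarray,
                           cortical_band: float = 3.0,
                           noise_tolerance: float | None = None) -> bool:
    """True iff the cell contains at least one interior intensity maximum.

    The interior is the cell mask eroded by ``cortical_band`` px, so maxima
    on the cortex never influence the call.  Cells too small to retain an
    interior after erosion are unscorable and raise.
    """
    cell_mask = np.asarray(cell_mask, dtype=bool)
    if not cell_mask.any():
        raise ValueError("empty cell mask")
    interior = ndimage.binary_erosion(
        cell_mask, iterations=int(round(cortical_band)))
    if not interior.any():
        raise ValueError(
            f"cell unscorable: smaller than twice the cortical band "
            f"({cortical_band} px)")
    maxima = find_maxima(img, noise_tolerance)
    return any(interior[y, x] for x, y in maxima.points)


def aggregation_timecourse(
        scores_by_timepoint: dict[float, list[bool]]) -> list[AggregationScore]:
    """Percentage of cells without cytosolic aggregates at each timepoint.

    ``scores_by_timepoint`` maps timepoint (min) to per-cell booleans
    (True = has aggregates, as returned by :func:`score_cell_aggregation`).
    """
    out = []
    for tp in sorted(scores_by_timepoint):
        scores = scores_by_timepoint[tp]
        if not scores:
            raise ValueError(f"no cells scored at timepoint {tp}")
        n_without = sum(1 for has_agg in scores if not has_agg)
        out.append(AggregationScore(
            timepoint=tp, n_cells=len(scores),
            n_without_aggregates=n_without,
            percent_without=100.0 * n_without / len(scores)))
    return out


def sedimentation_fractions(table: pd.DataFrame) -> list[SedimentationResult]:
    """Pellet and supernatant fractions per row of a densitometry table.

    Expects columns ``sample_id, temperature_C, pellet, supernatant``; the
    two fractions of each row sum to 1 exactly.
    """
    required = {"sample_id", "temperature_C", "pellet", "supernatant"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"densitometry table missing columns: {sorted(missing)}")
    out = []
    for _, row in table.iterrows():
        p, s = float(row["pellet"]), float(row["supernatant"])
        if p < 0 or s < 0:
            raise ValueError(f"negative band intensity in row {row['sample_id']!r}")
        total = p + s
        if total <= 0:
            raise ValueError(f"zero total intensity in row {row['sample_id']!r}")
        out.append(SedimentationResult(
            sample_id=str(row["sample_id"]),
            temperature=float(row["temperature_C"]),
            pellet_fraction=p / total,
            supernatant_fraction=s / total))
    return out


def sedimentation_summary(results: list[SedimentationResult]) -> pd.DataFrame:
    """Per-temperature mean ± SD of the pellet fraction."""
    df = pd.DataFrame([{"temperature_C": r.temperature,
                        "pellet_fraction": r.pellet_fraction} for r in results])
    g = df.groupby("temperature_C")["pellet_fraction"]
    return pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1).fillna(0.0),
                         "n": g.size()}).reset_index()
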