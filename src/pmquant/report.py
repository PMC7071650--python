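"""Cohort statistics, significance tests, and the pipeline orchestrator.

The significance tests mirror figure-legend usage: a two-sided Welch t test
for pairwise comparisons (robust default; Student's t available via flag)
and a one-way ANOVA for multi-group comparisons.  ``run_pipeline`` executes
requested stages end to end — simulating inputs with the stage's seed,
running the measurement, and writing CSV/JSON outputs plus a run log — so a
fixed config reproduces its report bit for bit.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import frap as frap_mod
from . import polarity as pol_mod
from . import puncta as pun_mod
from . import scoring as sco_mod
from . import synthgen as gen_mod

__all__ = ["CohortComparison", "welch_t_test", "anova_oneway", "run_pipeline"]

log = logging.getLogger("pmquant")


@dataclass
class CohortComparison:
    group_labels: list[str]
    n: list[int]
    means: list[float]
    sds: list[float]
    test: str
    statistic: float
    p_value: float


def _summaries(groups: list[np.ndarray]) -> tuple[list[int], list[float], list[float]]:
    ns = [g.size for g in groups]
    means = [float(g.mean()) for g in groups]
    sds = [float(g.std(ddof=1)) if g.size > 1 else 0.0 for g in groups]
    return ns, means, sds


def welch_t_test(group_a, group_b, labels: tuple[str, str] = ("A", "B"),
                 equal_var: bool = False) -> CohortComparison:
    """Two-sided t test (Welch by default, Student with ``equal_var=True``).

    Two zero-variance groups with equal means give statistic 0 and p = 1 by
    convention instead of the 0/0 the formula would produce.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    ns, means, sds = _summaries([a, b])
    if sds[0] == 0 and sds[1] == 0:
        stat, p = (0.0, 1.0) if means[0] == means[1] else (np.inf, 0.0)
    else:
        stat, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return CohortComparison(list(labels), ns, means, sds,
                            "student_t" if equal_var else "welch_t",
                            float(stat), float(p))


def anova_oneway(groups: list, labels: list[str] | None = None) -> CohortComparison:
    """One-way ANOVA across two or more groups.

    All-identical groups (zero variance everywhere, equal means) give p = 1
    by convention.
    """
    arrs = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least two groups")
    if any(a.size < 2 for a in arrs):
        raise ValueError("each group needs at least 2 observations")
    labels = labels or [f"group{i}" for i in range(len(arrs))]
    ns, means, sds = _summaries(arrs)
    if all(s == 0 for s in sds) and len(set(means)) == 1:
        stat, p = 0.0, 1.0
    else:
        stat, p = sps.f_oneway(*arrs)
    return CohortComparison(labels, ns, means, sds, "anova_oneway",
                            float(stat), float(p))


# ---------------------------------------------------------------------------
# Pipeline orchestration
# ---------------------------------------------------------------------------

def _stage_polarity(cfg: dict, rng_seed: int, outdir: Path) -> dict:
    """Simulate cell-pair cohorts and measure Fd/Fm per condition."""
    rows, summaries = [], {}
    for cond in cfg.get("conditions", [{"label": "26C", "ratio_true": 7.5, "n_cells": 40}]):
        measurements = []
        for i in range(cond["n_cells"]):
            params = gen_mod.CellPairParams(
                ratio_true=cond["ratio_true"],
                snr=cond.get("snr", 10.0),
                seed=rng_seed + 1000 * hash(cond["label"]) % 100_000 + i)
            channels, geom = gen_mod.generate_cell_pair(params)
            m = pol_mod.measure_cell_polarity(
                channels["reporter"], channels["marker"], geom.line,
                (geom.daughter_interval, geom.mother_interval),
                cell_id=f"{cond['label']}_{i}")
            measurements.append(m)
            rows.append({"cell_id": m.cell_id, "Fd": m.Fd, "Fm": m.Fm,
                         "ratio": m.ratio, "flag": m.flag or ""})
        summaries[cond["label"]] = asdict(pol_mod.cohort_polarity(measurements))
    pd.DataFrame(rows).to_csv(outdir / "polarity_cells.csv", index=False)
    return summaries


def _stage_er_association(cfg: dict, rng_seed: int, outdir: Path) -> dict:
    params = gen_mod.FieldParams(
        n_maxima=cfg.get("n_maxima", 1000),
        assoc_fraction_true=cfg.get("assoc_fraction_true", 0.8),
        seed=rng_seed)
    channels, truth = gen_mod.generate_field(params)
    er = channels["er"]
    thr, mn, bg = pun_mod.derive_binary_threshold(er, truth.er_mask, ~truth.er_mask)
    maxima = pun_mod.find_maxima(channels["puncta"],
                                 noise_tolerance=params.puncta_amplitude / 2)
    res = pun_mod.classify_association(maxima, er, thr, mn, bg)
    pd.DataFrame({"x": [p[0] for p in maxima.points],
                  "y": [p[1] for p in maxima.points],
                  "value": maxima.values,
                  "associated": [er.pixels[y, x] >= thr for x, y in maxima.points],
                  }).to_csv(outdir / "maxima.csv", index=False)
    return asdict(res)


def _stage_frap(cfg: dict, rng_seed: int, outdir: Path) -> dict:
    n_rois = cfg.get("n_rois", 22)
    fits, traces, rows = [], [], []
    for i in range(n_rois):
        params = gen_mod.FrapSimParams(
            mobile_fraction_true=cfg.get("mobile_fraction_true", 0.2),
            seed=rng_seed + i)
        stack, truth = gen_mod.generate_frap_series(params)
        corrected = frap_mod.correct_bias(stack, truth.background_stack)
        rois = frap_mod.build_bleach_rois([truth.bleach_point], stack.frames[0].shape)
        series = frap_mod.extract_series(corrected, rois)
        norm = frap_mod.normalize_trace(series.roi_traces["roi0"],
                                        series.reference_trace,
                                        series.bleach_frame_index)
        fit = frap_mod.fit_recovery(norm, series.timestamps,
                                    series.bleach_frame_index)
        fits.append(fit)
        traces.append(norm)
        rows.append({"roi_id": f"roi{i}", "F_post": fit.F_post, "F_inf": fit.F_inf,
                     "k": fit.k, "mobile": fit.mobile_fraction,
                     "immobile": fit.immobile_fraction, "flag": fit.flag or ""})
    cohort = frap_mod.cohort_curve(traces, fits)
    pd.DataFrame(rows).to_csv(outdir / "frap_fits.csv", index=False)
    pd.DataFrame({"t": np.arange(cohort["mean_trace"].size),
                  "mean": cohort["mean_trace"], "sd": cohort["sd_trace"]
                  }).to_csv(outdir / "frap_cohort_curve.csv", index=False)
    return {"n_fits": cohort["n_fits"],
            "mean_mobile_fraction": cohort["mean_mobile_fraction"],
            "mean_immobile_fraction": cohort["mean_immobile_fraction"]}


def _stage_sedimentation(cfg: dict, rng_seed: int, outdir: Path) -> dict:
    table = gen_mod.generate_densitometry(
        n=cfg.get("n_replicates", 3),
        pellet_fraction_true=cfg.get("pellet_fraction_true", {26.0: 0.1, 42.0: 0.9}),
        noise_cv=cfg.get("noise_cv", 0.1), seed=rng_seed)
    table.to_csv(outdir / "densitometry.csv", index=False)
    results = sco_mod.sedimentation_fractions(table)
    summary = sco_mod.sedimentation_summary(results)
    summary.to_csv(outdir / "sedimentation_summary.csv", index=False)
    return summary.to_dict(orient="records")


_STAGES = {
    "polarity": _stage_polarity,
    "er_association": _stage_er_association,
    "frap": _stage_frap,
    "sedimentation": _stage_sedimentation,
}


def run_pipeline(config: dict) -> dict:
    """Run the requested stages and write their outputs.

    ``config`` keys: ``outdir`` (required), ``seed`` (default 0), ``stages``
    (list of stage names; default all), plus one optional sub-dict of options
    per stage.  Returns the report bundle (also written as ``report.json``).
    Unknown stages or stage failures are reported with the stage name.
    """
    outdir = Path(config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    stages = config.get("stages", list(_STAGES))

    report: dict = {"seed": seed, "stages": {}, "errors": {}}
    t0 = time.time()
    for name in stages:
        if name not in _STAGES:
            raise ValueError(f"unknown pipeline stage: {name!r}")
        log.info("running stage %s", name)
        try:
            report["stages"][name] = _STAGES[name](config.get(name, {}), seed, outdir)
        except FileNotFoundError as exc:
            report["errors"][name] = f"missing input: {exc}"
        except ValueError as exc:
            report["errors"][name] = str(exc)
    report["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "report.json").write_text(json.dumps(report, indent=2, default=float))
    return report
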