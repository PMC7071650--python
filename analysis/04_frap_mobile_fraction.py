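#!/usr/bin/env python
"""FRAP mobile fractions of heat-induced Osh3 puncta and in vitro condensates.

Simulates the two published FRAP cohorts — 22 cellular puncta with a true
mobile fraction of 0.20 and 8 in vitro condensates at 0.33 — at 5% noise
with incidental whole-field photobleaching and camera bias, then runs the
full pipeline (bias correction, 5x5 template ROIs, double normalization,
single-exponential fit) and reports cohort mobile fractions.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from pmquant.experiments import frap_mobile_fraction

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

cohorts = {"in_vivo_puncta": (0.20, 22, 900),
           "in_vitro_condensates": (0.33, 8, 950)}
summary = {}
for label, (truth, n_rois, seed0) in cohorts.items():
    out = frap_mobile_fraction(truth, n_rois=n_rois, noise_frac=0.05,
                               base_seed=seed0)
    summary[label] = {"truth": truth, "n_rois": out["n_fits"],
                      "mean_mobile_fraction": round(out["mean_mobile_fraction"], 4),
                      "mean_immobile_fraction": round(out["mean_immobile_fraction"], 4)}
    print(f"{label}: mobile fraction = {out['mean_mobile_fraction']:.3f} "
          f"(truth {truth}, n = {out['n_fits']} ROIs)")
    pd.DataFrame({"frame": np.arange(out["mean_trace"].size),
                  "mean": out["mean_trace"], "sd": out["sd_trace"]}
                 ).to_csv(OUT / f"frap_curve_{label}.csv", index=False)

(OUT / "frap_mobile_fractions.json").write_text(json.dumps(summary, indent=2))
print("written:", OUT / "frap_mobile_fractions.json")
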