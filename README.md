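# pmquant

Quantitative fluorescence-microscopy measurements for studies of
plasma-membrane (PM) lipid polarity in budding yeast — the kind of analysis
used to show that the phosphoinositide PI4P is enriched at the PM of growing
daughter cells and redistributes to mother cells under heat stress, and that
this is controlled by a heat-sensitive lipid-exchange protein (Osh3) which
aggregates upon heat shock.

The package implements, as tested reusable code, every measurement such a
study chains together:

- **Line-scan polarity ratios (F<sub>d</sub>/F<sub>m</sub>).** A line is
  drawn through a daughter/mother cell pair; peaks of a PM-marker channel
  (e.g. mCherry-2xPH) locate the membrane crossings, and within each cell
  the two highest reporter peaks (e.g. GFP-P4C for PI4P) coinciding with
  marker peaks are averaged to give F<sub>d</sub> and F<sub>m</sub>; the
  polarity ratio is F<sub>d</sub>/F<sub>m</sub>.
- **Maxima detection and ER-association.** Puncta (PI 4-kinase "PIK
  patches", aggregates) are detected as intensity maxima under a
  noise-tolerance (topographic prominence) criterion equivalent to ImageJ's
  Find Maxima; a binary threshold derived from the ER-marker intensity range
  (minimal specific ER signal vs maximal ER-free background) classifies each
  maximum as ER-associated or not.
- **Thresholded overlap colocalization** (percent of above-threshold pixel
  area of one channel overlapping the other, and vice versa) and
  marker-masked ROI mean intensities.
- **FRAP.** Camera-bias correction by subtraction of an averaged dark
  stack, 5×5 template ROIs, double normalization against unbleached
  reference fluorescence to remove incidental photobleaching, and a
  single-exponential recovery fit
  F(t) = F<sub>∞</sub> − (F<sub>∞</sub> − F<sub>post</sub>)·e<sup>−kt</sup>;
  the mobile fraction is
  (F<sub>∞</sub> − F<sub>post</sub>)/(F<sub>pre</sub> − F<sub>post</sub>).
- **Aggregation-state scoring** (fraction of cells without interior puncta
  after eroding a cortical band) and **sedimentation densitometry**
  (pellet fraction P/(P+S) per condition).
- **Cohort statistics**: Welch t test and one-way ANOVA as used in the
  figure-legend comparisons.

Because raw microscopy from such studies is typically not deposited, the
package ships a synthetic-data generator (`pmquant.synthgen`) that renders
every input class — two-channel cell pairs with a controllable
daughter:mother ratio, cortical ER/puncta fields with a controllable
association fraction, FRAP time-lapses with controllable mobile fraction and
incidental photobleaching, and densitometry tables — together with its
ground truth, so every estimator has a parameter-recovery test.

## Worked example

```sh
python analysis/01_polarity_heat_shock.py
```

simulates the two wild-type line-scan cohorts (40 cells with true
F<sub>d</sub>/F<sub>m</sub> = 7.5 for non-stress growth at 26 °C; 45 cells
at 1.5 for a 10-min 42 °C heat shock; Poisson + Gaussian noise at SNR 10),
measures every cell, and prints:

```
26C: mean Fd/Fm = 7.60 (truth 7.5, n = 40)
42C_10min: mean Fd/Fm = 1.50 (truth 1.5, n = 45)
Welch t test 26C vs 42C: t = 68.1, p = 1.63e-45
```

i.e. the estimator recovers both ground-truth ratios within a few percent,
and the heat-shock collapse of PI4P polarity (7.5 → 1.5) is overwhelmingly
significant.  The remaining drivers under `analysis/` cover the
osh3-deletion comparison (`02`), ER-association of PIK patches (`03`), FRAP
mobile fractions of heat-induced puncta and in vitro condensates (`04`),
the aggregation-recovery time course (`05`), and sedimentation fractions
(`06`); each writes its tables to `results/`.

Library use mirrors the drivers:

```python
from pmquant import synthgen, polarity

channels, geom = synthgen.generate_cell_pair(
    synthgen.CellPairParams(ratio_true=5.4, snr=10, seed=1))
m = polarity.measure_cell_polarity(
    channels["reporter"], channels["marker"], geom.line,
    (geom.daughter_interval, geom.mother_interval))
print(m.Fd, m.Fm, m.ratio)
```

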