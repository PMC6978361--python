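# ndrscreen

Quantification of drug effects in cell-based high-throughput viability
screens using the **normalized drug response (NDR)** metric, with the
full surrounding pipeline: fold-change scoring, dose-response curve
fitting, drug sensitivity scores (DSS), drug-effect classification,
plate quality control, and a ground-truth growth simulator.

## The problem

In two-time-point viability screens (e.g. luminescence read at seeding
and after ~72 h of drug exposure on 384-well plates), the usual
endpoint normalizations are biased by two experimental realities:
cells grow at different rates, and the positive-control signal — wells
treated with a uniformly lethal agent such as benzethonium chloride —
never actually reaches zero, because whole-well assays carry
background. Percent inhibition (PI) ignores growth dynamics entirely;
growth-rate normalization (GR) ignores the positive control. NDR uses
both control conditions and both time points.

With `foldChange = End_Readout / Start_Readout` per well, and the
plate's median control fold changes `fc_neg` (DMSO) and `fc_pos`
(positive control):

```
NDR = max(-1, (1 - 2^(log2 fc_drug / log2 fc_pos))
            / (1 - 2^(log2 fc_neg / log2 fc_pos)))

GR  = 2^(log2 fc_drug / log2 fc_neg) - 1

PI  = (End_neg - End_drug) / (End_neg - End_pos)
```

NDR reads directly as drug behavior: **1** = growth like the negative
control, **0** = complete growth inhibition (cytostasis), **−1** =
complete killing (the clamp floor), **> 1** = growth stimulation.

Downstream, each drug's five-concentration response series is fitted
with a four-parameter log-logistic curve; the **DSS** integrates the
fitted inhibition curve above a minimum activity level `A_min` over the
tested log-concentration window (normalized to 100 for a full-window
100%-inhibition plateau, negative for uniformly stimulatory drugs).
Drugs are classified as *lethal / sub-effective / non-effective /
growth-stimulatory* from their top-concentration fold change relative
to the negative-control growth distribution, and plate quality is
summarized by the Z′-factor on metric-transformed control values.

## Worked example

```python
from ndrscreen import *
from ndrscreen.dose_response import dss_for_series
from ndrscreen.qc_stats import screen_z_prime

# direct metric evaluation: a drug well doubling while DMSO wells
# quadruple and the positive control halves
ndr(2.0, 4.0, 0.5)   # 0.6666666666666666  (partial growth inhibition)
gr(2.0, 4.0)         # 0.41421356237309515
pi(550, 1000, 100)   # 0.5                 (fraction; x100 for percent)

# a simulated 16-drug screen with seeding/readout noise, scored and QC'd
table, truth = generate_synthetic_screen(
    n_drugs=16, noise=NoiseModel(seeding_cv=0.1, readout_cv=0.02, seed=42))
scored = score_screen(table, "NDR")
screen_z_prime(scored)[0].z_prime        # 0.981 -> high-quality plate (> 0.5)

# dose-response curve and DSS for one lethal drug
wells = scored.wells.query("drug_name == 'lethal_001'").sort_values("concentration")
series = DoseSeries("lethal_001", tuple(wells.concentration),
                    tuple(wells.NDR), "NDR")
value, fit = dss_for_series(series)
# observed NDR: [1.006, 0.990, 0.742, -0.804, -1.0]
# value = 36.3 (DSS_NDR), fit.curve.ec50 = 2.91e-07 M

classify_screen(table)["category"].value_counts()
# growth_stimulatory 5, lethal 4, sub_effective 4, non_effective 3
```

The NDR series runs from negative-control-like growth (≈ 1) at the
lowest concentration to complete killing (−1) at the top — a lethal
drug; its DSS of 36.3 places it well above the near-zero scores of
non-effective drugs.

The same pipeline is available from the shell:

```bash
ndr simulate --scenario screen --seed 42 --output sim.csv --truth truth.csv
ndr score    --input sim.csv --metric ndr --output scored.csv
ndr fit      --input scored.csv --output curves.csv
ndr dss      --input scored.csv --output dss.csv
ndr classify --input sim.csv --output categories.csv
ndr qc       --input sim.csv --replicate sim2.csv --output qc.csv
```

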