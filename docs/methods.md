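# Methods

## Response metrics

All metrics operate on two-time-point viability readouts. The per-well
fold change is `End_Readout / Start_Readout`; wells with a zero start
readout are accepted by the data model but rejected by every metric
(the fold change is undefined), and the reader flags them on load.

**NDR.** For a drug-treated fold change `fc_drug` and per-plate control
fold changes `fc_neg`, `fc_pos`:

```
NDR = max(-1, (1 - 2^(log2 fc_drug / log2 fc_pos))
            / (1 - 2^(log2 fc_neg / log2 fc_pos)))
```

The exponent base is fixed at 2. Any base gives quantitatively similar
values, but a configurable base would make outputs irreproducible
across configurations for no analytical gain. Only the lower clamp at
−1 is applied; values above 1 (growth stimulation) are reported as-is.

**GR** is `2^(log2 fc_drug / log2 fc_neg) − 1`; **PI** is
`(End_neg − End_drug) / (End_neg − End_pos)`, kept as a fraction —
the ×100 display scale is applied only by the DSS scaling transform or
explicit formatting.

**Degenerate guards.** `|log2 fc| < 1e-9` for either control raises an
error rather than returning near-infinities: a positive control at
fold change 1 makes the NDR exponent undefined and a negative control
at fold change 1 zeroes the denominator (and the GR exponent). Equal
negative/positive endpoint medians make PI undefined. The tolerance is
`response_metrics.LOG2_GUARD`.

**Control aggregation** uses the median of per-well fold changes, per
plate. The median (not the mean) guards against outlier control wells;
per-plate aggregation reflects that plate-level artifacts are the
dominant noise source (plate quality itself is judged per plate). The
alternative reading — fold change of median readings — is available as
`aggregation="fold_change_of_medians"`.

**Start-readout estimation.** External datasets often lack a baseline
measurement. `estimate_start_readout` divides the median
negative-control endpoint by an assumed negative-control fold change
(e.g. the 3.2 observed for MDA-MB-231 cells) and applies that single
start value to every well of the plate. This assumes uniform seeding;
per-well baselines simply do not exist in such data.

## Dose-response fitting

Curves are four-parameter log-logistic in log10-concentration space:

```
R(x) = R_min + (R_max - R_min) / (1 + 10^(slope * (log10 EC50 - x)))
```

Fitting is least squares via Levenberg–Marquardt from five data-driven
starts: asymptotes from the extreme responses, EC50 anchored at the
concentration whose response is nearest the half-range (plus the mean
and median log-concentration as alternatives), Hill slopes
{0.5, 1, 2} signed by the observed response trend. The candidate with
the lowest residual sum of squares wins; ties break to the smallest
|slope|. `(R_min, R_max, slope)` and `(R_max, R_min, −slope)` describe
the same curve, so fits are canonicalized to `R_max ≥ R_min`. A series
of identical responses short-circuits to the exact flat curve
(RMSD 0) instead of entering the optimizer. Non-convergent fits are
returned with `converged=False`, never dropped silently. Fit quality is
the RMSD `sqrt(mean((O_i − E_i)^2))` at the tested concentrations, and
the baseline distance |lowest-concentration response − no-effect
level| (1 for NDR/GR, 100 on the PI-viability orientation) flags
normalization bias at the curve foot. Four points are the minimum for
a four-parameter fit; the standard screen provides five.

## DSS

Metrics are first mapped onto a percent-inhibition axis:
`PI×100`, `0.5(1−GR)×100`, `0.5(1−NDR)×100` — 0 at negative-control
behavior, 100 at complete killing, negative for stimulation.

The score is a normalized area: with the fitted curve `R(x)` on that
axis and the tested window `[x1, x2]` in log10 concentration,

```
DSS = 100 * ∫ max(R(x) - A_min, 0) dx / ((100 - A_min) * (x2 - x1))
```

so a full-window plateau at 100% inhibition scores exactly 100 and a
curve never exceeding `A_min` scores 0. `A_min` defaults to 10 (percent
inhibition): responses below that level are within typical assay noise
and should not accrue score. The integral is closed-form — the 4PL has
the elementary antiderivative `c·x + (d−c)/k · ln(1 + e^(k(x−m)))` with
`k = slope·ln 10` — with the threshold crossing solved analytically, so
no quadrature error enters the score (quadrature is used only as an
independent oracle in the tests).

Uniformly stimulatory drugs (all scaled responses negative) are scored
by mirroring the responses about the zero-inhibition baseline, fitting
and integrating the mirrored curve, and negating the result. Mixed-sign
series fall back to the plain score of the original responses. A flat
series exactly at `−A_min` mirrors onto the threshold itself and scores
0: the excess above the threshold has measure zero.

## Classification

A drug's category comes from the fold change of its
highest-concentration well against the negative-control fold-change
distribution (mean `m`, sample SD `s`, per plate by default):

| band | category |
|---|---|
| `fc < 1` | lethal |
| `1 ≤ fc < m − k·s` | sub-effective |
| `m − k·s ≤ fc ≤ m + k·s` | non-effective |
| `fc > m + k·s` | growth-stimulatory |

`k` defaults to 1; band boundaries are assigned to non-effective —
claiming an effect requires strict exceedance. The bands partition the
positive reals, and increasing fold change never moves a drug down the
lethal → stimulatory order. A 2-SD band is available via `--k-sd 2`.

## Plate QC and consistency statistics

`Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg|`, computed on
metric-transformed control values by default (raw endpoints optional),
with sample (n−1) SDs because control-well counts are small (16 per
role in the default layout). Z′ > 0.5 marks a high-quality plate.

Replicate consistency is the absolute per-well metric difference
between two scored runs matched on (plate, well), drug wells only;
time-point consistency is each well's deviation from its median
response across ≥ 2 time points. The overlapping coefficient of two
normal densities uses the closed form `2Φ(−|μ1−μ2|/(2σ))` for equal
variances and otherwise integrates the pointwise minimum exactly via
the two density-crossing points (comparison in log-density to avoid
tail underflow). Standard hypothesis tests (Wilcoxon, KS, F, Welch t,
Shapiro–Wilk) are deliberately not re-implemented; scipy provides them.

## Simulator

Populations follow **base-2 exponential growth**:
`readout(t) = S0 · 2^(g·t)`, doubling time `1/g`. This convention is
chosen so that the stated negative-control rate 0.03 h⁻¹ corresponds to
the ~30 h doubling time it is meant to represent (1/0.03 ≈ 33 h; the
natural-log convention would give 23 h). This choice affects every
simulated number and is therefore stated prominently.

Default rates: negative control g = 0.03 h⁻¹, positive control
g = −0.01 h⁻¹, duration 72 h, base start signal 1000 (arbitrary
luminescence units).

Three stock scenarios evaluate the metrics on fold-change grids, with
fold changes specified directly (they, not the rate/time pairs, are
what enter the metrics):

* **s1** — fixed controls: fc_neg = 4, fc_pos = 0.5, drug 0.5–8 fold.
* **s2** — varying positive-control background: fc_pos 0.4–0.8
  (rates −0.015 to −0.005 h⁻¹), fc_neg = 4.
* **s3** — varying negative-control growth: fc_neg 2–15
  (rates 0.01–0.055 h⁻¹), fc_pos = 0.5.

Grid densities are not dictated by the scenario definitions; the
default is 100 log-spaced drug fold changes (log spacing because fold
changes are ratios) and 5 points per varying control axis, both
configurable. Grid points with fc_neg = 1 are skipped with a warning
(metrics undefined there).

**Synthetic screens.** Drugs carry true 4PL inhibition profiles
(fraction `f(c)`; negative = stimulation); a well's effective rate is
`g_neg + f(c) · (g_pos − g_neg)`. The default layout is 16 negative +
16 positive controls per 384-well plate with drug wells at five 10-fold
dilutions (10,000-fold range, top 10 µM), mirroring a standard oncology
screen; 131 drugs × 5 concentrations need 2 plates. The default drug
panel cycles through the four potency archetypes so every category is
represented. Noise is multiplicative log-normal with mean 1 —
`seeding_cv` on the true per-well start signal, `readout_cv`
independently on each measurement — because luminescence noise scales
with signal. The defaults are noise-free; validation experiments use
seeding CV 0.2 (uneven seeding, the dominant artifact the metric is
designed to absorb) and readout CV 0.02. All randomness flows from one
integer seed; identical seeds give byte-identical screens.

**What the simulator does not emulate:** spatial plate effects (edge
evaporation, dispensing gradients), signal bleed-through between wells,
drug interactions with the readout chemistry, heteroscedastic
background drift, and concurrent growth-and-death kinetics within a
well (the model is a single net rate). Passing tests therefore
demonstrate correctness of the quantification given the stated noise
structure, not robustness to every real-screen artifact.

## Validation problem sizes

The bundled checks use: 10,000 random fold-change triples for
formula-oracle equivalence (tolerance 1e−12); 200 noisy 4PL fits at 2%
multiplicative noise (median |log10 EC50 error| < 0.1); 1000 random
curves for closed-form-vs-quadrature DSS agreement (1e−6 of full
scale); a 32-drug noise-free screen for exact pipeline recovery of
metrics and categories; and 100 simulated replicate plate pairs at
seeding CV 0.2 for the replicate-consistency comparison, where the
median per-plate |ΔNDR| (~0.006) is far below the median |ΔPI| (~0.17)
— the direction expected when seeding noise dominates, since PI has no
access to the start readout that would cancel it.

## Known limitations

* The DSS closed form here is the normalized-AUC variant described
  above; other DSS flavors (unnormalized AUC, log-EC50-weighted) are
  not implemented, and `a_min`/normalization are exposed in
  `DSSConfig` for auditability.
* Only two-time-point fold changes are supported — no time-lapse
  growth-rate inference, and no biphasic or 5PL dose-response models.
* PI's baseline distance requires responses on the viability
  orientation (100·(1−PI)); the package does not guess the scale.
* The classifier uses a single top-concentration well per drug;
  replicate top-concentration wells are not pooled.
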