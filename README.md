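# trendim

Trend interchangeability analysis for method-comparison studies of paired
serial measurements — the setting where a continuous test method (TM), such
as an arterial pulse contour cardiac output monitor, is validated against
an intermittent reference method (RM), such as bolus thermodilution, and
the question is whether *changes* seen by the two methods are
interchangeable.

## The method

Each change between consecutive paired measurements (RM₁, TM₁) → (RM₂, TM₂)
is classified in two steps using the reference method's repeatability
coefficient RC (a single reading `v` is trusted to `v ± v·RC`):

1. **Interpretability.** The change is *uninterpretable* (blue) when the
   precision intervals of RM₁ and RM₂ overlap — the apparent change cannot
   be told apart from repeat-measurement noise.
2. **Interchangeability.** Otherwise the second pair is located relative to
   the two interchangeability lines anchored at the first pair,

       X = Y(1+RC) + (1+RC)(RM₁−TM₁)
       X = Y(1−RC) + (1+RC)(RM₁−TM₁)

   with X the reference and Y the test coordinate: *interchangeable*
   (green) inside the zone, *gray zone* (orange) when only the precision
   interval of RM₂ reaches the zone, *noninterchangeable* (red) otherwise.

The **trend interchangeability rate** = interchangeable / interpretable
changes, labeled excellent (≥95%), good (≥90%), poor (75–90%) or not
clinically relevant (<75%).  The legacy four-quadrant concordance rate and
polar-plot statistics (angular bias, radial limits of agreement) are
provided for side-by-side reporting, along with color-coded diagnostic
plots and a chi-square comparison of rates across devices.
Details, conventions and limitations: [docs/methods.md](docs/methods.md).

## Worked example

Simulate the default 150-patient, three-range validation cohort and
classify its 300 changes at a 5% repeatability coefficient:

```sh
$ trendim simulate --seed 1 --out sim.csv
wrote sim.csv (150 patients, seed 1)

$ trendim classify sim.csv --rc 5 --no-first-exclusion --out tim_out
note: 9 change(s) involve non-positive measurements; the multiplicative precision geometry assumes positive values
0 pair(s) excluded (sim.csv)
device  n_changes  uninterpretable  noninterchangeable  gray_zone  interchangeable  interpretable  tim_rate_pct           rate_category
    TM        300               61                 183         24               32            239          13.4 not_clinically_relevant
wrote tim_out/changes.csv, summary.csv, exclusions.csv
```

Of the 300 simulated changes, 61 fail the interpretability screen at
RC = 5% (their two reference readings are within measurement noise of each
other), leaving 239 interpretable changes of which 32 are interchangeable:
a trend interchangeability rate of 13.4%, far below the 75% floor of
clinical relevance — at this tight repeatability, almost no change measured
by the noisy test method is interchangeable with the reference.  The legacy
comparators paint a much rosier picture of the same data:

```sh
$ trendim compare sim.csv --rc 5 --no-first-exclusion
note: 9 change(s) involve non-positive measurements; the multiplicative precision geometry assumes positive values
device  concordance_pct  polar_bias_deg  polar_radial_loa_deg  tim_rate_pct           rate_category
    TM             81.0            3.13                 66.63          13.4 not_clinically_relevant
```

The concordance rate (81%) and the polar angular bias (3.1°, within the
customary ±5°) both look acceptable while the radial limits of agreement
(±66.6°, against ±30°) and the interchangeability rate reveal the
disagreement in magnitude.  `trendim plot … --out figs` writes the
color-coded four-quadrant and polar figures; the same functionality is
available as a library (`trendim.classify_series`, `trendim.summarize`,
`trendim.concordance_rate`, …).

Python equivalent of the classification step:

```python
import trendim

series = trendim.generate(trendim.SimulationDesign(seed=1))
table = trendim.classify_series(series, trendim.RepeatabilitySpec.from_percent(5))
summary = trendim.summarize(
    [trendim.Category(c) for c in table["category"]]
)
print(summary.tim_rate, summary.category_label)
```

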