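# Methods

## The problem

Validation studies of continuous monitors (the motivating case is cardiac
output measured by arterial pulse contour analysis against bolus
thermodilution) increasingly care less about agreement of single readings
and more about *trending*: when the reference method (RM) says the patient's
value moved, does the test method (TM) report a compatible movement?  The
two legacy answers — the four-quadrant concordance rate and the polar-plot
angular statistics — ignore the repeatability of the reference method, rely
on arbitrary central exclusion zones, and can bless changes whose magnitudes
disagree badly.  The trend interchangeability method (TIM) implemented here
classifies every individual change against the reference method's own
measurement noise and summarizes the result as a single rate.

## The classification model

The unit of analysis is a **change**: two consecutive paired measurements
(RM1, TM1) → (RM2, TM2) within one subject-device series.  One parameter
enters: the reference method's repeatability coefficient RC, a
dimensionless fraction, so that a single reference reading `v` is trusted
to `v ± v·RC` (its *precision interval*).

**Step 1 — interpretability.** A change is interpretable only when the
precision intervals of RM1 and RM2 are disjoint; otherwise the apparent
change is indistinguishable from repeat-measurement noise and the change is
**uninterpretable** (plotted blue).  Test readings are never consulted in
this step.  Intervals that touch at exactly one point are treated as
overlapping: a measure-zero separation is no evidence of change.

**Step 2 — interchangeability.** An interpretable change is assessed in the
plane of the second pair, with Y the test-method coordinate and X the
reference-method coordinate.  Two lines anchored at the first pair bound
the zone of second pairs consistent with the first:

    X = Y·(1+RC) + (1+RC)·(RM1 − TM1)
    X = Y·(1−RC) + (1+RC)·(RM1 − TM1)

If RM2 lies between the two line evaluations at Y = TM2 (closed region,
points on a line included) the change is **interchangeable** (green).  If
not, but the precision interval of RM2 — taken as a segment along the
reference axis at fixed Y = TM2 — still intersects the closed zone, the
change sits in the **gray zone** (orange).  Otherwise it is
**noninterchangeable** (red).

The headline statistic is the **trend interchangeability rate**:
interchangeable changes divided by interpretable changes (total minus
uninterpretable).  Gray-zone changes count in the denominator but not the
numerator.  With no interpretable change the rate is undefined (reported as
such, never as 0).  Rates are labeled excellent (≥95%), good (≥90%), poor
(75–90%) or not clinically relevant (<75%).  Rates across devices are
compared with a Pearson chi-square test (no continuity correction) on the
devices × {interchangeable, interpretable-but-not} table.

### Conventions where the method leaves room

These points are genuine design choices of this package; the classification
they produce is exercised against an independent brute-force classifier in
the test suite.

- **Axis convention.** X is the reference coordinate and Y the test
  coordinate of the *second* pair.  This is the only reading under which a
  test method that copies the reference exactly classifies every
  interpretable change as interchangeable (the identity oracle, a property
  test).
- **Asymmetric intercept.** The lower line carries slope (1−RC) but the
  same intercept factor (1+RC)·(RM1−TM1) as the upper line.  That is the
  published form and it is the default; `symmetric_intercepts=True`
  switches the lower intercept to (1−RC)·(RM1−TM1) for users who regard
  the asymmetry as a typographical artifact.  One behavioral consequence of
  the default: a constant *positive* level shift of the test method cancels
  out of the geometry entirely (trends are identical, so every
  interpretable change is interchangeable), while a large constant
  *negative* shift pushes the zone away and drives the rate toward zero.
- **Gray-zone interval attachment.** The precision interval consulted in
  step 2 is that of RM2, because repeatability is a property of the
  reference method; attaching it to the test coordinate instead is
  conceivable but not implemented.
- **Boundary ties.** All boundary comparisons use a relative tolerance of
  1e−9, far below any physiological resolution.  Ties resolve
  conservatively: touching precision intervals → uninterpretable; a point
  exactly on a line → inside (interchangeable); a precision interval
  touching the zone → gray.
- **Non-positive readings.** The precision half-width uses |value| so the
  interval is always well ordered, and a `NonPositiveMeasurementWarning` is
  emitted: the multiplicative geometry is motivated by strictly positive
  quantities and degenerates near zero.

## Legacy comparators

- **Four-quadrant concordance**: fraction of changes with
  ΔRM·ΔTM > 0 after removing a central exclusion zone.  No zone is applied
  unless the user opts in, since published choices are arbitrary.  The zone
  is a square of half-width given either in units or as a percentage of the
  mean change magnitude max(|ΔRM|,|ΔTM|) of the dataset (the percentage
  form is scale-invariant).  Changes exactly on an axis count as
  discordant.
- **Polar statistics**: each change becomes a vector; its angle from the
  identity line is atan2(ΔTM, ΔRM) − 45°.  By default vectors in the
  lower-left half-plane are folded through the origin onto their mirror
  image, so a concordant decrease (−d, −d) reads 0° like the concordant
  increase — the fold is what keeps bias and limits of agreement
  interpretable for decreasing trends; `fold_half_plane=False` gives the
  unfolded convention.  Angular bias is the arithmetic mean of the angles
  and the radial limits of agreement are 1.96·SD; plain rather than
  circular statistics are used because trending angles of interest cluster
  near 0°, which is what the customary ±5°/±30° thresholds presuppose.
  Points with radius below an opt-in exclusion radius (customarily
  0.5 L/min for cardiac output) are removed first.

## Synthetic data generator

`SimulationDesign` emulates a simulated validation cohort: 150 patients,
3 paired values (2 changes) each, patients assigned wholly to one of three
ranges centered at 2.5, 3.5 and 5 units (50 patients per range, hence 100
changes per range and 300 changes in total).  Within a range each (rm, tm)
pair is an independent draw from a bivariate normal with mean at the
center.  The per-range covariances are a reconstruction, chosen once:
reference SDs 1.3, 1.1, 0.9 units for the low/middle/high range (variance
*decreasing* as the center grows), test-method SD 15% larger, correlation
0.8.  These values make the pooled readings span roughly 0–8 units with a
pooled mean near 3.67 — the grand mean of the three centers — while leaving
room for occasional negative test readings, the features a simulated
cardiac-output-like cohort should show.

What the generator does *not* emulate: within-patient serial correlation
(the three values are independent draws, so there is no autocorrelated
drift), calibration drift over time, device-specific error structure, or
truncation at physical zero.  Passing tests on this generator therefore
demonstrate the correctness and the qualitative behavior of the
classification machinery — e.g. that raising RC from 5% to 20% screens out
more changes while rejecting fewer of the survivors — not the exact
category counts any particular real or published dataset would give.

`generate_biased` builds controlled scenarios on top of a design's
reference trajectories: `tm = rm + bias + N(0, noise_sd)`.  With zero bias
and noise it is the identity scenario used by the oracle property test.

## Input handling

Long-format delimited text (CSV by default, header required, configurable
column mapping) with one row per subject/device/time.  The reader applies
the study exclusion rules: the first pair of every subject-device series is
dropped by default (it is conventionally consumed calibrating the test
device), pairs with a missing member are dropped, and every exclusion is
logged with its reason.  Excluded pairs leave a gap in the within-series
rank, and changes are only ever formed between rank-adjacent pairs, so no
change bridges a gap.  Each device's series is classified independently
against the shared reference column.

## Numerical and degenerate cases

- Undefined rates (empty input, all changes uninterpretable, everything
  excluded) are reported as undefined/None with a warning — never coerced
  to 0.
- Devices with zero interpretable changes are excluded from the chi-square
  comparison with a warning; fewer than two usable devices is an error.
- The zero change vector has no polar representation and is excluded with
  a warning wherever polar coordinates are needed.
- A degenerate (all-zero) simulation covariance is accepted and yields
  identical repeated values, every change uninterpretable — a useful
  end-member for tests.

## Problem sizes

The default analyses operate on the 300-change simulated design and
complete in well under a minute; the brute-force cross-validation of the
classifier uses 10,000 random quadruples per repeatability setting, sizes
chosen to make Monte-Carlo noise negligible for the properties asserted.

## Known limitations

- RC is a single fixed coefficient: repeatability is assumed constant over
  time and across the measurement range.
- The qualitative rate labels (excellent/good/poor/not clinically relevant)
  are conventional cut-offs, not derived quantities.
- No confidence interval is attached to the trend interchangeability rate.
- Uninterpretable changes are simply screened out; no overlap-weighted
  reinterpretation of them is attempted.
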