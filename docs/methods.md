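# Methods

## Scope and model

`accelee` turns raw tri-axial acceleration from body-worn inertial sensors
into activity counts, count-based MET estimates, and between-device /
between-placement reliability statistics. The quantities of interest are
per-bout: one 2-min treadmill bout at a fixed belt speed yields one epoch
summary (counts/min on a designated vertical axis, counts/min on the vector
magnitude, counts/10 s on the vertical axis) and ten MET values (five
published equations, each plain and RMR-corrected). Reliability is then a
property of *pairs* of such measurements of the same bout.

## Activity counts

The count algorithm is the published open replication of the ActiGraph
counts chain (Brønd et al. 2017; the same constants ship in the R
`activityCounts` library). Per axis:

1. **Resampling.** Linear interpolation onto a uniform 30 Hz grid anchored
   at the first timestamp. Input already uniformly sampled at 30 Hz passes
   through bit-exact. Linear interpolation is deterministic and adequate for
   the ≤ 100 Hz rates of wearable loggers; it slightly attenuates content
   near Nyquist, which the band-pass filter discards anyway.
2. **Band-pass filter.** The published 21-coefficient IIR filter (≈ 0.29–1.63
   Hz passband, peak gain ≈ 0.96 near 0.8 Hz) with the 0.965 input gain. The
   filter state is initialised to the steady state for the first sample
   (`lfilter_zi · x₀`), so a constant gravity-only trace produces its
   steady-state response from sample one instead of a power-on step
   transient. The filter's residual DC gain (≈ 0.044) times 1 g sits well
   below the dead-band, so constant input yields exactly zero counts.
3. **Decimation** to 10 Hz by keeping every third filtered sample.
4. **Clip** at ±2.13 g, **rectify**, zero everything below the **0.068 g
   dead-band**, quantize by flooring in **0.0164 g** steps.
5. **Sum** 10 consecutive samples → integer counts per second. Partial
   trailing seconds are discarded (counts are defined on complete 1-s
   windows; the reference implementation instead keeps a padded final
   window, which never differs on whole-minute bouts).

A per-second count is bounded by ⌊2.13/0.0164⌋ · 10 = 1290, so saturated
input cannot overflow. The vector magnitude is computed on per-second counts
(not raw samples), matching the pipeline ordering in which counts are the
primitive unit. Epoch averages generalise the study's ÷2 (counts/min over a
2-min bout) and ÷12 (counts/10 s) to arbitrary bout lengths:
`sum/bout_min` and `sum/(6·bout_min)`, which keeps the exact invariant
`per_min = 6 × per_10s`.

The tests verify the vectorized implementation element-wise against a
straight-line scalar transcription of the same published algorithm (hand
difference equation, no scipy), with frozen regression values for a standard
2 Hz / 0.5 g / 2-min sinusoid (steady-state 94 counts/s, 11 273 total).

## MET equations

All coefficients are used exactly as published; gender enters the
Santos-Lozano equations as the raw 1 = female / 2 = male code, not a 0/1
dummy. Two readings required a decision:

- **Crouter 2010** is implemented as `2.294275 · exp(8.4679e−5 · AC_VT′)`.
  The source table's typesetting (`exp(8.4679e−5)×AC′`) read literally is a
  straight line through the origin — zero METs at rest — which is not a MET
  model; the exponential-in-counts form matches the cited equation family.
  The rate constant is kept as printed even though it is smaller in
  magnitude than the original publication's; only the printed walking/running
  branch is implemented (no two-regression lifestyle branching).
- **The corrected-MET factor** is implemented as
  `METs × 3.5 / RMR` with `RMR = HB · 1000 / (1440 · 5 · BM)`
  mL O₂·kg⁻¹·min⁻¹ — the standard Compendium-style individual correction and
  the only dimensionally coherent arrangement of the constants 3.5, 1000,
  1440, 5 and body mass around the Harris–Benedict kcal/day prediction
  (÷1440 min/day, ÷5 kcal per litre O₂, ×1000 mL/L, ÷BM).

Heights are stored in metres and converted to cm inside Harris–Benedict;
`read_participants(..., height_unit="cm")` serves data already in cm.
Intensity bins are half-open — [0,1.5) light, [1.5,3) moderate, [3,6)
vigorous — with exactly 6.0 classified very vigorous (the published category
edges "<6" and ">6" leave 6.0 unassigned; assigning upward keeps the bins a
partition). Equation functions accept `validate=False` solely so intercepts
can be checked at degenerate inputs (zero mass/height/age); normal use
validates.

The linear equations can return slightly negative METs at very low counts
for heavy participants; values are propagated as computed (the correction is
multiplicative) and clamped at zero only for intensity classification.

## Reliability statistics

`icc_two_way_mixed` computes, from the subjects × raters ANOVA mean squares,
the consistency-type two-way mixed ICC: single-measure
ICC(3,1) = (MS_S − MS_E)/(MS_S + (k−1)·MS_E) and average-measure
ICC(3,k) = (MS_S − MS_E)/MS_S, where MS_E is the interaction mean square
(rater main effects removed — systematic device offsets do not count against
consistency). Negative estimates are legitimate and returned as computed;
zero total variance raises a degenerate-input error rather than returning a
conventional value. `cronbach_alpha_standardized` is k·r̄/(1+(k−1)·r̄) with
r̄ the mean pairwise Pearson correlation (the "standardized items"
convention). For k = 2 exchangeable raters, α_std and ICC(3,k) agree, which
the tests check by simulation. The implementation is cross-checked against
pingouin's ICC(C,1)/ICC(C,k) in the test suite; pingouin is never used in
the computation path.

`agreement_table` pairs records by (participant, configuration, speed) cell
and emits one row per speed plus an arithmetic MEAN row, one ICC column per
equation (single-measure by default, `icc_form="average"` optional), and a
per-speed α_std column. Because the source tables print a *single* alpha per
speed against ten equation columns, the per-speed alpha here pools
equations: each equation's paired columns are z-scored and stacked before
computing alpha over the two raters — a package choice, documented rather
than asserted to match any published cell. Cells with an unmatched or
ambiguous rater are dropped listwise and listed in a skipped-records report.
In the default design the device contrast at a given placement has n = 5
pairs per speed (the low-cost sensor visits each site in only one of the two
wearing configurations) while the placement contrast pools both
configurations, n = 10.

No confidence intervals or p-values are emitted by default.

## Synthetic study generator

`simulate_study` reproduces the reference design: 5 participants × 3 sensors
(wrist ActiGraph, thigh ActiGraph, low-cost sensor co-located wrist-then-
thigh across the two configurations) × 2 configurations × 10 speeds
(1.4–10 km/h) × 2-min bouts at 30 Hz = 300 records, 600 min. Record IDs
follow `t{participant}{configuration}{sensor}{speed-index}` with the first
sensor's digit elided; IDs are opaque downstream.

A bout is gravity (1 g on the z axis) + a harmonic series at the gait
fundamental (3 harmonics, amplitude halving per overtone, per-axis ratios
x:y:z = 0.4:1.0:0.6 with y the limb's long axis) + white motion noise
(sd 0.02 g) + white device noise. Defaults, chosen once as plausible
study conditions:

- **Stride rate** linear in speed from 1.0 Hz at 1.4 km/h to 1.8 Hz at
  10 km/h. The cap keeps the fundamental inside the count filter's high-gain
  region; with a 2.5 Hz cap the filter's rolloff (gain 0.36 at 2.5 Hz versus
  0.68 at 1.63 Hz) makes total counts non-monotone over the top speeds,
  contradicting the qualitative behaviour the simulator must emulate
  (more intense gait → more counts).
- **Dominant-axis amplitude** linear from 0.05 g to 1.2 g over the same
  range; wrist amplitude is 0.8 × thigh, which makes the placement contrast
  weaker than the device contrast, qualitatively echoing the reference
  findings. At 1.4 km/h the wrist signal sits near the count dead-band —
  realistic (slow strolling barely registers on wrist-worn ActiGraphs) but
  it means slowest-speed cells can have zero count variance and an undefined
  ICC, reported as NaN.
- **Device noise** sd 0.005 g (ActiGraph) / 0.01 g (low-cost sensor);
  **between-subject variation** as a lognormal amplitude multiplier with
  σ = 0.15.
- Sensors taped at the same site in the same bout share one motion
  realization (phases + motion noise) and differ only in device noise, so
  between-device ICC has the shared-signal structure of the real experiment.

Randomness is hierarchical: every stream is keyed by
(study seed, participant, configuration, placement, speed, [sensor]) through
`numpy.random.SeedSequence`, so record sets are byte-stable under design
edits and the whole study is deterministic given the seed.

What the generator does **not** emulate: biomechanically realistic waveforms
(impact transients, asymmetry, arm-swing phase relationships), non-wear or
attachment artefacts, device clock drift and dropped samples, and
population-specific count-to-MET calibration error. Passing tests therefore
demonstrate that the pipeline's algebra, filtering and statistics behave
correctly and reproducibly — not that any equation is accurate against
calorimetry, which the package deliberately does not claim.

## Numerical and interface choices

- Timestamps are elapsed seconds; absolute wall-clock, when present in an
  ISO-8601 time column, is retained as metadata only.
- CSV layout is explicit config (`CsvDialect`: column names, delimiter,
  elapsed vs ISO-8601 time); the default matches a comma-separated RAW
  export with a header line. Unparseable rows are errors, never silent
  drops. All writers emit RFC-4180 CSV (CRLF line endings, fixed float
  formats) so repeated runs are byte-identical.
- The vertical-axis choice per placement is mandatory config (default `y`
  for both wrist and thigh — the axis conventionally aligned with the limb's
  long axis); it is never inferred from data.
- The four-record default exclusion list ships as configuration
  (`DEFAULT_EXCLUDED_RECORDS`); excluding IDs absent from a manifest warns
  and continues, and exclusion is idempotent.
- The test suite and the acceptance script use the full 300-record design
  with 2-min bouts (the complete pipeline runs in under a second) except
  where statistical power dictates otherwise: variance-component recovery
  uses n = 200 simulated subjects with 30-s bouts, the device-noise
  monotonicity grid 3 × 200 bouts.

## Known limitations

- Only the printed walking/running Crouter branch is implemented.
- Counts use the standard filter only (no low-frequency-extension mode), and
  there is no step counting, wear-time or sleep detection.
- The reliability layer assumes exactly two raters per contrast; k > 2
  matrices are accepted by the statistics but not produced by the table
  builder.
- Binary vendor formats (.gt3x) and live Bluetooth ingestion are out of
  scope; input is CSV.
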