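# Methods

This note documents the models, numerical choices and limitations behind
`qamskit`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is asserted that the code
does not itself verify.

## The single-marker model

QAMS rests on one assumption: within the linear range of the detector,
each analyte's peak area is proportional to the amount injected,
`A = rf · W · V` with a per-analyte response factor `rf` (area units per
mg·mL⁻¹·µL at a fixed wavelength). Under that assumption the relative
correction factor

    f_k/m = (W_k · A_m) / (W_m · A_k)

reduces to `rf_m / rf_k` — a property of the analyte pair and detector,
not of the particular injection — which is why it can be established once
on mixed standards and then reused. The single-marker content formula

    W_m = (W_k · A_m) / (f_k/m · A_k)

is the exact algebraic inverse: if the RCFs are computed from the same
response data that defines the external-standard factors, QAMS and ESM
agree cell-for-cell to floating-point precision (asserted at 1e-10
relative in the tests). Real disagreement between the methods therefore
measures drift between the RCF-determination runs and the sample runs,
which is what the standard method difference

    SMD = (W_QAMS − W_ESM) / W_QAMS · 100 %

quantifies. SMD is signed per cell; summaries report |SMD| because the
accepted quality bound is a range on magnitudes. Cells where both
methods report zero (analyte absent) are defined as SMD 0; the marker
itself has no SMD because its QAMS value is by construction its ESM
value.

Peak location across instruments uses the relative retention time
`t_m/k = t_m / t_k`, which cancels any uniform rescaling of the time
axis. Assignment accepts a peak when its RRT is within a fractional
tolerance (default 3 %, the empirical cross-instrument reproducibility of
RRTs for this panel) of the analyte's expected RRT. Two candidates in
one window — or one peak claimed by two analytes — raise an error rather
than silently taking the nearest match: mis-assignment corrupts
quantification invisibly, so ambiguity is treated as a hard failure.
The marker peak itself must be identified absolutely; it is taken as the
largest-area peak inside a configured retention window (default ±1.5 min
around the nominal marker apex, wide enough to survive ±10 % retention
drift).

## The simulator

The generator emulates a 30-minute gradient separation of the
ten-flavonoid panel at 283 nm with 2 µL injections:

- **Peak shape.** Gaussian by default; exponentially modified Gaussian
  when an asymmetry constant (τ/σ) is set. Peak area is exactly
  `rf · concentration · injection volume`, so the manifest shipped with
  every trace is ground truth, not a fit.
- **Retention times.** Fixed placements spanning 5.8–25.2 min in the
  panel's elution order, with widths growing mildly along the gradient
  (σ = 0.04 + 0.002·rt min). These are conventional simulator settings,
  not measured values — no public retention-time table exists for this
  panel.
- **Response factors.** Chosen so the simulated detector's RCFs equal the
  panel's accepted reference values (naringin 1000, others scaled by
  their published mean f). This makes the simulator's downstream RCF
  estimates directly comparable to the reference table.
- **Noise model.** Additive white Gaussian noise (default SD 2, ~25×
  below the smallest default peak height) plus linear baseline drift
  (default 1 intensity unit/min) — the simplest models that exercise
  baseline correction and S/N-limited detection. No detector
  saturation, no wander/1-f noise, no co-elution beyond what the fixed
  layout produces.
- **Cohorts.** Per-sample contents are log-normal around class means with
  a 15 % coefficient of variation. Raw-material means put naringin at
  42 mg/g and neohesperidin at 48 mg/g (consistent with pharmacopoeial
  minima of 4 % and 3 %) with essentially no aglycones; the default
  fermentation effect depletes the seven glycosides (ratios 0.45–0.75)
  and strongly increases hesperidin-7-O-glucoside, naringenin and
  hesperetin. Passing an all-ones effect profile yields a null cohort
  for permutation checks.

What passing tests on simulated data do **not** show: robustness to
retention drift that is non-uniform in time, to overlapping peaks needing
deconvolution, or to matrix effects on response factors — none of which
the generator produces.

## Peak processing

- **Baseline.** Low-quantile (q = 0.1) anchor points are taken inside 30
  equal time windows and joined by linear interpolation (linear
  extrapolation at the ends). Under noise the q-quantile anchor sits
  systematically `Φ⁻¹(q)·σ` below the true baseline; σ is estimated
  robustly from first differences (MAD/√2) and the offset added back, so
  the correction is unbiased to first order and exact (to machine
  precision) on flat or linearly drifting noise-free traces.
- **Detection.** Local maxima via `scipy.signal.find_peaks` with three
  gates: height and prominence above 0.5 % of the global maximum
  (prominence removes noise bumps riding on peak flanks), a
  signal-to-noise floor of 5× the estimated noise SD, and a 0.1-min
  minimum separation. The relative thresholds make the detected count
  invariant under intensity scaling.
- **Integration.** Valley-to-valley: bounds at the minimum between
  neighbouring apices (midpoint of a flat valley), found on a lightly
  smoothed copy of the trace so that noise dips on a small peak's flank
  do not truncate its window; the area itself is the trapezoidal
  integral of the *unsmoothed* corrected trace with interpolated
  endpoints, which makes integration exactly additive over adjacent
  intervals. On noise-free simulated traces recovered areas match the
  manifest within 0.5 % and survive added linear drift within 1 %.
  Peaks near the detection limit remain biased low by a few percent
  (flank truncation) — an inherent property of valley-to-valley
  integration at low S/N, visible in the pipeline's SMD report for
  trace-level contents.

## Calibration and validation statistics

Ordinary least squares of area on concentration with a free intercept
(the conservative choice; proportionality is an assumption of QAMS, not
of ESM). `r` is the Pearson correlation of the fitted pairs;
LOD = 3.3·s/slope and LOQ = 10·s/slope with s the residual SD (n−2 df) —
the ICH convention. Contents below LOD are still reported, but flagged.
All RSDs use the sample (n−1) standard deviation, the analytical
convention; the reference RCF table's printed RSDs recompute only
approximately from its rounded 3-decimal f values, so tests assert the
means (which do recompute exactly for 8 of 10 analytes) rather than the
RSDs.

## OPLS-DA

Implemented from first principles for a single response: class labels are
coded ±1 and centered; the predictive weight vector is the unit-norm
`X'y` direction; each of `n_orthogonal` components (default 1, the
standard two-class choice) removes Y-uncorrelated systematic variation
via the orthogonalized loading `p − (w'p)w`; the predictive component is
then extracted from the filtered matrix. Because every orthogonal weight
is built orthogonal to `w`, orthogonal scores have exactly zero
covariance with the response (asserted < 1e-8). With `n_orthogonal = 0`
the model degenerates to single-component PLS1 — cross-checked against
scikit-learn in the tests, which is never used in the fit itself.
Default scaling is unit variance with mean centering (the convention of
the commercial package this model family is associated with);
center-only and Pareto are available, and constant columns are dropped
with a warning under variance scaling.

VIP is computed on the predictive component, `VIP_j = √(J·w_j²/Σw²)`, so
the squared scores average exactly 1 and the usual VIP > 1 marker rule
has its textbook meaning; a total variant folding in orthogonal
components (weighted by explained X variance) is available behind a
flag, since reports from commercial tools do not always state which is
shown. Marker selection uses strict inequality: a panel of exactly
exchangeable analytes (all VIP = 1.0) selects nothing. There is no
cross-validated choice of `n_orthogonal` in this version; a
label-permutation utility provides the null reference for the class
separation statistic instead.

## Reference tables and their precision limits

The packaged reference tables carry printed precision only: 3 decimals
for RCFs, 2 for contents. Two consequences are documented rather than
hidden:

- Two RCF rows (narirutin, hesperetin) have printed means that round the
  other way from the unrounded source data; tests exclude exactly those
  two rows and assert the remaining eight to 3 decimals.
- Recomputing SMD from two-decimal contents is unreliable for
  trace-level cells: a 0.01 mg/g printing step on a 0.17 mg/g content is
  ~6 % by itself. The recomputed maximum |SMD| over all 180 pairs is
  5.56 % (one such trace-level cell); the second largest is 2.67 %,
  inside the accepted 0–2.8 % range that was established on unrounded
  data. The toolkit reports the honestly recomputed value.

## Problem sizes and determinism

Default traces are 3001 points (100 points/min over 30 min); the
pipeline's default study is 6 calibration levels, 5 injection volumes and
a 5 + 20 cohort, which runs in well under a second. Every stochastic
stage takes an explicit seed (child seeds are spawned via
`numpy.random.SeedSequence`), and a pipeline rerun with the same
configuration is byte-identical across all CSV artifacts.
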