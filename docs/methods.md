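# Methods

## Problem and measurement model

`titracam` analyses complexometric EDTA titrations in which the endpoint is
read by a camera instead of the operator's eye.  A webcam photographs the
reaction beaker after every dose step of standard EDTA (0.025 mol/L by
default).  Because EDTA chelates Ca²⁺ 1:1, the cumulative titrant volume at
the indicator's color transition is proportional to the calcium amount in
the titrated aliquot:

    V_ep = V_blank + n_Ca / (c_EDTA · 1000)        [mL, µmol, mol/L]

`V_blank` collects the titrant consumed by the indicator and by calcium
intrinsic to the matrix (for 1 mL of milk in 100 mL of water it is on the
order of 1.2–1.35 mL).  Quantification inverts this relation either by
direct stoichiometry with an explicit blank, or through an ordinary
least-squares calibration line of `V_ep` against known spiked amounts whose
intercept absorbs the blank; the two routes are mutually exclusive so the
blank is never subtracted twice.  Contents are reported as
mg Ca / 100 mL (volume-based aliquots) or mg / 100 g (mass-based), using a
fixed molar mass of 40.078 g/mol.

## Color signals

Each frame is reduced to mean R, G, B over an operator-chosen rectangular
sampling region (means first, in floating point), and the mean triple is
converted to the HSI-model hue:

    θ = arccos( ((R−G)+(R−B)) / (2·√((R−G)² + (R−B)(G−B))) )
    Hue = θ if B ≤ G else 360° − θ

Hue depends only on channel differences, so it is exactly invariant to a
common multiplicative gain (lighting intensity) and to a common additive
offset (the achromatic "whitening" of turbid milk dispersions).  These two
invariances are asserted exactly in the test suite and are the reason Hue
is the recommended automatic-detection signal for both indicators.
Achromatic readings (R = G = B) carry an explicit marker instead of a hue,
never 0°, so "no hue" can never be confused with "red".  Per-pixel hues are
never averaged — circular means near the 0/360° wrap are ill-behaved.

Regions smaller than 8 × 8 pixels are permitted but flagged with a warning:
small areas are vulnerable to specular reflections and bubbles.  The flag is
applied uniformly to all channels for simplicity.

## Endpoint detection

The Hue series is unwrapped before any processing (steps > 180° between
consecutive points are treated as wraps; unwrapped values may leave
[0, 360°)), and achromatic points carry the last defined hue forward.

Two estimators are exposed:

* **sigmoid** (default): least-squares fit of the four-parameter logistic
  `A + (D−A)/(1+exp(−k(V−V₀)))`; the endpoint is the inflection `V₀` and the
  jump is `|D−A|`, so rising and falling transitions are handled
  identically.  The fit is increment-independent and averages noise itself,
  so no pre-smoothing is applied by default.  Bounds keep `V₀` inside the
  dosed range; a fit that fails or lands on the range edge falls back to
  `max_slope` (configurable).
* **max_slope**: the graphical first-derivative reading.  The signal is
  smoothed with a centered moving average (default window 7, shrinking
  symmetrically at the ends); the transition is localized at the first
  half-height crossing of the smoothed curve (plateau levels taken as the
  medians of the first and last five points); the steepest adjacent volume
  pair within one window of that crossing is refined to the slope-weighted
  centroid of the contiguous region where |dS/dV| stays above 30% of its
  peak.  The crossing-based localization stops single-pair noise spikes on
  a low-chroma plateau from hijacking the reading; the centroid reduces
  exactly to the classic pair midpoint when a single pair carries the whole
  jump.  Ties in the steepest pair break toward the smallest volume —
  under-titration is the conservative error.

A detection is rejected ("no transition detected") when the jump does not
exceed `noise_threshold` (default 5) times the pre-transition plateau SD;
this discards oscillating channels of the kind a weak indicator dose
produces.  Channel ranking scores every channel by jump/plateau-noise and
attaches the indicator prior — Green + Hue for calcein, Red + Hue for HNB —
as the recommended default.

Known bias: when the analytical signal is a nonlinear transform of the
underlying chemistry (Hue is a warped combination of three logistic
channels), its inflection does not coincide exactly with the stoichiometric
midpoint.  For the calcein color pair this offset is ≈0.012 mL — below one
0.02 mL dose increment, and absorbed into the calibration intercept, but
visible in worst-case single-run recovery at high noise.

## Synthetic runs

The simulator replaces the burette/beaker/camera loop.  Each RGB channel
follows a logistic transition between measured start and end beaker colors
with shared steepness `k` (default 40 /mL, i.e. a 10–90% width of ≈0.11 mL,
consistent with the step-like jumps of real curves; the true chemical
sharpness is not recoverable from bench data, so `k` is a free parameter).
When a transition-point color is known, a `4·s(1−s)` bump term bends the
path so it passes through that color exactly at `V*`; note this can make
channels with a small total span non-monotone, which is why detection on
minor channels of such profiles is not guaranteed.  Camera-order
post-processing: whitening blend toward (255, 255, 255) (affine, hence
hue-preserving), linear illumination gain drift, additive Gaussian sensor
noise from a seeded generator, clamping to [0, 255], and 8-bit rounding.
Rounding is applied last, matching camera output; it can be disabled
(`quantize=False`) for continuous-signal analyses such as the exact
stoichiometric-slope check.  Fixed seeds give bit-identical curves and
frame stacks.

Built-in profiles anchor the three bench conditions: calcein in milk
(206/223/89 → 205/168/114), HNB in water (117/33/114 → 13/31/130 through
76/29/118) and HNB in milk (193/132/164 → 104/152/178 through 143/136/154).
Default study conditions used throughout the tests: 0.02 mL increments,
0.025 M titrant, 1.25 mL blank, channel noise σ = 1 (routine) or σ = 2
(stress), calcium amounts 5–250 µmol, dosing to 1 mL past the endpoint.

What the simulator does **not** emulate: fluorescence vs. reflectance
optics beyond what the anchor colors encode, indicator-concentration
chemistry (only a jump-magnitude scale factor), bubbles/reflections inside
the sampling region, colored matrices, or operator variability in region
placement.  Passing tests therefore demonstrate correctness of the signal
processing chain under realistic noise, not robustness to every field
condition.

Rendered frames are flat color rectangles plus seeded per-pixel noise and
optional saturated speckle confined outside the recommended region of
interest; they exist to exercise the full image → curve → endpoint path.

## Validation statistics

Replicate sets are summarized as mean, sample SD (n−1), RSD (100·SD/mean)
and recovery (100·mean/nominal).  Pairwise comparisons use Welch's
unequal-variance two-sided t-test by default: replicate counts of 8–10 and
visibly unequal variances across method/signal combinations make the
pooled assumption unsafe; the pooled variant is available behind a flag.
Zero-variance degeneracies resolve by convention (equal constants → p = 1,
different constants → p = 0, flagged).  No multiple-testing correction is
applied across a comparison matrix; the count of significant pairs at
α = 0.05 is reported instead.  The implementation is cross-checked in the
tests against an independent incomplete-beta evaluation of the p-value and
calibrated against the nominal type-I rate under the null.

## Numerical choices

* Hue arccos argument is clipped to [−1, 1] before `acos`; the achromatic
  denominator test is `den² ≤ 0`.
* Logistic fits run `scipy.optimize.curve_fit` (TRF, tolerances 1e-14,
  `expit` for overflow safety); initial values come from the plateau means
  and the max-slope candidate.
* Steepest-pair selection compares slopes with a 1e-9 relative tolerance so
  that a rounded volume grid cannot silently break the earliest-volume
  tie-break.
* Calibration R² is the squared Pearson correlation, forced to exactly 1
  for collinear input to avoid reporting 0.999999999 for exact lines.
* Problem sizes in the test suite and acceptance script (6 calcium levels,
  3 seeds, 10,000 null pairs) were chosen as the smallest sets that
  exercise the full dosing range and give stable rates.

## Known limitations

* The endpoint detectors assume a single monotone transition; multi-analyte
  curves with two jumps report only the first.
* Sub-increment accuracy of `max_slope` degrades when the jump-to-noise
  ratio falls below ≈10; the sigmoid fit should be preferred there (it is
  the default).
* The simulator's Gaussian, channel-independent noise is idealized; real
  sensors show correlated, signal-dependent noise.
* Blank volumes must come from the operator or a calibration line; the
  package cannot infer them from a single run.
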