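# Methods

## The measurement problem

The light-adapted (photopic) flash electroretinogram (ERG) is the retina's
mass electrical response to a brief flash: a negative **a-wave** (cone
photoreceptor hyperpolarization, trough near 13–15 ms), a positive **b-wave**
(bipolar-cell depolarization, peak near 28–35 ms), and the **oscillatory
potentials** (OPs) — high-frequency (~80–160 Hz) wavelets riding on the
b-wave, attributed mainly to amacrine cells.  Conventional time-domain
measures (a-/b-wave amplitude and implicit time) collapse this structure to
two numbers.  A dyadic discrete wavelet transform (DWT) instead tiles
time–frequency space and lets energy be read off per frequency band *and*
per physiologic time window, separating ON-/OFF-pathway contributions
(nominal 20 and 40 Hz bands) from the slow and fast OPs (80 and 160 Hz
bands).

This package implements that analysis end to end for cohort comparisons:
a synthetic-cohort generator with controllable group effects, the Haar-DWT
descriptor extraction, and nonparametric multiple contrast tests producing a
comparison table (per-group medians with 95% CIs and adjusted p-values per
group pair, per flash strength and parameter).

## Analysis grid and transform

Epochs are analyzed on a fixed grid of 256 samples at 2048 Hz starting at
-20 ms (flash onset = 0 ms; 125 ms span).  A power-of-two length permits the
full dyadic decomposition, and 2048 Hz places the four nominal band centers
inside dyadic bands:

| detail level j | band (Hz) | nominal center | coefficients | segment width |
|---|---|---|---|---|
| 3 | 128–256 | 160 | 32 | 3.906 ms |
| 4 | 64–128  | 80  | 16 | 7.812 ms |
| 5 | 32–64   | 40  | 8  | 15.625 ms |
| 6 | 16–32   | 20  | 4  | 31.25 ms |

The transform is the orthonormal Haar DWT (PyWavelets, periodization mode),
so Parseval's identity and perfect reconstruction hold to machine precision;
both are asserted in the test suite at 1e-9 relative, and the coefficients
are verified against brute-force inner products with the explicit Haar basis
at 1e-12.  Sign convention: a detail coefficient is positive when the first
half of its support exceeds the second.

## Descriptors

Six descriptors summarize the scalogram, one per (band, physiologic window):
a20 [-20, 17.5] ms, a40 [0, 17.5] ms, b20 and b40 [17.5, 55] ms, op80 and
op160 [8.125, 55] ms.  A coefficient belongs to a window iff its segment
midpoint lies in the closed interval (ties are impossible on the dyadic
grid).  The a20 window deliberately begins before flash onset; it is adopted
as stated in the source methodology even though pre-stimulus energy is noise
by construction.

Three reductions over a window's coefficient magnitudes are available:

- **rss** (default): root sum of squares — the square root of the window's
  energy.  By Parseval this is phase-insensitive: shifting a burst's phase
  relative to the dyadic grid redistributes magnitude among coefficients but
  conserves their summed squares within the window.
- **max_abs**: the scalogram-maximum |coefficient| in the window.
- **sum_abs**: the sum of |coefficients|.

The field's descriptor definition is ambiguous — the values are called
"energy (μV·s)" without a formula.  We default to the energy reading (rss)
because the max-coefficient reading is measurably phase-fragile: for a
burst-like OP component, a ±1 ms shift of burst onset (well inside
biological variability) can halve or double the maximum coefficient in a
band, since it changes both the alignment of the burst with segment
boundaries and the sign of its interference with the a-/b-wave transient's
spectral leakage.  In simulation this fragility is large enough to mask a
20% group difference in OP amplitude at n = 50/group.  The units label
(μV·s-style "energy units") is kept for parity with the field's reporting;
no dimensional conversion is attempted.

**%OPs** = 100·(op80 + op160)/(b20 + b40 + op80 + op160), the OPs' share of
the summed b-wave + OP band energies; undefined (not an exception) when the
denominator is zero.  Note that published descriptor medians and published
%OPs values are not always mutually consistent under this formula; the
formula as stated is what is implemented, and the alternate descriptor modes
allow exploring the discrepancy.

Time-domain measures: baseline = mean of pre-stimulus samples; a-trough =
minimum in [5, 25] ms (configurable); a_amp = max(0, baseline - trough);
b-peak = maximum in (a-trough time, 60 ms]; b_amp = trough-to-peak (the
conventional clinical definition).

## Quality control and preprocessing

- Sweep averaging rejects sweeps whose peak-to-peak amplitude falls outside
  the [25th, 75th] percentile band of the sweep set (inclusive), i.e. the
  interquartile band: the only reading of a "25th centile" rejection rule
  that trims both high- and low-amplitude outliers.  Whether such a rule
  should operate per sweep or per time point is underdetermined; the
  per-sweep reading is our documented choice.  At least 4 sweeps required.
- Inclusion rules: measured a-wave amplitude must exceed 1 μV; recordings
  with the electrode more than 2 mm below the reference position are
  excluded (height = -2 mm is inclusive).  Missing electrode metadata never
  excludes.  QC is a pure per-recording predicate.
- Recordings off the analysis grid are linearly interpolated onto it; no
  extrapolation is permitted.

## Synthetic cohorts

The generator is a parametric stand-in for the photopic ERG, not a
biophysical model:

    x(t) = -a_amp·g(t; a_time, a_width) + b_amp·g(t; b_time, b_width)
           + op_amp·e^{-(t-op_onset)/op_decay}·sin(2π f_op (t-op_onset))·1[t ≥ op_onset]
           + ε(t),   ε ~ N(0, noise_sd²) white

with g a unit-peak Gaussian kernel.  Defaults (μV, ms): a_amp 12, a_time 14,
a_width 5, b_amp 30, b_time 32, b_width 8, op_amp 16, f_op 116 Hz, op_onset
16, op_decay 55, noise_sd 2 (representing post-averaging residual noise).
Two constraints fixed these choices:

1. **The a-trough must survive every group effect.**  The symmetric b-wave
   kernel bleeds backward into the a-wave window; if it swallows the trough,
   the a-wave > 1 μV inclusion rule starts culling participants on noise
   alone, which silently randomizes group membership downstream.  The
   defaults keep the modeled trough ≥ ~10 μV deep for all group multipliers
   in use.
2. **The OP burst must dominate its own bands.**  The Haar transform has
   poor frequency selectivity, so the steep a→b transient leaks energy into
   the 80–160 Hz bands.  The burst amplitude and slow envelope decay are set
   so the OP component is the dominant source of OP-band energy (as in
   recorded photopic ERGs, where the OPs are the principal high-frequency
   content), and so the burst's dyadic band-energy split stays stable under
   per-participant onset jitter.

Cohort structure: group sizes default to 55 ASD, 15 ADHD, 156 control; five
flash strengths (-0.119, 0.398, 0.602, 0.949, 1.204 log photopic cd·s·m⁻²)
with a saturating per-flash gain table (0.60, 0.85, 1.00, 1.05, 1.00) rather
than a luminance-response fit, since the analysis stratifies by flash; two
eyes per participant as independent-noise replicates of shared participant
parameters.  Per-participant biological variability: times (a, b, OP onset)
jittered N(0, 1 ms), amplitudes jittered log-normally (σ = 0.10), all drawn
from a participant-level seed spawned from the cohort seed so every artifact
is reproducible end to end.

Group effect presets (multiplicative on a_amp/b_amp/op_amp): control
(1, 1, 1); ADHD (1.2, 1.5, 1.4); ASD (1, 1, 0.8).  These are *directional
stand-ins* for the reported cohort pattern — ADHD elevated across b-wave
band and OP energies, ASD with reduced OPs at near-control b-wave energy —
not calibrated effect sizes, which the source reporting does not permit.

What the generator does **not** emulate: line interference and drift,
blink/movement artifacts, asymmetric (non-Gaussian) wave shapes, amplitude
dependence of implicit times, inter-eye correlation beyond shared
parameters, age/sex/iris-color covariate structure, and any luminance-
response nonlinearity beyond the gain table.  Passing tests therefore
demonstrate the *machinery* (transform, descriptors, inference) and the
*internal consistency* of the pipeline under known ground truth — not that
real cohorts would show these effect sizes.

## Statistical inference

For groups i, j the relative effect p(i,j) = P(X_i < X_j) + ½P(X_i = X_j)
is estimated by mid-rank placements (equal to exhaustive pair enumeration,
ties counted ½).  The Tukey-type (all-pairs) multiple contrast test:

- variance of each p̂(i,j) by the placement (Brunner–Munzel-type) plug-in
  estimator;
- covariance between contrasts sharing a group from the empirical
  covariance of the shared group's Hájek-projection components;
- test statistics T = (p̂ - ½)/SE on the probability scale, referred to a
  central multivariate t over the estimated contrast correlation matrix with
  Satterthwaite degrees of freedom (minimum over contrasts);
- adjusted p-values as 1 - P(max |T| ≤ |t_obs|); simultaneous CIs from the
  two-sided equicoordinate quantile.  With the Fisher option (default) the
  CIs are built on the logit scale and back-transformed, which keeps them in
  [0, 1]; the logit transformation is applied to interval construction only,
  because the logit-scale statistic with the delta-method SE at p̂ is
  noticeably conservative at moderate n (the package's own null calibration,
  `analysis/04_calibration_checks.py`, measures the familywise error of the
  implemented procedure near the nominal 5%).
- Boundary estimates (p̂ ∈ {0, 1}) are shrunk by a half-count before
  transformation; completely separated contrasts (zero plug-in variance)
  receive an SE floor of 1/√(4·n_i·n_j·(n_i+n_j)) so statistics stay finite.
- Degenerate input (all values identical) returns p̂ = ½, p = 1 with a flag.

Numerical choices: the multivariate-t box probabilities use quasi-Monte-
Carlo integration (scipy) with a fixed seed and a sample budget giving
integration noise well below 1e-4; the equicoordinate quantile is found by
bracketed root-finding (tolerance 5e-4).  Both are deterministic given the
seed.

The significance policy reports both the procedure's familywise-adjusted
p-values at α = 0.05 and the stringent p < 0.005 cut-off; the comparison
table carries the adjusted p-values so either rule can be applied.

Companions behind the same surface: tie-corrected Kruskal–Wallis and
Mann–Whitney (exact enumeration when n_a·n_b ≤ 400 and tie-free; U counts
pairs where the first sample exceeds the second), Pearson chi-square without
continuity correction, and the Wilcox percentage-bend correlation (bend
constant β ∈ (0, 0.5], default 0.2; p by t-approximation with n-2 df;
cross-checked in tests against an independent implementation).

Median CIs in the comparison table are distribution-free binomial
order-statistic intervals (coverage ≥ the nominal level; endpoints are
always observed values; conservative below n ≈ 6).

## Pipeline conventions

- Eyes are aggregated per participant by the mean of the two eyes' feature
  values (options: one eye only, or both eyes as units — the latter inflates
  n and is non-default).  No pooling rule is canonical in the field's
  reporting; the per-participant mean is our documented choice.
- QC-excluded recordings are dropped before aggregation and logged; a group
  emptied by QC raises an explicit error naming the group.
- All randomness (cohort generation, QMC integration) derives from the study
  seed; identical configuration + seed reproduces byte-identical artifacts.
- p-values below 1e-16 render as "<1e-16" in reports.

## Problem sizes used by the checks

The packaged verification uses: 300 random signals per length (8/16/32) for
the transform-vs-oracle identity and 1000 random 256-sample epochs for
Parseval/reconstruction; 2000 null replicates (3 groups × n = 20) for the
familywise-error calibration; and 100 seeded cohorts of 50/group (the
acceptance script uses 40) for effect-fingerprint recovery.  These sizes
give Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

- The Haar wavelet's frequency selectivity is poor; band labels are nominal
  and transient leakage across bands is inherent to the method (it is the
  method of the field, reproduced faithfully, not repaired).
- Descriptor values depend on the reduction mode; cross-study comparison of
  absolute "energy" values is only meaningful within one convention.
- The multiple-contrast procedure is asymptotic; below n ≈ 4 per group it
  warns, and its small-sample behavior is only validated at the simulated
  sizes.
- The synthetic generator's effect presets are directional, so recovery
  rates quantify sensitivity of the pipeline under the generator's
  assumptions only.
- No covariate adjustment (age, sex, iris color, electrode height beyond the
  exclusion rule), no mixed models, no classifier.
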