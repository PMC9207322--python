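# ergdwt — Haar-DWT descriptors and nonparametric contrasts for flash ERGs

`ergdwt` is an analysis pipeline for comparing groups of light-adapted flash
electroretinograms (ERGs) in the time–frequency domain.  It is aimed at
clinical electrophysiology and neurodevelopmental research settings where
the question is whether cohorts (e.g. autistic, ADHD and control
participants) differ in specific retinal signal components — the
ON-/OFF-pathway-dominated a- and b-waves and the amacrine-cell-driven
oscillatory potentials (OPs) — rather than only in overall amplitude.

## What it computes

Each epoch x(t) (256 samples at 2048 Hz from -20 ms, flash at 0 ms) is
decomposed with the orthonormal Haar DWT,

    d(j,k) = ⟨x, ψ_{j,k}⟩,   ψ_{j,k}(t) = 2^{-j/2} ψ(2^{-j} t - k),

into a dyadic scalogram whose levels bracket nominal band centers 20, 40,
80 and 160 Hz.  Six descriptors summarize band energy inside physiologic
windows — a20 [-20, 17.5] ms, a40 [0, 17.5] ms, b20/b40 [17.5, 55] ms,
op80/op160 [8.125, 55] ms — plus

    %OPs = 100·(op80 + op160)/(b20 + b40 + op80 + op160)

and the time-domain b-wave amplitude (trough-to-peak).  Groups are compared
per flash strength with Tukey-type nonparametric multiple contrast tests of
relative effects p(i,j) = P(X_i < X_j) + ½P(X_i = X_j): placement
(Brunner–Munzel-type) variances, simultaneous CIs and adjusted p-values from
the equicoordinate quantile of a multivariate t over the estimated contrast
correlation, logit-scale (Fisher) interval construction.  A built-in
synthetic-cohort generator with documented per-group effect multipliers
makes the whole pipeline testable without any recorded data.

Modules: `waveform_io` (long-CSV epochs), `simulate` (cohort generator),
`preprocess` (sweep averaging with interquartile rejection, inclusion rules,
resampling), `features` (DWT, scalogram, descriptors, time-domain measures),
`stats` (contrast tests, rank tests, chi-square, percentage-bend
correlation), `pipeline` (orchestration + comparison table), `cli`.

## Worked example

Run the numbered analysis drivers (or the equivalent `erg-dwt` CLI
commands):

```sh
python analysis/01_simulate_cohort.py     # 226 participants -> results/waveforms.csv
python analysis/02_extract_features.py    # descriptors + QC   -> results/features.tsv
python analysis/03_compare_groups.py      # contrasts          -> results/results.tsv, results.md
python analysis/04_calibration_checks.py  # null + recovery    -> results/calibration.json
```

The third step prints the comparison table (markdown in
`results/results.md`); at the top flash strength (1.204 log photopic
cd·s·m⁻², groups ordered ADHD / ASD / control, medians with
distribution-free 95% CIs, then adjusted p for A·v·a, A·v·c, a·v·c):

```
| 1.204 | b40   | 67.6 (55.2–73.6)    | 48.7 (46.6–53.2) | 49.6 (48.7–51.1) | 1.69e-05 | 7.7e-06  | 0.989    |
| 1.204 | op160 | 67.8 (60.5–75.5)    | 41.4 (38.1–43.1) | 47.6 (46.2–48.4) | <1e-16   | 1.95e-08 | 3.08e-06 |
| 1.204 | b20   | 111.0 (103.5–125.7) | 84.9 (82.6–90.1) | 81.0 (78.3–83.3) | 7.1e-13  | <1e-16   | 0.159    |
```

Reading: the simulated ADHD group is elevated over control on the b-wave
band energies (b40: 67.6 vs 49.6 energy units, adjusted p = 7.7e-06), the
simulated ASD group is reduced versus control on the fast-OP energy (op160:
41.4 vs 47.6, p = 3.08e-06) while indistinguishable from control on b20
(p = 0.159) — the built-in effect pattern, recovered through the full
transform-and-contrast machinery.  The same step prints this fingerprint
check explicitly (15 PASS lines at p < 0.005).  The calibration step
reported a familywise error of 0.057 over 1000 null replicates (nominal
0.05) and fingerprint recovery in 37/40 cohorts.

## Data formats

Waveforms: long CSV, one sample per row, header
`participant,group,eye,flash,repeat,time_ms,microvolts`, flash in log
photopic cd·s·m⁻², time in ms (onset 0), amplitude in μV.  Feature/QC/result
tables: TSV.  Configuration: JSON validated against `pipeline.StudyConfig`
(unknown keys rejected).
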