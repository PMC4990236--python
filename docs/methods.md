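# Methods

## Spectral analysis

A VF record is a uniformly sampled single-channel voltage trace in mV with
sampling rate `fs` and a start time `t0` relative to VF onset. Analysis
frames of `window_s` = 2.1 s are advanced every `step_s` = 0.5 s; frame k
covers `[t0 + k*step_s, t0 + k*step_s + window_s)` and is stamped at its
center. A record shorter than one window is an error, not an empty result.

Each frame is mean-removed (default on; this keeps DC from leaking into the
2 Hz band edge), multiplied by a periodic Tukey taper with taper fraction
`tukey_alpha` = 0.5, and transformed with an N = `round(window_s*fs)` point
DFT with **no zero padding**, so the bin width is `fs/N` (0.476 Hz at
250 Hz). One-sided amplitudes are normalised by the taper's coherent gain
Σw — `A_i = (2/Σw)|X_i|` for interior bins, `(1/Σw)|X_i|` at DC and
Nyquist — so an in-bin unit sinusoid under a rectangular taper reads 1 mV.

AMSA is `Σ A_i F_i` over `band_lo ≤ F_i ≤ band_hi`, both edges inclusive
(the bound "2 to 48 Hz" is read inclusively; with a 2.1-s window the bins
rarely fall exactly on an edge, so the choice is numerically minor). Because
AMSA is a summed rather than integrated spectrum, its absolute magnitude
depends on the bin width and hence on `window_s` and `fs`; comparisons
should keep the spectral configuration fixed. The taper fraction likewise
scales absolute values (via Σw and leakage); 0.5 is the package default and
is recorded in every run manifest. Absolute comparability with values from
proprietary defibrillator pipelines is therefore approximate; *relative*
time-course structure is robust to these conventions.

Per-frame AMSA values are averaged in half-open one-minute bins
`[(m-1)·60, m·60)` anchored at VF onset, minute index 1-based. Only minutes
fully covered by the record get a mean; an incomplete trailing minute is
reported separately and never pooled. A minute whose frames are all flagged
invalid yields a missing (NaN) mean.

### Artifact flagging

Pulsatile interference (pump or compression artifact) concentrates spectral
amplitude below the 2 Hz band edge. A frame is marked invalid when the
sub-band amplitude fraction `Σ A_i [F_i < band_lo] / Σ A_i` exceeds 0.5,
i.e. when sub-band content dominates the spectrum. An all-zero frame has
ratio 0 and stays valid. This is a deliberately simple, transparent rule:
it is not a validated artifact detector for clinical recordings, but it
reliably separates the sub-band pulse trains the generator produces from
in-band VF content, which is what the in-silico experiments require.

## Synthetic VF cohorts

The generator's purpose is controllability, not electrophysiological
realism: a record is Gaussian white noise band-pass filtered (4th-order
Butterworth, zero-phase) to `center_freq ± bandwidth/2` = 6–12 Hz, where VF
spectral content concentrates, multiplied by an envelope that interpolates
the target AMSA linearly between per-minute knots (knots placed at minute
centers; flat extrapolation beyond the first/last knot). Because AMSA is
exactly linear in signal amplitude, one gain calibration transfers to the
whole record: the uncalibrated signal's minute-mean AMSA at the first
knot's minute is measured with the very pipeline used for analysis and the
signal scaled so that minute hits its target. The closed loop makes the
generator robust to any of the windowing/normalisation conventions above.
The true within-subject trajectory *between* the knot minutes is unknown;
linear interpolation is a stated modelling assumption.

Cohorts add a persistent multiplicative offset per subject,
`s_j = exp(ε_j)`, `ε_j ~ N(0, subject_sigma²)` with `subject_sigma` = 0.25
by default — multiplicative and lognormal because AMSA is
amplitude-proportional and strictly positive. The offsets are drawn once
per subject from the cohort seed's stream and applied to the entire
recording, which is what makes early AMSA predictive of late AMSA across
subjects (observed anchor correlations ≈ 0.97–0.99 at n = 16). With
`subject_sigma` 0.25 the simulated minute-1 spread (≈ 6.6–16.4 mV·Hz at
n = 16, seed 0) brackets the kind of between-animal range seen in practice.
All outputs are pure functions of (profile, spec, n_subjects): the master
seed yields the offsets and per-subject child seeds for the noise.

The optional ECC artifact is a Hann-shaped unipolar pulse train at a
sub-band rate (< 2 Hz) with 80% duty cycle, peak amplitude
`relative_amplitude` × record RMS, added from an onset time to the end of
the record. The wide duty cycle concentrates pulse energy at the pulse rate
and its first harmonic, i.e. below the band edge, matching the phenomenon
the flagging rule is meant to catch; at 10× RMS essentially all post-onset
frames are invalidated.

What the generator does *not* emulate: ECG morphology, restitution or
spiral-wave dynamics, non-stationary spectral drift within a minute,
electrode noise, or any coupling between AMSA and the physiological panel.
Passing the in-silico experiments therefore demonstrates correctness of the
measurement and statistics chain under known ground truth — not performance
on real animal or clinical recordings.

## Physiological derivations

All derivations are elementwise per (subject, timepoint): coronary
perfusion pressure `CPP = MAP − RAP` (mmHg, may be negative and is reported
as-is); Fick oxygen metrics `MDO₂ = flow·CaO₂`, `MVO₂ = flow·(CaO₂−CvO₂)`,
extraction `(CaO₂−CvO₂)/CaO₂`; lactate flux `flow·(lac_a − lac_v)` with
consumption positive and production negative; veno-arterial PCO₂ gradient
`PvCO₂ − PaCO₂`. Flow is never converted to absolute ml/min: when it is
expressed as percent of baseline, the Fick products are meaningful only
relative to their own baseline, and the module normalises the joint product
(flow × content) to its baseline value rather than flow alone. Sign
conventions are attached to outputs because they are otherwise easy to flip.

## Statistics

The container is a wide subjects × timepoints table. Descriptives report
mean, SD (n−1), SEM = SD/√n per timepoint. The one-way repeated-measures
ANOVA uses the classical within-subject decomposition — SS_time (df k−1)
against SS_error = SS_within − SS_time (df (n−1)(k−1)) — with no sphericity
correction by default, matching the desktop-statistics convention this
analysis style follows; a Greenhouse–Geisser epsilon and corrected p are
available on request. Missing data: listwise deletion for the ANOVA
(excluded subjects reported), pairwise for correlations. Degenerate inputs
are resolved explicitly: zero time variance gives F = 0, p = 1; zero
residual variance with nonzero time variance gives F = ∞, p = 0 flagged
degenerate (sums of squares are compared against a 1e-12 relative
tolerance of the total SS).

Holm–Šidák: the i-th smallest of m p-values is tested at
`1 − (1−α)^(1/(m−i+1))`; the step-down stops at the first failure; adjusted
p-values are `1 − (1−p)^(m−i+1)`, made monotone and capped at 1. Families
follow the all-vs-baseline and all-vs-reference-timepoint pattern, with
significance reported at the 0.05 and 0.001 tiers. All tests are two-sided;
Pearson p-values come from `t = r√((n−2)/(1−r²))` on n−2 df, and the
simple linear regression is ordinary least squares with the slope tested
the same way. A constant response in the regression returns slope 0, r = 0
rather than an error (the fit is exact); a constant predictor is an error.

## Problem sizes and numerical choices

The canonical in-silico configuration is fs = 250 Hz, 22-minute records,
cohorts of 8 (profile recovery) and 16 (variability experiments); the null
calibration of the ANOVA uses 2 000 replicates of 16 × 4 tables, and the
null correlation experiment 100 seeded cohorts. These sizes give stable
estimates (minute means average ~120 frames; cohort means average 8–16
subjects) while keeping every experiment in the seconds-to-a-minute range.
The spectral pipeline computes all frames in one vectorised batch; a test
asserts bit-level agreement with the documented frame-by-frame path.
Frame-count and minute-bin arithmetic uses a 1e-9 guard against float
jitter in duration ratios. The profile-recovery tolerance of 10% relative
per knot reflects generator noise at these sizes (observed ≲ 6%), not a
claim about the spectral arithmetic, which matches a brute-force DFT oracle
to ~1e-13 relative.

## Known limitations

- The generator's calibration pins each record's first-knot minute to its
  target, so with `subject_sigma = 0` the anchor minute's between-subject
  variance is residual; null anchor correlations are then ordinary n = 16
  Pearson nulls (|r| < 0.6 in ~98–99% of draws), not exactly zero.
- Artifact flagging is a spectral-ratio heuristic; it does not detect
  in-band artifacts (e.g. electrode pop at 10 Hz).
- The physiology stage treats blood O₂ contents and lactate as inputs; it
  does not compute contents from Hb/SO₂/PO₂.
- Waveform I/O is CSV-based; no binary physiological-record formats are
  read.
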