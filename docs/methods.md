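# Methods

`gaitinit` implements, validates and exercises a single lower-back
accelerometer method for timing gait initiation (GI). This note documents
the detection rules, the statistics, the synthetic-data model behind the
test suite, and the numerical choices that were genuinely open.

## The measurement problem

Cued gait initiation — standing still, hearing "go", taking the first
step — decomposes into three phases bounded by three instants:

* **APA onset**: the anticipatory postural adjustment begins; the centre of
  pressure (CoP) moves posteriorly and toward the swing leg to throw the
  centre of mass forward over the stance leg. Stimulus → onset is the
  *motor planning* phase (time-to-APA).
* **Swing-leg toe-off**: the APA ends and the first step begins
  (APA duration = onset → toe-off).
* **Swing-leg heel-strike**: the first step lands
  (swing duration = toe-off → heel-strike).

The laboratory reference measures these with force platforms (CoP and
vertical ground-reaction force at 1000 Hz) plus an optoelectronic marker on
the swing-side malleolus. The method under test replaces all of that with
one triaxial accelerometer at L5 sampled at 140 Hz.

## Gold-standard rules (`forceplate_events`)

All rules operate on CoP low-pass filtered at 10 Hz (4th-order Butterworth,
zero-phase) under the convention AP positive anterior, ML positive toward
the stance limb:

1. **APA onset** — first frame at/after the stimulus in which both CoP
   velocity components are negative. A debounce count (default 1 frame,
   the literal rule) is configurable because measured CoP velocity is
   noisy.
2. **Stance-leg toe-off** — last frame with vertical GRF at/above an
   unloading threshold (default 10 N; platforms never read exactly zero).
3. **Swing-leg toe-off** — the frame between (1) and (2) at which the CoP
   is farthest (perpendicular distance) from the line joining its positions
   at (1) and (2). Ties break to the earliest frame; if the two endpoints
   coincide the rule degrades to point distance.
4. **Swing-leg heel-strike** — first downward zero crossing of the marker
   AP velocity after its swing-phase maximum, sub-sample interpolated.
   Starting the search at the velocity peak avoids triggering on pre-swing
   stillness. The velocity comes from central differences on the raw
   marker trace: optoelectronic data are already low-noise and zero-phase
   smoothing measurably biases the crossing (about −1.5 ms on the
   synthetic templates), so no pre-filter is applied by default.

## Single-accelerometer algorithm (`imu_events`)

The acceleration is conditioned with a 0.2–4.5 Hz 4th-order Butterworth
band-pass. The filter is applied forward and backward: causal filtering
would delay every detected instant by the group delay, and timing validity
is the whole point of the method. Quoted cut-offs are design cut-offs of
the single-pass prototype.

**APA onset** (per axis, then the earliest over AP/ML/V):

1. *Change point.* Inside a window from 0.5 s before to 1.2 s after the
   stimulus, the sample minimising SSE(left) + SSE(right) of two
   independent straight-line fits — a change of both mean and slope. Split
   candidates leave at least 3 samples per side; numerical ties break to
   the earliest split. A mean-only variant is available (`model="mean"`)
   for sensitivity analysis.
2. *Backward search.* From the change point, walk backwards (at most the
   stimulus-to-change span) to the first sample strictly lower than both
   neighbours. If no interior minimum exists the axis is flagged and
   excluded from the cross-axis minimum; if every axis is flagged,
   detection fails rather than returning a window edge as an "event".

**Toe-off and heel-strike** (vertical axis):

3. Candidate positive peaks inside a window after the stimulus, above
   τ₁ = 1 % of the P90–P10 range of the windowed values.
4. The largest candidate above τ₂ = 25 % of the windowed P95
   (`Peak_va_max`), ties to the earliest. Both thresholds admit more than
   one literal reading; the fractions and percentiles are arguments, not
   constants.
5. The first-step peak: inside a look-back window 1.5–0.5 s before
   `Peak_va_max`, the peak closest to the window's *end* boundary.
6. Toe-off: the last zero crossing from ≤0 to >0 before the first-step
   peak.
7. Heel-strike: the last upward crossing of 20 % of the first-step peak
   amplitude between toe-off and that peak.

Zero- and level-crossings are sub-sample by linear interpolation: one
140 Hz sample (7 ms) is the same order as the agreement being measured, so
rounding to the grid would waste precision.

**Window configuration.** The literal peak-search window ends 2 s after
the stimulus. That end is arithmetically incompatible with parkinsonian
heel-strike times near 1.7 s plus the 0.5–1.5 s look-back lead of the
first-step window, so the package also ships `EXTENDED_WINDOWS` with the
end at 3 s, used as the default for synthetic cohorts. All windows are
user-configurable (`AlgorithmWindows`).

## Validation statistics (`stats`)

Paired differences are always wearable − force platform.

* **Bland–Altman**: bias, SD of differences (n−1 denominator), 95 % limits
  of agreement (bias ± 1.96 SD), and a coefficient of variation defined as
  100 × SD of differences / mean of the pairwise means (one isolated
  function, since CV conventions vary).
* **ICC(A,1)**: single-measure, absolute-agreement, two-way model, from
  the ANOVA mean squares, with the F-based 95 % CI (Satterthwaite degrees
  of freedom) and Cronbach's alpha (= 1 − MSE/MSR) from the same
  decomposition. Fleiss classes: poor < 0.40 ≤ fair-to-good ≤ 0.75 <
  excellent (boundaries belong to the middle class).
* **Event errors**: both the signed mean error and the true mean absolute
  error are computed and labelled — published "MAE" tables sometimes carry
  signs, i.e. are signed means, and reporting both removes the ambiguity.
* **Group contrasts**: Shapiro–Wilk per group (reported as a flag; the
  test is computed regardless), two-sided unpaired t-test, Cohen's d with
  the df-weighted pooled SD, classes negligible < 0.20 ≤ small < 0.50 ≤
  moderate < 0.80 ≤ large.
* **Correlations**: Pearson or Spearman with the five-band magnitude
  scheme (very slight / slight / moderate / strong / very strong at
  0.20/0.40/0.60/0.80, boundaries to the higher band).
* **Sample size for agreement studies** (`ba_sample_size`): the smallest n
  such that, with the requested power, both 95 % LOA confidence bounds lie
  inside ±δ. The power is computed exactly under normality by conditioning
  on the sample SD (chi distribution) and integrating the containment
  interval of the sample mean; δ is an explicit argument because no single
  δ convention exists. With bias −0.02 s, SD 0.13 s, α = 0.05 and power
  0.9, δ = 0.45 s gives n = 23. The implementation is checked against a
  Monte-Carlo containment simulation in the test suite.
* **No multiplicity correction** is applied; per-comparison α = 0.05 is
  reported as-is, matching the validation protocol this package
  implements.

## Synthetic data (`synthetic`)

No public dataset exists for this protocol, so the generator is
first-class: it produces paired accelerometer and force-platform trials
with known ground-truth events, and the entire validation study runs on
it.

**Event-time model.** Per group (PD, FOG−, FOG+, ELD), the three
independent durations (time-to-APA, APA duration, swing duration) have
published means and SDs; the elderly-control APA-duration SD is taken as
0.09 s (the abstract-level figure) where two published values disagree.
Subject means are Gaussian draws; trial-level times add Gaussian jitter
with SD equal to 20 % of the group SD (the subject/trial variance split is
not published; 80/20 is this package's choice, configurable via
`TRIAL_JITTER_FRACTION`). Draws are rejected and redrawn outside a
feasibility envelope (time-to-APA 0.15–0.75 s, APA duration 0.20–1.30 s,
swing 0.25–0.72 s, heel-strike ≤ 2.28 s) chosen so that every sampled
trial is geometrically detectable under the extended windows; the envelope
sits ≥ 2 group SDs from every group mean, so the induced truncation
displaces group means by < 0.01 s.

**Waveform templates.** Morphological, not biomechanical — no
inverted-pendulum dynamics. Each template plants the events so the
documented detection rules recover them in the noiseless limit:

* AP/ML axes carry a biphasic anticipatory lobe whose last pre-change local
  minimum is exactly the APA onset. The small positive hump before the
  minimum is slope-matched to the lobe's rise, so zero-phase smoothing
  cannot displace the minimum. The vertical axis carries a scaled copy
  when the postural phase is long enough for it to survive the 4.5 Hz
  cut-off (lobe half-width ≥ 0.15 s); for shorter postural phases the
  pre-swing dip, then inside the APA window, anchors the V-axis search.
* The vertical axis crosses zero upward exactly at toe-off (slope-matched
  corner), runs along a positive shelf through the swing, crosses 20 % of
  the first-step peak exactly at heel-strike in the middle of a linear
  ramp, peaks 0.15 s later, swings sharply negative (so the peak/valley
  doublet carries little low-frequency content), and carries the dominant
  peak 0.7 s after heel-strike. A final wide lobe cancels the residual
  signed area so the 0.2 Hz high-pass sees a zero-mean transient.
  Because the high-pass still displaces level crossings by a
  template-dependent amount, the generator runs a short fixed-point
  calibration: it filters its own noiseless template with the standard
  conditioning, measures the residual crossing displacement, and shifts
  the two crossing knots to cancel it. The planted instants are therefore
  exact in the *filtered* domain the detector actually sees.
* The CoP path is built in the chord frame of the line joining its
  positions at APA onset and stance toe-off. The tangential coordinate
  carries a forward pre-stimulus sway whose velocity crosses zero linearly
  exactly at APA onset (so both lab-frame velocity components change sign
  there simultaneously); the perpendicular coordinate peaks exactly at
  swing toe-off inside a locally symmetric cap and vanishes at both chord
  endpoints, making the perpendicular distance from the detected line
  equal to |d(t)| identically. GRF unloads linearly to zero at
  heel-strike + 0.15 s; the marker AP velocity is a swing-phase half-sine
  crossing zero exactly at heel-strike, extended into a small recoil so the
  crossing is a genuine sign change after smoothing.
* Noise is Gaussian, band-limited (0.2–10 Hz for acceleration, 0.2–15 Hz
  for CoP) and rescaled after band-limiting so the stated SD is the SD
  actually added. Defaults: 0.05 m/s² (acceleration), 0.5 mm (CoP),
  0.2 mm (marker). At these levels the detectors' mean absolute event
  errors are ≈ 1–6 ms (wearable) and ≈ 0.5–4 ms (gold standard), giving
  subject-level limits of agreement well inside the published 0.04 s.
* Amplitudes (APA lobe 1 m/s², first-step peak 3 m/s², dominant peak
  4.5 m/s², CoP excursion ≈ 2.8 cm, body weight 700 N, step length
  0.40 m) are plausible for lower-back sensing during gait initiation and
  chosen once; event *timing* is amplitude-invariant by construction.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: physiological inter-axis coupling and realistic
accelerometer noise spectra, step-to-step correlation of waveform shape,
freezing episodes and aborted APAs, sensor misalignment and drift, marker
occlusion, and any systematic disagreement between the two modalities
(both templates share the same ground truth, so cross-system bias is by
construction near zero; only the *precision* of each detector is
stressed).

## Numerical choices and degenerate inputs

* Tie-breaks are everywhere to the earliest time; numerically tied SSE
  splits (within 1e-10 of the minimum) count as ties and are logged.
* The first/last 0.25 s of any filtered signal are edge transient;
  container invariants keep detection windows away from them.
* Degenerate inputs fail loudly with stage-named errors rather than
  returning a wrong event: flat trials (no axis yields a minimum),
  stationary CoP (no joint-negative velocity frame), never-unloading GRF,
  all-positive vertical acceleration (no toe-off crossing), a level never
  crossed (no heel-strike). A fully collinear CoP path returns the
  earliest interior sample with a logged degeneracy warning.
* Detection failures within a cohort are excluded from subject averages
  and counted (`StudyResult.n_failed`); averaging is over however many
  trials succeed.

## Problem sizes

The shipped validation study uses the full published cohort shape (25 + 8
subjects × 5 trials × 2 modalities ≈ 330 synthesised and detected trials)
and completes in well under a minute on one CPU; unit and property suites
use smaller signals (50–1000 Hz, seconds-long) and 100-repetition oracle
sweeps. The Monte-Carlo oracle for the sample-size routine uses 6000–8000
replicates per grid point, enough to resolve the power curve to ±0.01.
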