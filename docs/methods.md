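# Methods

This note documents the models, numerical choices and limitations behind
startlekit's four layers: schedule generation, synthetic EMG, blink
quantification, and group statistics.

## Paradigm schedule

The default `ScheduleConfig` encodes a differential conditioning session:
9 habituation probe tones (ITIs drawn from {12, 14, 16} s); per
conditioning phase 10 CS+ and 10 CS− of 8 s; 50 % partial reinforcement
of the CS+ during acquisition only, with the 100 ms shock co-terminating
with the CS; probes on 60 % of each CS type (6 + 6) at 4.5 or 7 s after
CS onset; 4 ITI probes; extinction mirrors the acquisition sequence
trial-for-trial with reinforcement cleared.

Choices the paradigm family leaves open, fixed here:

- **Pseudorandomization** means "no more than `max_run = 2` consecutive
  trials of one CS type". Sequences are built constructively with an
  exact feasibility check (a two-symbol remainder with counts (a, b),
  trailing run r and limit k is packable iff a ≤ (k − r) + k·b and
  b ≤ k·(a + 1)), so draws never dead-end and infeasible configurations
  raise immediately rather than after retries.
- **Probe offsets** (4.5 vs 7 s) are split as evenly as possible within
  each CS type per phase and shuffled.
- **Conditioning-phase ITIs** are drawn from the same {12, 14, 16} s set
  as habituation.
- **Reinforced CS+ trials may carry probes** (the probe, at ≤ 7 s,
  precedes the 7.9 s shock onset): with 6 of 10 CS+ probed and 5 of 10
  reinforced, overlap is unavoidable in some draws.
- A 10 s silent lead-in precedes each phase and a 300 s gap separates
  acquisition from extinction (an immediate-extinction design: extinction
  follows within minutes).
- ITI probes are placed at the midpoint of their host ITI, clear of the
  preceding CS offset and the next CS onset.

Events are exchanged as a BIDS-events-style TSV (`onset`, `duration`,
`phase`, `trial_type`, `probe_onset`, `reinforced`, `us_onset`, `n/a`
for absent values).

## Synthetic EMG model

Each probed trial (unless a non-response is drawn with probability
`p_nonresponse`) receives a blink burst added onto stationary background
noise:

- **Envelope**: gamma-shaped (shape 2, scale 15 ms, ≈60 ms effective
  width), peak normalized to 1, starting `blink_latency_ms` (default
  45 ms, Gaussian jitter SD 5 ms, clipped to 25–95 ms) after probe onset.
  With these defaults the processed peak lands near 65 ms post-probe,
  inside the 40–90 ms amplitude window, and the onset inside 20–110 ms —
  i.e. the analysis windows are correct for clean inputs by construction.
- **Carrier**: one fixed band-limited (30–300 Hz) noise waveform, drawn
  once from an internal constant seed and shared by all bursts. Because
  every burst is an amplitude-scaled, time-shifted copy of one waveform
  and every processing stage is positively homogeneous and
  shift-invariant, noise-free proportional scores equal the generating
  potentiation factors exactly — the property that makes the generator a
  scoring oracle. Trial-to-trial morphology variation of real blinks is
  deliberately not modelled (see Limitations).
- **Amplitude**: `blink_gain_iti × potentiation[phase, cs_type] ×
  habituation_rate^ordinal`, the ordinal counting probes across the whole
  session (habituation is multiplicative with rate 0.985 per probe; the
  functional form is a modelling choice, matching the observation that
  background startle declines across a session). ITI probes and
  habituation tones have potentiation 1.
- **Background**: white noise band-passed 1–200 Hz (the acquisition
  amplifier's passband, applied here because it is a property of the
  recorded data, not of offline analysis) and scaled to
  `baseline_noise_rms` (default 2 µV against a 100 µV ITI blink gain).
- **Artifacts**: with probability `p_artifact` per CS trial, a 20 mV,
  200 ms step transient — an electrode pop, orders of magnitude above
  EMG — at a uniform position in the trial.

### Cohort parameter model

Participants are drawn from `CohortDesign` (defaults: 37 patients, 40
controls). True per-cell proportional scores are built from a phase CS−
level (acquisition 0.90, extinction 0.85; between-subject SD 0.15) plus a
group-dependent differential: acquisition 0.40 in both groups
(differential fear learning of equal strength), extinction 0.30 in
controls versus 0.00 in patients (persisting fear in controls, complete
extinction in patients), between-subject SD 0.35, floored at 0.05. These
effect sizes are free parameters of the generator — the study being
emulated reports no raw amplitudes — chosen once as plausible for startle
differentials of this kind.

Illness duration (patients only; mean 10.6, SD 9.5 years, floored at
0.25) is linked to the standardized true extinction differential by a
bivariate-normal model with correlation −0.40: longer illness, smaller
remaining differential. Correlations recovered from *observed* scores are
attenuated below 0.40 in magnitude by measurement noise (six-trial cell
means), typically to ≈ −0.35 at the default noise level. Age, depression
score, and two contingency-quiz answers (each correct with probability
0.95, feeding the fully/partially/unaware classification) are drawn per
participant.

Two layers share this parameter model: `simulate_cohort_scores` emits
observed cell scores directly (true score + Gaussian measurement noise,
SD 0.12) for Monte-Carlo work at many replicates, and `simulate_cohort`
renders full EMG sessions. Per-participant generators are spawned from
the design seed via `SeedSequence`, so cohorts are reproducible and
participant k's data do not depend on the other group's size.

## Processing chain

Stage order: 65 Hz high-pass → full-wave rectification → 40 ms moving
average → 2 Hz high-pass → clamp at zero. Both high-passes are 4th-order
Butterworth filters applied forward–backward (zero-phase), preserving the
latency semantics of the 20–110 ms window; the moving average is centered
(40 samples at 1 kHz) with reflected edges to avoid onset bias. The drift
filter runs after smoothing as listed; a configuration flag
(`drift_after_smoothing`) moves it before rectification for comparison.
Residual negative excursions after the drift filter are clamped to 0 so
the output is a non-negative response curve. Only 1 kHz input is
supported; resampling is out of scope. The 1–200 Hz acquisition band-pass
is *not* re-applied offline.

Automated artifact marking (a surrogate for visual inspection) masks
processed samples above an absolute ceiling (default 800 µV, several
times the largest plausible processed blink) or with sample-to-sample
jumps above 100 µV, dilated by 50 ms; trials whose baseline or response
window touches a mask are invalidated with reason `artifact`.

## Response definition and scoring

Per probe: threshold = mean + 3 SD of the 500 ms pre-probe baseline of
the processed curve; onset = first strictly supra-threshold sample in
20–110 ms; the curve must return to ≤ threshold within the same window;
amplitude = max of the 40–90 ms window minus baseline mean, floored at 0.
Reason codes separate `no_crossing`, `late_onset` (a crossing exists
within 300 ms after the window), `no_return`, and `artifact`. Numerical
conventions: "3 SDs of baseline" is mean + 3·SD (not 3·SD absolute); a
degenerate zero-variance baseline requires strict exceedance of the mean;
a probe closer than 500 ms to the recording start is an error.

Cell means use valid trials only — non-responses are excluded, never
zero-filled (how invalid trials entered the original six-trial averages
is not specified anywhere; exclusion is this package's choice, and no
minimum-valid-trial inclusion criterion is imposed beyond the reference
cell). The proportional reference is the mean *acquisition* ITI
amplitude for both phases: phase-specific referencing would hide
acquisition→extinction changes, and pooling both phases' ITIs would
inflate acquisition scores, since ITI startle habituates. Participants
without a valid acquisition ITI response are returned explicitly flagged
unscoreable. The successful-acquisition filter keeps strictly positive
acquisition differentials.

## Statistics

The 2×2 split-plot ANOVA is computed from the classical decomposition on
subject means (between part) and CS+ − CS− differences (within part).
For unbalanced groups the CS-type main effect tests the *unweighted* mean
of group difference-means (Type-III convention, as SPSS-style GLM
software reports it); pingouin's `mixed_anova` — used as an independent
cross-check in the tests, never as the implementation — matches exactly
on balanced designs and differs on unbalanced ones only in that weighted
vs unweighted choice. Identities maintained by construction and verified
in tests: single-group within-F equals the squared paired t;
η_p² = F·df_num / (F·df_num + df_den); listwise deletion with reported
counts. t-tests, Pearson r and the chi-square delegate to scipy.stats
behind validated entry points (pooled t is the default independent test,
Welch available by flag — published t-tables of this design are
ambiguous between the two); summary-statistic entry points allow
recomputation from printed mean ± SD ± n. No multiple-testing correction
is applied; α = .05 two-tailed throughout.

## What the tests do and do not show

Because every burst is a scaled copy of one waveform, synthetic-data
tests demonstrate correctness of the *pipeline* (windows, thresholds,
referencing, statistics) and calibration of the *tests* (type-I rate of
the interaction 0.05 ± 0.02 under a null design at 500 score-level
replicates), not robustness to real-world blink variability, ocular or
movement artifacts beyond step transients, or line noise. Monte-Carlo
problem sizes are chosen for single-CPU runs: noisy parameter recovery
uses 100 replicate compact sessions of ~100 scored CS trials each;
type-I calibration and detection-rate checks run at the score level
(500/100 replicates); the full-EMG headline check uses 5 replicate
cohorts of 77 participants.

## Known limitations

- EDF files can be read (via mne, single channel) but not written; the
  native signal format is the headered TSV.
- Blink morphology is fixed; magnitude-vs-probability startle
  decomposition, T-scoring and z-standardization are out of scope.
- The generator does not model shock artifacts in the EMG, US-expectancy
  rating data, multi-channel montages, or 50/60 Hz interference (and the
  chain has no notch filter).
- Proportional scores under session-wide habituation are attenuated
  relative to the generating potentiation factors in extinction (both CS
  types shrink against the fixed acquisition ITI reference); this mirrors
  the real phenomenon and is why differential, not absolute, effects are
  the analysis target.
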