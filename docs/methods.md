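# Methods

`lmbci` re-implements, against synthetic data, the complete offline analysis of a
four-condition lower-limb motor-imagery (LMI) EEG experiment in which a kinesthetic
illusion (KI) — the sensation of limb movement induced by tendon vibration — is used
to strengthen imagery. The four conditions are `rest`, `V-rest` (rest with
vibration), `no-LMI` (imagery alone) and `KI-LMI` (imagery with vibration). This
note documents the models, the parameters that matter, the numerical choices, and
what the synthetic experiments do and do not demonstrate.

## Signal model of the simulator

No public data accompany the paradigm, so the simulator is a first-class module.
Each of the 16 sensorimotor channels (a 10–10 grid of the FC/C/CP rows:
FC3…FC4, C5…C6, CP3…CP2) is an independent sum of

* a 1/f^γ background (default γ = 1, RMS 5 µV), generated by spectrally shaping
  white noise in the frequency domain;
* an alpha-band process (8–13 Hz, RMS 10 µV) — band-pass-filtered white noise;
* a beta-band process (14–30 Hz, RMS 5 µV).

Event-related desynchronization (ERD) is imposed multiplicatively: during the task
window of a trial whose condition has depth `d` at a channel, the narrowband
amplitude ramps linearly over `erd_latency` (default 0.5 s) from 1 to √(1−d) and
holds there, so band **power** drops by the fraction `d`. Default depths follow the
phenomenology the analysis expects: zero for `rest`; a slight drop (0.05 at Cz/CPz)
for `V-rest`; 0.30 at Cz falling off over neighboring mesial channels for `no-LMI`;
and 0.45 at Cz with broader, contralaterally-spread modulation for `KI-LMI`. These
defaults were set once from the qualitative pattern the study reports (KI deepens
and accelerates the ERD and recruits contralateral channels) and are the conditions
under which all behavioral claims are tested.

The paradigm timing is: fixation cross 2 s → cue 1 s → task 3.5 s → relax 4 s;
12 runs of 16 trials (8 rest-type + 8 imagery-type, equal per-condition splits,
order randomized within run) give 192 trials per session. The default sampling
rate is 1200 Hz; analyses in the test-suite run the same paradigm at 128–256 Hz,
which is well above twice the highest analysis frequency (32 Hz) and changes
nothing but cost. An optional lagged-coupling term adds a shared narrowband source
to two channels, one copy delayed (default 25 ms, a quarter period at 10 Hz),
during the task windows of chosen conditions — the ground truth for connectivity
tests. Artifact injection adds 0.3 s half-sine "blink" pulses (default 300 µV) on
the frontocentral row to a Bernoulli subset of trials.

What the generator does **not** emulate: volume conduction (channels are
independent by construction except for the explicit coupling term), realistic
artifact morphology, non-stationary background, inter-subject variability beyond
the seed. Passing tests therefore demonstrate the correctness of the analysis
arithmetic and its qualitative behavior under known ground truth — not performance
on human EEG, whose headline accuracies are out of reach of any synthetic desk
check.

## Preprocessing

Epochs are time-locked to the task onset (t = 0): baseline −2.5…−1.5 s (the calm
final second of the fixation cross) and task 0.5…3.5 s (the first half second
is discarded as cue-transient-contaminated). Windows are half-open in samples.
A trial is rejected when any electrode's peak-to-peak amplitude in either window
strictly exceeds 200 µV; a value exactly at threshold passes (the rule is "greater
than"). The original workflow additionally removed trials by visual inspection;
that step cannot be automated as described, so only the quantitative rule is
implemented, plus a pluggable predicate for custom criteria. After rejection, a
fixed number of trials per condition (default 40) is drawn uniformly without
replacement, seeded.

Epoch sets carry, besides the two analysis windows, a margin-padded continuous
segment (−3.0…+4.0 s). Band-limited power estimation filters this segment and
slices the windows out afterwards: filtering the already-cut 1 s baseline loses
roughly 16 % of narrowband power to IIR edge transients versus ~11 % for the 3 s
task window, which would bias ERD by 7–9 percentage points. The margins absorb
the transients instead.

## ERD quantification

All band-limited operations use a 4th-order Butterworth band-pass applied
forward–backward (zero phase). Instantaneous power is the squared filtered signal
smoothed by a 0.25 s moving window with a one-sample hop. The pipeline is
trial-average-first: power is averaged across trials, the baseline power `P_base`
is the time-average over the baseline window, and

    ERD(t)   = (P(t) − P_base) / P_base × 100      [%]
    mean ERD = (P_task − P_base) / P_base × 100

Normalizing each trial by its own baseline before averaging is a different,
positively biased estimator (Jensen's inequality); a regression test guards the
order. Edge-truncated smoothing windows are excluded from averages. `E_min` is
the minimum of ERD(t) in the task window; the arrival time `T` is the first time
the trace reaches a reference level — its own minimum for the plain-imagery
condition, the plain-imagery `E_min` for the KI condition — with a NaN sentinel
when the level is never reached.

A practical caution established during development: a single 40-trial session's
mean-ERD estimate carries a sampling SD of roughly (1−d)·6 percentage points,
because 1 s of an 8–13 Hz process contributes only ~5 effective degrees of freedom
to the baseline. Recovery checks therefore average over several independent
sessions (the analogue of the study's across-subject grand averages); the ±5-point
recovery band itself is unchanged.

The decibel relative-power view (10·log10 of one condition's smoothed power over
a reference condition's) is provided as a clearly separate output. It is **not**
derivable from the percentage ERD definition, and the −21 dB peak scale that
motivated it cannot be reconciled with a −21 % ERD (≈ −1 dB); the package exposes
the dB quantity as its own alternative and asserts only its closed forms.

## Connectivity: imaginary part of coherency

Coherency is estimated trial-as-segment: each Hann-tapered 3 s task epoch
contributes one cross/auto periodogram; averaging across ≥ 2 trials gives
R_xy(f) = S_xy/√(S_xx S_yy) at ~⅓ Hz resolution. The imaginary part is blind to
instantaneous mixing (volume conduction) because a signal is not time-lagged with
itself — the property is tested explicitly: zero-lag mixed channels show
coherence > 0.8 yet band |Im R| < 0.05, while a 25 ms lagged coupling drives
Im R(10 Hz) → ±1 and ranks that pair first among all 120. The band summary is the
mean of |Im R| over in-band bins (connection strength, for maps); the signed mean
is retained separately and is antisymmetric. Whether the original analysis
averaged signed or absolute values is undocumented; absolute is the default here.
Grand averages are elementwise means over sessions with matching montage and band.

## Classification: FBCSP + RBF-SVM

Six zero-phase sub-bands (7–12, 12–16, 16–20, 20–24, 24–28, 28–32 Hz); per band,
common spatial patterns from the generalized eigenproblem
`C_a w = λ (C_a + C_b) w`, where class covariances are averages of per-trial
trace-normalized covariances (shrinkage 10⁻⁶ applied and logged when
ill-conditioned). Filters are sorted by descending eigenvalue; the first and last
2 rows (2 pairs → 4 components per band, 24 pooled candidates) feed log
normalized-variance features, which are scale-invariant by construction. Exactly
8 features are kept by mutual information with the label, estimated by a histogram
whose bin count follows the Freedman–Diaconis rule with equal-frequency
(quantile) edges; ties break toward the lower index. The decoder is an RBF SVM
with C ∈ 2⁻³…2⁷ and γ ∈ 2⁻⁷…2³ selected by an inner 3-fold grid search on
standardized features.

Evaluation is stratified outer 5-fold cross-validation with everything — CSP,
selection, grid search — fitted inside each training fold; the four dataset
pairings are D1 rest/V-rest, D2 rest/no-LMI, D3 rest/KI-LMI, D4 V-rest/KI-LMI
(40 trials per class by default). Headline accuracy and F1 come from confusion
counts pooled over folds; per-fold values and their mean ± SD are reported
alongside. Two numerical choices matter at this sample size (64 training trials):

* many (C, γ) cells tie in the inner search, and "first best wins" would select
  degenerate corner values; the grids are ordered centre-out (C near 1, γ near
  1/k first) so ties resolve to the least extreme hyperparameters;
* whether fold metrics are pooled or averaged changes F1 by up to a point; the
  pooled value is headline, both are reported.

Two structural facts verified in tests: uniform power modulation of *all*
channels is invisible to CSP (trace normalization removes it — discriminability
requires spatial structure), and the trained model is independent of held-out
labels by construction (no leakage through the public interface).

## Statistics and reporting

Group comparisons use two-sided paired and one-sample t-tests (the latter against
the 50 % chance level), gated by Shapiro–Wilk at α = 0.05; data failing the gate
are routed to a Wilcoxon signed-rank fallback and flagged as a divergence from the
parametric pipeline. Degenerate inputs (zero-variance differences) are reported
as such rather than raising. p-values get conventional star bands (0.05, 0.01,
0.001). No multiple-testing correction is applied by default, matching the
reported workflow across the nine channel × band tests; Holm adjustment is
available behind a flag. Aggregation is a plain mean ± SD over subjects, with
rounding to the report's one-decimal convention applied only at the output
boundary. The packaged reference table of per-subject F1 values (transcribed from
the original study's published results) reproduces its printed row averages
(74.3 / 81.9 / 76.4 %), the 7.6-point condition improvement, and the printed
11-subject subset means (72.6 / 79.24 %) exactly at that rounding. The published
list of below-70 % ("BCI-illiterate") subjects contains six IDs but is referred to
as five subjects in the source text; the six-ID list is stored verbatim and the
inconsistency surfaced, not resolved.

## Sizes used by the reference experiments

Tests and the acceptance script run the full paradigm at 160 Hz with 40 trials
per condition. ERD depth recovery averages 5 sessions in the test suite and 12
in the acceptance script; the coherency ranking
property uses 20 seeded runs; classifier behavior uses 10 seeded sessions for the
condition contrast (plain vs KI imagery), 3 label permutations for the chance
check, and one strongly contrasted session — depth 0.7 across the ten central and
centroparietal channels — for the separability check (depth 0.5 at six channels
tops out near 93 % under this generator; see the limitations above on narrowband
degrees of freedom). Type-I calibration uses 20 000 vectorized null simulations
validated sample-by-sample against the package's t-test functions.

## Known limitations

* The simulator's independence across channels makes spatial filters easier to
  find than in volume-conducted recordings; absolute accuracies are not
  comparable to human data.
* The ERD latency ramp is linear and common to a condition; real onset dynamics
  vary by trial.
* EDF output is 16-bit with a per-session physical range (quantization ≤ 0.03 µV
  at typical amplitudes); the writer supports integer sampling rates only.
* The visual-inspection stage of artifact rejection is not modelled; only the
  amplitude rule is.
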