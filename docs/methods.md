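# Methods

## Scope and model

The package simulates and analyzes threshold-EMG gesture control as used
in EMG-driven bilateral hand rehabilitation: a subject follows a random
sequence of open/rest/close instructions; two forearm sEMG channels are
conditioned in real time; a Boolean threshold rule recognizes the gesture;
and performance is the delay-compensated squared distance between target
and recognized series. The physical exoskeleton, its actuators and
control signals are out of scope; their only trace is a fixed
recognition-latency constant in the behavioral subject model.

## Signal chain

All filters are causal (forward-only IIR), because the reference system
runs on a real-time microcontroller and zero-phase filtering would
misrepresent its latency. Stages, in order, at 200 Hz input:

| stage | choice | default | rationale |
|---|---|---|---|
| notch | 2nd-order IIR, Q = 30 | 50 Hz | narrow mains line removal |
| high-pass | 2nd-order Butterworth | 10 Hz | drift/motion-artifact rejection |
| RMS | trailing window | 50 ms (10 samples) | causal envelope; shortened windows at the start |
| low-pass | 2nd-order Butterworth | 2 Hz | envelope smoothing; anti-alias for the rate reduction |
| decimation | keep every 10th sample | ×10 → 20 Hz | the 2 Hz low-pass already bounds the band |
| normalization | divide by per-channel MVC | — | nEMG in MVC units, deliberately **not** clipped at 1 |

The 2 Hz low-pass is initialized at steady state for the first RMS sample;
with zero initial conditions its warm-up transient reaches ~0 and would
masquerade as the rest-phase minimum, pinning both deactivation thresholds
at exactly their 0.1 floor regardless of the subject's actual resting tone.

Sample indexing is 0-based with the time origin at the first sample;
decimated timestamps are t = k/20 s.

## Calibration

MVC per channel is the maximum of the rectified envelope over the whole
24 s trace. The relaxation phase is taken as the nominal first 8 s window
(no onset detection). Thresholds are rest-phase nEMG minima plus 0.1, so
they can never fall below 0.1; there is no upper clamp — a threshold at or
above 1 MVC raises a calibration-quality warning, not an error, since the
data remain classifiable.

## Classifier conventions

All comparisons are strict: a sample exactly at a threshold counts as
inactive, and an exact dominance tie (both muscles active, nEMG_ED =
nEMG_FDS) makes C false so the close rule fires — the literal reading of
"ED higher than FDS". No hysteresis or dwell-time debouncing is applied.
The printed form of the open/close equations is ambiguous as typeset;
the algebra implemented, OPEN = A·(B̄+C) and CLOSE = B·(Ā+C̄), is the only
reading consistent with the accompanying prose and with mutual exclusivity
over all eight (A, B, C) combinations, which the tests enumerate.

## Synchronization and scoring

The lag search maximizes the raw (not demeaned, not normalized) sliding
dot product over non-negative lags up to 2 s — recognition physically lags
the instruction, and larger delays are implausible given reaction plus
processing time. Ties break toward the smallest lag; a flat correlation
(constant series) falls back to zero delay with a warning. The delay is a
single constant per test. After shifting the recognized series back, the
target is truncated at the end to the common length, so d_L2 sums
(60 − T_d)/T_s aligned samples. The stated sample-count expression in the
source material is dimensionally inconsistent; it is interpreted as
n_samples = (60 − T_d)/T_s, which matches the described truncation.

## Statistics

The additive ANOVA uses sequential (Type I) sums of squares in the order
test, order, individual — immaterial for the balanced design, where each
subject contributes one trial per condition (default 72 rows, residual
df 48). The fit goes through statsmodels OLS; an explicit
design-matrix-projection oracle cross-checks the decomposition in the
tests. Saturated (residual df ≤ 0) and rank-deficient designs (e.g. order
perfectly confounded with test) are rejected with explicit errors.

Duncan's multiple range test is implemented from the studentized-range
distribution: groups sorted by mean, a pair separated by r ranks differs
at level α when its mean difference exceeds q at protection level
1 − (1 − α)^(r−1) with the residual df and SE = √(MS_resid/n). The
reported pairwise p-value inverts this criterion in closed form,
α = 1 − (1 − P(Q_{r,df} > q_obs))^(1/(r−1)), which is exact and monotone
(bisection would only approximate the same number). For r = 2 this equals
the pooled-variance two-sample t-test p-value, which the tests assert.
Homoscedasticity uses Levene's median-centered test by default (robust to
the right-skew of squared-distance scores); Bartlett is available via a
flag. All p-values are two-sided; α defaults to 0.05.

## Synthetic cohorts

The generator emulates the study conditions: 18 subjects, four feedback
conditions A–D in random per-subject order (a cyclic Latin-square mode is
available for sharper order-effect analysis), one 24 s calibration per
subject, 60 s tests of 20 × 3 s uniformly random gestures.

Signal model: zero-mean Gaussian noise band-passed to 20–90 Hz (unit RMS)
serves as the sEMG carrier, amplitude-modulated by trapezoidal activation
envelopes with 100 ms causal rise/fall; additive 50 Hz interference (10%
of MVC) and 0.5 Hz drift (5% of MVC) make the notch and high-pass stages
functionally necessary. Millivolt scales are conventional placeholders —
the threshold logic is scale-invariant by construction, which the tests
verify.

Subject model: per-gesture response delays are truncated-normal
(mean ≈ 0.4 s per subject, sd drawn from 0.07–0.15 s, truncated to
[0.05, 1.5] s); the device adds a fixed 0.45 s recognition latency in the
behavioral path (in the raw path the chain's own group delay plays this
role, ≈ 0.2 s, giving mean T_d ≈ 0.6 s). With per-gesture probability
`error_prob`, scaled by 2·(1 − skill) for the subject, an error episode of
0.3–0.7 s precedes self-correction: wrong muscle (mirrored gesture),
co-contraction (both muscles firing, recognized gesture flickering), or
sub-threshold activation (envelope at 0.07 MVC, below the 0.1 threshold
floor), chosen uniformly. Error episodes are brief because persistent
whole-gesture errors would inflate trial variance far beyond what a
healthy cohort shows.

Default condition effects are error probabilities A = B = 0.08, C = 0.03,
D = 0.055 (no extra delay), ordering expected error C < D < A ≈ B — EMG
visual feedback alone gives the best control. These values were
calibrated once, by simulating cohorts and matching the per-condition
mean d_L2 to the 2.9–3.4 range a real cohort of this design produces
(raw-path expectation ≈ 2.8 / 3.1 / 3.3 / 3.5 for C / D / B / A); they
are a modeling choice, not ground truth. Consequences worth knowing:
within-cell variance is larger than a real cohort's (errors arrive in
discrete lumps), so a single simulated 18-subject cohort frequently fails
to reach significance at the default contrast — effect-recovery checks
use a materially stronger contrast (C = 0.01 vs A/B = 0.25, D = 0.20).

What the generator does **not** emulate: motor-unit physiology, force or
kinematics, fatigue, electrode lift-off, learning across tests, or
correlated noise between channels. Passing tests therefore demonstrate
the correctness of the pipeline's algebra and its statistical machinery
under the stated behavioral model, not validity on human data.

## Determinism and problem sizes

All randomness flows through explicitly passed `numpy.random.Generator`
objects; cohort runs derive per-subject generators from
`SeedSequence([master_seed, subject_id])`, so results are bit-reproducible
and independent of iteration order. Monte-Carlo suites run on the
behavioral path (500 null cohorts for p-value calibration, 100 cohorts
for effect recovery, ~0.1 s per cohort); the raw-EMG path is exercised
end-to-end on full 18-subject cohorts and in every chain-level test.

## Known limitations

- The behavioral path's fixed 0.45 s latency and the raw path's ≈ 0.2 s
  chain delay differ; T_d comparisons across paths are not meaningful.
- Duncan p-values are per-pair inversions of the range criterion; the
  classic step-down protection (declaring a pair non-significant when an
  enclosing range fails) is not layered on top.
- `reanalyze` targets this package's own CSV dialect; external trial
  archives must be mapped to it (columns `t_sec, gesture`, codes −1/0/+1,
  file names `subject<i>_test<T>_order<k>_{target,recognized}.csv`).
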