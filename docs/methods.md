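# Methods

## Signal model and pipeline

A single mastoid EEG channel sampled at 1000 Hz is treated, within each
analysis window, as the output of a stochastic linear system in innovation
form:

    x[T+1] = A x[T] + K e[T]
    y[T]   = C x[T] + e[T]

with latent state x (dimension m), white innovations e, and steady-state
Kalman gain K. No input signal exists — the perturbation acts through the
cortex, not through a measured channel — so identification is output-only.
The pipeline classifies perturbation responses as Predicted vs Unpredicted
from features of the identified (A, C, K), and a streaming variant fuses
EEG with platform acceleration to detect unexpected perturbations in under
400 ms of signal time.

## Subspace identification

`pepdetect.sysid.identify` is covariance-driven stochastic subspace
identification:

1. sample output covariances Λ_l up to lag 2h (h = horizon, default 20);
2. the h × h Hankel matrix H = [Λ_{i+j−1}] is weighted on both sides by the
   inverse symmetric square root of the Toeplitz matrix [Λ_{|i−j|}]
   (canonical-variate weighting). The square root uses an eigenvalue floor
   (10⁻¹⁰ of the largest eigenvalue) because band-limited signals sampled
   far above their bandwidth give numerically rank-deficient Toeplitz
   matrices. Unweighted SVD is available (`weighting="none"`), but CVA
   weighting roughly halves pole-recovery error in our benchmarks and is
   the default;
3. rank-m truncation of the weighted SVD gives the extended observability
   matrix; C is its first row and A the shift-invariance least-squares
   solution;
4. K solves the forward Riccati fixed point
   P = A P Aᵀ + (G − A P Cᵀ)(Λ₀ − C P Cᵀ)⁻¹(G − A P Cᵀ)ᵀ by iteration
   (tolerance 10⁻¹², up to 2·10⁴ iterations). When the estimated
   (A, G, Λ₀) triple is not positive-real the iteration fails; the package
   then regresses one-step observer residuals for K and flags the result
   (`riccati_converged=False`) rather than failing silently. On short
   noisy epochs the fallback is common and harmless — the features remain
   deterministic functions of the data.

Identifiability caveat: an innovation model whose zeros (eigenvalues of
A − KC) approach its poles is indistinguishable from a lower-order model
from output statistics alone. The recovery benchmarks therefore draw truth
models with pole moduli in [0.8, 0.95] and pole–zero separation > 0.2;
under these conditions the median worst-pole error over 20 random order-3
models at n = 10,000 is ≈ 0.03 (tested bound 0.05) and the median relative
L2 error between identified and true output spectra over 2.5–30 Hz is
≈ 0.05 (bound 0.10).

## Canonical form

(A, C, K) is unique only up to a state-space similarity transform, so raw
matrix entries are meaningless as features. `canonicalize` maps every
realization to a real modal form: A becomes block-diagonal with 1 × 1
blocks for real eigenvalues and 2 × 2 rotation-scaled blocks
[[a, b], [−b, a]] (b > 0) for complex pairs. Modes are ordered by |angle|
(i.e., mode frequency) ascending, then modulus descending — mode frequency
is by far the most stable ordering statistic across noisy re-estimates of
the same signal, which keeps corresponding features in corresponding
columns; modulus-first ordering is available. The residual per-mode freedom
(scale, and rotation inside complex blocks) is pinned by rotating the C
sub-row to (‖c‖, 0) and balancing ‖C‖ against ‖K‖ blockwise with a sign
convention making C's leading entry positive; degenerate blocks (c ≈ 0 or
k ≈ 0) fall back to normalizing whichever is nonzero. Two realizations
related by any well-conditioned invertible transform map to the same
canonical matrices to ~10⁻¹⁴ relative (tested bound 10⁻⁶). Poles on or
outside the unit circle are reflected to 1/|λ| and flagged. Defective A
(Jordan blocks) raises a conditioning error — it cannot occur for
realizations identified from generic data.

Note that canonical (A, C, K) entries are blind to overall amplitude: an
output gain is absorbed by state rescaling and the innovation variance.
Class differences that are pure gain changes are therefore invisible to
these features — a structural property of realization-based features that
shaped the synthetic generator (below).

## Features

- State-space: row-major A entries, then C, then K — m² + 2m values
  (35 at the offline order 5, 15 at the streaming order 3). Epochs are
  FIR-decimated ×4 before identification: with a 2.5–30 Hz passband
  sampled at 1000 Hz the covariance sequence is so smooth that the Hankel
  problem is ill-conditioned; identifying at 250 Hz loses no in-band
  information and substantially improves feature stability. The horizon
  shrinks automatically for windows too short to fill the default Hankel
  matrix.
- AR + wavelet-packet entropy: Burg AR(4) coefficients in the
  prediction-weight sign convention (positive a_k multiply past samples),
  plus Shannon entropies of the 16 terminal nodes of a level-4 wavelet
  packet decomposition (Daubechies-4, periodization; both configurable).
  Entropy uses the normalized squared-coefficient distribution
  p_i = w_i²/Σw² with H = −Σ p_i log₂ p_i (bounded by log₂ of node length,
  scale-invariant, 0·log 0 := 0); the unnormalized −Σw² log w² variant is
  available behind a flag. Both AR and entropy features are
  scale-invariant, matching the state-space features' amplitude blindness.

## Classification and metrics

Bootstrap-aggregated decision trees (100 trees, unlimited depth, Gini
splits, bootstrap size n), with vote ties broken toward the negative
(Predicted/Expected) class to favor specificity. Repeated stratified
cross-validation runs R independent F-fold partitions (default 10 × 10);
held-out predictions are pooled into one confusion table per repetition
and per-repetition metrics are summarized as mean ± sd. Epoch-level folds
are the default; a subject-blocked mode keeps each subject's epochs in one
fold and is recommended whenever between-subject generalization is the
question. Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), accuracy =
(TP+TN)/total, with Unpredicted positive; zero denominators yield NaN plus
an explicit `undefined` flag, never a silent zero.

## Streaming fusion detector

Acceleration (150 Hz) is Savitzky–Golay smoothed and polyphase-resampled to
the EEG rate; EEG is filtered causally (forward-only) since zero-phase
filtering is non-causal. Both are divided by per-subject reference scalars
(maximum magnitude of the first event's analysis window, per signal). The
sweep holds a 256 ms window offset 80 ms from the sweep position and
advances 30 ms; a window whose normalized EEG **or** acceleration maximum
exceeds its threshold (disjunction by default — conjunction is a flag) is
classified from order-3 state-space features of the EEG and acceleration
windows concatenated (2 × 15 values; EEG-only mode available). An
Unexpected verdict records a detection stamped at the window's end time and
advances the sweep 1 s, structurally preventing double counts. Thresholds
are the minimum over Unexpected training events of the within-window
normalized maxima, per signal.

Training windows per event: the aligned response window plus ±30/±60 ms
jittered copies, all labeled by the event's class, and four Expected
context windows (a quiet window ~1.3 s pre-onset, two onset-straddling
windows, one post-response window). The sliding detector must judge
windows at arbitrary offsets, so the classifier needs off-alignment
positives and non-response negatives; without them its verdicts on such
windows are arbitrary, and an early false positive skips the sweep past
the real event. Event-level scoring: a detection whose window overlaps a
true Unpredicted event's response window ([onset+80, onset+336] ms) is a
TP, otherwise an FP; undetected true events are FNs; each supra-threshold
classifier call resolved Expected outside true response windows counts one
TN (window-level negatives — the only reading under which streaming
specificity has a meaningful denominator). Per-iteration compute time is
measured and logged against the 30 ms step budget, not asserted.

## Synthetic cohort generator

The generator emulates a platform-perturbation experiment of the kind the
detector targets: 40 subjects × 34 scheduled
translations with 40 dropouts (1320 completed events), Unpredicted
fraction 435/1320, EEG at 1000 Hz, acceleration at 150 Hz, inter-event
intervals 4–6 s.

- Background EEG: 1/f^α colored noise (α = 1, RMS 10 µV) plus a 10 Hz
  rhythm (0.3 relative RMS, random phase per subject).
- PEP template (per completed event, gated to exactly zero before 80 ms
  post-onset by a smoothstep at 80–95 ms): N1 negativity at 130 ms
  (σ 20 ms) and P2 positivity at 240 ms (σ 35 ms, 0.8 relative amplitude),
  base peak amplitude 20 µV — single-trial PEPs are clearly visible over
  a 10 µV background, and the per-subject normalization reference (first
  event epoch) must reliably exceed background maxima for thresholding to
  behave. Per-event latency jitter ±10 ms.
- Class effect (scaled by `effect_size`, zero ⇒ identical classes):
  Unpredicted responses have amplitude ×(1+e), latency delay 20·min(e,1.5)
  ms (saturated — physiological latency differences are tens of ms), N1
  widening ×(1+e/4), and a phase-locked 18 Hz low-beta burst (Gaussian
  envelope σ 150 ms at 200 ms, amplitude 1.2·e·20 µV). The burst is the
  load-bearing signature: realization features cannot see pure gain
  changes, but an extra oscillatory mode in a band free of both the
  deflections' 3–8 Hz energy and the 10 Hz background appears directly as
  a pole pair of the identified models.
- Onset artifact: a class-independent damped ~8 Hz oscillation (τ 25 ms,
  ~30 µV, random amplitude and phase per event) in the first tens of ms
  after onset — platform jerk and short-latency reflex EMG. It adds
  class-irrelevant variance to the 0–80 ms segment, which is why epochs
  starting at 80 ms classify at least as well as epochs starting at the
  onset.
- Acceleration: trapezoidal-velocity pulse honoring the 20 cm stroke and
  0.2 g ramps. These figures over-determine the 100 cm/s peak velocity —
  0.2 g over 20 cm can reach at most √(a·d) ≈ 62.6 cm/s — so the profile
  caps velocity at the kinematically feasible value (a triangular profile)
  rather than violating the stroke or the ramp limit. White sensor noise
  0.005 g.
- Dropouts are removed uniformly at random; labels are assigned by exact
  count (round of the Unpredicted fraction). Everything derives from one
  integer seed; identical configs give bit-identical cohorts.

What the generator does **not** emulate: multi-channel topography, eye or
muscle artifacts outside the onset window, non-stationary background
(drowsiness, impedance drift), subject-specific PEP shapes, and any
overlap between consecutive responses. Passing tests therefore show that
the pipeline's machinery is correct and well-calibrated under the stated
statistical structure, not that the reported human-data performance would
be reproduced.

## Problem sizes used in tests and the acceptance script

Chance-level calibration uses a balanced zero-effect cohort of 800 events
with 10 × 10 CV (accuracy within [0.45, 0.55]; complex classifiers sit
slightly below 0.5 on null data — the familiar pessimism of
cross-validated overfit models). Effect-size monotonicity compares
effect 0.5 vs 2.0 over 10 paired seeds (sign test); the epoch-window
comparison averages 0 ms- vs 80 ms-start accuracy over 10 seeds; both use
120-event cohorts with 2 × 5 CV. The streaming detector is evaluated on an
8-subject, strong-effect (effect 3) cohort with a 6/2 subject split.
These sizes keep every property measurable with comfortable statistical
margins while the full suite stays in the minutes range.

## Known limitations

- The Riccati fallback yields a K that is consistent but not efficient;
  flagged per-realization.
- Canonicalization assumes diagonalizable A with distinct mode
  frequencies; exact ties are ordered by a rounded lexical key and may be
  unstable under infinitesimal perturbations (not observed on generated
  data).
- The detector's event thresholds (min-of-max) carry no safety margin by
  construction; a validation event whose maxima fall below every training
  event's maxima can fail the candidacy gate. The disjunctive EEG/accel
  trigger makes a joint failure rare.
- Subject-level normalization uses the first event epoch, whose class is
  random; between-subject comparability of normalized amplitudes is
  correspondingly rough. This mirrors the stated protocol rather than an
  optimal design.
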