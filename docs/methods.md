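# Methods

This note documents the models, numerical choices and limitations of the
`fsvmd` package in one place. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Variational mode decomposition (`fsvmd.vmd`)

The solver minimizes the summed bandwidth of K modes subject to
reconstructing the input, where the bandwidth of mode *u_k* is the squared
H1 norm of its analytic representation demodulated by `exp(−jω_k t)`. The
alternating frequency-domain scheme is the classical one: a Wiener-type
mode update with denominator `1 + 2α(ω − ω_k)²`, a center-frequency update
by power-spectrum centroid, and dual ascent with time-step τ on the
reconstruction constraint. Center frequencies are handled in normalized
units internally (so the conventional α ≈ 2000 behaves as users of other
VMD implementations expect) and reported in Hz.

**Real vs. complex path.** Real inputs are processed on the one-sided
spectrum with Hermitian completion at synthesis, and center frequencies lie
in [0, fs/2]. Complex inputs — analytic signals shifted to baseband — use
the full two-sided axis; center frequencies may be negative.

**Boundary handling.** Inputs are extended by half-length mirror reflection
at each end and the extension cropped after synthesis. For complex inputs
the reflected flanks are *conjugated*: plain time reversal negates the
frequency of complex exponentials and would smear a one-sided spectrum
across zero. (This is observable: without conjugation the baseband
decomposition of two close tones leaks ~30 % of the neighbor into the
fundamental mode; with it, leakage drops below 1 %.)

**Initialization.** `zeros` starts all ω_k at 0 (biased toward
low-frequency components; adequate for broadband signals), `uniform` spaces
them as (k/K)·fs/2 — the first mode at DC so low components are not
orphaned — and `random` draws from [0, fs/2) under the run seed. An
explicit `omega_init` override exists for callers that know where the
components sit; the FS-VMD driver uses it (below).

**Convergence.** Iteration stops when Σ_k ‖û_k⁽ⁿ⁺¹⁾ − û_k⁽ⁿ⁾‖²/‖û_k⁽ⁿ⁾‖²
falls below `tol` (default 1e-6) or at `max_iters` (default 500; hitting
the cap warns and sets `converged=False` rather than raising). The reported
per-mode bandwidth σ_k is the square root of the spectral second moment
about ω_k.

## FS-VMD (`fsvmd.fsvmd`)

Each round:

1. **Fundamental estimation** — the dominant Welch-periodogram peak above
   0.5 Hz, refined by parabolic interpolation of the log-spectrum.
   A spectral-flatness guard rejects near-white residuals: flatness is the
   geometric/arithmetic PSD mean ratio computed from short (128-sample)
   Welch segments, because a single long segment has too much estimator
   variance to separate peaked from flat spectra. The default threshold
   0.75 sits between well-averaged white-noise flatness (≈0.8–0.9) and the
   flatness of peaked/1-f EEG-like spectra (≈0.4–0.7). On the first round a
   rejection falls back to plain VMD with a warning; on later rounds it
   ends extraction (the residual has no structure left worth shifting).
2. **Shift** — analytic signal (Hilbert transform) times
   `exp(−j2π f_shift t)` with `f_shift = f₀ − f_target`; the analytic form
   makes the carrier exactly invertible. `f_target` defaults to 1 Hz.
3. **Baseband VMD** — the complex solver with seeded center frequencies:
   the first mode at `f_target`, the remaining K−1 at the strongest
   secondary spectral peaks of the residual (mapped to baseband). The shift
   stage exists precisely because the fundamental's location is known, so
   informed seeding is part of the method, not a tuning knob; with all-zero
   initialization every baseband mode collapses onto the fundamental.
4. **Refinement** — gradient descent on
   `J = Σ_k ∫ |∂_t(u_k e^{−jω_k t})|² + σ_k|u_k|² + α|u_k − s|² dt`,
   discretized with forward differences and the trapezoid rule (time in
   seconds). ∂J/∂σ_k is the mode energy exactly; ∂J/∂ω_k is the exact
   derivative of the discretized smoothness term, so a finite-difference
   check passes at 1e-4 and descent provably reduces J. σ_k is carried as a
   per-mode bandwidth *state* (floored at 1e-3 Hz) — it does not feed back
   into the spectral filter, whose bandwidth is governed by α. Learning
   rate defaults to 1e-3 and is halved whenever J rises five steps in a
   row; persistent divergence returns the best-visited parameters with a
   warning.
5. **Acceptance and subtraction** — modes whose restored center frequency
   lies within ±1 Hz of f₀ are accepted and subtracted from the residual
   (if none lies in the window, the closest mode is taken). The window is
   deliberately *half* the closest component spacing the method is designed
   to resolve (2 Hz): a ±2 Hz window would swallow both members of a
   9/11 Hz pair in round one and reduce the method to plain VMD.

Rounds stop when the residual energy falls below `residual_stop` (default
5 %) of the input energy or after `max_rounds` (default 4) rounds.

## Preprocessing (`fsvmd.preprocess`)

MSPCA wavelet-decomposes each channel (db4, 5 levels, symmetric extension —
each level spans roughly one classical EEG band at 100 Hz), applies PCA per
scale across channels with the Kaiser retention rule (eigenvalue above the
mean; a fraction-of-variance rule is available), reconstructs and inverts.
With every component kept it is the identity to machine precision; the
per-scale projection never increases trial energy.

The shipped 18-channel motor-cortex scheme uses the symmetric 10/20 grid
C5–C6, CP5–CP6, P5–P6 rows (three published electrode names that do not
exist in the extended 10/20 system — "C7", "CP", "Pi" — are mapped to their
montage-consistent neighbors C1, CPz, Pz, and the grid is completed with Cz
and C6 to reach eighteen). The 3-channel scheme is the standard
sensorimotor triplet C3, Cz, C4.

## Features (`fsvmd.features`)

Nine features per (channel, IMF): mean absolute value; approximate entropy
(m=2, r=0.2·SD, the literature-standard setting, classic definition with
self-matches); relative μ (8–12 Hz) and β (13–30 Hz) power and their ratio;
average μ-band power; energy; Shannon entropy of the normalized per-sample
energy distribution (the signal-level reading of "uncertainty"; a histogram
variant would need a binning rule the source formulation does not supply);
and mean Teager–Kaiser energy. The L2 norm is exported as a function but
excluded from the default table because it is exactly √energy. PSDs use
1-s Hann Welch segments with 50 % overlap, giving ≥3 segments per 3.5-s
trial. Zero (padded) modes produce all-zero features; an infinite μ/β ratio
(zero β power) is mapped to 0 in tables to keep them NaN/Inf-free.

## Selection (`fsvmd.selection`)

iRelief uses the soft-neighbor reading of iterative Relief: features are
z-scored; the weighted L1 distance defines, per sample, the k=5 nearest
hits and misses; their contributions are softened by a Gaussian kernel of
width σ=2 on the distances; weights move along the expected margin with
learning rate η=0.001, are clipped at zero and max-normalized; iteration
stops at an L1 weight change below θ=0.01 or at 100 iterations. All samples
are used each iteration (the "sample size" of the published configuration
is left open; datasets here are small). FCBF and the information-gain
ratio discretize features into 10 equal-frequency bins (robust to heavy
tails). Binary PSO follows the standard sigmoid-transfer scheme with the
published swarm settings (10 particles, c1=c2=2, v_max=6, inertia
0.9→0.4); fitness is mean CV accuracy of a supplied classifier.

## Classification and evaluation (`fsvmd.classify`)

FWkNN z-scores by training statistics and uses weighted Euclidean distance
(the Relief-family weighting plugs in directly); vote ties break by smaller
summed distance, then lower class id; k defaults to 5, matching iRelief's
neighborhood. The RBF-SVM is a thin adapter over scikit-learn's SVC with
`gamma = 1/(n_features·var)`. Evaluation uses stratified splits (classes
are balanced by design, making stratification the faithful protocol):
80/20 holdout and 5-fold CV with accuracy, sensitivity, specificity,
precision, F1 and Cohen's κ; the positive class defaults to the
lexicographically last label ("RH" — right hand — in the simulations) and
is configurable. Per-fold values, their mean and their population SD are
reported alongside pooled out-of-fold metrics; the SD across folds is the
spread measure (repeated-run SD can be obtained by reseeding).

## Synthetic data (`fsvmd.synthetic`)

`gen_mi_eeg` emulates the standard two-class MI recording conditions:
100 Hz sampling, 3.5-s trials, 140 trials per class, C3/Cz/C4 montage.
Each trial and channel is 1/f background (exponent 1, unit variance) + a μ
oscillator (10 ± 0.5 Hz jitter, amplitude 1) + a β oscillator (20 ± 0.5 Hz,
amplitude 0.5) + white noise (SD 0.5). ERD is modeled as a class-dependent
attenuation of the μ amplitude on the contralateral channel (right-hand
trials attenuate C3; right-foot trials attenuate C4, a deliberate
simplification — foot representation is actually medial); `erd_depth=0.8`
is a strong, clearly decodable effect, `erd_depth=0` an exact null in
which both classes are generated from the same distribution. The generator
does **not** simulate volume conduction, inter-trial nonstationarity,
artifacts (EOG/EMG) or inter-subject variability, so pipeline accuracies on
it say nothing about absolute accuracy on recorded EEG — the null case and
the monotonicity in `erd_depth` are the meaningful calibration checks.

## Pipeline profile and problem sizes

Batch decomposition of hundreds of trials uses the same method parameters
(K=4, α=2000, τ=0, tol=1e-6) with bounded budgets — 50 solver iterations,
6 refinement steps, 3 extraction rounds per signal — which this package
treats as its standard batch profile; single-signal analyses default to
the unbounded profile (500 iterations, 4 rounds). Accepted modes are
standardized to 4 per (trial, channel) — highest energy kept, zero-padded
if fewer — because the feature table requires a uniform mode count.
MSPCA is off by default in the pipeline driver: per-scale PCA assumes the
informative activity is shared across many channels, and on a 3-channel
montage the Kaiser rule keeps only the dominant shared component,
discarding exactly the lateralized (channel-differential) ERD contrast the
classifier needs. It remains available via configuration for many-channel
recordings. Feature selection (iRelief, top 30 of 108 columns) runs
*inside* each CV training fold via a scikit-learn `Pipeline`, so the
chance-level null calibration genuinely guards against selection leakage.
Calibration checks use 140 trials/class for the strong-effect case and
100 trials/class (20 seeds) for the null.

## Known limitations

* The fundamental estimator assumes a single dominant peak; signals with
  two equal-power components resolve them over successive rounds, but the
  first-round shift may sit between them when peaks are within the Welch
  resolution.
* The flatness guard's 0.75 threshold is calibrated for 100-Hz-class
  signals of a few hundred samples; very long signals have higher
  white-noise flatness and keep a comfortable margin, but heavily
  oversampled inputs should be decimated first.
* σ_k is descriptive state: the printed bandwidth gradient always points
  downward (it equals the mode energy), so under refinement σ_k decreases
  to its floor unless the caller uses it only as a diagnostic.
* Complex-path and real-path VMD treat boundaries differently (conjugate
  mirror of the analytic signal vs. mirror of the real signal), so a
  zero-shift FS-VMD run agrees with plain VMD only to about a percent near
  the edges, not to machine precision.
* `EvalReport` rates are binary-oriented (one positive class); multi-class
  inputs are accepted but sensitivity/specificity then refer to the chosen
  positive class against the rest.
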