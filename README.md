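# fsvmd — frequency-shifting variational mode decomposition for EEG

`fsvmd` is a signal-decomposition library for electroencephalography (EEG)
and other narrowband-mixture signals, built around **FS-VMD**: variational
mode decomposition applied *at baseband* after analytic-signal frequency
shifting. Around the decomposition it provides the full motor-imagery (MI)
brain–computer-interface classification pipeline: multiscale-PCA denoising,
motor-cortex channel selection, per-IMF feature extraction, Relief-family
feature weighting, and weighted-kNN / RBF-SVM classification under
stratified cross-validation — plus a seeded generator of two-class MI-like
EEG with event-related desynchronization (ERD) structure for end-to-end
testing without any external data.

## The method

Classical VMD decomposes a signal *x(t)* into *K* narrowband intrinsic mode
functions *u_k(t)* with center frequencies *ω_k* by alternating, in the
frequency domain,

* a Wiener-type mode update
  `û_k(ω) = (x̂(ω) − Σ_{i≠k} û_i(ω) + λ̂(ω)/2) / (1 + 2α(ω − ω_k)²)`,
* a center-frequency update (power-spectrum centroid), and
* dual ascent on the reconstruction constraint (time-step τ).

When two components are closely spaced, the joint decomposition mixes them.
FS-VMD instead extracts components sequentially: each round estimates the
fundamental frequency *f₀* of the current residual, forms the analytic
signal and multiplies by `exp(−j2π(f₀ − f_target)t)` so the fundamental sits
near baseband, runs VMD on the complex baseband series, refines each mode's
center frequency and bandwidth state by gradient descent on a
smoothness-plus-fidelity cost *J*, reshifts the modes with the conjugate
carrier (`u_k'(t) = u_k(t)·exp(+j2πf_shift t)`), accepts the mode(s) in the
fundamental band, and subtracts them from the residual. On a 9 Hz / 11 Hz
two-tone mixture this sequential scheme yields a strictly lower pairwise
spectral-overlap (mode-mixing) index than plain VMD with identical solver
settings.

## Worked example

```python
import numpy as np
from fsvmd import FSVMDConfig, VMDConfig, fs_vmd, vmd, mode_mixing_index
from fsvmd.synthetic import gen_tones

rec, truth = gen_tones([(9.0, 1.0, 0.0), (11.0, 0.8, 0.0)],
                       fs=100, duration=10, noise_sd=0.1, seed=0)
x = rec.data[:, 0]

cfg = FSVMDConfig(vmd=VMDConfig(K=2, alpha=2000, tau=0.0, tol=1e-6))
ms = fs_vmd(x, 100.0, cfg)
print("centers:", np.round(ms.omega, 3))
print("mixing:", round(mode_mixing_index(ms), 5),
      "vs plain VMD:", round(mode_mixing_index(vmd(x, 100.0, cfg.vmd)), 5))
```

prints

```
centers: [ 9.     11.003]
mixing: 0.0017 vs plain VMD: 0.00524
```

— the two tones, 2 Hz apart at 100 Hz sampling, are recovered with center
frequencies within a few mHz, and the spectral overlap between the two
extracted modes is about 3× lower than plain VMD's on the same noisy
mixture.

The end-to-end pipeline runs from the command line:

```bash
fsvmd pipeline --seed 0 --trials-per-class 20 --erd-depth 0.8 --out run/
# cv accuracy 0.9750 (fold SD 0.0500) -> run/report.json
```

which simulates a two-class ERD dataset (μ-rhythm attenuation contralateral
to the imagined movement), decomposes every trial and channel with FS-VMD,
extracts nine features per (channel, IMF), and reports stratified five-fold
CV metrics for an iRelief-selected RBF-SVM. `run/manifest.json` records the
full configuration and seed for exact reproduction.

## Layout

| module | contents |
| --- | --- |
| `fsvmd.containers` | `Recording`, `TrialSet`, `ModeSet`, `FeatureTable` … |
| `fsvmd.io` | csv+header / mat-container readers, epoching, mode-set files |
| `fsvmd.vmd` | the variational solver (real and complex/baseband paths) |
| `fsvmd.fsvmd` | fundamental estimation, shifting, refinement, FS-VMD loop |
| `fsvmd.preprocess` | MSPCA denoising, 18-channel / 3-channel schemes |
| `fsvmd.features` | per-IMF time/frequency/nonlinear features |
| `fsvmd.selection` | iRelief, FCBF, info-gain ratio, binary PSO (sklearn API) |
| `fsvmd.classify` | FWkNN, RBF-SVM adapter, holdout/CV evaluation |
| `fsvmd.synthetic` | seeded tone/chirp/MI-EEG generators |
| `fsvmd.cli`, `fsvmd.pipeline` | `fsvmd` command and the end-to-end driver |

See `docs/methods.md` for the model details, parameter choices and known
limitations.
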