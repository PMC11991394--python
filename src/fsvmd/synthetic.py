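"""Seeded synthetic-signal generators for decomposition and pipeline tests.

Three generators:

* :func:`gen_tones` — exact sinusoid mixtures plus Gaussian noise, with the
  noise-free components returned as ground truth (decomposition fixtures);
* :func:`gen_chirp_plus_tone` — a linear chirp crossing a stationary tone
  (mode-mixing fixtures);
* :func:`gen_mi_eeg` — two-class motor-imagery-like EEG with event-related
  desynchronization (ERD) structure: every channel carries a 1/f background,
  a mu (~10 Hz) and a beta (~20 Hz) oscillator plus white noise, and the mu
  amplitude is attenuated by ``erd_depth`` on the class-dependent
  contralateral channel (class "RH" on C3, class "RF" on C4).

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .containers import Recording, TrialSet

__all__ = ["gen_tones", "gen_chirp_plus_tone", "MISimConfig", "gen_mi_eeg"]


def gen_tones(
    spec: list[tuple[float, float, float]],
    fs: float = 100.0,
    duration: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, np.ndarray]:
    """Sum of sinusoids ``(freq_hz, amplitude, phase_rad)`` plus noise.

    Returns the single-channel Recording and the ground-truth components as
    an array ``[n_components, n_samples]`` (empty spec gives pure noise).
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    comps = np.array(
        [a * np.cos(2 * np.pi * f * t + ph) for f, a, ph in spec]
    ).reshape(len(spec), n)
    x = comps.sum(axis=0) if len(spec) else np.zeros(n)
    x = x + noise_sd * rng.standard_normal(n)
    return Recording(x[:, None], fs, ["SIG"]), comps


def gen_chirp_plus_tone(
    f_start: float = 5.0,
    f_end: float = 15.0,
    tone_hz: float = 20.0,
    tone_amp: float = 1.0,
    chirp_amp: float = 1.0,
    fs: float = 100.0,
    duration: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, dict]:
    """Linear chirp (``f_start`` -> ``f_end``) plus a stationary tone.

    Ground truth holds the two components and the chirp's instantaneous
    frequency track.
    """
    from scipy.signal import chirp as _chirp

    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    c = chirp_amp * _chirp(t, f0=f_start, f1=f_end, t1=duration, method="linear")
    tone = tone_amp * np.cos(2 * np.pi * tone_hz * t)
    x = c + tone + noise_sd * rng.standard_normal(n)
    truth = {
        "chirp": c,
        "tone": tone,
        "instantaneous_freq": f_start + (f_end - f_start) * t / duration,
    }
    return Recording(x[:, None], fs, ["SIG"]), truth


@dataclass
class MISimConfig:
    """Two-class motor-imagery EEG simulation settings.

    Defaults emulate the standard MI recording conditions: 100 Hz sampling,
    3.5 s trials, 140 trials per class, the C3/Cz/C4 sensorimotor montage.
    ``erd_depth`` in [0, 1] is the class-dependent attenuation of the mu
    amplitude on the contralateral channel (0 = classes identical);
    ``ers_boost`` optionally adds the symmetric beta enhancement.
    """

    fs: float = 100.0
    trial_s: float = 3.5
    n_trials_per_class: int = 140
    channels: list[str] = field(default_factory=lambda: ["C3", "Cz", "C4"])
    mu_amp: float = 1.0
    beta_amp: float = 0.5
    mu_hz: float = 10.0
    beta_hz: float = 20.0
    freq_jitter: float = 0.5
    erd_depth: float = 0.8
    ers_boost: float = 0.0
    noise_sd: float = 0.5
    background_exponent: float = 1.0
    background_amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.erd_depth <= 1:
            raise ValueError("erd_depth must lie in [0, 1]")
        if self.n_trials_per_class < 10:
            raise ValueError("need at least 10 trials per class")


def _one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent amplitude spectrum."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.ones_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def gen_mi_eeg(config: MISimConfig | None = None) -> TrialSet:
    """Simulate a balanced two-class ERD motor-imagery trial set.

    Class ``"RH"`` (right hand) attenuates the mu oscillator on C3, class
    ``"RF"`` (right foot) on C4; trials are interleaved RH/RF and every
    random draw comes from the config seed.
    """
    config = config or MISimConfig()
    upper = [c.upper() for c in config.channels]
    if "C3" not in upper or "C4" not in upper:
        raise ValueError("channel set must include C3 and C4")
    rng = np.random.default_rng(config.seed)
    n = int(round(config.trial_s * config.fs))
    t = np.arange(n) / config.fs
    n_trials = 2 * config.n_trials_per_class
    labels = np.array(["RH", "RF"] * config.n_trials_per_class)
    erd_channel = {"RH": upper.index("C3"), "RF": upper.index("C4")}

    trials = np.empty((n_trials, len(config.channels), n))
    for i in range(n_trials):
        lab = labels[i]
        for c in range(len(config.channels)):
            mu_f = config.mu_hz + rng.uniform(-config.freq_jitter,
                                              config.freq_jitter)
            beta_f = config.beta_hz + rng.uniform(-config.freq_jitter,
                                                  config.freq_jitter)
            mu_a = config.mu_amp
            beta_a = config.beta_amp
            if c == erd_channel[lab]:
                mu_a *= 1.0 - config.erd_depth
                beta_a *= 1.0 + config.ers_boost
            sig = (
                config.background_amp
                * _one_over_f(rng, n, config.background_exponent)
                + mu_a * np.cos(2 * np.pi * mu_f * t + rng.uniform(0, 2 * np.pi))
                + beta_a * np.cos(2 * np.pi * beta_f * t + rng.uniform(0, 2 * np.pi))
                + config.noise_sd * rng.standard_normal(n)
            )
            trials[i, c] = sig
    return TrialSet(trials, labels, config.fs, list(config.channels))
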