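"""Frequency-shifting variational mode decomposition (FS-VMD).

The method targets mode mixing between closely spaced oscillations.  Instead
of decomposing the raw signal jointly, it works round by round:

1. estimate the fundamental (dominant) frequency :math:`f_0` of the current
   residual from its Welch periodogram;
2. form the analytic signal and multiply by the carrier
   :math:`e^{-j 2\\pi f_{\\mathrm{shift}} t}` with
   :math:`f_{\\mathrm{shift}} = f_0 - f_{\\mathrm{target}}`, moving the
   fundamental down to a low-frequency band where it is maximally separated
   from the remaining spectrum on a relative scale;
3. run VMD on the complex baseband series;
4. refine the per-mode center frequencies and bandwidth states by gradient
   descent on a smoothness + fidelity cost;
5. reshift the modes with the conjugate carrier (restoring their original
   band), accept the mode(s) that landed in the fundamental band, and
   subtract them from the residual.

Rounds continue until the residual energy falls below a configured fraction
of the input energy or the round budget is exhausted.  Working on the
analytic signal (one-sided spectrum) keeps the carrier multiplication
exactly invertible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import hilbert, welch

from .containers import ModeSet, TrialSet
from .vmd import VMDConfig, vmd

__all__ = [
    "ShiftState",
    "GradientConfig",
    "FSVMDConfig",
    "estimate_fundamental",
    "shift",
    "unshift",
    "cost_and_gradients",
    "refine_parameters",
    "fs_vmd",
    "decompose_trials",
    "DecompositionResult",
    "standardize_mode_count",
]


@dataclass
class ShiftState:
    """Carrier bookkeeping for one shift: ``f_shift`` in Hz, and direction."""

    f_shift: float
    fs: float

    @property
    def direction(self) -> str:
        return "down" if self.f_shift >= 0 else "up"


@dataclass
class GradientConfig:
    """Gradient-descent settings for the parameter-refinement stage.

    ``eta`` is the learning rate (halved on persistent divergence),
    ``alpha_cost`` the fidelity weight in the cost, ``sigma_floor`` the
    smallest admissible bandwidth state in Hz.
    """

    eta: float = 1e-3
    alpha_cost: float = 2000.0
    max_steps: int = 50
    step_tol: float = 1e-8
    sigma_floor: float = 1e-3

    def __post_init__(self) -> None:
        if self.eta < 0:
            raise ValueError("eta must be non-negative")


@dataclass
class FSVMDConfig:
    """Full FS-VMD configuration.

    ``target_baseband_hz`` is where the fundamental is moved before
    decomposition; ``band_halfwidth_hz`` the half-width of the acceptance
    window around the restored fundamental; ``residual_stop`` the residual
    energy fraction below which extraction stops.
    """

    vmd: VMDConfig = field(default_factory=VMDConfig)
    grad: GradientConfig = field(default_factory=GradientConfig)
    target_baseband_hz: float = 1.0
    max_rounds: int = 4
    residual_stop: float = 0.05
    band_halfwidth_hz: float = 1.0
    flatness_threshold: float = 0.75

    def __post_init__(self) -> None:
        if self.target_baseband_hz < 0:
            raise ValueError("target_baseband_hz must be >= 0")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")


def estimate_fundamental(
    signal: np.ndarray,
    fs: float,
    *,
    fmin: float = 0.5,
    flatness_threshold: float = 0.75,
) -> float:
    """Dominant-peak frequency of the Welch periodogram, in Hz.

    The peak above ``fmin`` is refined by parabolic interpolation of the
    log-spectrum.  Near-white inputs (spectral flatness above the threshold)
    have no meaningful fundamental and raise ``ValueError``.
    """
    x = np.asarray(signal, dtype=float)
    nperseg = min(len(x), 512)
    f, p = welch(x, fs=fs, nperseg=nperseg)
    band = f >= fmin
    if not np.any(band) or np.all(p[band] <= 0):
        raise ValueError("no dominant fundamental: empty or degenerate spectrum")
    pb = p[band]
    fb = f[band]
    # flatness from short, well-averaged segments (a single long segment has
    # too much estimator variance to separate peaked from white spectra)
    ff, pf = welch(x, fs=fs, nperseg=min(len(x), 128))
    pf = pf[ff >= fmin]
    with np.errstate(divide="ignore"):
        flatness = np.exp(np.mean(np.log(pf + 1e-300))) / np.mean(pf)
    if flatness > flatness_threshold:
        raise ValueError(
            f"no dominant fundamental: spectral flatness {flatness:.2f} "
            f"exceeds {flatness_threshold}"
        )
    i = int(np.argmax(pb))
    if 0 < i < len(pb) - 1:
        # parabolic interpolation on the log-spectrum
        la, lb, lc = np.log(pb[i - 1 : i + 2] + 1e-300)
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
    else:
        delta = 0.0
    df = fb[1] - fb[0]
    return float(fb[i] + delta * df)


def _secondary_peaks(
    signal: np.ndarray,
    fs: float,
    f0: float,
    n_peaks: int,
    exclude_hz: float,
) -> list[float]:
    """Largest non-fundamental Welch-spectrum peaks, for mode seeding."""
    if n_peaks <= 0:
        return []
    from scipy.signal import find_peaks

    x = np.asarray(signal, dtype=float)
    f, p = welch(x, fs=fs, nperseg=min(len(x), 512))
    idx, _ = find_peaks(p)
    idx = idx[np.abs(f[idx] - f0) >= exclude_hz]
    idx = idx[np.argsort(p[idx], kind="stable")[::-1]]
    chosen: list[float] = []
    for i in idx:
        if all(abs(f[i] - c) >= 1.0 for c in chosen):
            chosen.append(float(f[i]))
        if len(chosen) == n_peaks:
            break
    # fall back to an even spread above the fundamental when the spectrum
    # offers too few distinct peaks
    k = 0
    while len(chosen) < n_peaks:
        k += 1
        cand = f0 + exclude_hz + k * (fs / 2 - f0 - exclude_hz) / (n_peaks + 1)
        chosen.append(float(np.clip(cand, 0, fs / 2)))
    return chosen


def shift(
    signal: np.ndarray, f_shift: float, fs: float
) -> tuple[np.ndarray, ShiftState]:
    """Analytic signal multiplied by ``exp(-j 2 pi f_shift t)``.

    Spectral mass near ``f_shift`` moves to near 0 Hz.  The transform is
    exactly invertible by :func:`unshift` because the analytic signal's
    spectrum is one-sided.
    """
    if abs(f_shift) >= fs / 2:
        raise ValueError("|f_shift| must be below the Nyquist frequency")
    x = np.asarray(signal, dtype=float)
    z = hilbert(x)
    t = np.arange(len(x)) / fs
    return z * np.exp(-2j * np.pi * f_shift * t), ShiftState(f_shift, fs)


def unshift(modes: ModeSet, state: ShiftState) -> ModeSet:
    """Reshift baseband modes to their original band (conjugate carrier).

    Each mode is multiplied by ``exp(+j 2 pi f_shift t)``; the real part is
    taken and ``f_shift`` is added to every stored center frequency.
    """
    if modes.n_modes == 0 or modes.modes.size == 0:
        raise ValueError("cannot unshift an empty ModeSet")
    if not modes.baseband:
        raise ValueError("ModeSet is not at baseband (already unshifted?)")
    t = np.arange(modes.n_samples) / state.fs
    carrier = np.exp(2j * np.pi * state.f_shift * t)
    restored = np.real(modes.modes * carrier[None, :])
    return ModeSet(
        restored,
        modes.omega + state.f_shift,
        modes.sigma.copy(),
        modes.fs,
        modes.n_iters,
        modes.residual,
        modes.converged,
        baseband=False,
    )


def _smoothness_terms(
    u: np.ndarray, f_hz: float, t: np.ndarray, dt: float
) -> tuple[float, float]:
    """H1 smoothness of the demodulated mode and its df-derivative.

    Forward differences for the time derivative, trapezoid rule for the
    integral; time axis in seconds.
    """
    v = u * np.exp(-2j * np.pi * f_hz * t)
    d = np.diff(v) / dt
    term = float(np.trapezoid(np.abs(d) ** 2, dx=dt))
    # d/df of the forward difference: each v_n picks up -j*2*pi*t_n
    dv = -2j * np.pi * t * v
    dd = np.diff(dv) / dt
    grad = float(np.trapezoid(2.0 * np.real(np.conj(d) * dd), dx=dt))
    return term, grad


def cost_and_gradients(
    modes: ModeSet,
    target: np.ndarray,
    grad: GradientConfig,
    omega: np.ndarray | None = None,
    sigma: np.ndarray | None = None,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Refinement cost J and its gradients w.r.t. center frequency/bandwidth.

    .. math::

        J = \\sum_k \\int \\big|\\partial_t[u_k e^{-j\\omega_k t}]\\big|^2
            + \\sigma_k |u_k|^2
            + \\alpha |u_k - s|^2 \\; dt

    so that :math:`\\partial J/\\partial\\sigma_k = \\int |u_k|^2 dt` — the
    mode energy — and :math:`\\partial J/\\partial\\omega_k` is the exact
    derivative of the discretized smoothness term (forward differences +
    trapezoid rule).  Returns ``(J, dJ_domega, dJ_dsigma)``; gradients are in
    per-Hz units.
    """
    omega = modes.omega if omega is None else omega
    sigma = modes.sigma if sigma is None else sigma
    s = np.asarray(target)
    dt = 1.0 / modes.fs
    t = np.arange(modes.n_samples) * dt
    K = modes.n_modes
    j_total = 0.0
    d_omega = np.zeros(K)
    d_sigma = np.zeros(K)
    for k in range(K):
        u = modes.modes[k]
        term, g = _smoothness_terms(u, omega[k], t, dt)
        energy = float(np.trapezoid(np.abs(u) ** 2, dx=dt))
        fid = float(np.trapezoid(np.abs(u - s) ** 2, dx=dt))
        j_total += term + sigma[k] * energy + grad.alpha_cost * fid
        d_omega[k] = g
        d_sigma[k] = energy
    return j_total, d_omega, d_sigma


def refine_parameters(
    modes: ModeSet, target: np.ndarray, grad: GradientConfig
) -> ModeSet:
    """Gradient-descent refinement of per-mode center frequencies/bandwidths.

    Iterates ``omega_k -= eta * dJ/domega_k`` and ``sigma_k -= eta *
    dJ/dsigma_k`` (the latter floored at ``sigma_floor``) until the largest
    parameter step falls below ``step_tol`` or ``max_steps`` is reached.  If
    J increases for five consecutive steps the learning rate is halved and
    the best parameters restored; persistent divergence returns the best
    visited state with a warning.
    """
    if len(np.asarray(target)) != modes.n_samples:
        raise ValueError("modes and target must have the same length")
    omega = modes.omega.astype(float).copy()
    sigma = modes.sigma.astype(float).copy()
    if grad.eta == 0 or grad.max_steps == 0:
        return ModeSet(modes.modes.copy(), omega, sigma, modes.fs,
                       modes.n_iters, modes.residual, modes.converged,
                       modes.baseband)

    eta = grad.eta
    j_best, _, _ = cost_and_gradients(modes, target, grad, omega, sigma)
    best = (omega.copy(), sigma.copy())
    j_prev = j_best
    bad_streak = 0
    halvings = 0
    for _ in range(grad.max_steps):
        j_cur, d_om, d_sig = cost_and_gradients(modes, target, grad, omega, sigma)
        if j_cur < j_best:
            j_best = j_cur
            best = (omega.copy(), sigma.copy())
        if j_cur > j_prev:
            bad_streak += 1
            if bad_streak >= 5:
                eta /= 2.0
                halvings += 1
                omega, sigma = best[0].copy(), best[1].copy()
                bad_streak = 0
                if halvings > 10:
                    warnings.warn(
                        "parameter refinement diverged; returning best-so-far",
                        RuntimeWarning, stacklevel=2,
                    )
                    break
                j_prev = j_best
                continue
        else:
            bad_streak = 0
        j_prev = j_cur
        step_om = eta * d_om
        step_sig = eta * d_sig
        omega = omega - step_om
        sigma = np.maximum(sigma - step_sig, grad.sigma_floor)
        if max(np.abs(step_om).max(initial=0.0),
               np.abs(step_sig).max(initial=0.0)) < grad.step_tol:
            break
    j_final, _, _ = cost_and_gradients(modes, target, grad, omega, sigma)
    if j_final > j_best:
        omega, sigma = best
    return ModeSet(modes.modes.copy(), omega, sigma, modes.fs,
                   modes.n_iters, modes.residual, modes.converged,
                   modes.baseband)


def fs_vmd(signal: np.ndarray, fs: float, config: FSVMDConfig | None = None) -> ModeSet:
    """Full FS-VMD decomposition of one real series.

    Returns all accepted modes ordered by ascending center frequency; the
    ``residual`` field holds the relative L2 norm of what is left
    unexplained, and ``residual_signal_`` (attached attribute) the residual
    series itself.
    """
    config = config or FSVMDConfig()
    x = np.asarray(signal, dtype=float)
    e0 = float(np.sum(x**2))
    residual = x.copy()
    acc_modes: list[np.ndarray] = []
    acc_omega: list[float] = []
    acc_sigma: list[float] = []
    n_iters = 0

    for rnd in range(config.max_rounds):
        try:
            f0 = estimate_fundamental(
                residual, fs, flatness_threshold=config.flatness_threshold
            )
        except ValueError:
            if rnd == 0:
                warnings.warn(
                    "no dominant fundamental; falling back to plain VMD",
                    RuntimeWarning, stacklevel=2,
                )
                ms = vmd(x, fs, config.vmd)
                ms.residual_signal_ = x - ms.reconstruction()  # type: ignore[attr-defined]
                return ms
            break

        f_shift = f0 - config.target_baseband_hz
        z, state = shift(residual, f_shift, fs)
        # seed the baseband solver: first mode at the shifted fundamental,
        # remaining modes at the strongest secondary spectral peaks
        peaks = _secondary_peaks(
            residual, fs, f0, config.vmd.K - 1, config.band_halfwidth_hz
        )
        omega_init = tuple(
            [config.target_baseband_hz] + [p - f_shift for p in peaks]
        )
        from dataclasses import replace as _replace

        round_cfg = _replace(config.vmd, omega_init=omega_init)
        ms = vmd(z, fs, round_cfg)
        n_iters += ms.n_iters
        ms = refine_parameters(ms, z, config.grad)
        ms = unshift(ms, state)

        in_band = np.abs(ms.omega - f0) < config.band_halfwidth_hz
        if not np.any(in_band):
            in_band = np.zeros(ms.n_modes, dtype=bool)
            in_band[int(np.argmin(np.abs(ms.omega - f0)))] = True
        for k in np.nonzero(in_band)[0]:
            acc_modes.append(np.real(ms.modes[k]))
            acc_omega.append(float(ms.omega[k]))
            acc_sigma.append(float(ms.sigma[k]))
            residual = residual - np.real(ms.modes[k])
        if e0 == 0 or float(np.sum(residual**2)) < config.residual_stop * e0:
            break

    rel = float(np.linalg.norm(residual) / np.linalg.norm(x)) if e0 > 0 else 0.0
    out = ModeSet(
        np.asarray(acc_modes),
        np.asarray(acc_omega),
        np.asarray(acc_sigma),
        fs,
        n_iters,
        rel,
        True,
        baseband=False,
    ).sorted_by_omega()
    out.residual_signal_ = residual  # type: ignore[attr-defined]
    return out


def mode_mixing_index(modes: ModeSet) -> float:
    """Mean pairwise spectral overlap between modes (0 = perfectly disjoint).

    For each pair the normalized inner product of the magnitude spectra of
    the (real) modes is computed; the index is the mean over pairs.  A single
    mode yields 0.
    """
    spectra = [np.abs(np.fft.rfft(np.real(m))) for m in modes.modes]
    overlaps = []
    for i in range(len(spectra)):
        for j in range(i + 1, len(spectra)):
            ni = np.linalg.norm(spectra[i])
            nj = np.linalg.norm(spectra[j])
            if ni > 0 and nj > 0:
                overlaps.append(float(np.dot(spectra[i], spectra[j]) / (ni * nj)))
    return float(np.mean(overlaps)) if overlaps else 0.0


@dataclass
class DecompositionResult:
    """Batch output: ``modesets[trial][channel]`` plus failure bookkeeping."""

    modesets: list
    failures: list

    def __iter__(self):
        return iter(self.modesets)


def decompose_trials(
    trials: TrialSet, config: FSVMDConfig | None = None, *, verbose: bool = False
) -> DecompositionResult:
    """Channel-wise FS-VMD of every trial.

    Per-(trial, channel) failures are recorded (``(trial, channel,
    message)``) without aborting the batch; the corresponding slot holds
    ``None``.
    """
    config = config or FSVMDConfig()
    out: list[list[ModeSet | None]] = []
    failures: list[tuple[int, int, str]] = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for i in range(trials.n_trials):
            row: list[ModeSet | None] = []
            for c in range(trials.n_channels):
                try:
                    row.append(fs_vmd(trials.trials[i, c], trials.fs, config))
                except Exception as exc:  # noqa: BLE001 - batch isolation
                    row.append(None)
                    failures.append((i, c, str(exc)))
            out.append(row)
            if verbose and (i + 1) % 25 == 0:
                print(f"decomposed {i + 1}/{trials.n_trials} trials")
    return DecompositionResult(out, failures)


def standardize_mode_count(result: DecompositionResult, n_modes: int) -> DecompositionResult:
    """Trim/pad every ModeSet to exactly ``n_modes`` modes.

    Keeps the ``n_modes`` highest-energy modes (then reorders by center
    frequency); pads with zero modes when fewer were extracted.  Feature
    extraction requires a uniform mode count across trials.
    """
    fixed = []
    for row in result.modesets:
        new_row = []
        for ms in row:
            if ms is None:
                new_row.append(None)
                continue
            energies = np.sum(np.abs(ms.modes) ** 2, axis=1)
            keep = np.sort(np.argsort(energies, kind="stable")[::-1][:n_modes])
            modes = ms.modes[keep]
            omega = ms.omega[keep]
            sigma = ms.sigma[keep]
            if len(keep) < n_modes:
                pad = n_modes - len(keep)
                modes = np.vstack([modes, np.zeros((pad, ms.n_samples))])
                omega = np.concatenate([omega, np.zeros(pad)])
                sigma = np.concatenate([sigma, np.zeros(pad)])
            new_row.append(
                ModeSet(modes, omega, sigma, ms.fs, ms.n_iters,
                        ms.residual, ms.converged, ms.baseband).sorted_by_omega()
            )
        fixed.append(new_row)
    return DecompositionResult(fixed, list(result.failures))
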