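"""Variational mode decomposition (VMD).

Decomposes a series into K narrowband intrinsic mode functions (IMFs) by
minimizing the summed bandwidth of the modes subject to reconstructing the
input.  Bandwidth of mode :math:`u_k` is measured as the squared H1 norm of
its analytic representation demodulated to baseband,
:math:`\\|\\partial_t[u_k^+(t) e^{-j\\omega_k t}]\\|^2`, weighted by the
balancing parameter ``alpha``; exact reconstruction is (optionally) enforced
through a dual variable updated by ascent with time-step ``tau``.

The solver alternates, entirely in the frequency domain:

* mode update — Wiener-type filtering
  :math:`\\hat u_k = (\\hat f - \\sum_{i \\ne k}\\hat u_i + \\hat\\lambda/2)
  / (1 + 2\\alpha(\\omega - \\omega_k)^2)`;
* center-frequency update — power-spectrum centroid of the mode;
* dual ascent — :math:`\\hat\\lambda \\leftarrow \\hat\\lambda +
  \\tau(\\hat f - \\sum_k \\hat u_k)`.

Real inputs are handled classically on the one-sided spectrum (center
frequencies in ``[0, fs/2]``); complex inputs — e.g. analytic signals that
have been frequency-shifted to baseband — use the full two-sided spectrum and
may have negative center frequencies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import ModeSet

__all__ = ["VMDConfig", "vmd", "mirror_extend", "crop_extension"]


@dataclass
class VMDConfig:
    """Solver parameters.

    Parameters
    ----------
    K : int
        Number of modes to extract.
    alpha : float
        Balance between data fidelity and mode bandwidth (larger = narrower
        modes).  Default 2000.
    tau : float
        Dual-ascent time step; 0 disables strict reconstruction enforcement.
    tol : float
        Convergence threshold on the summed relative change of the modes.
    init : {"zeros", "uniform", "random"}
        Center-frequency initialization.
    dc : bool
        Pin the first mode's center frequency at 0.
    max_iters : int
        Iteration cap; non-convergence at the cap is flagged, not raised.
    seed : int
        Seed for ``init="random"``.
    omega_init : sequence of float, optional
        Explicit initial center frequencies in Hz; overrides ``init`` when
        given (used by the FS-VMD driver, which knows where the shifted
        fundamental sits).
    """

    K: int = 4
    alpha: float = 2000.0
    tau: float = 0.0
    tol: float = 1e-6
    init: str = "zeros"
    dc: bool = False
    max_iters: int = 500
    seed: int = 0
    omega_init: tuple | None = None

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.tau < 0:
            raise ValueError("tau must be non-negative")
        if self.tol <= 0:
            raise ValueError("tol must be positive")
        if self.init not in ("zeros", "uniform", "random"):
            raise ValueError(f"unknown init {self.init!r}")


def mirror_extend(signal: np.ndarray) -> np.ndarray:
    """Reflect half the series at each end (boundary handling for the FFT).

    For input of length N the output has length 2N: the first ``N//2``
    samples reversed are prepended and the last ``N - N//2`` samples reversed
    are appended.  Complex (analytic/baseband) input is conjugated in the
    reflected flanks: plain time reversal negates the frequency of complex
    exponentials, which would smear a one-sided spectrum, while conjugate
    reflection preserves it.
    """
    x = np.asarray(signal)
    n = len(x)
    if n < 2:
        raise ValueError("signal too short to mirror (need length >= 2)")
    left = x[: n // 2][::-1]
    right = x[n - (n - n // 2):][::-1]
    if np.iscomplexobj(x):
        left = np.conj(left)
        right = np.conj(right)
    return np.concatenate([left, x, right])


def crop_extension(extended: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`mirror_extend`."""
    x = np.asarray(extended)
    if len(x) % 2 != 0 or len(x) < 4:
        raise ValueError("not a mirror-extended series")
    n = len(x) // 2
    return x[n // 2 : n // 2 + n]


def _init_omega(config: VMDConfig, fs: float, two_sided: bool) -> np.ndarray:
    K = config.K
    if config.omega_init is not None:
        om = np.asarray(config.omega_init, dtype=float)
        if len(om) != K:
            raise ValueError("omega_init length must equal K")
        om = om.copy()
        if config.dc:
            om[0] = 0.0
        return om
    if config.init == "zeros":
        om = np.zeros(K)
    elif config.init == "uniform":
        # evenly spaced across the positive band, first mode at DC so low
        # components are not orphaned
        om = (np.arange(K) / K) * (fs / 2)
    else:
        rng = np.random.default_rng(config.seed)
        om = np.sort(rng.uniform(0, fs / 2, K))
    if config.dc:
        om[0] = 0.0
    return om


def vmd(signal: np.ndarray, fs: float, config: VMDConfig) -> ModeSet:
    """Decompose one series into ``config.K`` narrowband modes.

    Returns a :class:`ModeSet` ordered by ascending center frequency, with
    per-mode bandwidths (square root of the spectral second moment about the
    center frequency), the iteration count, the relative reconstruction
    residual and a convergence flag.
    """
    x = np.asarray(signal)
    if len(x) < 16:
        raise ValueError("signal too short for decomposition (need >= 16 samples)")
    if not np.all(np.isfinite(x)):
        raise ValueError("signal contains non-finite values")
    is_complex = np.iscomplexobj(x)
    n = len(x)
    K = config.K

    if not np.any(x != 0):
        omega = _init_omega(config, fs, is_complex)
        zeros = np.zeros((K, n), dtype=complex if is_complex else float)
        return ModeSet(zeros, omega, np.zeros(K), fs, 0, 0.0, True,
                       baseband=is_complex)

    ext = mirror_extend(x)
    T = len(ext)
    f_hat = np.fft.fftshift(np.fft.fft(ext))
    freqs = np.arange(-(T // 2), T - T // 2) / T  # normalized, cycles/sample
    if not is_complex:
        # one-sided: negative-frequency half plays no role for real input
        f_hat = f_hat.copy()
        f_hat[freqs < 0] = 0.0
    pos = freqs >= 0

    omega = _init_omega(config, fs, is_complex) / fs  # normalized
    alpha = config.alpha
    u_hat = np.zeros((K, T), dtype=complex)
    lam = np.zeros(T, dtype=complex)
    sum_u = u_hat.sum(axis=0)

    converged = False
    it = 0
    for it in range(1, config.max_iters + 1):
        u_diff = 0.0
        for k in range(K):
            sum_others = sum_u - u_hat[k]
            numer = f_hat - sum_others + lam / 2.0
            u_new = numer / (1.0 + 2.0 * alpha * (freqs - omega[k]) ** 2)
            if not is_complex:
                u_new[~pos] = 0.0
            old_norm = np.vdot(u_hat[k], u_hat[k]).real
            d = u_new - u_hat[k]
            if old_norm > 0:
                u_diff += np.vdot(d, d).real / old_norm
            elif np.any(d):
                u_diff += 1.0
            sum_u = sum_others + u_new
            u_hat[k] = u_new
            if config.dc and k == 0:
                omega[0] = 0.0
            else:
                p = np.abs(u_new) ** 2
                if not is_complex:
                    p = p * pos
                tot = p.sum()
                if tot > 0:
                    omega[k] = float(np.dot(freqs, p) / tot)
        if config.tau > 0:
            lam = lam + config.tau * (f_hat - sum_u)
        if u_diff < config.tol:
            converged = True
            break

    if not converged:
        warnings.warn(
            f"VMD did not converge in {config.max_iters} iterations "
            f"(last relative change {u_diff:.3g})",
            RuntimeWarning,
            stacklevel=2,
        )

    # per-mode bandwidth: sqrt of spectral second moment about omega_k
    sigma = np.zeros(K)
    for k in range(K):
        p = np.abs(u_hat[k]) ** 2
        tot = p.sum()
        if tot > 0:
            sigma[k] = float(np.sqrt(np.dot((freqs - omega[k]) ** 2, p) / tot)) * fs

    # back to time domain
    modes = np.empty((K, n), dtype=complex if is_complex else float)
    for k in range(K):
        spec = u_hat[k]
        if not is_complex:
            # Hermitian completion of the one-sided spectrum
            # (fftshift layout: index 0 is -Nyquist, index T//2 is DC)
            half = T // 2
            full = np.zeros_like(spec)
            full[half:] = spec[half:]
            full[1:half] = np.conj(spec[half + 1 :][::-1])
            m = np.fft.ifft(np.fft.ifftshift(full))
            modes[k] = crop_extension(np.real(m))
        else:
            m = np.fft.ifft(np.fft.ifftshift(spec))
            modes[k] = crop_extension(m)

    recon = modes.sum(axis=0)
    denom = np.linalg.norm(x)
    residual = float(np.linalg.norm(x - recon) / denom) if denom > 0 else 0.0

    ms = ModeSet(modes, omega * fs, sigma, fs, it, residual, converged,
                 baseband=is_complex)
    return ms.sorted_by_omega()
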