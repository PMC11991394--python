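"""Time-domain, frequency-domain and nonlinear features of IMFs.

All features are computed per (channel, mode) series and assembled into a
:class:`~fsvmd.containers.FeatureTable` whose column names encode
``channel|mode|feature``.  The default set holds nine features:

========================  =====================================================
``mav``                   mean absolute value
``apen``                  approximate entropy (m=2, r=0.2*SD)
``relp_mu``               relative mu-band (8-12 Hz) power
``relp_beta``             relative beta-band (13-30 Hz) power
``mu_beta_ratio``         relp_mu / relp_beta
``bp_mu``                 average mu-band power (integrated Welch PSD)
``energy``                sum of squares
``shannon_entropy``       Shannon entropy of the per-sample energy distribution
``tke``                   mean Teager-Kaiser energy
========================  =====================================================

The L2 norm is available as a function but excluded from the default table
(it is the square root of ``energy``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch
from scipy.spatial.distance import cdist

from .containers import FeatureTable, ModeSet

__all__ = [
    "BandDef",
    "mean_absolute_value",
    "approximate_entropy",
    "band_power",
    "relative_band_power",
    "mu_beta_ratio",
    "energy",
    "l2_norm",
    "shannon_entropy",
    "mean_teager_kaiser",
    "DEFAULT_FEATURES",
    "compute_features",
    "extract_features",
]


@dataclass
class BandDef:
    """Classical EEG band edges in Hz (editable)."""

    mu: tuple[float, float] = (8.0, 12.0)
    beta: tuple[float, float] = (13.0, 30.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.mu, self.beta):
            if not 0 < lo < hi:
                raise ValueError("band edges must satisfy 0 < lo < hi")


def mean_absolute_value(series: np.ndarray) -> float:
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    return float(np.mean(np.abs(x)))


def approximate_entropy(series: np.ndarray, m: int = 2, r: float = 0.2) -> float:
    """Approximate entropy ApEn(m, r*SD) — classic definition.

    Counts Chebyshev-ball template matches including self-matches:
    ``ApEn = Phi_m - Phi_{m+1}`` with ``Phi_m`` the mean log fraction of
    ``m``-length templates within ``r*SD`` of each template.  Zero-variance
    series return 0 by convention.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < m + 2:
        raise ValueError(f"series too short for ApEn (need >= {m + 2} samples)")
    sd = float(np.std(x))
    if sd == 0:
        return 0.0
    tol = r * sd

    def phi(mm: int) -> float:
        emb = np.lib.stride_tricks.sliding_window_view(x, mm)
        d = cdist(emb, emb, metric="chebyshev")
        c = np.mean(d <= tol, axis=1)
        return float(np.mean(np.log(c)))

    return phi(m) - phi(m + 1)


def _psd(series: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # 1 s Hann segments with 50% overlap: >= 3 segments per 3.5 s trial
    x = np.asarray(series, dtype=float)
    nperseg = min(len(x), int(round(fs)))
    return welch(x, fs=fs, nperseg=nperseg)


def band_power(series: np.ndarray, fs: float, band: tuple[float, float]) -> float:
    """Power in ``band`` (trapezoid-integrated Welch PSD)."""
    f, p = _psd(series, fs)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if mask.sum() < 2:
        return float(p[mask].sum() * (f[1] - f[0])) if mask.any() else 0.0
    return float(np.trapezoid(p[mask], f[mask]))


def relative_band_power(
    series: np.ndarray, fs: float, band: tuple[float, float], fmin: float = 0.5
) -> float:
    """Band power as a fraction of total power between ``fmin`` and fs/2."""
    total = band_power(series, fs, (fmin, fs / 2))
    if total == 0:
        return 0.0
    return band_power(series, fs, band) / total


def mu_beta_ratio(
    series: np.ndarray, fs: float, bands: BandDef | None = None
) -> float:
    """Ratio of relative mu to relative beta power.

    Zero beta power with nonzero mu power yields ``inf``; both zero yields 0.
    """
    bands = bands or BandDef()
    mu = relative_band_power(series, fs, bands.mu)
    beta = relative_band_power(series, fs, bands.beta)
    if beta == 0:
        if mu == 0:
            return 0.0
        import warnings

        warnings.warn("zero beta-band power; ratio is +inf", RuntimeWarning,
                      stacklevel=2)
        return float("inf")
    return mu / beta


def energy(series: np.ndarray) -> float:
    x = np.asarray(series, dtype=float)
    return float(np.sum(x**2))


def l2_norm(series: np.ndarray) -> float:
    return float(np.sqrt(energy(series)))


def shannon_entropy(series: np.ndarray) -> float:
    """Shannon entropy of the normalized per-sample energy distribution.

    ``p_n = x_n^2 / sum(x^2)``; ``-sum p log p`` with ``0 log 0 = 0``.
    Ranges over [0, ln N]; a single spike gives 0, equal energy gives ln N.
    """
    x = np.asarray(series, dtype=float)
    tot = np.sum(x**2)
    if tot == 0:
        return 0.0
    p = x**2 / tot
    nz = p[p > 0]
    return float(-np.sum(nz * np.log(nz)))


def mean_teager_kaiser(series: np.ndarray) -> float:
    """Mean Teager-Kaiser energy ``psi_n = x_n^2 - x_{n-1} x_{n+1}``.

    Averaged over interior samples; for a pure tone ``A cos(Omega n)`` the
    operator returns ``A^2 sin^2(Omega)``.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 samples for Teager-Kaiser energy")
    psi = x[1:-1] ** 2 - x[:-2] * x[2:]
    return float(np.mean(psi))


DEFAULT_FEATURES = (
    "mav",
    "apen",
    "relp_mu",
    "relp_beta",
    "mu_beta_ratio",
    "bp_mu",
    "energy",
    "shannon_entropy",
    "tke",
)


def compute_features(
    series: np.ndarray,
    fs: float,
    bands: BandDef | None = None,
    feature_set: tuple[str, ...] = DEFAULT_FEATURES,
) -> dict[str, float]:
    """All requested features of one real series, NaN-free by construction."""
    bands = bands or BandDef()
    x = np.real(np.asarray(series))
    if not np.any(x):
        return {name: 0.0 for name in feature_set}
    table = {
        "mav": lambda: mean_absolute_value(x),
        "apen": lambda: approximate_entropy(x),
        "relp_mu": lambda: relative_band_power(x, fs, bands.mu),
        "relp_beta": lambda: relative_band_power(x, fs, bands.beta),
        "mu_beta_ratio": lambda: mu_beta_ratio(x, fs, bands),
        "bp_mu": lambda: band_power(x, fs, bands.mu),
        "bp_beta": lambda: band_power(x, fs, bands.beta),
        "energy": lambda: energy(x),
        "l2": lambda: l2_norm(x),
        "shannon_entropy": lambda: shannon_entropy(x),
        "tke": lambda: mean_teager_kaiser(x),
    }
    out = {}
    for name in feature_set:
        val = table[name]()
        if not np.isfinite(val):
            val = 0.0  # inf sentinel (mu/beta ratio) is unusable downstream
        out[name] = val
    return out


def extract_features(
    modesets,
    labels,
    channel_labels: list[str],
    bands: BandDef | None = None,
    feature_set: tuple[str, ...] = DEFAULT_FEATURES,
) -> FeatureTable:
    """Assemble a trials x features table from per-trial/channel mode sets.

    ``modesets`` is a nested sequence ``[trial][channel] -> ModeSet`` (a
    :class:`~fsvmd.fsvmd.DecompositionResult` iterates this way).  The mode
    count must be uniform across trials/channels; column order is
    deterministic: channel-major, then mode, then feature, named
    ``{channel}|imf{j}|{feature}``.
    """
    bands = bands or BandDef()
    rows = []
    n_modes_ref: int | None = None
    ragged: list[int] = []
    for ti, row in enumerate(modesets):
        feats: list[float] = []
        for ci, ms in enumerate(row):
            if ms is None:
                raise ValueError(f"trial {ti} channel {ci} has no decomposition")
            if n_modes_ref is None:
                n_modes_ref = ms.n_modes
            elif ms.n_modes != n_modes_ref:
                ragged.append(ti)
            for k in range(ms.n_modes):
                f = compute_features(ms.modes[k], ms.fs, bands, feature_set)
                feats.extend(f.values())
        rows.append(feats)
    if ragged:
        raise ValueError(
            f"ragged mode counts across trials (expected {n_modes_ref}); "
            f"offending trials: {sorted(set(ragged))}"
        )
    names = [
        f"{ch}|imf{k}|{feat}"
        for ch in channel_labels
        for k in range(n_modes_ref or 0)
        for feat in feature_set
    ]
    return FeatureTable(np.asarray(rows, dtype=float), names,
                        np.asarray(labels))


def parse_feature_name(name: str) -> tuple[str, int, str]:
    """Inverse of the column naming: ``channel|imfK|feature`` triplet."""
    ch, imf, feat = name.split("|")
    return ch, int(imf.removeprefix("imf")), feat
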