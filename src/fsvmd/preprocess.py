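"""Multiscale PCA (MSPCA) denoising and motor-cortex channel selection.

MSPCA combines the wavelet transform's multiresolution view with PCA's
ability to exploit cross-channel correlation: each channel of a trial is
wavelet-decomposed, the coefficients of each scale are gathered into a
coefficients x channels matrix, projected onto the retained principal
components and reconstructed, and the denoised channels are re-synthesized
by the inverse wavelet transform.  Shared (low-rank) activity survives;
channel-independent noise is attenuated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .containers import Recording, TrialSet

__all__ = [
    "MSPCAConfig",
    "MSPCADenoiser",
    "mspca_denoise",
    "ChannelScheme",
    "select_channels",
    "CHANNELS_18",
    "CHANNELS_3",
]

# The published 18-channel motor-cortex montage names three electrodes that
# do not exist in the 10/20 extended system ("C7", "CP", "Pi"); they are
# mapped to their symmetric-montage neighbors C1, CPz and Pz, and the grid is
# completed with Cz and C6.
CHANNELS_18 = [
    "C5", "C3", "C1", "Cz", "C2", "C4", "C6",
    "CP5", "CP3", "CPz", "CP4", "CP6",
    "P5", "P3", "Pz", "P2", "P4", "P6",
]

# Sensorimotor triplet preserving ERD/ERS contrast during hand/foot imagery.
CHANNELS_3 = ["C3", "Cz", "C4"]


@dataclass
class MSPCAConfig:
    """Wavelet + component-retention settings.

    ``retention`` is ``"kaiser"`` (keep eigenvalues above the mean — the
    classic MSPCA rule) or ``"fraction"`` (smallest set of components
    explaining at least fraction ``q`` of variance).
    """

    wavelet: str = "db4"
    levels: int = 5
    retention: str = "kaiser"
    q: float = 0.95
    mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.retention not in ("kaiser", "fraction"):
            raise ValueError(f"unknown retention rule {self.retention!r}")
        if self.retention == "fraction" and not 0 < self.q <= 1:
            raise ValueError("fraction-of-variance q must lie in (0, 1]")


def _denoise_scale(coeffs: np.ndarray, config: MSPCAConfig) -> np.ndarray:
    """PCA-project one scale's coefficients x channels matrix."""
    mean = coeffs.mean(axis=0)
    xc = coeffs - mean
    # eigendecomposition of the channel covariance
    cov = xc.T @ xc / max(xc.shape[0] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    if config.retention == "kaiser":
        keep = evals > evals.mean()
        if not np.any(keep):
            keep[0] = True
    else:
        if config.q >= 1.0:
            keep = np.ones(len(evals), dtype=bool)
        else:
            frac = np.cumsum(evals) / max(evals.sum(), np.finfo(float).tiny)
            n_keep = int(np.searchsorted(frac, config.q) + 1)
            keep = np.zeros(len(evals), dtype=bool)
            keep[:n_keep] = True
    v = evecs[:, keep]
    return xc @ v @ v.T + mean


class MSPCADenoiser:
    """Stateless transformer applying MSPCA per trial.

    Parameters mirror :class:`MSPCAConfig`; ``transform`` accepts and
    returns a :class:`TrialSet` of identical shape.
    """

    def __init__(self, config: MSPCAConfig | None = None) -> None:
        self.config = config or MSPCAConfig()

    def transform(self, trials: TrialSet) -> TrialSet:
        cfg = self.config
        n = trials.n_samples
        max_level = pywt.dwt_max_level(n, pywt.Wavelet(cfg.wavelet).dec_len)
        if cfg.levels > max_level:
            raise ValueError(
                f"{cfg.levels} decomposition levels too deep for {n}-sample "
                f"trials with {cfg.wavelet} (max feasible level {max_level})"
            )
        out = np.empty_like(trials.trials)
        for i in range(trials.n_trials):
            # wavelet-decompose every channel, then denoise scale by scale
            per_channel = [
                pywt.wavedec(trials.trials[i, c], cfg.wavelet,
                             level=cfg.levels, mode=cfg.mode)
                for c in range(trials.n_channels)
            ]
            denoised: list[list[np.ndarray]] = [
                [] for _ in range(trials.n_channels)
            ]
            for scale in range(cfg.levels + 1):
                mat = np.stack(
                    [per_channel[c][scale] for c in range(trials.n_channels)],
                    axis=1,
                )
                clean = _denoise_scale(mat, cfg)
                for c in range(trials.n_channels):
                    denoised[c].append(clean[:, c])
            for c in range(trials.n_channels):
                rec = pywt.waverec(denoised[c], cfg.wavelet, mode=cfg.mode)
                out[i, c] = rec[:n]
        return TrialSet(out, trials.labels.copy(), trials.fs,
                        list(trials.channel_labels))


def mspca_denoise(trials: TrialSet, config: MSPCAConfig | None = None) -> TrialSet:
    """Functional wrapper over :class:`MSPCADenoiser`."""
    return MSPCADenoiser(config).transform(trials)


@dataclass
class ChannelScheme:
    """Named ordered channel subset."""

    name: str
    labels: list[str] = field(default_factory=list)

    @classmethod
    def builtin(cls, name: str) -> "ChannelScheme":
        if name == "18ch":
            return cls("18ch", list(CHANNELS_18))
        if name == "3ch":
            return cls("3ch", list(CHANNELS_3))
        raise ValueError(f"no builtin channel scheme {name!r}")


def select_channels(data: Recording | TrialSet, scheme: ChannelScheme | str):
    """Reorder/select channels per a scheme (case-insensitive label match).

    Works on a :class:`Recording` (columns) or :class:`TrialSet` (channel
    axis); missing labels raise with the offending name.
    """
    if isinstance(scheme, str):
        scheme = ChannelScheme.builtin(scheme)
    lookup = {lab.lower(): i for i, lab in enumerate(data.channel_labels)}
    idx = []
    for lab in scheme.labels:
        if lab.lower() not in lookup:
            raise ValueError(f"channel {lab} not found")
        idx.append(lookup[lab.lower()])
    new_labels = [data.channel_labels[i] for i in idx]
    if isinstance(data, Recording):
        return Recording(data.data[:, idx], data.fs, new_labels, data.start_time)
    return TrialSet(data.trials[:, idx, :], data.labels.copy(), data.fs, new_labels)
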