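"""Domain containers shared by every stage of the pipeline.

Conventions used throughout the package: sample indices are 0-based, time is
in seconds, frequency in Hz.  A :class:`Recording` is samples-major
(``data[sample, channel]``); a :class:`TrialSet` is ``[trial, channel,
sample]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Recording",
    "EventTable",
    "TrialSet",
    "ModeSet",
    "FeatureTable",
]


def _check_finite(arr: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(arr)):
        bad = np.argwhere(~np.isfinite(arr))
        raise ValueError(
            f"{name} contains {len(bad)} non-finite value(s); first at index "
            f"{tuple(bad[0])}"
        )


@dataclass
class Recording:
    """Multichannel time series with sampling rate and channel labels.

    Parameters
    ----------
    data : ndarray, shape (n_samples, n_channels)
        Signal matrix, one column per channel.
    fs : float
        Sampling rate in Hz; must be positive.
    channel_labels : list of str
        One label per column (10/20 names where available).
    start_time : float, default 0
        Time of the first sample, seconds.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording data must be 2-D (samples x channels)")
        if self.fs <= 0:
            raise ValueError("non-positive sampling rate")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.data.shape[1]} channels"
            )
        _check_finite(self.data, "Recording data")

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length of the recording in seconds."""
        return self.n_samples / self.fs


@dataclass
class EventTable:
    """Trial onsets (0-based sample indices) with class labels."""

    onsets: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=int)
        self.labels = np.asarray(self.labels)
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels must have equal length")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) <= 0):
            raise ValueError("onsets must be strictly increasing")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class TrialSet:
    """Epoched trials: ``trials[trial, channel, sample]`` plus labels."""

    trials: np.ndarray
    labels: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.trials = np.asarray(self.trials, dtype=float)
        if self.trials.ndim != 3:
            raise ValueError("trials must be 3-D (trial x channel x sample)")
        self.labels = np.asarray(self.labels)
        if len(self.labels) != self.trials.shape[0]:
            raise ValueError("labels length must equal trial count")
        if self.fs <= 0:
            raise ValueError("non-positive sampling rate")
        self.channel_labels = list(self.channel_labels)
        if len(self.channel_labels) != self.trials.shape[1]:
            raise ValueError("channel label count mismatch")
        _check_finite(self.trials, "TrialSet data")

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_channels(self) -> int:
        return self.trials.shape[1]

    @property
    def n_samples(self) -> int:
        return self.trials.shape[2]

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class ModeSet:
    """Intrinsic mode functions of one series with per-mode state.

    ``modes`` is ``[K, n_samples]``; complex when produced from an analytic
    (frequency-shifted) input, real otherwise.  ``omega`` holds the center
    frequency of each mode in Hz and ``sigma`` its bandwidth state in Hz.
    ``baseband`` marks a set whose carrier shift has not been undone yet.
    """

    modes: np.ndarray
    omega: np.ndarray
    sigma: np.ndarray
    fs: float
    n_iters: int = 0
    residual: float = 0.0
    converged: bool = True
    baseband: bool = False

    def __post_init__(self) -> None:
        self.modes = np.atleast_2d(np.asarray(self.modes))
        self.omega = np.asarray(self.omega, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        k = self.modes.shape[0]
        if len(self.omega) != k or len(self.sigma) != k:
            raise ValueError("omega/sigma length must equal mode count")
        if self.fs <= 0:
            raise ValueError("non-positive sampling rate")

    @property
    def n_modes(self) -> int:
        return self.modes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.modes.shape[1]

    def reconstruction(self) -> np.ndarray:
        """Sum of all modes (real part for real-signal mode sets)."""
        total = self.modes.sum(axis=0)
        return total if np.iscomplexobj(self.modes) and self.baseband else np.real(total)

    def sorted_by_omega(self) -> "ModeSet":
        order = np.argsort(self.omega, kind="stable")
        return ModeSet(
            self.modes[order],
            self.omega[order],
            self.sigma[order],
            self.fs,
            self.n_iters,
            self.residual,
            self.converged,
            self.baseband,
        )


@dataclass
class FeatureTable:
    """Trials x named features with class labels."""

    values: np.ndarray
    feature_names: list[str]
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature values must be 2-D (trials x features)")
        self.feature_names = list(self.feature_names)
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature name count mismatch")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("feature names must be unique")
        if self.labels is not None:
            self.labels = np.asarray(self.labels)
            if len(self.labels) != self.values.shape[0]:
                raise ValueError("labels length must equal row count")
        if np.any(np.isnan(self.values)):
            raise ValueError("feature table contains NaN")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, names: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(n) for n in names]
        return FeatureTable(self.values[:, idx], names, self.labels)

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(self.values, columns=self.feature_names)
        if self.labels is not None:
            df.insert(0, "label", self.labels)
        return df
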