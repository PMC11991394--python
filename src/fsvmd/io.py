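"""Readers and writers for the package's on-disk formats, plus epoching.

Two recording dialects are supported:

``csv+header``
    First line ``# fs=<Hz> channels=<comma-list>``, then one CSV row per
    sample.  Values are written with 17 significant digits so a write/read
    cycle is lossless at double precision.

``mat-container``
    A classic MATLAB ``.mat`` file holding a named numeric matrix plus fields
    for the sampling rate and channel labels.  Field names are passed
    explicitly (never guessed) so externally produced files — e.g. BCI
    competition exports — can be adapted without silent channel reordering.

Mode sets are stored as a one-line JSON header (K, fs, per-mode center
frequency and bandwidth) followed by CSV columns, one (or two, for complex
modes) per mode.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .containers import EventTable, ModeSet, Recording, TrialSet

__all__ = [
    "read_recording",
    "write_recording",
    "epoch",
    "segment_continuous",
    "write_modes",
    "read_modes",
    "RunConfig",
]

_FMT = "%.17g"


def write_recording(recording: Recording, path: str | Path) -> None:
    """Write a recording in the ``csv+header`` dialect."""
    path = Path(path)
    header = (
        f"# fs={recording.fs:.17g} "
        f"channels={','.join(recording.channel_labels)}"
    )
    with open(path, "w") as fh:
        fh.write(header + "\n")
        np.savetxt(fh, recording.data, fmt=_FMT, delimiter=",")


def _read_csv_header(path: Path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError(f"{path}: missing '# fs=... channels=...' header")
        fields = dict(
            tok.split("=", 1) for tok in header.lstrip("# ").split() if "=" in tok
        )
        if "fs" not in fields:
            raise ValueError(f"{path}: header lacks sampling rate 'fs='")
        fs = float(fields["fs"])
        if fs <= 0:
            raise ValueError("non-positive sampling rate")
        labels = fields.get("channels", "").split(",")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            cells = line.split(",")
            try:
                rows.append([float(c) for c in cells])
            except ValueError:
                bad = next(
                    i for i, c in enumerate(cells)
                    if not _is_number(c)
                )
                raise ValueError(
                    f"{path}: non-numeric cell at row {lineno}, column {bad + 1}"
                ) from None
    data = np.asarray(rows, dtype=float)
    if data.size and data.shape[1] != len(labels):
        raise ValueError(
            f"{path}: header declares {len(labels)} channels but rows have "
            f"{data.shape[1]} columns"
        )
    return Recording(data, fs, labels)


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_mat_container(
    path: Path,
    data_key: str,
    fs_key: str,
    labels_key: str | None,
    samples_axis: int = 0,
) -> Recording:
    from scipy.io import loadmat

    mat = loadmat(path, squeeze_me=True)
    for key in (data_key, fs_key):
        if key not in mat:
            raise ValueError(f"{path}: field '{key}' not found in mat container")
    data = np.asarray(mat[data_key], dtype=float)
    if samples_axis == 1:
        data = data.T
    fs = float(np.asarray(mat[fs_key]).ravel()[0])
    if fs <= 0:
        raise ValueError("non-positive sampling rate")
    if labels_key is not None:
        if labels_key not in mat:
            raise ValueError(f"{path}: field '{labels_key}' not found")
        raw = np.atleast_1d(mat[labels_key])
        labels = [str(x).strip() for x in raw]
    else:
        labels = [f"ch{i}" for i in range(data.shape[1])]
    return Recording(data, fs, labels)


def read_recording(
    path: str | Path,
    dialect: str = "csv+header",
    *,
    data_key: str = "data",
    fs_key: str = "fs",
    labels_key: str | None = None,
    samples_axis: int = 0,
) -> Recording:
    """Read a recording from disk.

    Parameters
    ----------
    path : path
        Input file.
    dialect : {"csv+header", "mat-container"}
        On-disk format; see module docstring.
    data_key, fs_key, labels_key : str
        Field names inside a mat container.  ``labels_key=None`` generates
        ``ch0..chN`` labels.
    samples_axis : {0, 1}
        Which axis of the mat matrix indexes samples (0 = samples-major).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv+header":
        return _read_csv_header(path)
    if dialect == "mat-container":
        return _read_mat_container(path, data_key, fs_key, labels_key, samples_axis)
    raise ValueError(f"unknown dialect {dialect!r}")


def epoch(recording: Recording, events: EventTable, duration_s: float) -> TrialSet:
    """Cut fixed-length trials out of a recording at event onsets.

    Trial ``t`` spans samples ``[onset_t, onset_t + round(duration_s * fs))``;
    labels are copied from the event table.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = int(round(duration_s * recording.fs))
    ends = events.onsets + n
    bad = np.nonzero(ends > recording.n_samples)[0]
    if bad.size:
        raise ValueError(
            f"trial(s) {[int(b) for b in bad]} overrun the recording "
            f"({recording.n_samples} samples, trial length {n})"
        )
    trials = np.stack(
        [recording.data[o : o + n].T for o in events.onsets], axis=0
    )
    return TrialSet(trials, events.labels.copy(), recording.fs,
                    list(recording.channel_labels))


def segment_continuous(
    recording: Recording, window_s: float, overlap_s: float
) -> TrialSet:
    """Slice a continuous recording into overlapping fixed-length windows.

    Windows start at ``0, hop, 2*hop, ...`` with ``hop = window_s -
    overlap_s``; a trailing partial window is dropped.  The returned trial set
    is unlabeled (all labels ``-1``).
    """
    if not 0 <= overlap_s < window_s:
        raise ValueError("require 0 <= overlap_s < window_s")
    w = int(round(window_s * recording.fs))
    hop = int(round((window_s - overlap_s) * recording.fs))
    if w > recording.n_samples:
        raise ValueError(
            f"window ({w} samples) longer than recording "
            f"({recording.n_samples} samples)"
        )
    starts = np.arange(0, recording.n_samples - w + 1, hop)
    events = EventTable(starts, np.full(len(starts), -1))
    return epoch(recording, events, window_s)


def write_modes(modes: ModeSet, path: str | Path) -> None:
    """Write a ModeSet as a JSON header line plus CSV columns per mode."""
    if modes.n_modes == 0 or modes.modes.size == 0:
        raise ValueError("refusing to write an empty ModeSet")
    is_complex = bool(np.iscomplexobj(modes.modes))
    header = {
        "K": int(modes.n_modes),
        "fs": modes.fs,
        "omega": [float(w) for w in modes.omega],
        "sigma": [float(s) for s in modes.sigma],
        "n_iters": int(modes.n_iters),
        "residual": float(modes.residual),
        "converged": bool(modes.converged),
        "baseband": bool(modes.baseband),
        "complex": is_complex,
    }
    if is_complex:
        cols = np.empty((modes.n_samples, 2 * modes.n_modes))
        cols[:, 0::2] = modes.modes.real.T
        cols[:, 1::2] = modes.modes.imag.T
    else:
        cols = np.real(modes.modes).T
    with open(path, "w") as fh:
        fh.write(json.dumps(header) + "\n")
        np.savetxt(fh, cols, fmt=_FMT, delimiter=",")


def read_modes(path: str | Path) -> ModeSet:
    """Inverse of :func:`write_modes` (lossless at double precision)."""
    with open(path) as fh:
        header = json.loads(fh.readline())
        cols = np.loadtxt(fh, delimiter=",", ndmin=2)
    k = header["K"]
    expected = 2 * k if header["complex"] else k
    if cols.shape[1] != expected:
        raise ValueError(
            f"{path}: header declares {k} modes but payload has "
            f"{cols.shape[1]} columns (expected {expected})"
        )
    if header["complex"]:
        arr = (cols[:, 0::2] + 1j * cols[:, 1::2]).T
    else:
        arr = cols.T
    return ModeSet(
        arr,
        np.asarray(header["omega"]),
        np.asarray(header["sigma"]),
        header["fs"],
        header["n_iters"],
        header["residual"],
        header["converged"],
        header["baseband"],
    )


@dataclass
class RunConfig:
    """Seed plus nested per-stage configuration for a pipeline run.

    Serializable to/from a flat dict so it can round-trip through TOML or
    JSON config files.  Unknown sections are preserved verbatim.
    """

    seed: int = 0
    log_level: str = "INFO"
    sections: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"seed": self.seed, "log_level": self.log_level, **self.sections}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        seed = int(d.pop("seed", 0))
        log_level = str(d.pop("log_level", "INFO"))
        return cls(seed=seed, log_level=log_level, sections=d)

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        import tomllib

        with open(path, "rb") as fh:
            return cls.from_dict(tomllib.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, default=str)
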