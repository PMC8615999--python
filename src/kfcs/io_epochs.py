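"""Recording / epoch / montage containers and their on-disk text formats.

Continuous signals travel as delimited text (TSV, rows = channels, header
row = channel labels); events as two-column ``onset_seconds<TAB>label``
files; montages as ``label x y`` lines.  EDF input is supported when
``pyedflib`` is installed, but nothing in the package requires it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "EpochSet",
    "Montage",
    "read_recording",
    "write_recording",
    "extract_epochs",
    "read_events",
    "write_events",
    "load_montage",
    "default_montage",
    "synthetic_montage",
]

BRAKING = "braking"
NORMAL = "normal"
VALID_LABELS = (BRAKING, NORMAL)


@dataclass
class Recording:
    """A continuous multichannel signal.

    Parameters
    ----------
    signal : ndarray, shape (n_channels, n_samples)
        Signal matrix in microvolts.
    fs : float
        Sampling rate in Hz, strictly positive.
    channel_labels : list of str
        Unique label per channel.
    """

    signal: np.ndarray
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2-D (channels x samples) matrix")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.signal.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.signal.shape[0]} channels"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        """Recording span in seconds."""
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length labelled epochs for one subject.

    ``epochs`` is stored as a single (n_epochs, n_channels, n_samples)
    array; every epoch therefore has the same shape by construction.
    """

    epochs: np.ndarray
    labels: list[str]
    fs: float
    subject_id: str = ""
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        if self.epochs.size and self.epochs.ndim != 3:
            raise ValueError("epochs must stack to (n_epochs, n_channels, n_samples)")
        if self.epochs.size == 0:
            self.epochs = self.epochs.reshape((0, 0, 0))
        if len(self.labels) != self.epochs.shape[0]:
            raise ValueError("one label per epoch required")
        bad = set(self.labels) - set(VALID_LABELS)
        if bad:
            raise ValueError(f"unknown labels: {sorted(bad)}")
        if self.channel_labels and self.epochs.size:
            if len(self.channel_labels) != self.epochs.shape[1]:
                raise ValueError("channel_labels length mismatch")

    def __len__(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.epochs.shape[1]


@dataclass
class Montage:
    """Mapping from channel label to a projected 2-D scalp coordinate."""

    positions: dict[str, tuple[float, float]]

    def __len__(self) -> int:
        return len(self.positions)

    def __contains__(self, label: str) -> bool:
        return label in self.positions

    def coords(self, labels: Sequence[str]) -> np.ndarray:
        """Return an (n, 2) coordinate array in the given label order."""
        missing = [lb for lb in labels if lb not in self.positions]
        if missing:
            raise KeyError(f"montage missing channels: {missing}")
        return np.array([self.positions[lb] for lb in labels], dtype=float)

    def covers(self, rec: Recording) -> bool:
        return all(lb in self.positions for lb in rec.channel_labels)


# ---------------------------------------------------------------------------
# Continuous recordings
# ---------------------------------------------------------------------------

def read_recording(
    path: str | Path,
    format: str = "delimited",
    fs: float | None = None,
    delimiter: str = "\t",
) -> Recording:
    """Read a continuous recording.

    ``delimited`` files carry one header line of channel labels followed by
    one row of samples per channel; the sampling rate must be supplied via
    ``fs`` (there is no place for it in the matrix itself).  ``edf`` input
    requires the optional ``pyedflib`` dependency.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "delimited":
        if fs is None:
            raise ValueError("delimited input requires an explicit sampling rate")
        with open(path) as fh:
            header = fh.readline().strip()
            if not header:
                raise ValueError(f"{path}: empty file")
            labels = header.split(delimiter)
            rows = []
            for ln, line in enumerate(fh, start=2):
                line = line.strip()
                if not line:
                    continue
                row = [float(tok) for tok in line.split(delimiter)]
                if rows and len(row) != len(rows[0]):
                    raise ValueError(f"{path}:{ln}: inconsistent row length")
                rows.append(row)
        if len(rows) != len(labels):
            raise ValueError(
                f"{path}: {len(labels)} labels in header but {len(rows)} channel rows"
            )
        return Recording(np.array(rows), fs, labels)
    if format == "edf":
        return _read_edf(path)
    raise ValueError(f"unknown format {format!r}")


def _read_edf(path: Path) -> Recording:
    try:
        import pyedflib
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ImportError(
            "EDF input requires the optional 'pyedflib' package; "
            "install it or convert the file to delimited text"
        ) from exc
    with pyedflib.EdfReader(str(path)) as reader:  # pragma: no cover
        labels = reader.getSignalLabels()
        fs = float(reader.getSampleFrequency(0))
        signal = np.vstack([reader.readSignal(i) for i in range(reader.signals_in_file)])
    return Recording(signal, fs, list(labels))  # pragma: no cover


def write_recording(rec: Recording, path: str | Path, delimiter: str = "\t",
                    fmt: str = "%.10g") -> None:
    """Write a recording in the delimited dialect read_recording accepts."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(delimiter.join(rec.channel_labels) + "\n")
        np.savetxt(fh, rec.signal, fmt=fmt, delimiter=delimiter)


# ---------------------------------------------------------------------------
# Events and epochs
# ---------------------------------------------------------------------------

def read_events(path: str | Path) -> list[tuple[float, str]]:
    """Read an event file: one ``onset_seconds<TAB>label`` line per epoch."""
    events = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{ln}: expected 'onset<TAB>label'")
            events.append((float(parts[0]), parts[1]))
    return events


def write_events(events: Sequence[tuple[float, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for onset, label in events:
            fh.write(f"{onset:.6f}\t{label}\n")


def extract_epochs(
    rec: Recording,
    events: Sequence[tuple[float, str]],
    duration: float = 1.0,
    subject_id: str = "",
) -> EpochSet:
    """Cut one fixed-length epoch per event from a continuous recording.

    Sample windows are half-open and 0-based:
    ``[round(onset * fs), round(onset * fs) + round(duration * fs))``,
    so adjacent events one duration apart never share samples.
    """
    n_epoch = int(round(duration * rec.fs))
    if n_epoch <= 0:
        raise ValueError("duration must span at least one sample")
    cut = []
    labels = []
    for onset, label in events:
        start = int(round(onset * rec.fs))
        if start < 0 or start + n_epoch > rec.n_samples:
            raise ValueError(
                f"event at {onset} s (+{duration} s) falls outside the "
                f"{rec.duration:.3f} s recording"
            )
        cut.append(rec.signal[:, start:start + n_epoch])
        labels.append(label)
    if not cut:
        return EpochSet(np.empty((0, 0, 0)), [], rec.fs, subject_id,
                        list(rec.channel_labels))
    return EpochSet(np.stack(cut), labels, rec.fs, subject_id,
                    list(rec.channel_labels))


# ---------------------------------------------------------------------------
# Montages
# ---------------------------------------------------------------------------

def load_montage(path: str | Path) -> Montage:
    """Load a ``label x y`` montage file (whitespace separated)."""
    positions: dict[str, tuple[float, float]] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{ln}: expected 'label x y'")
            label, xs, ys = parts
            if label in positions:
                raise ValueError(f"{path}:{ln}: duplicate label {label!r}")
            positions[label] = (float(xs), float(ys))
    return Montage(positions)


def default_montage() -> Montage:
    """The packaged 64-channel extended 10-10 layout (schematic 2-D projection)."""
    ref = resources.files("kfcs.data").joinpath("montage_64_1010.tsv")
    with resources.as_file(ref) as path:
        return load_montage(path)


def synthetic_montage(labels: Sequence[str]) -> Montage:
    """Deterministic placeholder montage: channels evenly spaced on a circle.

    Lets montage-dependent stages run on synthetic data whose channel count
    does not match the packaged 64-channel cap.
    """
    n = len(labels)
    positions = {}
    for i, lb in enumerate(labels):
        angle = 2.0 * math.pi * i / max(n, 1)
        positions[lb] = (math.cos(angle), math.sin(angle))
    return Montage(positions)
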