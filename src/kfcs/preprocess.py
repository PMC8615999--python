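"""Band restriction and a pluggable artifact-cleaning hook."""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal as sps

from .io_epochs import EpochSet, Recording

__all__ = ["bandpass", "bandpass_epochs", "clean_artifacts", "DEFAULT_BAND"]

DEFAULT_BAND = (0.5, 45.0)


def _band_sos(low_hz: float, high_hz: float, fs: float, order: int = 6):
    if not (0.0 < low_hz < high_hz < fs / 2.0):
        raise ValueError(
            f"band edges must satisfy 0 < low < high < fs/2 "
            f"(got {low_hz}-{high_hz} Hz at fs={fs})"
        )
    return sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")


def bandpass(
    rec: Recording,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 6,
) -> Recording:
    """Zero-phase (forward-backward) Butterworth band-pass copy of ``rec``.

    Zero-phase filtering preserves epoch timing; the output has the same
    shape as the input and the operation is linear.
    """
    sos = _band_sos(low_hz, high_hz, rec.fs, order)
    filtered = sps.sosfiltfilt(sos, rec.signal, axis=1)
    return Recording(filtered, rec.fs, list(rec.channel_labels))


def bandpass_epochs(
    epochs: EpochSet,
    low_hz: float = DEFAULT_BAND[0],
    high_hz: float = DEFAULT_BAND[1],
    order: int = 6,
) -> EpochSet:
    """Apply the zero-phase band-pass independently to every epoch."""
    if len(epochs) == 0:
        return epochs
    sos = _band_sos(low_hz, high_hz, epochs.fs, order)
    filtered = sps.sosfiltfilt(sos, epochs.epochs, axis=2)
    return EpochSet(filtered, list(epochs.labels), epochs.fs,
                    epochs.subject_id, list(epochs.channel_labels))


def clean_artifacts(
    rec: Recording,
    cleaner: Callable[[Recording], Recording] | None = None,
) -> Recording:
    """Apply a caller-supplied artifact cleaner; identity by default.

    The hook exists so an ICA-based (or any other) cleaner can be slotted
    in without the pipeline depending on one.  A cleaner must preserve the
    channel count.
    """
    if cleaner is None:
        return rec
    out = cleaner(rec)
    if not isinstance(out, Recording):
        raise TypeError("cleaner must return a Recording")
    if out.n_channels != rec.n_channels:
        raise ValueError(
            f"cleaner changed channel count ({rec.n_channels} -> {out.n_channels})"
        )
    return out
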