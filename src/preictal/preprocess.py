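"""Band-limiting, mains-notch filtering and per-channel normalization.

Applied exactly once per recording, before windowing. Filters are
zero-phase (forward-backward) so the preictal boundary is not shifted.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import signal

from .io import Recording

__all__ = ["FilterSpec", "DegenerateChannelError", "bandpass_notch", "normalize"]


@dataclass(frozen=True)
class FilterSpec:
    """Bandpass + notch configuration.

    Defaults: 0.5-100 Hz 4th-order Butterworth passband with a Q=30 notch
    at the 60 Hz mains frequency (use 50 Hz outside the Americas).
    """

    band_low: float = 0.5
    band_high: float = 100.0
    notch_freq: float = 60.0
    notch_q: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.band_low < self.band_high:
            raise ValueError("need 0 < band_low < band_high")
        if not self.band_low < self.notch_freq < self.band_high:
            raise ValueError("notch_freq must lie inside the passband")
        if self.order < 1:
            raise ValueError("order must be >= 1")


class DegenerateChannelError(ValueError):
    """A channel with (near-)zero variance cannot be normalized."""


def bandpass_notch(recording: Recording, spec: FilterSpec = FilterSpec()) -> Recording:
    """Zero-phase Butterworth bandpass plus IIR mains notch, per channel.

    Raises ``ValueError`` when ``band_high`` reaches the Nyquist frequency.
    """
    nyq = recording.fs / 2.0
    if spec.band_high >= nyq:
        raise ValueError(
            f"band_high={spec.band_high} Hz must be below Nyquist ({nyq} Hz)"
        )
    sos = signal.butter(
        spec.order, [spec.band_low, spec.band_high], btype="bandpass",
        fs=recording.fs, output="sos",
    )
    x = signal.sosfiltfilt(sos, recording.data, axis=1)
    b, a = signal.iirnotch(spec.notch_freq, spec.notch_q, fs=recording.fs)
    x = signal.filtfilt(b, a, x, axis=1)
    return replace(recording, data=x, channel_names=list(recording.channel_names))


def normalize(recording: Recording, mode: str = "per_channel_zscore") -> Recording:
    """Z-score each channel over the whole recording.

    The recording (not the segment) is the normalization scope so relative
    within-recording dynamics survive windowing. A constant channel raises
    :class:`DegenerateChannelError` naming the channel.
    """
    if mode != "per_channel_zscore":
        raise ValueError(f"unknown normalization mode {mode!r}")
    data = recording.data.astype(np.float64)
    mean = data.mean(axis=1, keepdims=True)
    sd = data.std(axis=1, keepdims=True)
    flat = np.nonzero(sd[:, 0] < 1e-12)[0]
    if flat.size:
        raise DegenerateChannelError(
            f"constant channel {recording.channel_names[flat[0]]!r} "
            "cannot be z-scored"
        )
    x = (data - mean) / sd
    return replace(recording, data=x, channel_names=list(recording.channel_names))
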