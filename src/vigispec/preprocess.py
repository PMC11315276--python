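"""Filtering and amplitude-based artifact rejection.

The preprocessing chain mirrors a standard rodent/human EEG pipeline:
a zero-phase Butterworth band-pass (0.5--70 Hz, order 4) on every EEG
channel, followed by flagging of 1-second epochs in which any EEG sample
deviates more than ``threshold_sd`` standard deviations from the
whole-recording channel mean.  The 1-s epoch is the only time quantum of
the pipeline; rejection therefore operates at epoch granularity.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

__all__ = [
    "Channel",
    "Recording",
    "ArtifactMask",
    "DegenerateSignalError",
    "bandpass_filter",
    "reject_artifacts",
]

EEG = "eeg"
EMG = "emg"

#: default high-pass edge applied to EMG channels instead of the EEG band-pass
EMG_HIGHPASS_HZ = 10.0


class DegenerateSignalError(ValueError):
    """Raised when a statistic is undefined (e.g. SD of a constant signal)."""


@dataclass
class Channel:
    """One named signal trace in microvolts with a role tag (``eeg``/``emg``)."""

    name: str
    data: np.ndarray
    role: str = EEG

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 1:
            raise ValueError("channel data must be 1-D")
        if self.role not in (EEG, EMG):
            raise ValueError(f"unknown channel role {self.role!r}")


@dataclass
class Recording:
    """Multichannel recording plus subject metadata.

    Channels are stored in microvolts and must share one sampling rate and
    one length.  ``group``/``sex``/``age`` carry the cohort factors used by
    the downstream statistics.
    """

    channels: list[Channel]
    fs: float
    subject: str = "s0"
    group: str = "none"
    sex: str = "na"
    age: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if not self.channels:
            raise ValueError("recording needs at least one channel")
        n = len(self.channels[0].data)
        if any(len(c.data) != n for c in self.channels):
            raise ValueError("all channels must have equal length")

    @property
    def n_samples(self) -> int:
        return len(self.channels[0].data)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def n_epochs(self) -> int:
        """Number of whole 1-s epochs; the partial trailing second is dropped."""
        return int(np.floor(self.duration_s))

    def eeg_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.role == EEG]

    def emg_channels(self) -> list[Channel]:
        return [c for c in self.channels if c.role == EMG]

    def copy(self) -> "Recording":
        return copy.deepcopy(self)


@dataclass
class ArtifactMask:
    """Per-epoch rejection flags (True = epoch rejected)."""

    epoch_flags: np.ndarray
    threshold_sd: float

    def __post_init__(self) -> None:
        self.epoch_flags = np.asarray(self.epoch_flags, dtype=bool)
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")

    @property
    def n_epochs(self) -> int:
        return len(self.epoch_flags)

    @property
    def fraction_rejected(self) -> float:
        return float(np.mean(self.epoch_flags)) if self.n_epochs else 0.0


def _epoch_view(x: np.ndarray, fs: float) -> np.ndarray:
    """Reshape a trace into (n_epochs, samples_per_epoch), dropping the tail."""
    spe = int(round(fs))
    n_ep = len(x) // spe
    return x[: n_ep * spe].reshape(n_ep, spe)


def bandpass_filter(
    recording: Recording,
    low_hz: float = 0.5,
    high_hz: float = 70.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass of every EEG channel.

    EMG channels are high-passed at 10 Hz instead, since muscle activity
    carries its information above the EEG band.  Filtering is applied
    forward-backward (``sosfiltfilt``) so band-power scoring sees no phase
    distortion; the output has the same length as the input.
    """
    nyq = recording.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for Nyquist {nyq} Hz"
        )
    sos_eeg = sps.butter(order, [low_hz, high_hz], btype="bandpass", fs=recording.fs, output="sos")
    sos_emg = sps.butter(order, EMG_HIGHPASS_HZ, btype="highpass", fs=recording.fs, output="sos")
    out = recording.copy()
    for ch in out.channels:
        sos = sos_eeg if ch.role == EEG else sos_emg
        ch.data = sps.sosfiltfilt(sos, ch.data)
    return out


def reject_artifacts(recording: Recording, threshold_sd: float = 3.0) -> ArtifactMask:
    """Flag 1-s epochs containing amplitude artifacts.

    Per EEG channel, the mean and SD are computed over the full recording;
    an epoch is rejected if any sample on any EEG channel deviates more
    than ``threshold_sd`` SD from that channel's mean.  EMG channels are
    excluded (muscle bursts legitimately dwarf EEG-scale deviations).
    The mask is invariant under rescaling of the signal.
    """
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if recording.duration_s < 2:
        raise ValueError("recording shorter than 2 s")
    eeg = recording.eeg_channels()
    if not eeg:
        raise ValueError("no EEG channels to screen")
    n_ep = recording.n_epochs
    flags = np.zeros(n_ep, dtype=bool)
    for ch in eeg:
        mu = float(np.mean(ch.data))
        sd = float(np.std(ch.data))
        if sd == 0.0:
            raise DegenerateSignalError(f"channel {ch.name!r} is constant; SD = 0")
        dev = np.abs(_epoch_view(ch.data, recording.fs) - mu)
        flags |= (dev > threshold_sd * sd).any(axis=1)
    return ArtifactMask(epoch_flags=flags, threshold_sd=threshold_sd)
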