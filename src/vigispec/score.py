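"""Vigilance-state scoring of 1-s epochs by band dominance.

Each epoch is classified from its power in three canonical bands —
delta 0.2–3 Hz, theta 3.2–6 Hz, alpha 6.2–12 Hz — after dividing each
band power by its bandwidth, so that the widest band cannot win by area
alone.  Humans are scored into the three awake states (a1 delta-dominated
active wake, a2 theta-dominated wake, a3 alpha-dominated rest).  Mice
additionally get REM (low EMG + theta dominance) and a single pooled
nREM class (low EMG + delta dominance); the EMG threshold defaults to
the median epoch EMG power of the recording, exploiting the bimodal
sleep/wake split of muscle tone.  Epochs rejected by the artifact mask
are always labelled ``noise``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .preprocess import ArtifactMask, Recording, _epoch_view

__all__ = [
    "BANDS",
    "BandPowers",
    "Hypnogram",
    "epoch_band_powers",
    "classify_epoch",
    "score_recording",
    "state_proportions",
]

#: scoring bands (Hz).  The 3–3.2 and 6–6.2 Hz gaps follow the band
#: definitions used for state scoring; bandwidth-normalised dominance makes
#: the tiny gap energy irrelevant.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.2, 3.0),
    "theta": (3.2, 6.0),
    "alpha": (6.2, 12.0),
}

#: band -> awake state mapping
BAND_STATE = {"delta": "a1", "theta": "a2", "alpha": "a3"}

HUMAN_STATES = ("a1", "a2", "a3", "noise")
MOUSE_STATES = ("a1", "a2", "a3", "rem", "nrem", "noise")

_EMG_HP_HZ = 10.0
_BAND_ORDER = ("delta", "theta", "alpha")  # also the tie-break priority


@dataclass
class BandPowers:
    """Mean-square band amplitudes (µV²) of one 1-s epoch."""

    delta: float
    theta: float
    alpha: float
    emg: float | None = None

    def relative(self) -> np.ndarray:
        """Band powers divided by bandwidth, in fixed (delta, theta, alpha) order."""
        widths = np.array([hi - lo for lo, hi in (BANDS[b] for b in _BAND_ORDER)])
        return np.array([self.delta, self.theta, self.alpha]) / widths


@dataclass
class Hypnogram:
    """Per-epoch state labels on the fixed 1-s grid."""

    labels: np.ndarray
    species_mode: str = "human"
    epoch_s: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        valid = HUMAN_STATES if self.species_mode == "human" else MOUSE_STATES
        bad = set(self.labels) - set(valid)
        if bad:
            raise ValueError(f"labels {sorted(bad)} invalid for {self.species_mode} mode")

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    def counts(self) -> pd.Series:
        states = HUMAN_STATES if self.species_mode == "human" else MOUSE_STATES
        c = pd.Series(0, index=list(states), dtype=int)
        vals, n = np.unique(self.labels.astype(str), return_counts=True)
        c[vals] = n
        return c

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "start_s": np.arange(self.n_epochs) * self.epoch_s,
                "label": self.labels.astype(str),
            }
        )


def _band_sos(fs: float) -> dict[str, np.ndarray]:
    return {
        b: sps.butter(4, BANDS[b], btype="bandpass", fs=fs, output="sos")
        for b in _BAND_ORDER
    }


def epoch_band_powers(epoch_signal: np.ndarray, fs: float, emg_epoch: np.ndarray | None = None) -> BandPowers:
    """Band powers of a single, isolated 1-s epoch.

    A 0.2-Hz filter edge cannot settle within one second of samples, so
    for an isolated epoch the band power is integrated from the epoch's
    periodogram bins (mean squared amplitude per band, DC excluded) —
    the spectral equivalent of band-pass-then-mean-square without the
    filter transients.  Epochs scored in context (:func:`score_recording`)
    use whole-recording Butterworth filtering instead.
    """
    x = np.asarray(epoch_signal, dtype=float)
    if len(x) < int(round(fs)):
        raise ValueError("epoch must be exactly 1 s of samples")
    f, p = sps.periodogram(x, fs=fs, window="boxcar")
    df = f[1] - f[0]
    powers = {}
    for b in _BAND_ORDER:
        lo, hi = BANDS[b]
        sel = (f > 0) & (f >= lo) & (f <= hi)
        powers[b] = float(np.sum(p[sel]) * df)
    emg_p = None
    if emg_epoch is not None:
        e = np.asarray(emg_epoch, float)
        fe, pe = sps.periodogram(e, fs=fs, window="boxcar")
        emg_p = float(np.sum(pe[fe > _EMG_HP_HZ]) * df)
    return BandPowers(emg=emg_p, **powers)


def classify_epoch(
    powers: BandPowers,
    rejected: bool = False,
    species_mode: str = "human",
    emg_threshold: float | None = None,
) -> str:
    """State label for one epoch from its band powers.

    Rejected epochs are ``noise``.  Awake dominance is the argmax of
    bandwidth-normalised band power (ties broken delta > theta > alpha).
    In mouse mode a low-EMG epoch becomes ``rem`` when theta-dominant and
    ``nrem`` when delta-dominant; otherwise the awake rule applies.
    """
    if rejected:
        return "noise"
    rel = powers.relative()
    dominant = _BAND_ORDER[int(np.argmax(rel))]
    if species_mode == "mouse" and powers.emg is not None and emg_threshold is not None:
        if powers.emg < emg_threshold:
            if dominant == "theta":
                return "rem"
            if dominant == "delta":
                return "nrem"
    return BAND_STATE[dominant]


def _epoch_powers_full(recording: Recording) -> tuple[np.ndarray, np.ndarray | None]:
    """Band powers for every epoch, averaged over EEG channels.

    The whole trace is filtered once per band and squared samples are then
    averaged per epoch — the same filters as :func:`epoch_band_powers`
    without per-epoch edge transients.  Returns an (n_epochs, 3) array in
    (delta, theta, alpha) order plus the per-epoch EMG power (or None).
    """
    sos = _band_sos(recording.fs)
    eeg = recording.eeg_channels()
    n_ep = recording.n_epochs
    acc = np.zeros((n_ep, len(_BAND_ORDER)))
    for ch in eeg:
        for j, b in enumerate(_BAND_ORDER):
            filt = sps.sosfiltfilt(sos[b], ch.data)
            acc[:, j] += _epoch_view(filt**2, recording.fs).mean(axis=1)
    acc /= len(eeg)
    emg = None
    emg_ch = recording.emg_channels()
    if emg_ch:
        sos_emg = sps.butter(4, _EMG_HP_HZ, btype="highpass", fs=recording.fs, output="sos")
        emg = np.zeros(n_ep)
        for ch in emg_ch:
            filt = sps.sosfiltfilt(sos_emg, ch.data)
            emg += _epoch_view(filt**2, recording.fs).mean(axis=1)
        emg /= len(emg_ch)
    return acc, emg


def score_recording(
    recording: Recording,
    mask: ArtifactMask,
    species_mode: str = "human",
    emg_threshold: float | None = None,
) -> Hypnogram:
    """Score every 1-s epoch of a recording into a vigilance state.

    Multi-channel recordings are scored from the mean EEG-channel band
    powers.  The EMG threshold, when not given, is the geometric mean of
    the epoch EMG powers: muscle tone is bimodal on a log scale
    (wake ≫ sleep), and the geometric mean falls in the valley between
    the modes regardless of the sleep/wake occupancy ratio, which a
    median does not.  Deterministic.
    """
    n_ep = recording.n_epochs
    if mask.n_epochs != n_ep:
        raise ValueError(f"mask has {mask.n_epochs} epochs, recording has {n_ep}")
    powers, emg = _epoch_powers_full(recording)
    widths = np.array([hi - lo for lo, hi in (BANDS[b] for b in _BAND_ORDER)])
    rel = powers / widths
    dominant = np.argmax(rel, axis=1)  # argmax keeps the delta>theta>alpha priority
    labels = np.array([BAND_STATE[_BAND_ORDER[d]] for d in dominant], dtype=object)
    if species_mode == "mouse" and emg is not None:
        if emg_threshold is None:
            emg_threshold = float(np.exp(np.mean(np.log(np.maximum(emg, 1e-30)))))
        thr = emg_threshold
        low = emg < thr
        labels[low & (dominant == 1)] = "rem"
        labels[low & (dominant == 0)] = "nrem"
    labels[mask.epoch_flags] = "noise"
    return Hypnogram(labels=labels, species_mode=species_mode)


def state_proportions(hypnograms: Hypnogram | list[Hypnogram]) -> pd.DataFrame:
    """Per-state occupancy fractions, with cohort mean and CV across subjects.

    Accepts one hypnogram or a list (one per subject).  Returns a frame
    indexed by state with columns ``mean`` (mean fraction, summing to 1)
    and ``cv`` (SD/mean across subjects; 0 for a single subject or a
    never-occupied state).
    """
    if isinstance(hypnograms, Hypnogram):
        hypnograms = [hypnograms]
    if not hypnograms or any(h.n_epochs == 0 for h in hypnograms):
        raise ValueError("state_proportions needs non-empty hypnograms")
    fracs = pd.DataFrame([h.counts() / h.n_epochs for h in hypnograms])
    mean = fracs.mean(axis=0)
    sd = fracs.std(axis=0, ddof=0) if len(fracs) > 1 else mean * 0.0
    cv = sd.where(mean > 0, 0.0) / mean.replace(0, np.nan)
    return pd.DataFrame({"mean": mean, "cv": cv.fillna(0.0)})
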