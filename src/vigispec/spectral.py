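"""State-resolved power spectra and aperiodic (1/f) spectral parameterization.

The central object is :class:`SpectralParameterization`, a model of a power
spectrum as an aperiodic component plus Gaussian oscillatory peaks in
log10 space,

    log10 P(f) = b − χ·log10 f + Σ_k h_k · exp(−(f − c_k)² / (2 s_k²)),

fitted by iterative peak extraction: an initial straight-line fit in
log–log coordinates, a robust refit that ignores points sitting on
oscillatory bumps, iterative detection and subtraction of Gaussian peaks
from the flattened spectrum, a joint nonlinear refit of all peaks, and a
final aperiodic refit on the peak-removed spectrum.  The aperiodic
exponent χ is the quantity of scientific interest (a putative
excitation/inhibition proxy); removing the peaks first is what makes it
robust to oscillatory power, which a naive log–log regression is not.

The model is "fixed" (no knee): a single power law over the analysis
band, 1–65 Hz by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.optimize import curve_fit

from .preprocess import Recording, _epoch_view
from .score import Hypnogram

__all__ = [
    "PowerSpectrum",
    "SpectralParameterization",
    "SpectralFitResults",
    "welch_psd",
    "state_psd",
    "fit_spectral_model",
    "subject_state_exponents",
]

FWHM_TO_SD = 2.0 * np.sqrt(2.0 * np.log(2.0))  # ≈ 2.355


@dataclass
class PowerSpectrum:
    """Linear power spectral density (µV²/Hz) on an increasing Hz grid."""

    freqs: np.ndarray
    power: np.ndarray
    n_epochs: int = 1
    state: str = "all"
    channel: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"freq_hz": self.freqs, "power": self.power})


def welch_psd(
    signal: np.ndarray,
    fs: float,
    fmin: float = 1.0,
    fmax: float = 65.0,
) -> PowerSpectrum:
    """Welch PSD with 2-s Hann segments and 50% overlap, cut to [fmin, fmax]."""
    x = np.asarray(signal, dtype=float)
    if len(x) < 2 * fs:
        raise ValueError("signal must be at least 2 s long")
    nperseg = int(round(2 * fs))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg)
    keep = (f >= fmin) & (f <= fmax)
    n_segments = max(1, (len(x) - nperseg // 2) // (nperseg // 2))
    return PowerSpectrum(freqs=f[keep], power=p[keep], n_epochs=n_segments)


def state_psd(
    recording: Recording,
    hypnogram: Hypnogram,
    state: str,
    min_epochs: int = 30,
    fmin: float = 1.0,
    fmax: float = 65.0,
) -> list[PowerSpectrum]:
    """Average per-epoch periodogram over all epochs of one vigilance state.

    State segments are 1-s fragments scattered through the recording, so
    the estimator is the mean rectangular-window periodogram of the 1-s
    epochs (1 Hz resolution); noise epochs are never included.  Returns
    one spectrum per EEG channel, or an empty list (with a warning) when
    the state has fewer than ``min_epochs`` epochs.
    """
    labels = hypnogram.labels.astype(str)
    n_ep = min(recording.n_epochs, len(labels))
    sel = np.flatnonzero(labels[:n_ep] == state)
    if state == "noise" and len(sel):
        raise ValueError("refusing to average noise epochs")
    if len(sel) < min_epochs:
        warnings.warn(
            f"state {state!r} has {len(sel)} epochs (< {min_epochs}); skipped",
            stacklevel=2,
        )
        return []
    out = []
    for ch in recording.eeg_channels():
        epochs = _epoch_view(ch.data, recording.fs)[sel]
        f, p = sps.periodogram(epochs, fs=recording.fs, window="boxcar", axis=1)
        keep = (f >= fmin) & (f <= fmax)
        out.append(
            PowerSpectrum(
                freqs=f[keep],
                power=p[:, keep].mean(axis=0),
                n_epochs=len(sel),
                state=state,
                channel=ch.name,
            )
        )
    return out


def _gaussian(f: np.ndarray, center: float, height: float, sd: float) -> np.ndarray:
    return height * np.exp(-((f - center) ** 2) / (2.0 * sd**2))


def _sum_gaussians(f: np.ndarray, *params: float) -> np.ndarray:
    total = np.zeros_like(f)
    for i in range(0, len(params), 3):
        total += _gaussian(f, params[i], params[i + 1], params[i + 2])
    return total


@dataclass
class SpectralFitResults:
    """Fitted aperiodic + peak decomposition of one power spectrum.

    ``offset`` and ``exponent`` are b and χ of the aperiodic component;
    ``peaks`` is an (n, 3) array of (center_hz, height_log10, sd_hz);
    ``r_squared`` and ``mae`` are computed on the log10 spectrum.
    """

    offset: float
    exponent: float
    peaks: np.ndarray
    r_squared: float
    mae: float
    freqs: np.ndarray = field(repr=False)
    log_power: np.ndarray = field(repr=False)
    converged: bool = True

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def aperiodic(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Aperiodic component b − χ·log10 f, in log10 power units."""
        f = self.freqs if freqs is None else np.asarray(freqs, float)
        return self.offset - self.exponent * np.log10(f)

    def model(self, freqs: np.ndarray | None = None) -> np.ndarray:
        """Full model (aperiodic + peaks) in log10 power units."""
        f = self.freqs if freqs is None else np.asarray(freqs, float)
        out = self.aperiodic(f)
        for c, h, s in self.peaks:
            out += _gaussian(f, c, h, s)
        return out

    def summary(self) -> str:
        lines = [
            "Spectral parameterization (fixed aperiodic mode)",
            "=" * 48,
            f"frequency range   {self.freqs[0]:.2f}-{self.freqs[-1]:.2f} Hz"
            f" ({len(self.freqs)} points)",
            f"offset (b)        {self.offset: .4f} log10(uV^2/Hz)",
            f"exponent (chi)    {self.exponent: .4f}",
            f"peaks             {self.n_peaks}",
        ]
        for c, h, s in self.peaks:
            lines.append(f"    center {c:6.2f} Hz  height {h:.3f}  sd {s:.2f} Hz")
        lines.append(f"R^2               {self.r_squared: .4f}")
        lines.append(f"MAE (log10)       {self.mae: .4f}")
        if not self.converged:
            lines.append("warning: joint peak refit did not converge; "
                         "iterative estimates reported")
        return "\n".join(lines)

    def plot(self, ax=None):
        """Plot the log spectrum with the aperiodic and full model overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.freqs, self.log_power, "k", lw=1, label="spectrum")
        ax.plot(self.freqs, self.aperiodic(), "b--", label="aperiodic")
        ax.plot(self.freqs, self.model(), "r", alpha=0.7, label="full model")
        ax.set_xscale("log")
        ax.set_xlabel("frequency (Hz)")
        ax.set_ylabel("log10 power")
        ax.legend()
        return ax


class SpectralParameterization:
    """Model of a PSD as aperiodic component plus Gaussian peaks.

    Parameters
    ----------
    spectrum
        A :class:`PowerSpectrum`, or any object with ``freqs``/``power``.
    max_peaks
        Maximum number of Gaussian peaks extracted.
    peak_threshold_sd
        Stop extracting peaks once the flattened-spectrum maximum drops
        below this multiple of the flattened spectrum's SD.
    peak_width_limits
        (lo, hi) full-width-at-half-maximum bounds in Hz.
    """

    def __init__(
        self,
        spectrum: PowerSpectrum,
        max_peaks: int = 6,
        peak_threshold_sd: float = 2.0,
        peak_width_limits: tuple[float, float] = (0.5, 12.0),
        tol: float = 1e-8,
    ) -> None:
        if np.any(spectrum.power <= 0):
            raise ValueError("power must be strictly positive to fit in log space")
        if len(spectrum.freqs) < 20:
            raise ValueError("need at least 20 frequency points")
        self.spectrum = spectrum
        self.max_peaks = int(max_peaks)
        self.peak_threshold_sd = float(peak_threshold_sd)
        self.peak_width_limits = tuple(peak_width_limits)
        self.tol = float(tol)
        self._log_f = np.log10(spectrum.freqs)
        self._log_p = np.log10(spectrum.power)

    # -- aperiodic helpers -------------------------------------------------
    def _linear_aperiodic(self, log_f: np.ndarray, log_p: np.ndarray) -> tuple[float, float]:
        slope, intercept = np.polyfit(log_f, log_p, 1)
        return float(intercept), float(-slope)  # (offset, exponent)

    def _robust_aperiodic(self) -> tuple[float, float]:
        b, chi = self._linear_aperiodic(self._log_f, self._log_p)
        resid = self._log_p - (b - chi * self._log_f)
        flat = np.clip(resid, 0.0, None)
        thresh = np.percentile(flat, 2.5)
        mask = flat <= thresh
        if mask.sum() >= 2:
            b, chi = self._linear_aperiodic(self._log_f[mask], self._log_p[mask])
        return b, chi

    # -- peak extraction ---------------------------------------------------
    def _guess_peaks(self, flat: np.ndarray) -> list[list[float]]:
        f = self.spectrum.freqs
        sd_lo, sd_hi = (w / FWHM_TO_SD for w in self.peak_width_limits)
        work = flat.copy()
        guesses: list[list[float]] = []
        for _ in range(self.max_peaks):
            spread = float(np.std(work))
            if spread == 0.0:
                break
            i = int(np.argmax(work))
            height = float(work[i])
            if height < self.peak_threshold_sd * spread:
                break
            # half-height extent -> FWHM -> sd
            half = height / 2.0
            li = i
            while li > 0 and work[li] > half:
                li -= 1
            ri = i
            while ri < len(work) - 1 and work[ri] > half:
                ri += 1
            left = f[i] - f[li] if work[li] <= half else np.inf
            right = f[ri] - f[i] if work[ri] <= half else np.inf
            hw = min(left, right)
            if not np.isfinite(hw):
                hw = (f[-1] - f[0]) / 4.0
            sd = float(np.clip(2.0 * hw / FWHM_TO_SD, sd_lo, sd_hi))
            guesses.append([float(f[i]), height, sd])
            work = work - _gaussian(f, f[i], height, sd)
        return guesses

    def _refit_peaks(self, flat: np.ndarray, guesses: list[list[float]]) -> tuple[np.ndarray, bool]:
        if not guesses:
            return np.empty((0, 3)), True
        f = self.spectrum.freqs
        sd_lo, sd_hi = (w / FWHM_TO_SD for w in self.peak_width_limits)
        p0, lo, hi = [], [], []
        for c, h, s in guesses:
            p0 += [c, h, s]
            lo += [max(f[0], c - 2 * s), 0.0, sd_lo * 0.999]
            hi += [min(f[-1], c + 2 * s), max(2.0 * h, 1e-3), sd_hi * 1.001]
        try:
            popt, _ = curve_fit(
                _sum_gaussians, f, flat, p0=p0, bounds=(lo, hi),
                xtol=self.tol, maxfev=5000,
            )
            return popt.reshape(-1, 3), True
        except RuntimeError:
            warnings.warn("joint peak refit did not converge; using iterative "
                          "estimates", stacklevel=2)
            return np.asarray(guesses, float).reshape(-1, 3), False

    # -- public API --------------------------------------------------------
    def fit(self) -> SpectralFitResults:
        """Run the full decomposition and return the results object."""
        b, chi = self._robust_aperiodic()
        flat = self._log_p - (b - chi * self._log_f)
        guesses = self._guess_peaks(flat)
        peaks, converged = self._refit_peaks(flat, guesses)
        peak_component = _sum_gaussians(self.spectrum.freqs, *peaks.ravel())
        b, chi = self._linear_aperiodic(self._log_f, self._log_p - peak_component)
        model = b - chi * self._log_f + peak_component
        resid = self._log_p - model
        ss_tot = float(np.sum((self._log_p - self._log_p.mean()) ** 2))
        r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
        return SpectralFitResults(
            offset=b,
            exponent=chi,
            peaks=peaks[np.argsort(peaks[:, 0])] if len(peaks) else peaks,
            r_squared=float(np.clip(r2, 0.0, 1.0)),
            mae=float(np.mean(np.abs(resid))),
            freqs=self.spectrum.freqs,
            log_power=self._log_p,
            converged=converged,
        )


def fit_spectral_model(
    spectrum: PowerSpectrum,
    max_peaks: int = 6,
    peak_threshold_sd: float = 2.0,
    peak_width_limits: tuple[float, float] = (0.5, 12.0),
) -> SpectralFitResults:
    """Convenience wrapper: build and fit a :class:`SpectralParameterization`."""
    return SpectralParameterization(
        spectrum,
        max_peaks=max_peaks,
        peak_threshold_sd=peak_threshold_sd,
        peak_width_limits=peak_width_limits,
    ).fit()


def subject_state_exponents(fits: pd.DataFrame) -> pd.DataFrame:
    """Pool channel-level fits to one exponent per subject × state.

    Expects a frame with columns ``subject, group, sex, state, channel,
    exponent`` (extra numeric columns are averaged too).  Channels within
    a subject are strongly correlated, so they are collapsed by the
    arithmetic mean, yielding one row per subject × state.
    """
    required = {"subject", "state", "exponent"}
    if not required <= set(fits.columns):
        raise ValueError(f"fits table needs columns {sorted(required)}")
    keys = [c for c in ("subject", "group", "sex", "state") if c in fits.columns]
    num = fits.select_dtypes("number").columns.difference(["n_epochs"])
    agg = {c: "mean" for c in num}
    if "n_epochs" in fits.columns:
        agg["n_epochs"] = "first"
    return fits.groupby(keys, as_index=False, sort=True).agg(agg)
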