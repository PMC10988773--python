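"""Amplitude spectra with exact frequency-bin bookkeeping.

Frequency tagging concentrates the response of interest in single FFT bins,
so the transform is taken without windowing or zero-padding: the bin
spacing is exactly ``1/duration`` and a cycle-cropped epoch puts every
stimulation frequency precisely on a bin centre.  The amplitude
normalization is chosen so that a real sinusoid of peak amplitude A uV
sitting on a bin reads A uV in the spectrum (``2|X|/N``; DC and Nyquist
unscaled).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, FrequencyAlignmentError
from .preprocess import Epoch


@dataclass
class AmplitudeSpectrum:
    """Per-channel one-sided amplitude spectrum on a uniform frequency grid."""

    amps: np.ndarray  # channels x bins, uV
    freqs: np.ndarray  # bin centres, Hz
    df_hz: float
    channel_names: list[str]

    def __post_init__(self) -> None:
        if self.amps.ndim != 2 or self.amps.shape[1] != len(self.freqs):
            raise ConfigurationError("amps must be channels x bins matching freqs")
        if self.amps.shape[0] != len(self.channel_names):
            raise ConfigurationError("channel count mismatch")

    @property
    def n_bins(self) -> int:
        return len(self.freqs)

    @property
    def nyquist_hz(self) -> float:
        return float(self.freqs[-1])

    def channel(self, name: str) -> np.ndarray:
        return self.amps[self.channel_names.index(name)]


def amplitude_spectrum(epoch: Epoch) -> AmplitudeSpectrum:
    """FFT amplitude spectrum of an epoch (rectangular window, no padding)."""
    n = epoch.n_samples
    spec = np.fft.rfft(epoch.data, axis=1)
    amps = np.abs(spec) * (2.0 / n)
    amps[:, 0] /= 2.0
    if n % 2 == 0:  # Nyquist bin present and unsplit
        amps[:, -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / epoch.fs_hz)
    return AmplitudeSpectrum(
        amps=amps,
        freqs=freqs,
        df_hz=epoch.fs_hz / n,
        channel_names=list(epoch.channel_names),
    )


def freq_resolution(epoch_duration_s: float) -> float:
    """Spectral bin spacing of an epoch: 1/duration (Hz)."""
    if epoch_duration_s <= 0:
        raise ConfigurationError("duration must be positive")
    return 1.0 / epoch_duration_s


def bin_index(spectrum: AmplitudeSpectrum, f_hz: float,
              tol: float | None = None) -> int:
    """Index of the bin at ``f_hz``; errors if no bin centre lies within ``tol``.

    The default tolerance is half a bin, so any frequency maps to its
    nearest bin; pass a tighter ``tol`` to insist on exact alignment.
    """
    if not (0 <= f_hz <= spectrum.nyquist_hz + 1e-12):
        raise FrequencyAlignmentError(
            f"{f_hz} Hz outside [0, {spectrum.nyquist_hz}] Hz"
        )
    if tol is None:
        tol = spectrum.df_hz / 2.0
    i = int(np.round(f_hz / spectrum.df_hz))
    i = min(max(i, 0), spectrum.n_bins - 1)
    if abs(spectrum.freqs[i] - f_hz) >= tol:
        raise FrequencyAlignmentError(
            f"no bin within {tol} Hz of {f_hz} Hz (nearest: {spectrum.freqs[i]} Hz)"
        )
    return i
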