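"""Preprocessing chain for frequency-tagged EEG.

The stages mirror standard FPVS practice and are applied in a fixed order:

1. FFT band-pass filter (0.1-100 Hz, hard spectral mask, zero-phase);
2. segmentation around stimulation onset (-2 to +62 s);
3. resampling to 512 Hz;
4. bad-channel interpolation (inverse-distance over k nearest neighbours);
5. re-referencing to the common average;
6. cropping to an integer number of oddball cycles (120 cycles of 500 ms),
   so both the oddball frequency and the base rate land exactly on FFT bins.

`preprocess` composes the stages in that order; the individual functions
are pure and reusable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal

from .errors import ConfigurationError, SegmentationError
from .montage import Montage
from .synth import Recording


@dataclass
class Epoch:
    """A segmented chunk of multi-channel EEG.

    ``t0_s`` is the time of the first sample relative to stimulation onset
    (negative for pre-stimulation baseline).
    """

    data: np.ndarray  # channels x samples
    fs_hz: float
    t0_s: float
    channel_names: list[str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.ndim != 2 or self.data.shape[1] == 0:
            raise ConfigurationError("epoch data must be channels x samples, non-empty")
        if self.fs_hz <= 0:
            raise ConfigurationError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_samples) / self.fs_hz


def bandpass_fft(recording: Recording, lo_hz: float = 0.1, hi_hz: float = 100.0,
                 transition_hz: float = 0.0) -> Recording:
    """Zero-phase FFT band-pass: Fourier coefficients outside [lo, hi] zeroed.

    The default is a hard spectral mask; ``transition_hz`` > 0 applies a
    raised-cosine roll-off of that width at both edges for users sensitive
    to ringing.
    """
    nyq = recording.fs_hz / 2.0
    if not (0 <= lo_hz < hi_hz <= nyq):
        raise ConfigurationError(
            f"band [{lo_hz}, {hi_hz}] Hz invalid for Nyquist {nyq} Hz"
        )
    n = recording.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / recording.fs_hz)
    if transition_hz <= 0:
        gain = ((freqs >= lo_hz) & (freqs <= hi_hz)).astype(float)
    else:
        gain = np.ones_like(freqs)
        lo_ramp = (freqs >= lo_hz - transition_hz) & (freqs < lo_hz)
        gain[freqs < lo_hz - transition_hz] = 0.0
        gain[lo_ramp] = 0.5 * (1 - np.cos(np.pi * (freqs[lo_ramp] - lo_hz + transition_hz)
                                          / transition_hz))
        hi_ramp = (freqs > hi_hz) & (freqs <= hi_hz + transition_hz)
        gain[freqs > hi_hz + transition_hz] = 0.0
        gain[hi_ramp] = 0.5 * (1 + np.cos(np.pi * (freqs[hi_ramp] - hi_hz)
                                          / transition_hz))
    spec = np.fft.rfft(recording.data, axis=1)
    filtered = np.fft.irfft(spec * gain, n=n, axis=1)
    return replace(recording, data=filtered)


def segment(recording: Recording, onset_marker: str = "sequence_onset",
            pre_s: float = 2.0, post_s: float = 62.0) -> Epoch:
    """Cut an epoch of [-pre_s, post_s) around a named marker."""
    onset = recording.marker_sample(onset_marker)
    start = onset - round(pre_s * recording.fs_hz)
    stop = onset + round(post_s * recording.fs_hz)
    if start < 0 or stop > recording.n_samples:
        raise SegmentationError(
            f"window [{start}, {stop}) outside recording of {recording.n_samples} samples"
        )
    return Epoch(
        data=recording.data[:, start:stop].copy(),
        fs_hz=recording.fs_hz,
        t0_s=-pre_s,
        channel_names=list(recording.channel_names),
        meta={"onset_marker": onset_marker},
    )


def resample(epoch: Epoch, target_fs: float = 512.0) -> Epoch:
    """Polyphase resampling to a lower rate; preserves in-band amplitudes."""
    if target_fs > epoch.fs_hz:
        raise ConfigurationError("upsampling is out of scope")
    if target_fs == epoch.fs_hz:
        return replace(epoch, data=epoch.data.copy())
    frac = Fraction(target_fs / epoch.fs_hz).limit_denominator(1000)
    data = signal.resample_poly(epoch.data, frac.numerator, frac.denominator, axis=1)
    return replace(epoch, data=data, fs_hz=target_fs)


def interpolate_channels(epoch: Epoch, bad: list[str], montage: Montage,
                         k: int = 4) -> Epoch:
    """Replace bad channels by inverse-distance means of k nearest good ones."""
    bad = list(bad)
    unknown = [c for c in bad if c not in epoch.channel_names]
    if unknown:
        raise ConfigurationError(f"bad channels not in epoch: {unknown}")
    good = [c for c in epoch.channel_names if c not in bad]
    if len(good) < k:
        raise ConfigurationError(f"need at least {k} good channels, have {len(good)}")
    if not bad:
        return replace(epoch, data=epoch.data.copy())
    idx = {c: i for i, c in enumerate(epoch.channel_names)}
    data = epoch.data.copy()
    for c in bad:
        neighbours = montage.k_nearest(c, good, k)
        w = np.array([1.0 / max(d, 1e-12) for _, d in neighbours])
        w /= w.sum()
        rows = [idx[name] for name, _ in neighbours]
        data[idx[c]] = w @ epoch.data[rows]
    return replace(epoch, data=data)


def rereference_average(epoch: Epoch) -> Epoch:
    """Re-reference to the common average: per-sample channel mean becomes 0."""
    if epoch.data.shape[0] < 2:
        raise ConfigurationError("average reference needs at least 2 channels")
    return replace(epoch, data=epoch.data - epoch.data.mean(axis=0, keepdims=True))


def crop_to_cycles(epoch: Epoch, cycle_s: float = 0.5,
                   stim_s: float | None = None) -> Epoch:
    """Crop from stimulation onset to the largest whole number of cycles.

    With the default 500-ms oddball cycle a 60-s stimulation window keeps
    120 cycles (30,720 samples at 512 Hz; last retained timestamp
    30,719/512 = 59.998 s), aligning both the oddball frequency and the
    base rate exactly with FFT bins.  ``stim_s`` bounds the usable window
    (the stimulation duration) when the epoch extends beyond it.
    """
    start = round(-epoch.t0_s * epoch.fs_hz)
    if start < 0 or start >= epoch.n_samples:
        raise SegmentationError("epoch does not cover stimulation onset")
    available_s = (epoch.n_samples - start) / epoch.fs_hz
    if stim_s is None:
        stim_s = epoch.meta.get("stim_duration_s", available_s)
    usable = min(available_s, stim_s)
    n_cycles = int(np.floor(usable / cycle_s + 1e-9))
    if n_cycles < 1:
        raise SegmentationError(
            f"epoch covers {usable:.3f}s after onset, less than one {cycle_s}s cycle"
        )
    n_keep = round(n_cycles * cycle_s * epoch.fs_hz)
    meta = dict(epoch.meta, n_cycles=n_cycles, cycle_s=cycle_s)
    return Epoch(
        data=epoch.data[:, start:start + n_keep].copy(),
        fs_hz=epoch.fs_hz,
        t0_s=0.0,
        channel_names=list(epoch.channel_names),
        meta=meta,
    )


def average_epochs(epochs: list[Epoch]) -> Epoch:
    """Sample-wise arithmetic mean of repeated sequences (time-domain averaging)."""
    if not epochs:
        raise ConfigurationError("no epochs to average")
    first = epochs[0]
    for e in epochs[1:]:
        if e.data.shape != first.data.shape or e.fs_hz != first.fs_hz \
                or abs(e.t0_s - first.t0_s) > 1e-9:
            raise ConfigurationError("epochs differ in shape, rate or alignment")
    data = np.mean([e.data for e in epochs], axis=0)
    meta = dict(first.meta, n_averaged=len(epochs))
    return Epoch(data=data, fs_hz=first.fs_hz, t0_s=first.t0_s,
                 channel_names=list(first.channel_names), meta=meta)


def preprocess(
    recording: Recording,
    montage: Montage | None = None,
    bad_channels: list[str] | None = None,
    lo_hz: float = 0.1,
    hi_hz: float = 100.0,
    pre_s: float = 2.0,
    post_s: float = 62.0,
    target_fs: float = 512.0,
    cycle_s: float = 0.5,
    stim_s: float = 60.0,
    interp_k: int = 4,
) -> Epoch:
    """The full chain: filter -> segment -> resample -> interpolate -> re-reference -> crop."""
    rec = bandpass_fft(recording, lo_hz, hi_hz)
    epoch = segment(rec, pre_s=pre_s, post_s=post_s)
    epoch = resample(epoch, target_fs)
    if bad_channels:
        if montage is None:
            raise ConfigurationError("bad-channel interpolation requires a montage")
        epoch = interpolate_channels(epoch, bad_channels, montage, k=interp_k)
    epoch = rereference_average(epoch)
    epoch.meta["stim_duration_s"] = stim_s
    return crop_to_cycles(epoch, cycle_s=cycle_s, stim_s=stim_s)
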