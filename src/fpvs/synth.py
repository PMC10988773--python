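"""Synthetic multi-channel EEG with known frequency-tagged responses.

The generator emulates the study's acquisition — a 68-channel cap sampled
at 1024 Hz, 60-s stimulation sequences flanked by 2-s fades — with a fully
known ground truth so every downstream stage can be tested without real
recordings.  A recording is the sum of:

* a *base-rate* steady-state response: cosines at 10 Hz and harmonics,
  weighted by a medial-occipital topography;
* an *oddball* response: cosines at 2 Hz and its non-base harmonics
  (2/4/6/8 Hz), weighted by a left-lateralized occipito-temporal
  topography (right-hemisphere weights about a third of the left, mirroring
  the left-dominant word-discrimination response);
* 1/f ("pink") background noise, optional narrow-band alpha, and optional
  white sensor noise, all drawn independently per channel.

Responses are phase-locked to stimulation onset and ramp linearly over the
fade windows.  All harmonic frequencies are commensurate with the 60-s
window, so injected components land exactly on FFT bins after cycle
cropping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .design import SequencePlan
from .errors import ConfigurationError
from .montage import CHANNELS_68

#: Reference bin width for noise amplitude calibration: one 60-s window.
REFERENCE_DF_HZ = 1.0 / 60.0


@dataclass
class ResponseSpec:
    """A periodic steady-state response: harmonics of one fundamental.

    ``harmonic_amps`` lists (harmonic index k, peak amplitude in uV); the
    component at ``k * freq_hz`` Hz is ``amp * cos(2*pi*k*f*t + phase)``
    scaled per channel by ``topography`` (weights in [0, 1], absent
    channels = 0).
    """

    freq_hz: float
    harmonic_amps: list[tuple[int, float]]
    topography: dict[str, float]
    harmonic_phases: list[float] | None = None

    def __post_init__(self) -> None:
        if any(a < 0 for _, a in self.harmonic_amps):
            raise ConfigurationError("harmonic amplitudes must be >= 0")
        if self.topography and not any(w > 0 for w in self.topography.values()):
            raise ConfigurationError("topography needs at least one positive weight")

    def phases(self) -> list[float]:
        if self.harmonic_phases is None:
            return [0.0] * len(self.harmonic_amps)
        return list(self.harmonic_phases)

    def scaled(self, factor: float) -> "ResponseSpec":
        return ResponseSpec(
            self.freq_hz,
            [(k, a * factor) for k, a in self.harmonic_amps],
            dict(self.topography),
            self.harmonic_phases,
        )


@dataclass
class NoiseSpec:
    """Background noise model: 1/f + optional alpha bump + white noise.

    ``pink_scale`` is the expected amplitude-spectrum value (uV) at 1 Hz on
    a 60-s analysis window; the noise floor then falls off as
    ``f**(-pink_exponent/2)`` in amplitude.  ``alpha_amp`` adds a
    narrow-band Gaussian bump centred at ``alpha_freq_hz`` (off by
    default).  ``white_scale`` is the time-domain SD of additive white
    Gaussian noise in uV.
    """

    pink_exponent: float = 1.0
    pink_scale: float = 0.15
    alpha_amp: float = 0.0
    alpha_freq_hz: float = 10.0
    alpha_bw_hz: float = 1.0
    white_scale: float = 0.02

    def __post_init__(self) -> None:
        if min(self.pink_scale, self.alpha_amp, self.white_scale) < 0:
            raise ConfigurationError("noise scales must be >= 0")

    def is_silent(self) -> bool:
        return self.pink_scale == 0 and self.alpha_amp == 0 and self.white_scale == 0


@dataclass
class Recording:
    """Multi-channel time series in uV with sample-indexed event markers."""

    data: np.ndarray  # channels x samples
    fs_hz: float
    channel_names: list[str]
    markers: list[tuple[int, str]] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        if self.data.shape[0] != len(self.channel_names):
            raise ConfigurationError("channel count != number of channel names")
        if self.fs_hz <= 0:
            raise ConfigurationError("sampling rate must be positive")
        for s, _ in self.markers:
            if not (0 <= s < self.data.shape[1]):
                raise ConfigurationError(f"marker sample {s} out of bounds")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def marker_sample(self, label: str) -> int:
        for s, lbl in self.markers:
            if lbl == label:
                return s
        raise KeyError(f"no marker {label!r}")


def default_oddball_response(amps: tuple[float, ...] = (0.30, 0.22, 0.15, 0.10)
                             ) -> ResponseSpec:
    """Left-lateralized oddball response at 2 Hz and harmonics 4/6/8 Hz.

    Weights peak around PO7 with right-hemisphere homologues at one third,
    emulating the roughly threefold left-hemisphere dominance of the
    word-discrimination response.
    """
    topo = {
        "PO7": 1.00, "P7": 0.80, "P9": 0.70, "PO9": 0.75, "O1": 0.60,
        "PO8": 0.33, "P8": 0.27, "P10": 0.23, "PO10": 0.25, "O2": 0.20,
        "PO3": 0.35, "P5": 0.40, "PO4": 0.12,
    }
    return ResponseSpec(2.0, [(k + 1, a) for k, a in enumerate(amps)], topo)


def default_base_response(amps: tuple[float, ...] = (1.0, 0.5, 0.25, 0.12)
                          ) -> ResponseSpec:
    """Medial-occipital base-rate response at 10 Hz and harmonics."""
    topo = {
        "Oz": 1.00, "Iz": 0.90, "O1": 0.80, "O2": 0.80,
        "POz": 0.70, "PO3": 0.45, "PO4": 0.45, "I1": 0.55, "I2": 0.55,
    }
    return ResponseSpec(10.0, [(k + 1, a) for k, a in enumerate(amps)], topo)


def make_pink_noise(
    n_samples: int,
    fs_hz: float,
    exponent: float = 1.0,
    scale: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Zero-mean 1/f^exponent noise via spectral shaping of white noise.

    Random-phase Fourier coefficients are drawn with SD proportional to
    ``f**(-exponent/2)`` and calibrated so the expected amplitude-spectrum
    value at 1 Hz on a 60-s analysis window equals ``scale`` uV (power
    spectral density is duration-invariant, so any sub-window of the output
    shows the same floor).
    """
    if n_samples <= 0:
        raise ConfigurationError("n_samples must be positive")
    if scale == 0:
        return np.zeros(n_samples)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    sigma = np.zeros_like(freqs)
    nz = freqs > 0
    sigma[nz] = freqs[nz] ** (-exponent / 2.0)
    # E|c| for c = sigma*(g1+i*g2)/sqrt(2) is sigma*sqrt(pi)/2; with the
    # 2|C|/N amplitude convention and bin width df = fs/N, matching the
    # reference 1/60-Hz grid requires the sqrt(df/df_ref) factor.
    df = fs_hz / n_samples
    target = scale * np.sqrt(df / REFERENCE_DF_HZ)
    amp_factor = target * n_samples / 2.0 / (np.sqrt(np.pi) / 2.0)
    coefs = sigma * (rng.standard_normal(len(freqs))
                     + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2.0)
    x = np.fft.irfft(amp_factor * coefs, n=n_samples)
    return x - x.mean()


def _alpha_noise(n_samples: int, fs_hz: float, spec: NoiseSpec,
                 rng: np.random.Generator) -> np.ndarray:
    """Narrow-band Gaussian bump centred on the alpha frequency."""
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs_hz)
    envelope = np.exp(-0.5 * ((freqs - spec.alpha_freq_hz) / spec.alpha_bw_hz) ** 2)
    df = fs_hz / n_samples
    target = spec.alpha_amp * np.sqrt(df / REFERENCE_DF_HZ)
    amp_factor = target * n_samples / 2.0 / (np.sqrt(np.pi) / 2.0)
    coefs = envelope * (rng.standard_normal(len(freqs))
                        + 1j * rng.standard_normal(len(freqs))) / np.sqrt(2.0)
    coefs[0] = 0
    return np.fft.irfft(amp_factor * coefs, n=n_samples)


def _envelope(t: np.ndarray, stim_s: float, fade_in_s: float,
              fade_out_s: float) -> np.ndarray:
    """Response amplitude envelope: linear fades around the stimulation window.

    ``t`` is time relative to stimulation onset; the envelope ramps from 0
    at ``-fade_in_s`` to 1 at 0, holds 1 through ``stim_s``, then ramps back
    to 0 at ``stim_s + fade_out_s``.
    """
    env = np.zeros_like(t)
    if fade_in_s > 0:
        m = (t >= -fade_in_s) & (t < 0)
        env[m] = 1.0 + t[m] / fade_in_s
    core = (t >= 0) & (t <= stim_s)
    env[core] = 1.0
    if fade_out_s > 0:
        m = (t > stim_s) & (t <= stim_s + fade_out_s)
        env[m] = 1.0 - (t[m] - stim_s) / fade_out_s
    return env


def synthesize_recording(
    plan: SequencePlan,
    oddball: ResponseSpec | None = None,
    base: ResponseSpec | None = None,
    noise: NoiseSpec | None = None,
    channel_names: list[str] | None = None,
    fs_hz: float = 1024.0,
    seed: int = 0,
) -> Recording:
    """Render one sequence plan into a synthetic multi-channel recording.

    The recording spans fade-in + stimulation + fade-out; markers tag the
    fade boundaries, stimulation onset/offset and every task event.  The
    ground truth (injected responses, noise spec, per-channel expected
    amplitudes after common-average referencing) travels in
    ``Recording.ground_truth`` for test oracles.
    """
    oddball = oddball if oddball is not None else default_oddball_response()
    base = base if base is not None else default_base_response()
    noise = noise if noise is not None else NoiseSpec()
    channel_names = list(channel_names) if channel_names else list(CHANNELS_68)
    f_max = max(
        (k * r.freq_hz for r in (oddball, base) for k, _ in r.harmonic_amps),
        default=0.0,
    )
    if fs_hz < 2 * f_max:
        raise ConfigurationError(
            f"fs {fs_hz} Hz below Nyquist for max simulated frequency {f_max} Hz"
        )
    n_ch = len(channel_names)
    total_s = plan.fade_in_s + plan.duration_s + plan.fade_out_s
    n = round(total_s * fs_hz)
    t = np.arange(n) / fs_hz - plan.fade_in_s  # relative to stimulation onset
    env = _envelope(t, plan.duration_s, plan.fade_in_s, plan.fade_out_s)

    data = np.zeros((n_ch, n))
    for resp in (oddball, base):
        weights = np.array([resp.topography.get(c, 0.0) for c in channel_names])
        if not weights.any():
            continue
        comp = np.zeros(n)
        for (k, amp), phase in zip(resp.harmonic_amps, resp.phases()):
            comp += amp * np.cos(2 * np.pi * k * resp.freq_hz * t + phase)
        data += np.outer(weights, env * comp)

    rng = np.random.default_rng(seed)
    if not noise.is_silent():
        for c in range(n_ch):
            if noise.pink_scale > 0:
                data[c] += make_pink_noise(n, fs_hz, noise.pink_exponent,
                                           noise.pink_scale, rng)
            if noise.alpha_amp > 0:
                data[c] += _alpha_noise(n, fs_hz, noise, rng)
            if noise.white_scale > 0:
                data[c] += noise.white_scale * rng.standard_normal(n)

    onset = round(plan.fade_in_s * fs_hz)
    markers = [
        (0, "fade_in_start"),
        (onset, "sequence_onset"),
        (round((plan.fade_in_s + plan.duration_s) * fs_hz) - 1, "sequence_offset"),
        (n - 1, "fade_out_end"),
    ]
    for ev in plan.events:
        markers.append((onset + round(ev.onset_s * fs_hz), f"event/{ev.kind}"))
    markers.sort()

    truth = {
        "oddball": _response_truth(oddball, channel_names),
        "base": _response_truth(base, channel_names),
        "noise": {
            "pink_exponent": noise.pink_exponent, "pink_scale": noise.pink_scale,
            "alpha_amp": noise.alpha_amp, "white_scale": noise.white_scale,
        },
        "seed": seed,
    }
    return Recording(data=data, fs_hz=fs_hz, channel_names=channel_names,
                     markers=markers, ground_truth=truth)


def _response_truth(resp: ResponseSpec, channel_names: list[str]) -> dict:
    """Ground truth for one response, including post-average-reference amplitudes.

    Common-average referencing subtracts the across-channel mean, so a
    topography with non-zero mean weight leaves each channel with an
    effective weight of ``w - mean(w)``; oracle comparisons must use these
    referenced amplitudes, not the raw injected ones.
    """
    weights = np.array([resp.topography.get(c, 0.0) for c in channel_names])
    w_ref = weights - weights.mean()
    return {
        "freq_hz": resp.freq_hz,
        "harmonics": [
            {
                "freq_hz": k * resp.freq_hz,
                "amp": amp,
                "referenced_amp_per_channel": {
                    c: float(amp * w_ref[i]) for i, c in enumerate(channel_names)
                },
            }
            for k, amp in resp.harmonic_amps
        ],
        "topography": {c: float(weights[i]) for i, c in enumerate(channel_names)},
        "mean_weight": float(weights.mean()),
    }
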