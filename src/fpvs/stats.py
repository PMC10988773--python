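"""Frequency-domain oddball statistics.

The response at a tagged frequency is evaluated against the *neighbouring
bins* of the same spectrum, which serve as an empirical noise estimate:

* **SNR** — bin amplitude divided by the mean of the 20 surrounding bins
  (10 on each side, immediately adjacent included); 1 under pure noise.
* **Baseline-subtracted amplitude** — bin amplitude minus the mean of a
  20-bin noise window that excludes the immediately adjacent bin on each
  side and the single most extreme (min and max) of the remainder; an
  estimate of the periodic signal in uV.
* **Z-score** — the same baseline-subtracted amplitude divided by the
  sample SD of that noise window; conventionally thresholded at 3.1
  (p < .001, one-tailed) for group-level harmonic selection and 1.64
  (p < .05) for individual-level significance.

Responses spread over harmonics are quantified by summing the
baseline-subtracted amplitudes of the significant harmonics, excluding
every multiple of the base stimulation rate (where general visual and
oddball responses are confounded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import ConfigurationError, EdgeError
from .spectral import AmplitudeSpectrum, bin_index

#: One-tailed critical values used throughout.
Z_GROUP = 3.1        # p < .001, group-level harmonic selection
Z_INDIVIDUAL = 1.64  # p < .05, individual-level significance


def critical_z(p: float) -> float:
    """One-tailed normal critical value for tail probability ``p``."""
    if not (0 < p < 1):
        raise ConfigurationError("p must be in (0, 1)")
    return float(sps.norm.isf(p))


@dataclass(frozen=True)
class NoiseWindowSpec:
    """Which neighbouring bins form the empirical noise distribution."""

    mode: str  # "snr" or "zscore"
    n_side: int
    exclude_adjacent: int = 0
    exclude_extremes: bool = False

    @classmethod
    def snr_default(cls) -> "NoiseWindowSpec":
        """10 bins per side, adjacent included: 20 noise bins."""
        return cls(mode="snr", n_side=10)

    @classmethod
    def zscore_default(cls) -> "NoiseWindowSpec":
        """12 per side minus adjacent minus global min/max: 20 noise bins."""
        return cls(mode="zscore", n_side=12, exclude_adjacent=1,
                   exclude_extremes=True)


@dataclass
class BinStats:
    """All noise-referenced indices for one target frequency bin."""

    f_hz: float
    amp: float
    noise_mean: float
    noise_sd: float
    snr: float
    corrected_amp: float
    z: float


@dataclass
class HarmonicSummary:
    """Baseline-subtracted amplitudes summed over a set of harmonics."""

    f_fund: float
    harmonics_used: list[float]
    summed_corrected_amp: float
    per_harmonic: list[BinStats] = field(default_factory=list)


def _amps_1d(spectrum: AmplitudeSpectrum | np.ndarray) -> np.ndarray:
    if isinstance(spectrum, AmplitudeSpectrum):
        if spectrum.amps.shape[0] != 1:
            raise ConfigurationError(
                "per-bin statistics need a single-channel (e.g. ROI-averaged) spectrum"
            )
        return spectrum.amps[0]
    a = np.asarray(spectrum, dtype=float)
    if a.ndim != 1:
        raise ConfigurationError("expected a 1-D amplitude vector")
    return a


def noise_bins(spectrum: AmplitudeSpectrum | np.ndarray, target_bin: int,
               spec: NoiseWindowSpec) -> np.ndarray:
    """Sorted indices of the noise bins around ``target_bin``.

    ``snr`` mode returns the ``n_side`` bins on each side verbatim; ``zscore``
    mode drops ``exclude_adjacent`` bins next to the target on each side and
    then, if requested, the single global minimum and maximum of the
    remaining candidates (ties broken toward the lowest bin index).
    """
    amps = _amps_1d(spectrum)
    n = len(amps)
    lo = target_bin - spec.n_side
    hi = target_bin + spec.n_side
    if lo < 0 or hi >= n:
        raise EdgeError(
            f"noise window [{lo}, {hi}] around bin {target_bin} exceeds "
            f"spectrum of {n} bins"
        )
    idx = [i for i in range(lo, hi + 1)
           if i != target_bin and abs(i - target_bin) > spec.exclude_adjacent]
    if spec.exclude_extremes:
        vals = amps[idx]
        i_min = idx[int(np.argmin(vals))]
        idx.remove(i_min)
        vals = amps[idx]
        i_max = idx[int(np.argmax(vals))]
        idx.remove(i_max)
    return np.array(idx)


def bin_stats(
    spectrum: AmplitudeSpectrum | np.ndarray,
    f_target: float,
    snr_spec: NoiseWindowSpec | None = None,
    z_spec: NoiseWindowSpec | None = None,
    df_hz: float | None = None,
) -> BinStats:
    """SNR, baseline-subtracted amplitude and z-score at one target frequency.

    When a raw amplitude vector is passed instead of a spectrum, ``f_target``
    is interpreted as a bin index unless ``df_hz`` is given.
    """
    snr_spec = snr_spec or NoiseWindowSpec.snr_default()
    z_spec = z_spec or NoiseWindowSpec.zscore_default()
    amps = _amps_1d(spectrum)
    if isinstance(spectrum, AmplitudeSpectrum):
        tb = bin_index(spectrum, f_target)
        f_hz = float(spectrum.freqs[tb])
    else:
        tb = int(round(f_target / df_hz)) if df_hz else int(round(f_target))
        f_hz = f_target
    amp = float(amps[tb])
    snr_win = amps[noise_bins(amps, tb, snr_spec)]
    z_win = amps[noise_bins(amps, tb, z_spec)]
    snr_noise = float(snr_win.mean())
    snr = amp / snr_noise if snr_noise > 0 else np.inf
    noise_mean = float(z_win.mean())
    noise_sd = float(z_win.std(ddof=1))
    corrected = amp - noise_mean
    if noise_sd > 0:
        z = corrected / noise_sd
    else:
        warnings.warn("noise window has zero SD; z reported as +/-inf")
        z = np.inf if corrected > 0 else (-np.inf if corrected < 0 else 0.0)
    return BinStats(f_hz=f_hz, amp=amp, noise_mean=noise_mean, noise_sd=noise_sd,
                    snr=float(snr), corrected_amp=float(corrected), z=float(z))


def snr_spectrum(spectrum: AmplitudeSpectrum,
                 snr_spec: NoiseWindowSpec | None = None) -> AmplitudeSpectrum:
    """Element-wise SNR across the whole spectrum (edge bins become NaN).

    Each interior bin is divided by the mean of its ``n_side`` neighbours on
    each side (target excluded).  The baseline level under pure noise is 1.
    """
    snr_spec = snr_spec or NoiseWindowSpec.snr_default()
    amps = spectrum.amps
    k = snr_spec.n_side
    n = amps.shape[1]
    out = np.full_like(amps, np.nan, dtype=float)
    if n >= 2 * k + 1:
        csum = np.cumsum(np.pad(amps, ((0, 0), (1, 0))), axis=1)
        # windowed sum over [i-k, i+k] inclusive, minus the target bin
        win = csum[:, 2 * k + 1:] - csum[:, :-(2 * k + 1)]
        centre = amps[:, k:n - k]
        noise = (win - centre) / (2 * k)
        with np.errstate(divide="ignore", invalid="ignore"):
            out[:, k:n - k] = np.where(noise > 0, centre / noise, np.inf)
    return AmplitudeSpectrum(amps=out, freqs=spectrum.freqs.copy(),
                             df_hz=spectrum.df_hz,
                             channel_names=list(spectrum.channel_names))


def candidate_harmonics(f_fund: float, f_base: float | None, f_max: float,
                        exclude_base: bool = True) -> list[float]:
    """Harmonics of ``f_fund`` up to ``f_max``, minus multiples of ``f_base``.

    Oddball and base-rate responses superimpose at shared multiples (10 Hz,
    20 Hz, ... for a 2 Hz oddball in a 10 Hz stream), so those bins are
    excluded from oddball quantification.  Pass ``exclude_base=False`` (or
    ``f_base=None``) when quantifying the base-rate response itself.
    """
    if f_fund <= 0:
        raise ConfigurationError("fundamental must be positive")
    ks = np.arange(1, int(np.floor(f_max / f_fund + 1e-9)) + 1)
    freqs = [float(k * f_fund) for k in ks]
    if exclude_base and f_base:
        freqs = [f for f in freqs
                 if abs(f / f_base - round(f / f_base)) > 1e-9]
    return freqs


def select_significant_harmonics(
    group_spectrum: AmplitudeSpectrum,
    candidates: list[float],
    z_spec: NoiseWindowSpec | None = None,
    z_crit: float = Z_GROUP,
) -> list[float]:
    """Harmonics whose group-level z exceeds ``z_crit`` on the grand average.

    Selection is made once on the designated group spectrum and then applied
    unchanged to every participant.
    """
    return [f for f in candidates
            if bin_stats(group_spectrum, f, z_spec=z_spec).z > z_crit]


def sum_harmonics(
    spectrum: AmplitudeSpectrum,
    harmonics: list[float],
    snr_spec: NoiseWindowSpec | None = None,
    z_spec: NoiseWindowSpec | None = None,
) -> HarmonicSummary:
    """Sum baseline-subtracted amplitudes over ``harmonics``.

    Negative per-harmonic corrected amplitudes are retained, keeping the
    sum unbiased around zero in the absence of signal.
    """
    if not harmonics:
        raise ConfigurationError("empty harmonic list")
    per = [bin_stats(spectrum, f, snr_spec=snr_spec, z_spec=z_spec)
           for f in harmonics]
    return HarmonicSummary(
        f_fund=min(harmonics),
        harmonics_used=list(harmonics),
        summed_corrected_amp=float(sum(b.corrected_amp for b in per)),
        per_harmonic=per,
    )


def summed_amplitude_z(
    spectrum: AmplitudeSpectrum,
    harmonics: list[float],
    z_spec: NoiseWindowSpec | None = None,
    method: str = "sum",
) -> float:
    """Individual-level z of the summed (non-corrected) harmonic amplitudes.

    ``method="sum"`` (default): the target amplitudes are summed across
    harmonics, and the noise distribution is built by summing, for each
    relative window offset, the amplitudes at that offset across the same
    harmonics; min/max trimming then applies to the summed values.  The z
    is (summed amplitude - mean) / SD of those summed noise values.

    ``method="mean_z"``: the per-harmonic z-scores are averaged and scaled
    by sqrt(n_harmonics) (the mean of k independent unit-variance scores
    has SD 1/sqrt(k)).
    """
    if not harmonics:
        raise ConfigurationError("empty harmonic list")
    z_spec = z_spec or NoiseWindowSpec.zscore_default()
    if method == "mean_z":
        zs = [bin_stats(spectrum, f, z_spec=z_spec).z for f in harmonics]
        return float(np.mean(zs) * np.sqrt(len(zs)))
    if method != "sum":
        raise ConfigurationError(f"unknown method {method!r}")
    amps = spectrum.amps[0] if isinstance(spectrum, AmplitudeSpectrum) \
        else _amps_1d(spectrum)
    bins = [bin_index(spectrum, f) for f in harmonics]
    offsets = [o for o in range(-z_spec.n_side, z_spec.n_side + 1)
               if o != 0 and abs(o) > z_spec.exclude_adjacent]
    lo = min(bins) + min(offsets)
    hi = max(bins) + max(offsets)
    if lo < 0 or hi >= len(amps):
        raise EdgeError("summed noise window exceeds spectrum bounds")
    summed_target = float(sum(amps[b] for b in bins))
    noise_vals = np.array([sum(amps[b + o] for b in bins) for o in offsets])
    if z_spec.exclude_extremes:
        keep = np.ones(len(noise_vals), dtype=bool)
        keep[int(np.argmin(noise_vals))] = False
        masked = np.where(keep, noise_vals, np.inf * -1)
        keep[int(np.argmax(masked))] = False
        noise_vals = noise_vals[keep]
    sd = noise_vals.std(ddof=1)
    if sd == 0:
        warnings.warn("summed noise window has zero SD; z reported as +/-inf")
        d = summed_target - noise_vals.mean()
        return float(np.inf if d > 0 else (-np.inf if d < 0 else 0.0))
    return float((summed_target - noise_vals.mean()) / sd)
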