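"""Oddball statistics: noise windows, SNR, z-scores, harmonic summation."""

import numpy as np
import pytest

from fpvs import (
    NoiseWindowSpec,
    bin_stats,
    candidate_harmonics,
    critical_z,
    noise_bins,
    select_significant_harmonics,
    snr_spectrum,
    sum_harmonics,
    summed_amplitude_z,
)
from fpvs.errors import ConfigurationError, EdgeError
from fpvs.preprocess import Epoch
from fpvs.spectral import AmplitudeSpectrum, amplitude_spectrum

from conftest import brute_force_bin_stats


def vector_spectrum(amps, df=1.0):
    amps = np.atleast_2d(np.asarray(amps, float))
    freqs = np.arange(amps.shape[1]) * df
    return AmplitudeSpectrum(amps=amps, freqs=freqs, df_hz=df,
                             channel_names=["roi"])


class TestNoiseBins:
    def test_snr_window_indices(self):
        amps = np.ones(1000)
        idx = noise_bins(amps, 120, NoiseWindowSpec.snr_default())
        assert list(idx) == list(range(110, 120)) + list(range(121, 131))

    def test_zscore_window_flat_tie_break(self):
        amps = np.ones(100)
        idx = noise_bins(amps, 50, NoiseWindowSpec.zscore_default())
        assert len(idx) == 20
        assert 50 not in idx and 49 not in idx and 51 not in idx
        # ties resolved toward the lowest index: 38 (min) and 39 (max) dropped
        assert 38 not in idx and 39 not in idx

    def test_zscore_window_drops_extremes(self):
        amps = np.ones(100)
        amps[45] = 10.0   # global max among candidates
        amps[57] = 0.01   # global min
        idx = noise_bins(amps, 50, NoiseWindowSpec.zscore_default())
        assert len(idx) == 20
        assert 45 not in idx and 57 not in idx

    def test_edge_error(self):
        with pytest.raises(EdgeError):
            noise_bins(np.ones(100), 5, NoiseWindowSpec.zscore_default())

    def test_brute_force_equivalence(self):
        """noise_bins + bin_stats match raw-list recomputation on random inputs."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            amps = rng.rayleigh(1.0, size=60)
            tb = int(rng.integers(13, 47))
            stats = bin_stats(amps, tb)
            snr, corrected, z = brute_force_bin_stats(amps, tb)
            assert stats.snr == pytest.approx(snr, rel=1e-12)
            assert stats.corrected_amp == pytest.approx(corrected, rel=1e-12)
            assert stats.z == pytest.approx(z, rel=1e-12)


class TestBinStats:
    def test_flat_window_degenerate_sd(self):
        amps = np.ones(100)
        amps[50] = 2.0
        with pytest.warns(UserWarning):
            stats = bin_stats(amps, 50)
        assert stats.snr == 2.0
        assert stats.corrected_amp == 1.0
        assert np.isinf(stats.z)

    def test_hand_computed_z(self):
        """Ten noise bins at 0.8 and ten at 1.2: z = 1.0/0.2052 = 4.873."""
        amps = np.ones(101)
        tb = 50
        # 22 z-window candidates at offsets +-2..+-12; add one extra low and
        # one extra high value to be dropped as global min / max.
        offs = [o for o in range(-12, 13) if abs(o) >= 2]
        lows, highs = offs[:11], offs[11:]
        for o in lows:
            amps[tb + o] = 0.8
        for o in highs:
            amps[tb + o] = 1.2
        amps[tb + lows[0]] = 0.79   # dropped as min
        amps[tb + highs[0]] = 1.21  # dropped as max
        amps[tb] = 2.0
        stats = bin_stats(amps, tb)
        assert stats.noise_mean == pytest.approx(1.0)
        assert stats.corrected_amp == pytest.approx(1.0)
        assert stats.z == pytest.approx(4.873, abs=1e-3)

    def test_null_bin_is_zero(self):
        rng = np.random.default_rng(9)
        amps = np.ones(100) + rng.uniform(0, 1e-6, 100)
        amps[50] = bin_stats(amps, 50).noise_mean  # target = noise mean
        stats_ = bin_stats(amps, 50)
        assert stats_.corrected_amp == pytest.approx(0.0, abs=1e-12)
        assert stats_.z == pytest.approx(0.0, abs=1e-9)
        assert stats_.snr == pytest.approx(1.0, abs=1e-5)

    def test_spectrum_input_maps_frequency(self):
        jitter = np.random.default_rng(0).uniform(0, 1e-6, 100)
        spec = vector_spectrum(np.ones(100) + jitter, df=0.5)
        spec.amps[0, 40] = 3.0
        stats = bin_stats(spec, 20.0)  # 20 Hz -> bin 40
        assert stats.amp == 3.0 and stats.f_hz == 20.0


class TestSnrSpectrum:
    def test_all_equal_spectrum_snr_one(self):
        out = snr_spectrum(vector_spectrum(np.ones(200)))
        interior = out.amps[0, 10:-10]
        assert np.allclose(interior, 1.0)
        assert np.isnan(out.amps[0, :10]).all()

    def test_single_spike(self):
        amps = np.ones(200)
        amps[100] = 5.0
        out = snr_spectrum(vector_spectrum(amps))
        assert out.amps[0, 100] == pytest.approx(5.0)

    def test_white_noise_baseline_near_one(self):
        """Mean SNR over pure-noise spectra ~ 1 (the Fig-2 baseline level)."""
        rng = np.random.default_rng(0)
        means = []
        for _ in range(20):
            epoch = Epoch(rng.standard_normal((1, 2048)), 256.0, 0.0, ["x"])
            out = snr_spectrum(amplitude_spectrum(epoch))
            means.append(np.nanmean(out.amps[0, 10:-10]))
        assert np.mean(means) == pytest.approx(1.0, abs=0.02)


class TestHarmonics:
    def test_oddball_candidates_exclude_base_multiples(self):
        assert candidate_harmonics(2.0, 10.0, 8.0) == [2.0, 4.0, 6.0, 8.0]
        assert candidate_harmonics(2.0, 10.0, 20.0) == \
            [2.0, 4.0, 6.0, 8.0, 12.0, 14.0, 16.0, 18.0]

    def test_base_candidates_without_exclusion(self):
        assert candidate_harmonics(10.0, 10.0, 40.0, exclude_base=False) == \
            [10.0, 20.0, 30.0, 40.0]

    def test_selection_on_constructed_spectrum(self):
        rng = np.random.default_rng(1)
        amps = np.abs(rng.normal(0.05, 0.01, size=2048))
        df = 1.0 / 60.0
        for f in (2.0, 4.0, 6.0):
            amps[round(f / df)] = 2.0  # far above noise
        spec = vector_spectrum(amps, df=df)
        got = select_significant_harmonics(spec, [2.0, 4.0, 6.0, 8.0])
        assert got == [2.0, 4.0, 6.0]

    def test_all_injected_all_retained(self):
        amps = 0.05 + np.random.default_rng(2).uniform(0, 1e-4, 2048)
        df = 1.0 / 60.0
        cands = [2.0, 4.0, 6.0, 8.0]
        for f in cands:
            amps[round(f / df)] = 3.0
        got = select_significant_harmonics(vector_spectrum(amps, df=df), cands)
        assert got == cands

    def test_sum_harmonics_additivity(self):
        df = 1.0 / 60.0
        rng = np.random.default_rng(3)
        base_noise = np.abs(rng.normal(0.05, 0.005, size=4096))
        injected = {2.0: 0.5, 4.0: 0.3, 6.0: 0.2, 8.0: 0.1}

        def with_signal(scale):
            amps = base_noise.copy()
            for f, a in injected.items():
                amps[round(f / df)] += scale * a
            return vector_spectrum(amps, df=df)

        h = list(injected)
        s1 = sum_harmonics(with_signal(1.0), h).summed_corrected_amp
        s2 = sum_harmonics(with_signal(2.0), h).summed_corrected_amp
        base = sum_harmonics(with_signal(0.0), h).summed_corrected_amp
        assert s2 - base == pytest.approx(2 * (s1 - base), rel=1e-9)

    def test_sum_single_harmonic(self):
        amps = 1.0 + np.random.default_rng(8).uniform(0, 1e-6, 200)
        amps[100] = 1.7
        spec = vector_spectrum(amps, df=1.0)
        summary = sum_harmonics(spec, [100.0])
        assert summary.summed_corrected_amp == \
            pytest.approx(bin_stats(amps, 100).corrected_amp)

    def test_empty_harmonics_error(self):
        with pytest.raises(ConfigurationError):
            sum_harmonics(vector_spectrum(np.ones(100)), [])


class TestSummedAmplitudeZ:
    def test_strong_signal_large_z(self):
        df = 1.0 / 60.0
        rng = np.random.default_rng(4)
        amps = np.abs(rng.normal(0.05, 0.01, size=2048))
        for f in (2.0, 4.0, 6.0, 8.0):
            amps[round(f / df)] = 1.0
        spec = vector_spectrum(amps, df=df)
        assert summed_amplitude_z(spec, [2.0, 4.0, 6.0, 8.0]) > 10

    def test_mean_z_variant(self):
        df = 1.0 / 60.0
        rng = np.random.default_rng(5)
        amps = np.abs(rng.normal(0.05, 0.01, size=2048))
        spec = vector_spectrum(amps, df=df)
        z_sum = summed_amplitude_z(spec, [2.0, 4.0], method="sum")
        z_mean = summed_amplitude_z(spec, [2.0, 4.0], method="mean_z")
        assert np.isfinite(z_sum) and np.isfinite(z_mean)


class TestCalibration:
    def test_critical_values(self):
        assert round(critical_z(0.001), 1) == 3.1
        assert round(critical_z(0.05), 2) == 1.64

    def test_null_z_rates_measured(self):
        """Empirical false-positive rates of the z-criterion on noise spectra.

        The z-statistic estimates its mean and SD from only 20 bins and the
        min/max trimming shrinks the SD estimate, so the criterion is
        liberal: the z>1.64 rate on pure-noise FFT amplitude bins sits near
        0.10-0.12 (not the nominal 0.05) and z>3.1 near 0.01-0.02.  This
        test pins those measured operating characteristics.
        """
        rng = np.random.default_rng(6)
        n_hits_164 = 0
        n_hits_31 = 0
        n_bins = 0
        for _ in range(60):
            epoch = Epoch(rng.standard_normal((1, 3840)), 64.0, 0.0, ["x"])
            amps = amplitude_spectrum(epoch).amps[0]
            for tb in range(20, len(amps) - 20, 25):
                z = bin_stats(amps, tb).z
                n_bins += 1
                n_hits_164 += z > 1.64
                n_hits_31 += z > 3.1
        rate_164 = n_hits_164 / n_bins
        rate_31 = n_hits_31 / n_bins
        assert n_bins >= 4000
        assert 0.07 < rate_164 < 0.16
        assert 0.003 < rate_31 < 0.04
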