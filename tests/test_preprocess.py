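"""Preprocessing chain: filtering, segmentation, resampling, referencing, cropping."""

import numpy as np
import pytest

from fpvs import (
    Epoch,
    Montage,
    Recording,
    average_epochs,
    bandpass_fft,
    crop_to_cycles,
    interpolate_channels,
    rereference_average,
    resample,
    segment,
)
from fpvs.errors import ConfigurationError, SegmentationError


def make_recording(data, fs=1024.0, markers=None, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return Recording(data=data, fs_hz=fs, channel_names=names,
                     markers=markers or [])


def make_epoch(data, fs=512.0, t0=0.0, names=None):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    names = names or [f"ch{i}" for i in range(data.shape[0])]
    return Epoch(data=data, fs_hz=fs, t0_s=t0, channel_names=names)


class TestBandpass:
    def test_in_band_identity(self):
        t = np.arange(4096) / 1024.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = bandpass_fft(make_recording(x), 0.1, 100.0)
        assert np.allclose(out.data[0], x, atol=1e-6)

    def test_out_of_band_rejection(self):
        t = np.arange(4096) / 1024.0
        x = np.sin(2 * np.pi * 120.0 * t)
        out = bandpass_fft(make_recording(x), 0.1, 100.0)
        assert np.sqrt(np.mean(out.data[0] ** 2)) < 1e-6 * np.sqrt(np.mean(x**2))

    def test_mixed_keeps_only_in_band_component(self):
        t = np.arange(8192) / 1024.0
        lo = np.sin(2 * np.pi * 1.0 * t)
        hi = np.sin(2 * np.pi * 200.0 * t)
        out = bandpass_fft(make_recording(lo + hi), 0.1, 100.0)
        assert np.allclose(out.data[0], lo, atol=1e-6)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass_fft(make_recording(np.zeros(128), fs=256.0), 0.1, 200.0)

    def test_raised_cosine_transition_in_band_identity(self):
        t = np.arange(4096) / 1024.0
        x = np.sin(2 * np.pi * 50.0 * t)
        out = bandpass_fft(make_recording(x), 0.1, 100.0, transition_hz=0.05)
        assert np.allclose(out.data[0], x, atol=1e-6)


class TestSegment:
    def test_index_arithmetic(self):
        rec = make_recording(np.zeros(80_000),
                             markers=[(10240, "sequence_onset")])
        epoch = segment(rec, pre_s=2.0, post_s=62.0)
        assert epoch.n_samples == 65_536
        assert epoch.t0_s == -2.0

    def test_zero_pre_starts_at_onset(self):
        rec = make_recording(np.arange(1000.0), fs=100.0,
                             markers=[(0, "sequence_onset")])
        epoch = segment(rec, pre_s=0.0, post_s=1.0)
        assert epoch.t0_s == 0.0
        assert epoch.data[0, 0] == 0.0

    def test_window_overrun_errors(self):
        rec = make_recording(np.zeros(1000), fs=100.0,
                             markers=[(990, "sequence_onset")])
        with pytest.raises(SegmentationError):
            segment(rec, pre_s=0.0, post_s=1.0)


class TestResample:
    def test_sinusoid_amplitude_preserved(self):
        t = np.arange(65_536) / 1024.0
        epoch = make_epoch(np.sin(2 * np.pi * 2.0 * t), fs=1024.0, t0=0.0)
        out = resample(epoch, 512.0)
        assert out.n_samples == 32_768
        # peak amplitude via the exact-bin spectrum
        amp = np.abs(np.fft.rfft(out.data[0])) * 2 / out.n_samples
        k = round(2.0 / (512.0 / out.n_samples))
        assert amp[k] == pytest.approx(1.0, abs=0.005)

    def test_identity_when_rates_match(self):
        epoch = make_epoch(np.random.default_rng(0).standard_normal(512))
        out = resample(epoch, 512.0)
        assert np.array_equal(out.data, epoch.data)

    def test_duration_preserved(self):
        epoch = make_epoch(np.zeros(65_536), fs=1024.0)
        out = resample(epoch, 512.0)
        assert out.duration_s == pytest.approx(epoch.duration_s)

    def test_upsampling_rejected(self):
        with pytest.raises(ConfigurationError):
            resample(make_epoch(np.zeros(512)), 1024.0)


class TestInterpolateChannels:
    @pytest.fixture()
    def square_montage(self):
        # bad channel at the pole, neighbours equidistant on a ring
        return Montage({
            "bad": np.array([0.0, 0.0, 1.0]),
            "a": np.array([1.0, 0.0, 1.0]),
            "b": np.array([-1.0, 0.0, 1.0]),
            "c": np.array([0.0, 1.0, 1.0]),
            "far": np.array([0.0, 0.0, -1.0]),
        })

    def test_equidistant_neighbours_average(self, square_montage):
        data = np.vstack([
            np.full(10, 99.0),   # bad
            np.full(10, 1.0),    # a
            np.full(10, 2.0),    # b
            np.full(10, 3.0),    # c
            np.full(10, 50.0),   # far
        ])
        epoch = make_epoch(data, names=["bad", "a", "b", "c", "far"])
        out = interpolate_channels(epoch, ["bad"], square_montage, k=3)
        assert np.allclose(out.data[0], 2.0)
        assert np.array_equal(out.data[1:], data[1:])

    def test_identical_neighbours_reproduced(self, square_montage):
        sig = np.sin(np.linspace(0, 3, 10))
        data = np.vstack([np.zeros(10), sig, sig, sig, np.full(10, 9.0)])
        epoch = make_epoch(data, names=["bad", "a", "b", "c", "far"])
        out = interpolate_channels(epoch, ["bad"], square_montage, k=3)
        assert np.allclose(out.data[0], sig)

    def test_empty_bad_list_is_identity(self, square_montage):
        data = np.random.default_rng(1).standard_normal((5, 16))
        epoch = make_epoch(data, names=["bad", "a", "b", "c", "far"])
        out = interpolate_channels(epoch, [], square_montage, k=3)
        assert np.array_equal(out.data, data)

    def test_too_few_good_channels(self, square_montage):
        epoch = make_epoch(np.zeros((5, 8)), names=["bad", "a", "b", "c", "far"])
        with pytest.raises(ConfigurationError):
            interpolate_channels(epoch, ["bad", "a", "b"], square_montage, k=3)


class TestRereference:
    def test_antisymmetric_pair_unchanged(self):
        data = np.vstack([np.ones(8), -np.ones(8)])
        out = rereference_average(make_epoch(data))
        assert np.array_equal(out.data, data)

    def test_common_offset_removed(self):
        data = np.full((4, 8), 7.5)
        out = rereference_average(make_epoch(data))
        assert np.allclose(out.data, 0.0)

    def test_column_means_zero(self):
        data = np.random.default_rng(2).standard_normal((6, 100))
        out = rereference_average(make_epoch(data))
        assert np.abs(out.data.mean(axis=0)).max() < 1e-10


class TestCropToCycles:
    def test_120_cycles_at_512(self):
        epoch = make_epoch(np.zeros(int(64 * 512)), fs=512.0, t0=-2.0)
        out = crop_to_cycles(epoch, cycle_s=0.5, stim_s=60.0)
        assert out.n_samples == 30_720
        assert out.meta["n_cycles"] == 120
        assert out.t0_s == 0.0
        # last retained timestamp: 30719/512 = 59.998 s
        assert out.times[-1] == pytest.approx(59.998, abs=5e-4)

    def test_partial_cycle_dropped(self):
        epoch = make_epoch(np.zeros(int(59.9 * 512)), fs=512.0, t0=0.0)
        out = crop_to_cycles(epoch, cycle_s=0.5)
        assert out.meta["n_cycles"] == 119

    def test_single_cycle(self):
        epoch = make_epoch(np.zeros(256), fs=512.0, t0=0.0)
        out = crop_to_cycles(epoch, cycle_s=0.5)
        assert out.meta["n_cycles"] == 1 and out.n_samples == 256

    def test_too_short_errors(self):
        epoch = make_epoch(np.zeros(100), fs=512.0, t0=0.0)
        with pytest.raises(SegmentationError):
            crop_to_cycles(epoch, cycle_s=0.5)


class TestAverageEpochs:
    def test_identical_epochs_unchanged(self):
        e = make_epoch(np.random.default_rng(3).standard_normal((2, 32)))
        out = average_epochs([e, e, e])
        assert np.allclose(out.data, e.data)
        assert out.meta["n_averaged"] == 3

    def test_opposite_epochs_cancel(self):
        e = make_epoch(np.ones((2, 16)))
        f = make_epoch(-np.ones((2, 16)))
        assert np.allclose(average_epochs([e, f]).data, 0.0)

    def test_constant_mean(self):
        epochs = [make_epoch(np.full((1, 8), v)) for v in (1.0, 2.0, 3.0)]
        assert np.allclose(average_epochs(epochs).data, 2.0)

    def test_shape_mismatch_errors(self):
        with pytest.raises(ConfigurationError):
            average_epochs([make_epoch(np.zeros((1, 8))),
                            make_epoch(np.zeros((1, 9)))])


class TestComposedChain:
    def test_full_chain_preserves_cycle_locked_amplitude(self, short_plan,
                                                         silent_noise):
        """A bin-locked in-band sinusoid survives the whole chain within 1%."""
        from fpvs import ResponseSpec, amplitude_spectrum, preprocess, \
            synthesize_recording
        from fpvs.stats import NoiseWindowSpec, bin_stats

        rec = synthesize_recording(
            short_plan,
            oddball=ResponseSpec(2.0, [(1, 1.0)], {"PO7": 1.0}),
            base=ResponseSpec(10.0, [(1, 0.5)], {"Oz": 1.0}),
            noise=silent_noise, fs_hz=1024.0, seed=0,
        )
        epoch = preprocess(rec, pre_s=0.5, post_s=6.5, stim_s=6.0)
        spec = amplitude_spectrum(epoch)
        w = rec.ground_truth["oddball"]["harmonics"][0]
        want = w["referenced_amp_per_channel"]["PO7"]
        got = spec.channel("PO7")[round(2.0 / spec.df_hz)]
        assert got == pytest.approx(want, rel=0.01)
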