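import numpy as np
import pytest

from nirsbci import (
    EventSchedule,
    Recording,
    average_trials,
    bandpass_filter,
    epoch_trials,
    savgol_smooth,
)

FS = 12.5


def _rec(data, fs=FS):
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] == 1:
        data = data.T
    return Recording(data, fs, "HbO", tuple(f"ch{i}" for i in range(data.shape[1])))


def _sine(freq, n=6000, fs=FS):
    t = np.arange(n) / fs
    return np.sin(2 * np.pi * freq * t)


def _interior_amplitude(x, trim=500):
    return np.abs(x[trim:-trim]).max()


class TestBandpass:
    def test_passband_tone_preserved(self):
        out = bandpass_filter(_rec(_sine(0.09))).data[:, 0]
        assert 0.9 <= _interior_amplitude(out) <= 1.1

    def test_cardiac_tone_rejected(self):
        out = bandpass_filter(_rec(_sine(1.1))).data[:, 0]
        assert _interior_amplitude(out) <= 0.01

    def test_dc_rejected(self):
        out = bandpass_filter(_rec(np.ones(6000))).data[:, 0]
        assert np.abs(out[500:-500]).max() <= 1e-6

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(_rec(_sine(0.09)), low=0.03, high=7.0)

    def test_short_signal_rejected(self):
        with pytest.raises(ValueError, match="warm-up"):
            bandpass_filter(_rec(np.zeros(10)))

    def test_channelwise_independence(self, rng):
        data = rng.normal(size=(3000, 4))
        perm = [2, 0, 3, 1]
        a = bandpass_filter(_rec(data)).data[:, perm]
        b = bandpass_filter(_rec(data[:, perm])).data
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestSavgol:
    def test_polynomial_reproduced_exactly(self):
        t = np.arange(200) / FS
        sig = 0.5 * t**3 - t**2 + 2.0
        out = savgol_smooth(_rec(sig), window_s=1.0, polyorder=3).data[:, 0]
        np.testing.assert_allclose(out[10:-10], sig[10:-10], atol=1e-9)

    def test_noise_variance_reduced(self, rng):
        sig = rng.normal(size=2000)
        out = savgol_smooth(_rec(sig)).data[:, 0]
        assert out.var() < sig.var()

    def test_single_sample_window_is_identity(self, rng):
        sig = rng.normal(size=100)
        out = savgol_smooth(_rec(sig), window_s=0.01, polyorder=0).data[:, 0]
        np.testing.assert_array_equal(out, sig)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(_rec(np.zeros(10)), window_s=10.0)


def _paradigm(n_trials=20, gap=27.0):
    onsets = 62.0 + gap * np.arange(n_trials)
    return EventSchedule(onsets, np.full(n_trials, 10.0), ("task",) * n_trials)


class TestEpoching:
    def test_300_samples_for_24s_window(self, rng):
        ev = _paradigm()
        rec = _rec(rng.normal(size=(int(700 * FS), 3)))
        ep = epoch_trials(rec, ev, (0.0, 24.0))
        assert ep.epochs.shape == (20, 300, 3)

    def test_125_samples_for_10s_window(self, rng):
        ev = _paradigm()
        rec = _rec(rng.normal(size=(int(700 * FS), 2)))
        assert epoch_trials(rec, ev, (0.0, 10.0)).epochs.shape[1] == 125

    def test_window_beyond_recording_rejected(self, rng):
        ev = EventSchedule(np.array([9.0]), np.array([1.0]), ("t",))
        rec = _rec(rng.normal(size=(125, 2)))  # 10 s
        with pytest.raises(ValueError, match=r"trial\(s\) \[0\]"):
            epoch_trials(rec, ev, (0.0, 5.0))

    def test_epoch_values_match_slices(self, rng):
        ev = _paradigm(5)
        rec = _rec(rng.normal(size=(int(300 * FS), 2)))
        ep = epoch_trials(rec, ev, (0.0, 4.0))
        i0 = int(round(ev.onsets[2] * FS))
        np.testing.assert_array_equal(ep.epochs[2], rec.data[i0 : i0 + 50])


class TestAveraging:
    def test_identical_epochs_idempotent(self, rng):
        ev = _paradigm(5)
        one_trial = rng.normal(size=(50, 3))
        data = np.zeros((int(300 * FS), 3))
        for onset in ev.onsets:
            i = int(round(onset * FS))
            data[i : i + 50] = one_trial
        ep = epoch_trials(_rec(data), ev, (0.0, 4.0))
        np.testing.assert_allclose(average_trials(ep), one_trial, atol=1e-12)

    def test_opposite_epochs_cancel(self, rng):
        from nirsbci.preprocess import EpochSet

        x = rng.normal(size=(1, 40, 2))
        ep = EpochSet(np.vstack([x, -x]), (0.0, 4.0), 10.0, ("t", "t"), ("a", "b"))
        assert np.abs(average_trials(ep)).max() <= 1e-15

    def test_matches_direct_summation(self, rng):
        from nirsbci.preprocess import EpochSet

        epochs = rng.normal(size=(20, 30, 4))
        ep = EpochSet(epochs, (0.0, 3.0), 10.0, ("t",) * 20, tuple("abcd"))
        expected = np.zeros((30, 4))
        for trial in epochs:
            expected += trial
        expected /= 20
        np.testing.assert_allclose(average_trials(ep, "t"), expected, atol=1e-12)

    def test_unknown_label_rejected(self, rng):
        from nirsbci.preprocess import EpochSet

        ep = EpochSet(rng.normal(size=(2, 10, 1)), (0, 1), 10.0, ("a", "a"), ("c",))
        with pytest.raises(ValueError, match="no epochs"):
            average_trials(ep, "b")
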