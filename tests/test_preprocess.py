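"""Filtering, epoching, normalisation and container I/O."""

import numpy as np
import pytest

from mi3d import (Recording, SynthParams, TrialSet, bandpass, epoch,
                  generate_recording, load_hdf5, load_recording, normalize,
                  notch, save_hdf5)
from tests.conftest import write_brainvision


def _sine_recording(freq, fs=250.0, seconds=8.0, n_ch=2):
    t = np.arange(int(fs * seconds)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    return Recording(data, [f"CH{i}" for i in range(n_ch)], fs)


def _rms(x):
    return np.sqrt(np.mean(x ** 2))


class TestContainers:
    def test_hdf5_recording_round_trip(self, tmp_path):
        rec = generate_recording(SynthParams(n_channels=8, trials_per_class=2,
                                             seed=3))
        path = tmp_path / "rec.h5"
        save_hdf5(rec, path)
        back = load_hdf5(path)
        np.testing.assert_array_equal(back.data, rec.data)
        assert back.fs == rec.fs
        assert back.events == rec.events
        assert back.channel_names == rec.channel_names

    def test_hdf5_trialset_round_trip(self, small_ts, tmp_path):
        ts, _ = small_ts
        path = tmp_path / "ts.h5"
        save_hdf5(ts, path)
        back = load_hdf5(path)
        np.testing.assert_array_equal(back.trials, ts.trials)
        np.testing.assert_array_equal(back.labels, ts.labels)

    def test_recording_validates_events_and_names(self):
        data = np.zeros((2, 100))
        with pytest.raises(ValueError, match="outside"):
            Recording(data, ["A", "B"], 250.0, events=[(500, 1)])
        with pytest.raises(ValueError, match="unique"):
            Recording(data, ["A", "A"], 250.0)
        with pytest.raises(ValueError, match="positive"):
            Recording(data, ["A", "B"], -1.0)


class TestLoadRecording:
    def test_brainvision_triplet_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 1000)).astype(np.float32)
        events = [(100, 1), (400, 2), (700, 3)]
        vhdr = write_brainvision(tmp_path, "fix", data,
                                 ["Fp1", "Fp2", "Cz", "Oz"], 250.0, events)
        rec = load_recording(vhdr)
        assert rec.events == events
        assert rec.channel_names == ["Fp1", "Fp2", "Cz", "Oz"]
        np.testing.assert_allclose(rec.data, data, atol=1e-4)

    def test_missing_marker_file_is_explicit(self, tmp_path):
        vhdr = write_brainvision(tmp_path, "x", np.zeros((2, 100)),
                                 ["A", "B"], 250.0, [])
        vhdr.with_suffix(".vmrk").unlink()
        with pytest.raises(FileNotFoundError, match="vmrk"):
            load_recording(vhdr)

    def test_64_channel_fixture_has_unique_names(self, tmp_path):
        rec = generate_recording(SynthParams(n_channels=64, trials_per_class=2,
                                             seed=0))
        path = tmp_path / "r64.h5"
        save_hdf5(rec, path)
        names = load_recording(path).channel_names
        assert len(names) == 64 and len(set(names)) == 64

    def test_unknown_format_rejected(self, tmp_path):
        p = tmp_path / "data.xyz"
        p.write_text("")
        with pytest.raises(ValueError, match="format"):
            load_recording(p)


class TestFilters:
    def test_zero_signal_stays_zero(self):
        rec = Recording(np.zeros((3, 1000)), ["A", "B", "C"], 250.0)
        assert np.allclose(bandpass(rec, 0.5, 40).data, 0)
        assert np.allclose(notch(rec).data, 0)

    def test_bandpass_passband_and_stopband(self):
        inside = bandpass(_sine_recording(10.0), 0.5, 40.0)
        # measure away from the edges to avoid transients
        seg = slice(500, -500)
        assert abs(_rms(inside.data[0, seg]) - _rms(_sine_recording(10.0).data[0, seg])) \
            < 0.05 * _rms(_sine_recording(10.0).data[0, seg])
        outside = bandpass(_sine_recording(60.0), 0.5, 40.0)
        atten_db = 20 * np.log10(_rms(_sine_recording(60.0).data[0, seg])
                                 / max(_rms(outside.data[0, seg]), 1e-30))
        assert atten_db >= 20

    def test_notch_rejects_mains_and_passes_alpha(self):
        seg = slice(500, -500)
        mains = notch(_sine_recording(50.0))
        atten_db = 20 * np.log10(_rms(_sine_recording(50.0).data[0, seg])
                                 / max(_rms(mains.data[0, seg]), 1e-30))
        assert atten_db >= 20
        alpha = notch(_sine_recording(10.0))
        ref = _rms(_sine_recording(10.0).data[0, seg])
        assert abs(_rms(alpha.data[0, seg]) - ref) < 0.05 * ref

    @pytest.mark.parametrize("low,high", [(40, 5), (-1, 40), (0.5, 200)])
    def test_invalid_band_edges_raise(self, low, high):
        rec = _sine_recording(10.0)
        with pytest.raises(ValueError):
            bandpass(rec, low, high)

    def test_filtering_is_linear(self):
        rng = np.random.default_rng(5)
        x = Recording(rng.normal(size=(2, 2000)), ["A", "B"], 250.0)
        y = Recording(rng.normal(size=(2, 2000)), ["A", "B"], 250.0)
        a, b = 2.5, -0.7
        combo = Recording(a * x.data + b * y.data, ["A", "B"], 250.0)
        lhs = bandpass(combo, 0.5, 40).data
        rhs = a * bandpass(x, 0.5, 40).data + b * bandpass(y, 0.5, 40).data
        np.testing.assert_allclose(lhs, rhs, rtol=1e-8, atol=1e-10)


class TestEpoch:
    def test_three_second_trials_have_750_samples(self):
        rec = generate_recording(SynthParams(n_channels=4, trials_per_class=3,
                                             seed=2))
        ts = epoch(rec, 0.0, 3.0)
        assert ts.n_samples == 750
        assert ts.n_trials == 12

    def test_epoching_copies_samples_exactly(self):
        rng = np.random.default_rng(1)
        data = rng.normal(size=(3, 2000))
        rec = Recording(data, ["A", "B", "C"], 250.0,
                        events=[(100, 1), (900, 2)])
        ts = epoch(rec, 0.0, 3.0)
        np.testing.assert_array_equal(ts.trials[0], data[:, 100:850])
        np.testing.assert_array_equal(ts.trials[1], data[:, 900:1650])
        assert list(ts.labels) == [1, 2]
        assert ts.channel_names == rec.channel_names

    def test_out_of_bounds_window_rejected(self, caplog):
        rec = Recording(np.zeros((2, 1000)) + 1.0, ["A", "B"], 250.0,
                        events=[(0, 1), (400, 2)])
        ts = epoch(rec, -1.0, 2.0)   # first event starts before the recording
        assert ts.n_trials == 1 and ts.labels[0] == 2

    def test_no_surviving_trial_errors(self):
        rec = Recording(np.ones((1, 100)), ["A"], 250.0, events=[(90, 1)])
        with pytest.raises(ValueError, match="no trial"):
            epoch(rec, 0.0, 3.0)

    def test_forty_events_give_forty_ordered_trials(self):
        fs, n = 250.0, 40
        onsets = [200 + 800 * i for i in range(n)]
        codes = [1 + (i % 4) for i in range(n)]
        rec = Recording(np.zeros((2, onsets[-1] + 1000)), ["A", "B"], fs,
                        events=list(zip(onsets, codes)))
        ts = epoch(rec, 0.0, 3.0)
        assert ts.n_trials == n
        assert list(ts.labels) == codes


class TestNormalize:
    def test_zero_mean_unit_variance(self, small_ts):
        ts, _ = small_ts
        z = normalize(ts)
        assert np.abs(z.trials.mean(axis=2)).max() < 1e-9
        assert np.abs(z.trials.var(axis=2) - 1).max() < 1e-6

    def test_idempotent(self, small_ts):
        ts, _ = small_ts
        once = normalize(ts)
        twice = normalize(once)
        np.testing.assert_allclose(twice.trials, once.trials, atol=1e-9)

    def test_constant_channel_stays_finite(self):
        trials = np.random.default_rng(0).normal(size=(2, 3, 100))
        trials[:, 1, :] = 5.0
        ts = TrialSet(trials, [1, 2], 250.0, ["A", "B", "C"])
        with pytest.warns(RuntimeWarning, match="constant"):
            z = normalize(ts)
        assert np.isfinite(z.trials).all()
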