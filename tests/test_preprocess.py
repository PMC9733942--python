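import numpy as np
import pytest
from scipy import signal as sps

import thetastim as th
from thetastim.preprocess import baseline_correct
from thetastim.types import epoch_time_ms


def make_rec(samples, fs=1000.0, events=(), hemis=None):
    n = np.atleast_2d(samples).shape[0]
    hemis = hemis or ["L"] * n
    chans = [th.ChannelInfo(label=f"c{i}", hemisphere=hemis[i]) for i in range(n)]
    return th.RawRecording(samples=samples, fs=fs, channels=chans, events=np.asarray(events))


class TestCommonAverage:
    def test_single_channel_group_zeroes_itself(self):
        rec = make_rec(np.random.default_rng(0).normal(size=(3, 100)))
        out = th.rereference_common_average(rec, ["c1"])
        assert np.allclose(out.samples[1], 0.0)
        assert np.array_equal(out.samples[0], rec.samples[0])

    def test_two_channel_algebra(self):
        a = np.arange(10.0)
        b = np.linspace(3, -3, 10)
        rec = make_rec(np.stack([a, b]))
        out = th.rereference_common_average(rec, ["c0", "c1"])
        assert np.allclose(out.samples[0], (a - b) / 2)
        assert np.allclose(out.samples[1], (b - a) / 2)

    def test_group_mean_is_zero_and_differences_preserved(self):
        rng = np.random.default_rng(1)
        rec = make_rec(rng.normal(size=(5, 1000)))
        out = th.rereference_common_average(rec, ["c0", "c1", "c2", "c3", "c4"])
        assert np.allclose(out.samples.mean(axis=0), 0.0, atol=1e-12)
        assert np.allclose(
            out.samples[2] - out.samples[4], rec.samples[2] - rec.samples[4]
        )

    def test_errors(self):
        rec = make_rec(np.zeros((2, 10)), hemis=["L", "R"])
        with pytest.raises(ValueError, match="empty"):
            th.rereference_common_average(rec, [])
        with pytest.raises(ValueError, match="c0.*c1|hemis"):
            th.rereference_common_average(rec, ["c0", "c1"])


class TestResample:
    def test_identity_at_1khz(self):
        rec = make_rec(np.random.default_rng(0).normal(size=(1, 2000)))
        out = th.resample_to_1khz(rec)
        assert out.fs == 1000.0
        assert np.array_equal(out.samples, rec.samples)

    def test_sine_amplitude_preserved(self):
        fs = 20000.0
        t = np.arange(int(4 * fs)) / fs
        rec = make_rec(np.sin(2 * np.pi * 5.0 * t)[None, :], fs=fs)
        out = th.resample_to_1khz(rec)
        assert out.fs == 1000.0
        mid = out.samples[0, 500:-500]  # avoid filter edges
        assert np.max(np.abs(mid)) == pytest.approx(1.0, rel=0.01)

    def test_broadband_attenuated_above_nyquist_band(self):
        fs = 32000.0
        rng = np.random.default_rng(2)
        x = rng.normal(size=int(4 * fs))
        rec = make_rec(x[None, :], fs=fs)
        out = th.resample_to_1khz(rec)
        f_in, p_in = sps.welch(x, fs=fs, nperseg=8192)
        f_out, p_out = sps.welch(out.samples[0], fs=1000.0, nperseg=1024)
        in_hi = p_in[(f_in > 500) & (f_in < 1500)].mean()  # input level per Hz
        out_hi = p_out[(f_out > 450)].mean()
        assert 10 * np.log10(in_hi / out_hi) > 20.0

    def test_upsampling_refused(self):
        rec = make_rec(np.zeros((1, 100)), fs=500.0)
        with pytest.raises(ValueError):
            th.resample_to_1khz(rec)


class TestEpoching:
    def test_constant_channel_gives_zero_trials(self):
        rec = make_rec(np.full((1, 5000), 10.0), events=[1.0, 2.5])
        ts = th.epoch_channel(rec, 0)
        assert ts.trials.shape == (2, 1250)
        assert np.allclose(ts.trials, 0.0)

    def test_event_near_edge_dropped(self):
        rec = make_rec(np.zeros((1, 10000)), events=[0.1, 5.0])
        ts = th.epoch_channel(rec, 0)
        assert ts.n_trials == 1

    def test_no_valid_events_raises(self):
        rec = make_rec(np.zeros((1, 1000)), events=[0.1])
        with pytest.raises(ValueError):
            th.epoch_channel(rec, 0)

    def test_cosine_value_at_onset(self):
        """Trial value at 0 ms equals the cosine's value there minus the
        baseline-window mean of the cosine (computed independently)."""
        fs = 1000.0
        t = np.arange(int(10 * fs)) / fs
        x = np.cos(2 * np.pi * 5.0 * t)
        event = 4.0  # cosine peak (5 Hz: integer cycles at 4 s)
        rec = make_rec(x[None, :], events=[event])
        ts = th.epoch_channel(rec, 0)
        time_ms = epoch_time_ms()
        base = np.cos(2 * np.pi * 5.0 * (event + time_ms / 1000.0))
        expected = 1.0 - base[(time_ms >= -750) & (time_ms <= -2)].mean()
        assert ts.trials[0, ts.onset_index()] == pytest.approx(expected, abs=1e-9)

    def test_baseline_idempotent(self):
        rng = np.random.default_rng(3)
        time_ms = epoch_time_ms()
        trials = rng.normal(size=(7, time_ms.size))
        once = baseline_correct(trials, time_ms)
        assert np.allclose(baseline_correct(once, time_ms), once, atol=1e-12)


class TestPruning:
    def _ts(self, trials):
        return th.TrialSet(trials=trials, time_ms=epoch_time_ms(),
                           channel=th.ChannelInfo(label="c0"))

    def test_range_artifact_pruned(self):
        rng = np.random.default_rng(4)
        trials = rng.normal(0, 10, size=(20, 1250))
        trials[3, 600] += 1000.0
        pruned, report = th.prune_trials(self._ts(trials))
        assert not pruned.kept[3]
        assert report.pruned_range == 1

    def test_identical_trials_none_pruned(self):
        """Degenerate kurtosis SD: the strict comparison prunes nothing."""
        trials = np.tile(np.sin(np.linspace(0, 10, 1250)), (5, 1))
        pruned, report = th.prune_trials(self._ts(trials), min_epochs=0)
        assert pruned.kept.all()
        assert report.pruned_kurtosis == 0

    def test_planted_heavy_tailed_outliers_caught(self):
        rng = np.random.default_rng(3)
        trials = rng.normal(0, 10, size=(300, 1250))
        out_idx = rng.choice(300, 10, replace=False)
        for i in out_idx:
            for _ in range(3):
                j = rng.integers(0, 1245)
                trials[i, j:j + 3] += rng.choice([-1, 1]) * rng.uniform(150, 250)
        pruned, report = th.prune_trials(self._ts(trials))
        assert np.sum(~pruned.kept[out_idx]) >= 8

    def test_pruning_monotone_in_range_threshold(self):
        rng = np.random.default_rng(5)
        trials = rng.normal(0, 100, size=(50, 1250))
        kept_tight = th.prune_trials(self._ts(trials), range_thresh=400)[0].n_kept
        kept_loose = th.prune_trials(self._ts(trials), range_thresh=800)[0].n_kept
        assert kept_tight <= kept_loose

    def test_under_min_epochs_flags_channel(self):
        trials = np.random.default_rng(6).normal(size=(50, 1250))
        _, report = th.prune_trials(self._ts(trials), min_epochs=200)
        assert report.excluded

    def test_reference_class(self):
        """Kurtosis statistics can come from a separate trial class."""
        rng = np.random.default_rng(7)
        ts = self._ts(rng.normal(0, 10, size=(30, 1250)))
        ref = self._ts(rng.normal(0, 10, size=(100, 1250)))
        pruned, _ = th.prune_trials(ts, reference=ref, min_epochs=0)
        assert pruned.n_kept >= 25
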