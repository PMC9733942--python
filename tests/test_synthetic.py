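import dataclasses

import numpy as np
import pytest
from scipy import signal as sps

import thetastim as th

FS = 1000.0


class TestBackground:
    def test_pure_sinusoid_spectrum(self):
        cfg = th.SynthConfig(theta_amp=10.0, theta_snr_db=None, noise_amp=0.0,
                             theta_freq_jitter_hz=0.0)
        x = th.generate_background(cfg, int(30 * FS), np.random.default_rng(0))
        f, p = sps.welch(x, fs=FS, nperseg=4096)
        assert f[np.argmax(p)] == pytest.approx(cfg.theta_freq, abs=0.3)

    def test_noise_exponent_recovered(self):
        cfg = th.SynthConfig(theta_amp=0.0, theta_snr_db=None)
        x = th.generate_background(cfg, int(120 * FS), np.random.default_rng(1))
        ps = th.fit_background(th.compute_psd(x, FS))
        assert ps.log_fit["slope"] == pytest.approx(-cfg.noise_exponent, abs=0.15)

    def test_default_background_has_theta_peak(self):
        cfg = th.SynthConfig()
        x = th.generate_background(cfg, int(120 * FS), np.random.default_rng(2))
        ps = th.detect_narrowband_peaks(th.fit_background(th.compute_psd(x, FS)))
        in_band = [p for p in ps.peaks if 3.0 <= p["freq"] <= 8.0 and p["corrected"] > 0.3]
        assert len(in_band) >= 1

    def test_requested_band_snr_achieved(self):
        """The derived theta amplitude lands within ~1.5 dB of the
        configured in-band SNR (measured by Welch integration)."""
        cfg = th.SynthConfig(theta_snr_db=10.0)
        n = int(120 * FS)
        amp = th.theta_amp_for_snr(cfg, n)
        noise = th.generate_background(
            th.SynthConfig(theta_amp=0.0, theta_snr_db=None), n, np.random.default_rng(3)
        )
        f, p = sps.welch(noise, fs=FS, nperseg=int(4 * FS))
        band = (f >= 3.0) & (f <= 8.0)
        p_noise = np.trapezoid(p[band], f[band])
        snr_db = 10 * np.log10((amp**2 / 2) / p_noise)
        assert snr_db == pytest.approx(10.0, abs=1.5)


class TestSession:
    def test_reproducible_from_seed(self):
        cfg = th.SynthConfig(n_pulses=20)
        rec1, gt1 = th.generate_session(cfg, np.random.default_rng(5))
        rec2, gt2 = th.generate_session(cfg, np.random.default_rng(5))
        assert np.array_equal(rec1.samples, rec2.samples)
        assert np.array_equal(gt1.true_phase_deg, gt2.true_phase_deg)

    def test_ground_truth_shapes_and_ranges(self, session_m03):
        rec, gt = session_m03
        n = gt.pulse_times.size
        assert rec.events.size == n
        assert gt.true_phase_deg.shape == (rec.n_channels, n)
        assert np.all((gt.true_phase_deg >= -180) & (gt.true_phase_deg < 180))
        # jittered ~1 Hz train: interpulse intervals uniform on [1, 1.25] s
        iv = np.diff(gt.pulse_times)
        assert iv.min() >= 1.0 and iv.max() <= 1.25
        # rest segments are >= 90 s and clear of every epoch
        for start, end in rec.rest_segments:
            assert end - start >= 90.0
            assert not np.any((rec.events + 0.5 > start) & (rec.events - 0.75 < end))

    def test_unmodulated_session_has_equal_bin_amplitudes(self):
        """With m = 0 the injected response does not depend on phase.  Theta
        is made negligibly small here so the phase-conditioned oscillation
        (the confound the sham-isolation procedure exists for) does not
        enter the window average; true phases are still defined by the
        noiseless theta series."""
        cfg = th.SynthConfig(n_pulses=400, modulation_depth=0.0,
                             theta_amp=1e-3, theta_snr_db=None)
        rec, gt = th.generate_session(cfg, np.random.default_rng(6))
        ts = th.epoch_channel(rec, 0).with_phases(gt.true_phase_deg[0])
        w = th.ComponentWindow("early", 60.0, 45.0, 75.0)
        amps = th.component_amplitude(ts.trials, ts.time_ms, w)
        labels = th.assign_phase_bins(gt.true_phase_deg[0])
        a_peak = amps[labels == "peak"]
        a_trough = amps[labels == "trough"]
        se = np.sqrt(a_peak.var(ddof=1) / a_peak.size + a_trough.var(ddof=1) / a_trough.size)
        assert abs(a_peak.mean() - a_trough.mean()) < 4 * se

    def test_modulated_scales_follow_arc_average(self):
        """Mean modulation scale in the peak vs trough bin differs by
        2 * m * <cos> over a 90-degree arc = 2 m sin(45)/(pi/4)."""
        cfg = th.SynthConfig(n_pulses=1000, modulation_depth=0.5)
        rec, gt = th.generate_session(cfg, np.random.default_rng(7))
        labels = th.assign_phase_bins(gt.true_phase_deg[0])
        scales = gt.early_scale[0]
        diff = scales[labels == "peak"].mean() - scales[labels == "trough"].mean()
        expected = 2 * 0.5 * np.sin(np.pi / 4) / (np.pi / 4)
        assert diff == pytest.approx(expected, abs=0.05)
        # and the measured evoked amplitudes go the injected way
        ts = th.epoch_channel(rec, 0).with_phases(gt.true_phase_deg[0])
        w = th.ComponentWindow("early", 60.0, 45.0, 75.0)
        amps = th.component_amplitude(ts.trials, ts.time_ms, w)
        assert amps[labels == "peak"].mean() < amps[labels == "trough"].mean()

    def test_epileptiform_outliers_are_pruned(self):
        cfg = th.SynthConfig(n_pulses=400, outlier_rate=0.05)
        rec, gt = th.generate_session(cfg, np.random.default_rng(8))
        ts = th.epoch_channel(rec, 0)
        pruned, report = th.prune_trials(ts)
        planted = gt.outlier_mask[0]
        assert planted.sum() >= 10
        caught = np.sum(~pruned.kept[planted]) / planted.sum()
        assert caught >= 0.8

    def test_channels_share_theta_at_fixed_offset(self):
        """Channels of one session see the same (jittered) oscillation at
        their configured phase offsets: high PLV at the offset angle."""
        cfg = th.SynthConfig(n_pulses=10, rest_s=120.0, n_channels=2,
                             channel_phase_offsets_deg=[0.0, -60.0])
        rec, _ = th.generate_session(cfg, np.random.default_rng(3))
        pa, va = th.ground_truth_phase(th.rest_segment_samples(rec, 0, 0), rec.fs)
        pb, _ = th.ground_truth_phase(th.rest_segment_samples(rec, 1, 0), rec.fs)
        res = th.plv_offset(pa[va], pb[va])
        assert res["plv"] > 0.9
        assert abs(th.circ_diff_deg(res["mean_offset_deg"], 60.0)) < 10.0

    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            th.SynthConfig(modulation_depth=1.5)
        with pytest.raises(ValueError):
            th.SynthConfig(rest_s=30.0)
        with pytest.raises(ValueError):
            th.SynthConfig(artifact_ms=10.0)


class TestStatisticalGenerators:
    def test_channel_stats_modulation_structure(self):
        rng = np.random.default_rng(9)
        phases, amps = th.generate_channel_stats(
            20_000, modulation_depth=0.4, preferred_phase_deg=30.0, rng=rng,
            noise_sd=0.0,
        )
        est = th.preferred_phase_continuous(phases, amps)
        assert abs(th.circ_diff_deg(est, 30.0)) < 2.0

    def test_lme_dataset_layout(self):
        df = th.generate_lme_dataset(np.random.default_rng(10), 3, 2, 5, beta=1.0)
        assert set(df.columns) == {"subject", "electrode", "phase", "amplitude"}
        assert len(df) == 3 * 2 * 2 * 5
        assert set(df.phase) == {"peak", "trough"}

    def test_config_roundtrips_through_asdict(self):
        cfg = th.SynthConfig(n_pulses=7)
        d = dataclasses.asdict(cfg)
        assert d["ep_early"]["latency_ms"] == 60.0
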