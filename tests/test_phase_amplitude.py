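import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import thetastim as th
from thetastim.types import TrialSet, epoch_time_ms

T_MS = epoch_time_ms()


def oracle_r(phases_deg, x):
    """Independent closed-form oracle built on np.corrcoef."""
    rad = np.deg2rad(np.asarray(phases_deg, float))
    c, s = np.cos(rad), np.sin(rad)
    rxc = np.corrcoef(x, c)[0, 1]
    rxs = np.corrcoef(x, s)[0, 1]
    rcs = np.corrcoef(c, s)[0, 1]
    return np.sqrt((rxc**2 + rxs**2 - 2 * rxc * rxs * rcs) / (1 - rcs**2))


class TestCircLinCorr:
    def test_worked_cardinal_example(self):
        """phi = cardinal angles, x = {2,1,0,1}: rxc = 1, rxs = 0, rcs = 0,
        hence r = 1 exactly."""
        r = th.circ_lin_corr([0.0, 90.0, 180.0, 270.0], [2.0, 1.0, 0.0, 1.0])
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_perfect_cosine_fit(self):
        phases = np.array([0.0, 90.0, 180.0, -90.0, 30.0, -120.0])
        x = np.cos(np.deg2rad(phases))
        assert th.circ_lin_corr(phases, x) == pytest.approx(1.0, abs=1e-9)

    def test_matches_oracle_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = rng.integers(5, 60)
            phases = rng.uniform(-180, 180, n)
            x = rng.normal(size=n)
            assert th.circ_lin_corr(phases, x) == pytest.approx(
                oracle_r(phases, x), abs=1e-12
            )

    def test_independent_noise_is_near_zero(self):
        rng = np.random.default_rng(1)
        r = th.circ_lin_corr(rng.uniform(-180, 180, 10_000), rng.normal(size=10_000))
        assert r < 0.05

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            th.circ_lin_corr([0.0, 90.0, 180.0], [1.0, 2.0, 3.0])  # n < 4
        with pytest.raises(ValueError):
            th.circ_lin_corr([0.0, 90.0, 180.0, -90.0], [1.0, 1.0, 1.0, 1.0])

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0), st.floats(-180.0, 180.0))
    def test_affine_amplitude_and_rotation_invariance(self, scale, shift, rot):
        rng = np.random.default_rng(7)
        phases = rng.uniform(-180, 180, 40)
        x = np.cos(np.deg2rad(phases)) + rng.normal(0, 0.5, 40)
        r0 = th.circ_lin_corr(phases, x)
        assert th.circ_lin_corr(phases, scale * x + shift) == pytest.approx(r0, abs=1e-9)
        assert th.circ_lin_corr(th.wrap_deg(phases + rot), x) == pytest.approx(
            r0, abs=1e-6
        )


class TestPermZscore:
    def test_strong_effect_gives_large_z(self):
        rng = np.random.default_rng(2)
        phases = rng.uniform(-180, 180, 200)
        res = th.perm_zscore(phases, np.cos(np.deg2rad(phases)), n_perm=500, seed=3)
        assert res.z > 5.0

    def test_null_calibration(self):
        """Shuffled data give z ~ N(0,1): the mean over 100 seeded runs
        stays within 0.2 of zero."""
        rng = np.random.default_rng(12)
        zs = [
            th.perm_zscore(rng.uniform(-180, 180, 100), rng.normal(size=100),
                           n_perm=200, seed=rng).z
            for _ in range(100)
        ]
        assert abs(np.mean(zs)) < 0.2

    def test_constant_amplitudes_error(self):
        with pytest.raises(ValueError):
            th.perm_zscore([0.0, 90.0, 180.0, -90.0], [1.0, 1.0, 1.0, 1.0], seed=0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(3)
        phases = rng.uniform(-180, 180, 50)
        x = rng.normal(size=50)
        assert th.perm_zscore(phases, x, seed=11).z == th.perm_zscore(phases, x, seed=11).z


class TestTimecourse:
    def test_modulated_template_peaks_at_its_latency(self):
        rng = np.random.default_rng(1)
        template = np.exp(-((T_MS - 60.0) ** 2) / (2 * 15.0**2))
        phases = rng.uniform(-180, 180, 600)
        amps = 1 + 0.5 * np.cos(np.deg2rad(phases))
        trials = amps[:, None] * (-30 * template)[None, :] + rng.normal(0, 10, (600, T_MS.size))
        tc = th.phase_amplitude_timecourse(
            TrialSet(trials=trials, time_ms=T_MS).with_phases(phases)
        )
        assert tc.peak_latencies_ms
        assert tc.peak_latencies_ms[0] == pytest.approx(60.0, abs=10.0)

    def test_ongoing_theta_decays_without_post_onset_peaks(self):
        """Stimulation-free trials scored against ground-truth phase: r(t)
        decays smoothly after onset; the group-mean timecourse has no
        qualifying local maxima."""
        rs = []
        for seed in range(5):
            cfg = th.SynthConfig(n_pulses=10, rest_s=120.0)
            rec, _ = th.generate_session(cfg, np.random.default_rng(4000 + seed))
            seg = th.rest_segment_samples(rec, 0, 0)
            sf = th.sample_stimulation_free_trials(seg, 1000.0)
            truth, _ = th.ground_truth_phase(seg, 1000.0)
            sf = sf.with_phases(truth[sf.onset_samples])
            rs.append(th.phase_amplitude_timecourse(sf).r)
        rbar = np.mean(rs, axis=0)
        from thetastim.phase_amplitude import find_timecourse_peaks

        assert find_timecourse_peaks(rbar, T_MS, min_prominence=0.025) == []
        i0 = 750
        assert rbar[i0] > rbar[i0 + 250] > rbar[i0 + 490]  # net decay

    def test_degenerate_timepoint_is_missing(self):
        rng = np.random.default_rng(5)
        trials = rng.normal(size=(8, T_MS.size))
        trials[:, 100] = 3.0  # zero variance at one timepoint
        tc = th.phase_amplitude_timecourse(
            TrialSet(trials=trials, time_ms=T_MS).with_phases(
                rng.uniform(-180, 180, 8)
            )
        )
        assert np.isnan(tc.r[100])
        assert np.isfinite(tc.r[101])


class TestElectrodeTTest:
    def test_symmetric_pair(self):
        res = th.electrode_t_test([1.0, -1.0])
        assert res["t"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_paired_identical(self):
        res = th.electrode_t_test([1.0, 2.0, 3.0], paired_partner=[1.0, 2.0, 3.0])
        assert res["t"] == 0.0

    def test_matches_arithmetic_oracle(self):
        vals = np.array([0.5, 0.7, 0.2, 0.9, 0.4])
        res = th.electrode_t_test(vals)
        assert res["t"] == pytest.approx(vals.mean() / (vals.std(ddof=1) / np.sqrt(5)))
        assert res["cohens_d"] == pytest.approx(vals.mean() / vals.std(ddof=1))


class TestPreferredPhase:
    def test_bin_solution_recovers_injected_phase(self):
        for phi_star in (0.0, -90.0, 135.0):
            bins = {
                lab: -30.0 * (1 + 0.4 * np.cos(np.deg2rad(c - phi_star)))
                for lab, c in th.BIN_CENTERS_DEG.items()
            }
            assert abs(
                th.circ_diff_deg(th.preferred_phase_from_bins(bins), phi_star)
            ) < 1e-9

    def test_continuous_fit_matches_bins_on_clean_data(self):
        rng = np.random.default_rng(6)
        phases = rng.uniform(-180, 180, 2000)
        amps = -30.0 * (1 + 0.3 * np.cos(np.deg2rad(phases - 40.0)))
        est = th.preferred_phase_continuous(phases, amps)
        assert abs(th.circ_diff_deg(est, 40.0)) < 1.0
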