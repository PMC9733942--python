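"""Synthetic LFP sessions with known ground truth.

Generates the statistical structure the analysis assumes: 1/f^alpha
background noise (spectral shaping), a theta oscillation within 3-8 Hz,
pulse trains at 0.5 Hz or jittered ~1 Hz (interpulse 1-1.25 s), and per
pulse an injected brief biphasic artifact plus two negative Gaussian EP
components whose amplitudes are multiplied by (1 + m cos(phi_true -
phi_pref)), with phi_true read from the noiseless theta component at pulse
onset — so ground truth is exact.  Rest segments of >= 90 s precede and
follow the train, matching the recording layout the spectral and sham
analyses expect.

Two lighter generators support calibration studies: a statistical-level
channel generator (phases + modulated amplitudes, no waveforms) and a
hierarchical amplitude generator for the mixed-model analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .circular import as_rng, wrap_deg
from .types import ChannelInfo, RawRecording


@dataclass
class EPComponentSpec:
    """One negative Gaussian EP component (amplitude is the magnitude of
    the negative deflection, in uV)."""

    latency_ms: float
    width_ms: float
    amplitude_uv: float


@dataclass
class SynthConfig:
    """Study conditions for a synthetic session.

    Defaults are the conditions of the emulated protocol: 1 kHz sampling,
    a 5.5 Hz theta oscillation at 10 dB in-band SNR over 1/f^1.5 background
    noise, a jittered ~1 Hz train (interpulse uniform on 1-1.25 s), early
    and late negative components at 60/140 ms (widths 15/30 ms), and >= 90 s
    of rest before and after the train.
    """

    fs: float = 1000.0
    theta_freq: float = 5.5
    theta_freq_jitter_hz: float = 0.5  # slow wander of the instantaneous frequency
    theta_amp: Optional[float] = None  # uV; derived from theta_snr_db when None
    theta_snr_db: Optional[float] = 10.0
    noise_exponent: float = 1.5
    noise_amp: float = 15.0  # total RMS, uV
    noise_knee_hz: float = 0.5  # spectrum is flat below this knee
    n_channels: int = 1
    channel_phase_offsets_deg: Optional[list] = None
    train: str = "jittered_1hz"  # or "0.5hz"
    n_pulses: int = 1200
    ep_early: EPComponentSpec = field(default_factory=lambda: EPComponentSpec(60.0, 15.0, 30.0))
    ep_late: EPComponentSpec = field(default_factory=lambda: EPComponentSpec(140.0, 30.0, 20.0))
    modulation_phase_deg: float = 0.0
    modulation_depth: float = 0.0
    modulation_target: str = "both"  # early | late | both
    artifact_amp: float = 200.0
    artifact_ms: float = 4.0
    outlier_rate: float = 0.0
    rest_s: float = 95.0

    def __post_init__(self):
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation depth must be in [0, 1]")
        if self.noise_exponent < 0:
            raise ValueError("noise exponent must be non-negative")
        if self.train not in ("jittered_1hz", "0.5hz"):
            raise ValueError("train must be 'jittered_1hz' or '0.5hz'")
        if self.modulation_target not in ("early", "late", "both"):
            raise ValueError("modulation target must be early, late, or both")
        if self.artifact_ms > 5.0:
            raise ValueError("artifact duration must be <= 5 ms")
        for spec in (self.ep_early, self.ep_late):
            if spec.amplitude_uv < 0:
                raise ValueError("component amplitudes are magnitudes and must be >= 0")
        if self.rest_s < 90.0:
            raise ValueError("rest segments must be at least 90 s")


def _shaping_weights(n_samples: int, fs: float, alpha: float,
                     knee_hz: float = 0.5) -> np.ndarray:
    """Amplitude shaping f_eff^(-alpha/2) with a low-frequency knee.

    Below ``knee_hz`` the spectrum is flat (f_eff = knee), as in real LFP
    aperiodic spectra; without the knee the total noise power would be
    dominated by arbitrarily slow drift and would grow with duration.
    """
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w = np.zeros_like(f)
    w[1:] = np.maximum(f[1:], knee_hz) ** (-alpha / 2.0)
    return w


def band_noise_fraction(n_samples: int, fs: float, alpha: float,
                        band=(3.0, 8.0), knee_hz: float = 0.5) -> float:
    """Expected fraction of shaped-noise power falling inside ``band``."""
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    w2 = _shaping_weights(n_samples, fs, alpha, knee_hz) ** 2
    total = w2.sum()
    in_band = w2[(f >= band[0]) & (f <= band[1])].sum()
    return float(in_band / total)


def theta_amp_for_snr(cfg: SynthConfig, n_samples: int, band=(3.0, 8.0)) -> float:
    """Theta amplitude (uV) giving the configured in-band SNR.

    SNR is defined as theta power (amp^2 / 2) over expected 3-8 Hz noise
    power of the shaped background.
    """
    frac = band_noise_fraction(n_samples, cfg.fs, cfg.noise_exponent, band,
                               cfg.noise_knee_hz)
    p_band = cfg.noise_amp**2 * frac
    return float(np.sqrt(2.0 * p_band * 10.0 ** (cfg.theta_snr_db / 10.0)))


def _resolve_theta_amp(cfg: SynthConfig, n_samples: int) -> float:
    if cfg.theta_amp is not None:
        return cfg.theta_amp
    if cfg.theta_snr_db is None:
        raise ValueError("either theta_amp or theta_snr_db must be set")
    return theta_amp_for_snr(cfg, n_samples)


def shaped_noise(n_samples: int, fs: float, alpha: float, rms: float, rng,
                 knee_hz: float = 0.5) -> np.ndarray:
    """Gaussian 1/f^alpha noise by spectral shaping, scaled to ``rms`` uV."""
    rng = as_rng(rng)
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white) * _shaping_weights(n_samples, fs, alpha, knee_hz)
    x = np.fft.irfft(spec, n=n_samples)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def theta_phase_series(cfg: SynthConfig, n_samples: int, rng=None,
                       phase_offset_deg: float = 0.0) -> np.ndarray:
    """Instantaneous theta phase (radians) of the noiseless oscillation.

    With ``theta_freq_jitter_hz`` > 0 the instantaneous frequency wanders
    slowly (smoothed Gaussian noise, ~0.5 s correlation, clipped to the
    jitter bound) so theta loses phase coherence over a few hundred ms, as
    real hippocampal theta does.  The integrated phase is exact ground
    truth either way.
    """
    if cfg.theta_freq_jitter_hz > 0:
        from scipy.ndimage import gaussian_filter1d

        rng = as_rng(rng)
        w = gaussian_filter1d(rng.standard_normal(n_samples), sigma=0.5 * cfg.fs)
        sd = w.std()
        if sd > 0:
            w = w / sd
        freq = cfg.theta_freq + np.clip(
            cfg.theta_freq_jitter_hz * w,
            -cfg.theta_freq_jitter_hz, cfg.theta_freq_jitter_hz,
        )
        phase = 2.0 * np.pi * np.cumsum(freq) / cfg.fs
    else:
        t = np.arange(n_samples) / cfg.fs
        phase = 2.0 * np.pi * cfg.theta_freq * t
    return phase + np.deg2rad(phase_offset_deg)


def generate_background(cfg: SynthConfig, n_samples: int, rng,
                        phase_offset_deg: float = 0.0,
                        return_phase: bool = False):
    """1/f^alpha background plus theta sinusoid; seeded and reproducible."""
    rng = as_rng(rng)
    amp = _resolve_theta_amp(cfg, n_samples)
    phi = theta_phase_series(cfg, n_samples, rng, phase_offset_deg)
    x = shaped_noise(n_samples, cfg.fs, cfg.noise_exponent, cfg.noise_amp, rng,
                     cfg.noise_knee_hz)
    x = x + amp * np.cos(phi)
    return (x, phi) if return_phase else x


def pulse_times(cfg: SynthConfig, rng) -> np.ndarray:
    """Stimulation onset times (s): first pulse 1 s after the leading rest."""
    rng = as_rng(rng)
    if cfg.train == "0.5hz":
        intervals = np.full(cfg.n_pulses - 1, 2.0)
    else:
        intervals = rng.uniform(1.0, 1.25, size=cfg.n_pulses - 1)
    return cfg.rest_s + 1.0 + np.concatenate([[0.0], np.cumsum(intervals)])


def _add_at(x: np.ndarray, start: int, wave: np.ndarray) -> None:
    """Add ``wave`` to ``x`` starting at ``start``, truncating at the end."""
    stop = min(start + wave.size, x.size)
    if stop > start:
        x[start:stop] += wave[: stop - start]


def _gaussian_component(spec: EPComponentSpec, fs: float) -> np.ndarray:
    """Negative Gaussian deflection sampled from onset to latency + 4 sigma."""
    n = int(round((spec.latency_ms + 4.0 * spec.width_ms) * fs / 1000.0)) + 1
    t_ms = np.arange(n) * 1000.0 / fs
    return -spec.amplitude_uv * np.exp(-((t_ms - spec.latency_ms) ** 2)
                                       / (2.0 * spec.width_ms**2))


@dataclass
class GroundTruth:
    """Exact per-pulse state of a generated session.

    ``true_phase_deg`` and the component scales are per channel x pulse;
    phases are read from the noiseless theta component.
    """

    pulse_times: np.ndarray
    true_phase_deg: np.ndarray  # (n_channels, n_pulses)
    early_scale: np.ndarray
    late_scale: np.ndarray
    outlier_mask: np.ndarray  # (n_channels, n_pulses) bool
    config: SynthConfig


def generate_session(cfg: SynthConfig, rng) -> tuple[RawRecording, GroundTruth]:
    """Generate a full multichannel session with stimulation train.

    Each channel gets independent background noise and a fixed theta phase
    offset; the pulse train, artifact, and modulated EP components are
    injected into every channel.  Optional epileptiform outliers (brief
    high-kurtosis transients below the range-pruning threshold) are injected
    per channel at ``outlier_rate`` for pruning round-trips.
    """
    rng = as_rng(rng)
    times = pulse_times(cfg, rng)
    duration = times[-1] + 1.0 + cfg.rest_s
    n_samples = int(round(duration * cfg.fs))
    onsets = np.round(times * cfg.fs).astype(int)

    offsets = (cfg.channel_phase_offsets_deg
               if cfg.channel_phase_offsets_deg is not None
               else [0.0] * cfg.n_channels)
    if len(offsets) != cfg.n_channels:
        raise ValueError("one phase offset per channel is required")

    early = _gaussian_component(cfg.ep_early, cfg.fs)
    late = _gaussian_component(cfg.ep_late, cfg.fs)
    n_art = max(2, int(round(cfg.artifact_ms * cfg.fs / 1000.0)))
    artifact = np.concatenate([
        np.full(n_art // 2, cfg.artifact_amp),
        np.full(n_art - n_art // 2, -cfg.artifact_amp),
    ])
    mod_rad = np.deg2rad(cfg.modulation_phase_deg)

    samples = np.empty((cfg.n_channels, n_samples))
    true_phase = np.empty((cfg.n_channels, cfg.n_pulses))
    e_scale = np.ones((cfg.n_channels, cfg.n_pulses))
    l_scale = np.ones((cfg.n_channels, cfg.n_pulses))
    outliers = np.zeros((cfg.n_channels, cfg.n_pulses), dtype=bool)

    # one underlying theta trajectory per session: channels see the same
    # oscillation at fixed phase offsets (noise is independent per channel)
    phi_base = theta_phase_series(cfg, n_samples, rng)
    theta_amp = _resolve_theta_amp(cfg, n_samples)

    for ci in range(cfg.n_channels):
        phi = phi_base + np.deg2rad(offsets[ci])
        x = shaped_noise(n_samples, cfg.fs, cfg.noise_exponent, cfg.noise_amp, rng,
                         cfg.noise_knee_hz) + theta_amp * np.cos(phi)
        phase_deg = wrap_deg(np.rad2deg(phi[onsets]))
        true_phase[ci] = phase_deg
        mod = 1.0 + cfg.modulation_depth * np.cos(np.deg2rad(phase_deg) - mod_rad)
        if cfg.modulation_target in ("early", "both"):
            e_scale[ci] = mod
        if cfg.modulation_target in ("late", "both"):
            l_scale[ci] = mod
        outliers[ci] = rng.random(cfg.n_pulses) < cfg.outlier_rate
        for pi, s0 in enumerate(onsets):
            _add_at(x, s0, artifact)
            _add_at(x, s0, e_scale[ci, pi] * early)
            _add_at(x, s0, l_scale[ci, pi] * late)
            if outliers[ci, pi]:
                for _ in range(3):
                    lat = s0 + int(rng.uniform(0.03, 0.45) * cfg.fs)
                    amp = rng.choice([-1.0, 1.0]) * rng.uniform(250.0, 350.0)
                    _add_at(x, lat, np.full(2, amp))
        samples[ci] = x

    channels = [
        ChannelInfo(label=f"ch{i}", subject="s0", region="hippocampus", hemisphere="L")
        for i in range(cfg.n_channels)
    ]
    rec = RawRecording(
        samples=samples,
        fs=cfg.fs,
        channels=channels,
        events=times,
        rest_segments=[(0.0, cfg.rest_s), (duration - cfg.rest_s, duration)],
    )
    gt = GroundTruth(
        pulse_times=times, true_phase_deg=true_phase,
        early_scale=e_scale, late_scale=l_scale,
        outlier_mask=outliers, config=cfg,
    )
    return rec, gt


def rest_segment_samples(rec: RawRecording, channel: int = 0, which: int = 0) -> np.ndarray:
    """Extract one rest segment of one channel as a continuous series."""
    start, end = rec.rest_segments[which]
    i0, i1 = int(round(start * rec.fs)), int(round(end * rec.fs))
    return rec.samples[channel, i0:i1]


def generate_channel_stats(
    n_trials: int,
    modulation_depth: float = 0.0,
    preferred_phase_deg: float = 0.0,
    rng=None,
    base_amplitude: float = -30.0,
    noise_sd: float = 10.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Statistical-level channel: uniform onset phases and per-trial
    component amplitudes base * (1 + m cos(phi - phi_pref)) + Gaussian noise.

    Used for large calibration studies (type-I error, power) where waveform
    simulation adds nothing to the quantity under test.
    """
    rng = as_rng(rng)
    phases = rng.uniform(-180.0, 180.0, size=n_trials)
    mod = 1.0 + modulation_depth * np.cos(np.deg2rad(phases - preferred_phase_deg))
    amps = base_amplitude * mod + rng.normal(0.0, noise_sd, size=n_trials)
    return phases, amps


def generate_lme_dataset(
    rng=None,
    n_subjects: int = 8,
    n_electrodes: int = 3,
    n_trials_per_level: int = 20,
    beta: float = 0.0,
    sd_subject_intercept: float = 5.0,
    sd_subject_slope: float = 2.0,
    sd_electrode_intercept: float = 3.0,
    sd_electrode_slope: float = 1.0,
    sd_noise: float = 10.0,
    baseline: float = -30.0,
) -> pd.DataFrame:
    """Hierarchical peak/trough amplitudes for mixed-model studies.

    amplitude = baseline + u_subject + v_electrode
                + (beta + b_subject + g_electrode) * phase_code + noise,
    phase_code = +0.5 (peak) / -0.5 (trough).
    """
    rng = as_rng(rng)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0.0, sd_subject_intercept)
        b = rng.normal(0.0, sd_subject_slope)
        for e in range(n_electrodes):
            v = rng.normal(0.0, sd_electrode_intercept)
            g = rng.normal(0.0, sd_electrode_slope)
            for label, code in (("peak", 0.5), ("trough", -0.5)):
                amps = (baseline + u + v + (beta + b + g) * code
                        + rng.normal(0.0, sd_noise, size=n_trials_per_level))
                for a in amps:
                    rows.append(
                        {"subject": f"s{s}", "electrode": f"e{e}",
                         "phase": label, "amplitude": a}
                    )
    return pd.DataFrame(rows)
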