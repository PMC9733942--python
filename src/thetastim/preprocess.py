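"""Continuous-recording preprocessing: re-referencing, downsampling,
epoching with baseline correction, and artifact pruning.

The chain mirrors standard intracranial-EP practice: common-average
re-referencing within the ipsilateral depth-electrode group, anti-aliased
downsampling to 1 kHz, epoching to [-750, 500) ms around each stimulation
pulse with baseline correction over [-750, -2] ms, then trial pruning by
peak-to-peak signal range (> 800 uV) and by sample kurtosis (> channel mean
+ 2 SD, computed within trial class).  Channels retaining fewer than 200
trials are flagged excluded (never silently dropped).
"""

from __future__ import annotations

import logging
from dataclasses import replace
from fractions import Fraction
from typing import Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy import stats as spstats

from .types import (
    BASELINE_MS,
    EPOCH_END_MS,
    EPOCH_START_MS,
    TARGET_FS,
    PruneReport,
    RawRecording,
    TrialSet,
    epoch_time_ms,
)

log = logging.getLogger(__name__)


def rereference_common_average(rec: RawRecording, group: Sequence[str]) -> RawRecording:
    """Subtract the per-sample mean of ``group`` channels from each of them.

    ``group`` must be non-empty, name channels present in ``rec``, and lie in
    a single hemisphere (the reference is the common average of ipsilateral
    depth electrodes).  Channels outside the group are left untouched.
    """
    if len(group) == 0:
        raise ValueError("re-reference group is empty")
    idx = [rec.channel_index(label) for label in group]
    hemis = {rec.channels[i].hemisphere for i in idx}
    if len(hemis) > 1:
        offenders = [f"{rec.channels[i].label}({rec.channels[i].hemisphere})" for i in idx]
        raise ValueError(
            "re-reference group mixes hemispheres: " + ", ".join(offenders)
        )
    out = rec.copy()
    mean = out.samples[idx].mean(axis=0)
    out.samples[idx] -= mean
    return out


def _antialias_lowpass(samples: np.ndarray, fs: float, cutoff_hz: float = 400.0) -> np.ndarray:
    """Zero-phase FIR low-pass prior to decimation.

    Hamming-window FIR with ~80 Hz transition band, applied forward-backward
    so the filter introduces no group delay (event times in seconds stay
    aligned with the waveform).
    """
    numtaps = int(np.ceil(3.3 * fs / 80.0))
    numtaps += (numtaps + 1) % 2  # odd length -> integer group delay
    taps = sps.firwin(numtaps, cutoff_hz, fs=fs)
    return sps.filtfilt(taps, [1.0], samples, axis=-1)


def resample_to_1khz(rec: RawRecording, target_fs: float = TARGET_FS) -> RawRecording:
    """Low-pass filter and downsample a recording to 1 kHz.

    Integer ratios decimate directly after the anti-alias filter; other
    ratios go through polyphase rational resampling.  Event and rest-segment
    times are in seconds and are unchanged.
    """
    if rec.fs < target_fs:
        raise ValueError(f"cannot downsample: fs={rec.fs} Hz is below {target_fs} Hz")
    if rec.fs == target_fs:
        return rec.copy()
    filtered = _antialias_lowpass(rec.samples, rec.fs)
    ratio = rec.fs / target_fs
    if abs(ratio - round(ratio)) < 1e-9:
        out_samples = filtered[:, :: int(round(ratio))]
    else:
        frac = Fraction(ratio).limit_denominator(1000)
        out_samples = sps.resample_poly(filtered, frac.denominator, frac.numerator, axis=-1)
    return RawRecording(
        samples=out_samples,
        fs=target_fs,
        channels=list(rec.channels),
        events=rec.events.copy(),
        rest_segments=list(rec.rest_segments),
    )


def baseline_correct(trials: np.ndarray, time_ms: np.ndarray) -> np.ndarray:
    """Subtract the per-trial mean over the baseline window (inclusive)."""
    mask = (time_ms >= BASELINE_MS[0]) & (time_ms <= BASELINE_MS[1])
    return trials - trials[..., mask].mean(axis=-1, keepdims=True)


def epoch_channel(
    rec: RawRecording, channel: str | int, events: Optional[np.ndarray] = None
) -> TrialSet:
    """Epoch one channel around stimulation events at 1 kHz.

    Events whose [-750, 500) ms window does not fit inside the recording are
    dropped (and logged).  Raises if no event yields a valid trial.
    """
    if rec.fs != TARGET_FS:
        raise ValueError(f"epoching expects fs = {TARGET_FS} Hz, got {rec.fs}")
    ci = rec.channel_index(channel) if isinstance(channel, str) else int(channel)
    ev = rec.events if events is None else np.asarray(events, dtype=float)
    time_ms = epoch_time_ms()
    n = rec.samples.shape[1]
    onsets = np.round(ev * rec.fs).astype(int)
    valid = (onsets + EPOCH_START_MS >= 0) & (onsets + EPOCH_END_MS <= n)
    n_dropped = int((~valid).sum())
    if n_dropped:
        log.warning(
            "channel %s: dropped %d/%d events whose epoch window exceeds the recording",
            rec.channels[ci].label, n_dropped, onsets.size,
        )
    onsets = onsets[valid]
    if onsets.size == 0:
        raise ValueError("no events with a complete epoch window")
    offsets = np.arange(EPOCH_START_MS, EPOCH_END_MS)
    trials = rec.samples[ci, onsets[:, None] + offsets[None, :]]
    trials = baseline_correct(trials, time_ms)
    return TrialSet(
        trials=trials, time_ms=time_ms, channel=rec.channels[ci], onset_samples=onsets
    )


def epoch_and_baseline(rec: RawRecording, events: Optional[np.ndarray] = None) -> list[TrialSet]:
    """Epoch every channel of ``rec``; see :func:`epoch_channel`."""
    return [epoch_channel(rec, i, events) for i in range(rec.n_channels)]


def trial_kurtosis(trials: np.ndarray) -> np.ndarray:
    """Pearson (non-excess) sample kurtosis of each trial's samples."""
    return spstats.kurtosis(trials, axis=-1, fisher=False, bias=True)


def prune_trials(
    ts: TrialSet,
    range_thresh: float = 800.0,
    k_sd: float = 2.0,
    min_epochs: int = 200,
    reference: Optional[TrialSet] = None,
) -> tuple[TrialSet, PruneReport]:
    """Flag artifactual trials by signal range, then by kurtosis.

    A trial is pruned if its peak-to-peak range exceeds ``range_thresh`` uV.
    Among the range-surviving trials, a trial is then pruned if its sample
    kurtosis strictly exceeds mean + ``k_sd`` * SD of the reference trial
    kurtoses.  The reference defaults to the channel's own range-surviving
    trials; pass a separate ``reference`` TrialSet to compare within another
    trial class (stimulation-free trials are compared only to stimulation-free
    trials of the same channel).

    Never raises for over-pruned channels: the report carries an ``excluded``
    flag when fewer than ``min_epochs`` trials remain.
    """
    if ts.n_trials < 2:
        raise ValueError("pruning requires at least 2 trials")
    ptp = np.ptp(ts.trials, axis=-1)
    range_ok = ptp <= range_thresh

    candidates = ts.kept & range_ok
    kurt = trial_kurtosis(ts.trials)
    if reference is not None:
        ref_ok = reference.kept & (np.ptp(reference.trials, axis=-1) <= range_thresh)
        ref_kurt = trial_kurtosis(reference.trials)[ref_ok]
    else:
        ref_kurt = kurt[candidates]
    if ref_kurt.size >= 2:
        sd = float(np.std(ref_kurt, ddof=1))
        thresh = float(np.mean(ref_kurt)) + k_sd * sd
    else:
        thresh = np.inf
    kurt_ok = ~(kurt > thresh)  # strict >: zero-SD references prune nothing

    kept = ts.kept & range_ok & kurt_ok
    report = PruneReport(
        channel=ts.channel.label if ts.channel is not None else "?",
        n_total=int(ts.kept.sum()),
        pruned_range=int((ts.kept & ~range_ok).sum()),
        pruned_kurtosis=int((candidates & ~kurt_ok).sum()),
        kept=int(kept.sum()),
        excluded=bool(kept.sum() < min_epochs),
        range_thresh_uv=range_thresh,
        k_sd=k_sd,
        min_epochs=min_epochs,
    )
    return replace(ts, kept=kept), report
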