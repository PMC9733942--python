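"""Core data containers.

Units and conventions: voltages in microvolts (uV); continuous-time
quantities in seconds; epoched-time axes in milliseconds relative to
stimulation onset; angles in degrees on [-180, 180) with 0 deg = theta peak.

Epochs span the half-open window [-750, 500) ms (1250 samples at 1 kHz,
sample index 750 is latency 0 ms) and are baseline-corrected to the mean of
[-750, -2] ms.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

REGIONS = ("hippocampus", "amygdala", "orbitofrontal", "lateral_temporal", "other")
HEMISPHERES = ("L", "R")

EPOCH_START_MS = -750
EPOCH_END_MS = 500  # exclusive: last sample is +499 ms at 1 kHz
BASELINE_MS = (-750, -2)  # inclusive
TARGET_FS = 1000.0


def epoch_time_ms() -> np.ndarray:
    """The canonical epoch time axis at 1 kHz: -750 .. 499 ms."""
    return np.arange(EPOCH_START_MS, EPOCH_END_MS, dtype=float)


@dataclass
class ChannelInfo:
    """Metadata for one recording contact."""

    label: str
    subject: str = "s0"
    region: str = "hippocampus"
    hemisphere: str = "L"

    def __post_init__(self):
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}; expected one of {REGIONS}")
        if self.hemisphere not in HEMISPHERES:
            raise ValueError(f"hemisphere must be 'L' or 'R', got {self.hemisphere!r}")


@dataclass
class RawRecording:
    """Continuous multichannel LFP with stimulation events.

    Attributes
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in uV.
    fs : float
        Sampling rate in Hz.
    channels : list of ChannelInfo
    events : ndarray
        Stimulation onset times in seconds.
    rest_segments : list of (start_s, end_s)
        Stimulation-free spans usable for spectra, sham trials, and
        connectivity.
    """

    samples: np.ndarray
    fs: float
    channels: Sequence[ChannelInfo]
    events: np.ndarray = field(default_factory=lambda: np.empty(0))
    rest_segments: list = field(default_factory=list)

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.events = np.asarray(self.events, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel entries for "
                f"{self.samples.shape[0]} sample rows"
            )
        if self.events.size and (
            self.events.min() < 0 or self.events.max() >= self.duration_s
        ):
            raise ValueError("event times must lie within the recording")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def duration_s(self) -> float:
        return self.samples.shape[1] / self.fs

    def channel_index(self, label: str) -> int:
        for i, ch in enumerate(self.channels):
            if ch.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")

    def copy(self) -> "RawRecording":
        return RawRecording(
            samples=self.samples.copy(),
            fs=self.fs,
            channels=list(self.channels),
            events=self.events.copy(),
            rest_segments=list(self.rest_segments),
        )


@dataclass
class TrialSet:
    """Epoched, baseline-corrected trials for one channel.

    ``kept`` is a boolean pruning mask over trials; rows are retained so
    that trial indices stay aligned with events.  ``onset_phase_deg`` holds
    the estimated theta phase at stimulation onset once computed.
    """

    trials: np.ndarray
    time_ms: np.ndarray
    channel: Optional[ChannelInfo] = None
    kept: Optional[np.ndarray] = None
    onset_phase_deg: Optional[np.ndarray] = None
    onset_samples: Optional[np.ndarray] = None

    def __post_init__(self):
        self.trials = np.atleast_2d(np.asarray(self.trials, dtype=float))
        self.time_ms = np.asarray(self.time_ms, dtype=float)
        if self.trials.shape[1] != self.time_ms.size:
            raise ValueError("trials and time_ms disagree on sample count")
        if self.kept is None:
            self.kept = np.ones(self.trials.shape[0], dtype=bool)
        else:
            self.kept = np.asarray(self.kept, dtype=bool)
        if self.onset_phase_deg is not None:
            self.onset_phase_deg = np.asarray(self.onset_phase_deg, dtype=float)

    @property
    def n_trials(self) -> int:
        return self.trials.shape[0]

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())

    def kept_trials(self) -> np.ndarray:
        return self.trials[self.kept]

    def kept_phases(self) -> np.ndarray:
        if self.onset_phase_deg is None:
            raise ValueError("onset phases have not been estimated for this TrialSet")
        return self.onset_phase_deg[self.kept]

    def with_phases(self, phases_deg) -> "TrialSet":
        phases = np.asarray(phases_deg, dtype=float)
        if phases.size != self.n_trials:
            raise ValueError("one phase per trial is required")
        return replace(self, onset_phase_deg=phases)

    def onset_index(self) -> int:
        """Sample index of latency 0 ms."""
        idx = np.flatnonzero(self.time_ms == 0.0)
        if idx.size != 1:
            raise ValueError("epoch time axis has no unique 0 ms sample")
        return int(idx[0])


@dataclass
class PruneReport:
    """Outcome of artifact pruning for one channel."""

    channel: str
    n_total: int
    pruned_range: int
    pruned_kurtosis: int
    kept: int
    excluded: bool
    range_thresh_uv: float
    k_sd: float
    min_epochs: int

    def to_row(self) -> dict:
        return {
            "channel": self.channel,
            "n_total": self.n_total,
            "pruned_range": self.pruned_range,
            "pruned_kurtosis": self.pruned_kurtosis,
            "kept": self.kept,
            "excluded": self.excluded,
        }
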