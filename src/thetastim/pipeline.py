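"""End-to-end per-channel analysis: raw session in, phase-dependence
statistics out.

Chains the module operations in the order the analysis prescribes: epoch ->
prune -> onset-phase estimation -> phase-balanced EP -> component windows ->
per-trial component amplitudes -> circular-linear permutation z -> sham
sampling, phase matching, and response isolation -> binned component
amplitudes (raw and isolated).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .binned import isolate_response, sample_matched_sham
from .circular import BIN_LABELS, as_rng
from .evoked import (
    ComponentWindow,
    component_amplitude,
    component_amplitudes,
    detect_components,
    phase_balanced_ep,
)
from .phase import estimate_onset_phase, sample_stimulation_free_trials
from .phase_amplitude import CircLinResult, perm_zscore
from .preprocess import epoch_channel, prune_trials
from .synthetic import rest_segment_samples
from .types import PruneReport, RawRecording, TrialSet


@dataclass
class ChannelAnalysis:
    trials: TrialSet
    prune_report: Optional[PruneReport]
    windows: list[ComponentWindow]
    amplitudes: dict  # component -> per-trial amplitudes (kept trials)
    circlin: dict  # component -> CircLinResult
    matched_sham: Optional[TrialSet]
    isolated: Optional[dict]  # bin label -> IsolatedResponse
    ep_bin_amps: Optional[dict]  # component -> {bin: mean amplitude of binned EP}
    iso_bin_amps: Optional[dict]  # component -> {bin: mean amplitude of isolated trace}


def stim_trialset(rec: RawRecording, channel: int = 0, prune: bool = True
                  ) -> tuple[TrialSet, Optional[PruneReport]]:
    """Epoch, prune, and phase-estimate the stimulation trials of a channel."""
    ts = epoch_channel(rec, channel)
    report = None
    if prune:
        ts, report = prune_trials(ts)
    return ts.with_phases(estimate_onset_phase(ts, fs=rec.fs)), report


def sham_trialset(rec: RawRecording, channel: int = 0, spacing_ms: float = 100.0) -> TrialSet:
    """Stimulation-free trials pooled over all rest segments, with phases.

    Each segment is sampled at ``spacing_ms`` intervals and pruned against
    its own trial class; the surviving trials are pooled.
    """
    if not rec.rest_segments:
        raise ValueError("recording has no rest segments")
    parts = []
    time_ms = None
    for which in range(len(rec.rest_segments)):
        seg = rest_segment_samples(rec, channel, which)
        ts = sample_stimulation_free_trials(
            seg, rec.fs, spacing_ms, channel=rec.channels[channel]
        )
        time_ms = ts.time_ms
        parts.append(ts.kept_trials())
    pooled = TrialSet(
        trials=np.vstack(parts), time_ms=time_ms, channel=rec.channels[channel]
    )
    return pooled.with_phases(estimate_onset_phase(pooled, fs=rec.fs))


def analyze_channel(
    rec: RawRecording,
    channel: int = 0,
    windows: Optional[list[ComponentWindow]] = None,
    n_perm: int = 500,
    seed=None,
    with_sham: bool = True,
    prune: bool = True,
) -> ChannelAnalysis:
    """Full phase-dependence analysis of one channel.

    ``windows`` may be supplied to apply group-level component windows
    (detected on a grand average across electrodes); otherwise they are
    detected on this channel's own phase-balanced EP.
    """
    rng = as_rng(seed)
    ts, report = stim_trialset(rec, channel, prune=prune)
    bep = phase_balanced_ep(ts)
    if windows is None:
        windows = detect_components(bep)
    amps = component_amplitudes(ts, windows)
    circlin = {
        w.label: perm_zscore(ts.kept_phases(), amps[w.label], n_perm=n_perm, seed=rng)
        for w in windows
    }

    matched = isolated = ep_bin = iso_bin = None
    if with_sham:
        sham = sham_trialset(rec, channel)
        matched = sample_matched_sham(ts.kept_phases(), sham, seed=rng)
        isolated = isolate_response(ts, matched)
        ep_bin = {
            w.label: {lab: component_amplitude(isolated[lab].ep, ts.time_ms, w)
                      for lab in BIN_LABELS}
            for w in windows
        }
        iso_bin = {
            w.label: {lab: component_amplitude(isolated[lab].isolated, ts.time_ms, w)
                      for lab in BIN_LABELS}
            for w in windows
        }
    return ChannelAnalysis(
        trials=ts, prune_report=report, windows=windows, amplitudes=amps,
        circlin=circlin, matched_sham=matched, isolated=isolated,
        ep_bin_amps=ep_bin, iso_bin_amps=iso_bin,
    )
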