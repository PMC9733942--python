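"""Binned phase contrasts, phase-matched sham resampling, and isolation of
the evoked response from the ongoing oscillation.

Because phase at onset predicts future amplitude by definition, peak- vs
trough-binned EPs differ even without any stimulation effect.  The
non-evoked component is estimated from stimulation-free ("sham") trials
resampled so their onset-phase distribution matches the stimulation trials
(weighted resampling on an 18 x 20-degree histogram), and subtracted from
the binned EP.  Good isolation abolishes pre-stimulus (-100..0 ms)
peak-vs-trough differences; that abolishment is reported as a quality
metric, never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .circular import BIN_LABELS, as_rng, assign_phase_bins, wrap_deg
from .phase_amplitude import electrode_t_test
from .types import TrialSet

SHAM_BIN_WIDTH_DEG = 20.0


@dataclass
class IsolatedResponse:
    """Per-bin EP, matched-sham mean, and their difference.

    Invariant: ``isolated + sham_mean == ep`` per timepoint.
    """

    label: str
    time_ms: np.ndarray
    ep: np.ndarray
    sham_mean: np.ndarray
    isolated: np.ndarray
    n_stim: int
    n_sham: int


def _phase_hist(phases_deg, width: float = SHAM_BIN_WIDTH_DEG) -> np.ndarray:
    idx = np.floor((wrap_deg(phases_deg) + 180.0) / width).astype(int)
    n_bins = int(round(360.0 / width))
    idx = np.clip(idx, 0, n_bins - 1)
    return np.bincount(idx, minlength=n_bins), idx


def sample_matched_sham(
    stim_phases_deg, sham: TrialSet, seed=None, bin_width_deg: float = SHAM_BIN_WIDTH_DEG
) -> TrialSet:
    """Resample sham trials to match the stimulation onset-phase distribution.

    Each sham trial is weighted by (stimulation count in its 20-degree phase
    bin) / (sham count in that bin) and drawn with replacement, n = number
    of stimulation trials.  Waveforms are untouched — this is pure
    resampling.  Raises, naming the gaps, if any occupied stimulation bin
    has no sham trial.
    """
    rng = as_rng(seed)
    sham_phases = sham.kept_phases()
    sham_trials = sham.kept_trials()
    if sham_trials.shape[0] == 0:
        raise ValueError("sham TrialSet has no kept trials")
    stim_counts, _ = _phase_hist(stim_phases_deg, bin_width_deg)
    sham_counts, sham_idx = _phase_hist(sham_phases, bin_width_deg)
    gaps = np.flatnonzero((stim_counts > 0) & (sham_counts == 0))
    if gaps.size:
        arcs = [f"[{-180 + g * bin_width_deg:g}, {-180 + (g + 1) * bin_width_deg:g})"
                for g in gaps]
        raise ValueError("no sham trials in occupied stimulation phase bin(s): "
                         + ", ".join(arcs))
    with np.errstate(divide="ignore", invalid="ignore"):
        bin_w = np.where(sham_counts > 0, stim_counts / np.maximum(sham_counts, 1), 0.0)
    w = bin_w[sham_idx]
    w = w / w.sum()
    n_stim = int(np.asarray(stim_phases_deg).size)
    pick = rng.choice(sham_trials.shape[0], size=n_stim, replace=True, p=w)
    return TrialSet(
        trials=sham_trials[pick],
        time_ms=sham.time_ms.copy(),
        channel=sham.channel,
        onset_phase_deg=sham_phases[pick],
    )


def _bin_mean_traces(ts: TrialSet) -> dict:
    labels = assign_phase_bins(ts.kept_phases())
    trials = ts.kept_trials()
    out = {}
    for lab in BIN_LABELS:
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"empty phase bin {lab!r}")
        out[lab] = (trials[sel].mean(axis=0), int(sel.sum()))
    return out


def isolate_response(stim: TrialSet, sham_matched: TrialSet) -> dict:
    """Per-bin isolated responses: binned EP minus binned matched-sham mean.

    Both trial sets must carry onset phases; bins use the same quarter-circle
    rule.  Returns {bin label: IsolatedResponse}.
    """
    stim_bins = _bin_mean_traces(stim)
    sham_bins = _bin_mean_traces(sham_matched)
    out = {}
    for lab in BIN_LABELS:
        ep, n_stim = stim_bins[lab]
        sham_mean, n_sham = sham_bins[lab]
        out[lab] = IsolatedResponse(
            label=lab, time_ms=stim.time_ms.copy(), ep=ep, sham_mean=sham_mean,
            isolated=ep - sham_mean, n_stim=n_stim, n_sham=n_sham,
        )
    return out


def prestim_contrast(
    iso_by_electrode: list[dict], window_ms: tuple[float, float] = (-100.0, 0.0)
) -> dict:
    """Abolishment check: paired t across electrodes of pre-stimulus mean
    isolated amplitude, peak vs trough and falling vs rising.

    Small |t| / large p indicates the ongoing oscillation was removed.
    """
    results = {}
    for a, b in (("peak", "trough"), ("falling", "rising")):
        va, vb = [], []
        for iso in iso_by_electrode:
            t = iso[a].time_ms
            mask = (t >= window_ms[0]) & (t <= window_ms[1])
            va.append(iso[a].isolated[mask].mean())
            vb.append(iso[b].isolated[mask].mean())
        results[f"{a}_vs_{b}"] = electrode_t_test(va, paired_partner=vb)
    return results


def compare_bin_components(amps: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of per-electrode component amplitudes across opposite
    phase bins (peak - trough and falling - rising).

    ``amps`` needs columns electrode, component, bin, amplitude with one row
    per (electrode, component, bin).  Returns one row per (component,
    contrast) with t, df, p, Cohen's d, and mean +/- SD of the differences.
    """
    required = {"electrode", "component", "bin", "amplitude"}
    if not required.issubset(amps.columns):
        raise ValueError(f"amps must have columns {sorted(required)}")
    rows = []
    for component, grp in amps.groupby("component"):
        wide = grp.pivot(index="electrode", columns="bin", values="amplitude")
        for a, b in (("peak", "trough"), ("falling", "rising")):
            pair = wide[[a, b]].dropna()
            if len(pair) < 2:
                raise ValueError(
                    f"component {component!r}: fewer than 2 electrodes with both "
                    f"{a!r} and {b!r} bins"
                )
            res = electrode_t_test(pair[a].to_numpy(), paired_partner=pair[b].to_numpy())
            diffs = pair[a].to_numpy() - pair[b].to_numpy()
            rows.append(
                {
                    "component": component,
                    "contrast": f"{a}-{b}",
                    "n_electrodes": len(pair),
                    "mean_diff": float(diffs.mean()),
                    "sd_diff": float(diffs.std(ddof=1)),
                    **{k: res[k] for k in ("t", "df", "p", "cohens_d")},
                }
            )
    return pd.DataFrame(rows)


def peak_trough_timecourse_diff(stim: TrialSet, sham_matched: TrialSet) -> dict:
    """Per-timepoint peak-minus-trough difference traces for stimulation and
    matched stimulation-free trials of one electrode."""
    stim_bins = _bin_mean_traces(stim)
    sham_bins = _bin_mean_traces(sham_matched)
    return {
        "time_ms": stim.time_ms.copy(),
        "stim_diff": stim_bins["peak"][0] - stim_bins["trough"][0],
        "sham_diff": sham_bins["peak"][0] - sham_bins["trough"][0],
    }


def group_mean_sem(traces: list[np.ndarray]) -> dict:
    """Mean +/- SEM across per-electrode traces."""
    arr = np.stack(traces)
    return {
        "mean": arr.mean(axis=0),
        "sem": arr.std(axis=0, ddof=1) / np.sqrt(arr.shape[0]) if arr.shape[0] > 1
        else np.zeros(arr.shape[1]),
        "n": arr.shape[0],
    }
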