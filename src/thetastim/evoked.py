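"""Phase-balanced evoked potentials and negative-component quantification.

The EP of interest has two negative components (early ~27-113 ms, late
~114-208 ms in hippocampus).  Component windows are detected once on a
grand-average phase-balanced EP: the first two negative local minima in
the +20..+500 ms search window (>= 50 ms apart, keeping the deeper of any
closer pair), with edges at the nearest inflection points within 150 ms of
each peak.  Per-trial component amplitude is the mean signal over the
window — deliberately not the peak, for single-trial noise robustness.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import BIN_LABELS, assign_phase_bins
from .types import TrialSet


@dataclass
class EvokedPotential:
    time_ms: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n_trials: int
    phase_balanced: bool = False


@dataclass
class ComponentWindow:
    """A named negative EP component: [start, end] ms around a peak latency."""

    label: str
    peak_ms: float
    start_ms: float
    end_ms: float

    def __post_init__(self):
        if not (20.0 <= self.peak_ms <= 500.0):
            raise ValueError(f"component peak {self.peak_ms} ms outside [20, 500] ms")
        if not (self.start_ms < self.peak_ms < self.end_ms):
            raise ValueError("component window must bracket its peak")
        if self.peak_ms - self.start_ms > 150.0 + 1e-9 or self.end_ms - self.peak_ms > 150.0 + 1e-9:
            raise ValueError("component edges must lie within 150 ms of the peak")


def plain_ep(ts: TrialSet) -> EvokedPotential:
    """Simple mean +/- SEM over kept trials."""
    trials = ts.kept_trials()
    if trials.shape[0] == 0:
        raise ValueError("no kept trials")
    return EvokedPotential(
        time_ms=ts.time_ms.copy(),
        mean=trials.mean(axis=0),
        sem=trials.std(axis=0, ddof=1) / np.sqrt(trials.shape[0]),
        n_trials=trials.shape[0],
        phase_balanced=False,
    )


def phase_balanced_ep(ts: TrialSet) -> EvokedPotential:
    """Mean of the four 90-degree phase-bin mean traces.

    Equalizes the contribution of peak/falling/trough/rising onsets so a
    non-uniform stimulation-phase distribution cannot bias the average EP.
    SEM is across the four bin means.  Raises if any bin is empty.
    """
    phases = ts.kept_phases()
    labels = assign_phase_bins(phases)
    counts = {lab: int((labels == lab).sum()) for lab in BIN_LABELS}
    if min(counts.values()) == 0:
        raise ValueError(f"empty phase bin(s): occupancies {counts}")
    trials = ts.kept_trials()
    bin_means = np.stack([trials[labels == lab].mean(axis=0) for lab in BIN_LABELS])
    return EvokedPotential(
        time_ms=ts.time_ms.copy(),
        mean=bin_means.mean(axis=0),
        sem=bin_means.std(axis=0, ddof=1) / 2.0,
        n_trials=trials.shape[0],
        phase_balanced=True,
    )


def grand_average(eps: list[EvokedPotential]) -> EvokedPotential:
    """Unweighted average of per-electrode EPs (the group-level trace on
    which component windows are detected)."""
    means = np.stack([ep.mean for ep in eps])
    return EvokedPotential(
        time_ms=eps[0].time_ms.copy(),
        mean=means.mean(axis=0),
        sem=means.std(axis=0, ddof=1) / np.sqrt(len(eps)) if len(eps) > 1 else np.zeros_like(means[0]),
        n_trials=sum(ep.n_trials for ep in eps),
        phase_balanced=all(ep.phase_balanced for ep in eps),
    )


def merge_close_extrema(times: np.ndarray, values: np.ndarray, min_separation: float,
                        deeper_is_smaller: bool = True) -> list[tuple[float, float]]:
    """Greedy left-to-right merge of candidate extrema closer than
    ``min_separation``: within a close pair the deeper one survives."""
    merged: list[tuple[float, float]] = []
    for t, v in zip(times, values):
        if merged and t - merged[-1][0] < min_separation:
            if (v < merged[-1][1]) == deeper_is_smaller:
                merged[-1] = (t, v)
        else:
            merged.append((t, v))
    return merged


def _inflection_times(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Latencies where the second difference changes sign (curvature zero
    crossings), each reported midway between the bracketing samples.

    Curvature below 1e-9 of the trace's maximum curvature is treated as
    zero so that exactly-straight stretches do not produce rounding-noise
    crossings.
    """
    d2 = np.diff(y, 2)  # d2[k] ~ y''(t[k+1])
    tol = 1e-9 * np.max(np.abs(d2)) if d2.size else 0.0
    sign = np.sign(np.where(np.abs(d2) <= tol, 0.0, d2))
    crossings = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    return (t[crossings + 1] + t[crossings + 2]) / 2.0


def detect_components(
    ep: EvokedPotential,
    search_ms: tuple[float, float] = (20.0, 500.0),
    min_separation_ms: float = 50.0,
    edge_halfwidth_ms: float = 150.0,
    labels: tuple[str, str] = ("early", "late"),
) -> list[ComponentWindow]:
    """Find the first two negative components of an evoked potential.

    Peaks are negative-valued local minima in the search window; candidates
    closer than ``min_separation_ms`` are merged keeping the deeper one.
    Edges are the nearest inflection points within ``edge_halfwidth_ms`` of
    each peak (clamped to peak +/- 150 ms when no inflection exists), and
    overlapping windows are split at the midpoint of the overlap.  Raises
    with a diagnostic when fewer than two qualifying minima exist.

    Inflections are computed on the raw trace; a 5 ms moving average is
    applied first only if the trace is so noisy that more than 10
    inflections fall within 150 ms of a peak.
    """
    t, y = ep.time_ms, ep.mean
    dt = t[1] - t[0]
    # the half-open epoch ends one sample short of +500 ms; allow that slack
    if t[0] > search_ms[0] or t[-1] < search_ms[1] - dt:
        raise ValueError("EP does not cover the component search window")
    search_ms = (search_ms[0], min(search_ms[1], float(t[-1])))
    interior = np.arange(1, t.size - 1)
    is_min = (y[interior] < y[interior - 1]) & (y[interior] < y[interior + 1])
    in_window = (t[interior] >= search_ms[0]) & (t[interior] <= search_ms[1])
    cand = interior[is_min & in_window & (y[interior] < 0)]
    merged = merge_close_extrema(t[cand], y[cand], min_separation_ms)
    if len(merged) < 2:
        raise ValueError(
            f"found {len(merged)} qualifying negative minima in "
            f"[{search_ms[0]:g}, {search_ms[1]:g}] ms (need 2); candidate latencies: "
            f"{[round(m[0], 1) for m in merged]}"
        )
    peaks = [m[0] for m in merged[:2]]

    infl = _inflection_times(y, t)
    # noise guard: a trace smooth at the scale of its components has only a
    # handful of curvature zero crossings near each peak; escalate moving-
    # average smoothing until that holds (raw traces are used when clean)
    for width_ms in (5.0, 11.0, 21.0):
        if all(np.sum(np.abs(infl - pk) <= edge_halfwidth_ms) <= 10 for pk in peaks):
            break
        k = int(round(width_ms / dt)) | 1
        ys = np.convolve(y, np.ones(k) / k, mode="same")
        infl = _inflection_times(ys, t)

    windows = []
    for label, pk in zip(labels, peaks):
        before = infl[(infl < pk) & (infl >= pk - edge_halfwidth_ms)]
        after = infl[(infl > pk) & (infl <= pk + edge_halfwidth_ms)]
        start = before.max() if before.size else pk - edge_halfwidth_ms
        end = after.min() if after.size else pk + edge_halfwidth_ms
        windows.append(ComponentWindow(label=label, peak_ms=pk, start_ms=start, end_ms=end))

    w1, w2 = windows
    if w1.end_ms > w2.start_ms:  # split the overlap at its midpoint
        mid = (w1.end_ms + w2.start_ms) / 2.0
        mid = min(max(mid, w1.peak_ms + dt), w2.peak_ms - dt)
        w1.end_ms = mid
        w2.start_ms = mid
    return windows


def component_amplitude(trials, time_ms: np.ndarray, window: ComponentWindow):
    """Mean amplitude over the component window (inclusive of both edges).

    ``trials`` may be a single trace or an (n_trials, n_samples) matrix;
    returns a scalar or a per-trial vector accordingly.
    """
    time_ms = np.asarray(time_ms, dtype=float)
    if window.start_ms < time_ms[0] or window.end_ms > time_ms[-1]:
        raise ValueError("component window extends beyond the trial time axis")
    mask = (time_ms >= window.start_ms) & (time_ms <= window.end_ms)
    out = np.asarray(trials, dtype=float)[..., mask].mean(axis=-1)
    return float(out) if out.ndim == 0 else out


def component_amplitudes(ts: TrialSet, windows: list[ComponentWindow]) -> dict:
    """Per-trial mean amplitudes for each window, over kept trials."""
    trials = ts.kept_trials()
    return {w.label: component_amplitude(trials, ts.time_ms, w) for w in windows}
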