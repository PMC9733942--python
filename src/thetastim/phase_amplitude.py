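"""Circular-linear phase-amplitude statistics with permutation nulls.

The circular-linear correlation between onset phase phi and a linear
amplitude x uses the three-Pearson-term closed form

    r = sqrt( (rxc^2 + rxs^2 - 2 rxc rxs rcs) / (1 - rcs^2) )

with rxc = corr(x, cos phi), rxs = corr(x, sin phi), rcs = corr(cos phi,
sin phi).  Significance is a permutation z-score: amplitudes are repeatedly
re-paired with the fixed phase vector and z = (r_obs - mean r_perm) /
sd(r_perm).  Aggregation across electrodes is on z (not p), matching how
single-electrode results feed the group t-test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import stats as spstats

from .circular import BIN_CENTERS_DEG, as_rng, wrap_deg
from .evoked import merge_close_extrema
from .types import TrialSet


@dataclass
class CircLinResult:
    r: float
    z: float
    n_perm: int
    n_trials: int
    perm_mean: float
    perm_sd: float


@dataclass
class CircLinTimecourse:
    time_ms: np.ndarray
    r: np.ndarray  # NaN where the correlation is undefined
    peak_latencies_ms: list


def _prepare_phase(phases_deg) -> tuple[np.ndarray, np.ndarray, float]:
    """Centered unit-norm cos/sin regressors and their correlation rcs."""
    rad = np.deg2rad(np.asarray(phases_deg, dtype=float))
    c = np.cos(rad)
    s = np.sin(rad)
    cc = c - c.mean()
    ss = s - s.mean()
    nc = np.linalg.norm(cc)
    ns = np.linalg.norm(ss)
    if nc == 0 or ns == 0:
        raise ValueError("cos/sin of the phases are constant; correlation undefined")
    cn, sn = cc / nc, ss / ns
    rcs = float(cn @ sn)
    if abs(rcs) >= 1.0 - 1e-12:
        raise ValueError("cos and sin of the phases are collinear; correlation undefined")
    return cn, sn, rcs


def _r_rows(X: np.ndarray, cn: np.ndarray, sn: np.ndarray, rcs: float) -> np.ndarray:
    """Circular-linear r for each row of amplitude matrix X (may yield NaN
    for zero-variance rows)."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rxc = (Xc @ cn) / norms
        rxs = (Xc @ sn) / norms
        num = rxc**2 + rxs**2 - 2.0 * rxc * rxs * rcs
        r2 = num / (1.0 - rcs**2)
    return np.sqrt(np.clip(r2, 0.0, None))


def circ_lin_corr(phases_deg, amplitudes) -> float:
    """Circular-linear correlation coefficient, in [0, 1].

    Requires n >= 4 pairs, non-constant amplitudes, and non-collinear
    cos/sin regressors.
    """
    x = np.asarray(amplitudes, dtype=float)
    phases = np.asarray(phases_deg, dtype=float)
    if x.size != phases.size:
        raise ValueError("phases and amplitudes must have equal length")
    if x.size < 4:
        raise ValueError("need at least 4 phase/amplitude pairs")
    if np.std(x) == 0:
        raise ValueError("amplitudes have zero variance; correlation undefined")
    cn, sn, rcs = _prepare_phase(phases)
    return float(_r_rows(x[None, :], cn, sn, rcs)[0])


def perm_zscore(phases_deg, amplitudes, n_perm: int = 500, seed=None) -> CircLinResult:
    """Permutation z-score of the circular-linear correlation.

    The amplitude vector is shuffled against the fixed phase vector
    ``n_perm`` times (equivalent to random re-pairing); reproducible given
    ``seed`` (int or numpy Generator).
    """
    rng = as_rng(seed)
    x = np.asarray(amplitudes, dtype=float)
    r_obs = circ_lin_corr(phases_deg, x)
    cn, sn, rcs = _prepare_phase(phases_deg)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, x.size)).copy(), axis=1)
    r_perm = _r_rows(perms, cn, sn, rcs)
    mu = float(r_perm.mean())
    sd = float(r_perm.std(ddof=1))
    if sd == 0.0:
        raise ValueError("permutation distribution has zero spread; z undefined")
    return CircLinResult(
        r=r_obs, z=(r_obs - mu) / sd, n_perm=n_perm, n_trials=x.size,
        perm_mean=mu, perm_sd=sd,
    )


def find_timecourse_peaks(
    r: np.ndarray,
    time_ms: np.ndarray,
    search_ms: tuple[float, float] = (20.0, 500.0),
    min_separation_ms: float = 50.0,
    min_prominence: Optional[float] = None,
) -> list[float]:
    """First two local maxima of r(t) in the search window.

    Same local-extremum/50 ms-separation scan as EP component detection but
    for maxima and without a sign requirement.  ``min_prominence`` guards
    against the sample-level noise wiggles every finite-trial r(t) carries:
    candidates below it are ignored.  Returns up to two latencies (possibly
    none) — a smooth post-onset decay yields an empty list.
    """
    valid = np.isfinite(r)
    interior = np.arange(1, r.size - 1)
    ok = valid[interior] & valid[interior - 1] & valid[interior + 1]
    is_max = np.zeros(interior.size, dtype=bool)
    is_max[ok] = (r[interior[ok]] > r[interior[ok] - 1]) & (r[interior[ok]] > r[interior[ok] + 1])
    in_window = (time_ms[interior] >= search_ms[0]) & (time_ms[interior] <= search_ms[1])
    cand = interior[is_max & in_window]
    if min_prominence is not None and cand.size:
        # prominence relative to the higher of the two flanking bases
        prom = np.empty(cand.size)
        for i, c in enumerate(cand):
            base_l = _flank_min(r, valid, c, -1)
            base_r = _flank_min(r, valid, c, +1)
            prom[i] = r[c] - max(base_l, base_r)
        cand = cand[prom >= min_prominence]
    merged = merge_close_extrema(
        time_ms[cand], r[cand], min_separation_ms, deeper_is_smaller=False
    )
    return [t for t, _ in merged[:2]]


def _flank_min(r: np.ndarray, valid: np.ndarray, c: int, direction: int) -> float:
    """Minimum of r from c outward until a sample exceeding r[c] (or the
    series end); the prominence base on that side."""
    base = r[c]
    i = c + direction
    while 0 <= i < r.size and valid[i]:
        if r[i] > r[c]:
            break
        base = min(base, r[i])
        i += direction
    return base


def phase_amplitude_timecourse(
    ts: TrialSet, search_ms: tuple[float, float] = (20.0, 500.0)
) -> CircLinTimecourse:
    """Circular-linear r between onset phase and signal amplitude at every
    epoch timepoint, with post-onset peak latencies.

    Timepoints where the correlation is undefined (e.g. zero amplitude
    variance) are recorded as NaN and skipped by the peak scan.
    """
    phases = ts.kept_phases()
    trials = ts.kept_trials()
    if trials.shape[0] < 4:
        raise ValueError("timecourse needs at least 4 kept trials")
    cn, sn, rcs = _prepare_phase(phases)
    r = _r_rows(trials.T, cn, sn, rcs)
    peaks = find_timecourse_peaks(
        r, ts.time_ms, search_ms,
        min_prominence=1.0 / np.sqrt(trials.shape[0]),
    )
    return CircLinTimecourse(time_ms=ts.time_ms.copy(), r=r, peak_latencies_ms=peaks)


def electrode_t_test(values, mu: float = 0.0, paired_partner=None) -> dict:
    """One-sample (vs ``mu``) or paired two-sided t-test with Cohen's d.

    Zero-variance convention as in :func:`thetastim.spectral.group_peak_test`.
    """
    x = np.asarray(values, dtype=float)
    if paired_partner is not None:
        y = np.asarray(paired_partner, dtype=float)
        if y.shape != x.shape:
            raise ValueError("paired samples must have equal length")
        x = x - y
        mu = 0.0
    n = x.size
    if n < 2:
        raise ValueError("t-test needs at least 2 values")
    d = x - mu
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
        cohens = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2.0 * spstats.t.sf(abs(t), df=n - 1))
        cohens = mean / sd
    return {"t": float(t), "df": n - 1, "p": p, "cohens_d": float(cohens),
            "mean": mean, "sd": sd}


def preferred_phase_from_bins(bin_means: dict, polarity: str = "negative") -> float:
    """Preferred phase (deg) from the four 90-degree-bin mean amplitudes.

    Solves amplitude(phi) ~ a + b cos phi + c sin phi exactly on the bin
    centers.  For negative-going components the preferred phase is where the
    response is most negative (largest magnitude); ``polarity='positive'``
    returns the argmax instead.
    """
    a0 = bin_means["peak"]
    a180 = bin_means["trough"]
    a90 = bin_means["falling"]
    a270 = bin_means["rising"]
    b = (a0 - a180) / 2.0
    c = (a90 - a270) / 2.0
    if polarity == "negative":
        b, c = -b, -c
    elif polarity != "positive":
        raise ValueError("polarity must be 'negative' or 'positive'")
    return float(wrap_deg(np.rad2deg(np.arctan2(c, b))))


def preferred_phase_continuous(phases_deg, amplitudes, polarity: str = "negative") -> float:
    """Preferred phase from a least-squares cosine fit to per-trial data."""
    rad = np.deg2rad(np.asarray(phases_deg, dtype=float))
    x = np.asarray(amplitudes, dtype=float)
    design = np.column_stack([np.ones_like(rad), np.cos(rad), np.sin(rad)])
    _, b, c = np.linalg.lstsq(design, x, rcond=None)[0]
    if polarity == "negative":
        b, c = -b, -c
    return float(wrap_deg(np.rad2deg(np.arctan2(c, b))))
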