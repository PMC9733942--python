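"""Narrowband-oscillation detection above a 1/f background.

Power is estimated on 50 logarithmically spaced frequencies from 1 to
50 Hz, the aperiodic background is a robust (Tukey bisquare) line on
log-log axes, and oscillations are positive local maxima of the
background-corrected spectrum after 4-point boxcar smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import statsmodels.api as sm
from scipy import signal as sps
from scipy import stats as spstats

N_FREQS = 50
FMIN_HZ = 1.0
FMAX_HZ = 50.0


def log_grid(n: int = N_FREQS, fmin: float = FMIN_HZ, fmax: float = FMAX_HZ) -> np.ndarray:
    """Geometric frequency grid used for all spectra."""
    return np.geomspace(fmin, fmax, n)


@dataclass
class PowerSpectrum:
    """Power on the log grid with optional 1/f fit and corrected spectrum.

    ``corrected`` is log10(power) minus the fitted background line; ``peaks``
    is a list of dicts {freq, corrected, smoothed}.
    """

    freqs: np.ndarray
    power: np.ndarray
    log_fit: Optional[dict] = None  # {"slope": ..., "intercept": ...}
    corrected: Optional[np.ndarray] = None
    peaks: Optional[list] = None

    def __post_init__(self):
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have the same shape")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def compute_psd(x, fs: float, min_duration_s: float = 10.0) -> PowerSpectrum:
    """Welch power spectrum interpolated onto the 50-frequency log grid.

    Welch parameters: 2 s Hann segments with 50% overlap — stable on the
    >90 s rest segments this is meant for.  Segments shorter than
    ``min_duration_s`` raise.
    """
    x = np.asarray(x, dtype=float)
    if x.size / fs < min_duration_s:
        raise ValueError(
            f"segment of {x.size / fs:.1f} s is shorter than the "
            f"{min_duration_s:.0f} s minimum for spectral estimation"
        )
    nperseg = int(round(2.0 * fs))
    f, p = sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)
    grid = log_grid()
    power = np.interp(grid, f, p)
    return PowerSpectrum(freqs=grid, power=power)


def fit_background(ps: PowerSpectrum, max_iter: int = 50, tol: float = 1e-8) -> PowerSpectrum:
    """Robust 1/f line fit on log-log axes; fills ``log_fit`` and ``corrected``.

    Iteratively reweighted least squares with Tukey bisquare weights
    (statsmodels RLM).  If ordinary least squares already fits to numerical
    precision (pure power law), its line is used directly — the robust
    iteration cannot improve on a zero-residual fit and its MAD scale
    estimate degenerates there.
    """
    if np.any(ps.power <= 0):
        raise ValueError("power must be strictly positive to fit a log-log background")
    logf = np.log10(ps.freqs)
    logp = np.log10(ps.power)
    X = sm.add_constant(logf)
    ols = sm.OLS(logp, X).fit()
    if np.max(np.abs(ols.resid)) < 1e-10:
        intercept, slope = ols.params
    else:
        with warnings.catch_warnings():
            # a (near-)perfect robust fit triggers a zero-scale warning
            warnings.simplefilter("ignore")
            rlm = sm.RLM(logp, X, M=sm.robust.norms.TukeyBiweight()).fit(
                maxiter=max_iter, tol=tol
            )
        intercept, slope = rlm.params
    corrected = logp - (intercept + slope * logf)
    return replace(
        ps,
        log_fit={"slope": float(slope), "intercept": float(intercept)},
        corrected=corrected,
    )


def boxcar_smooth(y: np.ndarray, width: int = 4) -> np.ndarray:
    """Centered even-length moving average with edge truncation.

    An even-width boxcar has no central sample; the standard centered form
    (a "2 x width" moving average) spans width + 1 samples with half weight
    on the two extremes, which keeps symmetric bumps symmetric.  At the
    edges the window shrinks to the available samples and the weights are
    renormalized.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    half = width // 2
    w = np.ones(width + 1)
    w[0] = w[-1] = 0.5
    out = np.empty(n)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        ww = w[lo - (i - half): hi - (i - half)]
        out[i] = float(y[lo:hi] @ ww / ww.sum())
    return out


def detect_narrowband_peaks(ps: PowerSpectrum, min_height: float = 1e-8) -> PowerSpectrum:
    """Positive interior local maxima of the smoothed corrected spectrum.

    The corrected spectrum is smoothed with a 4-point boxcar to suppress
    noisy single-bin peaks; a peak is an interior grid point strictly above
    both neighbours with smoothed value above ``min_height``.  The first and
    last grid points can never be peaks.  ``min_height`` is a numerical
    guard: a perfectly fit background leaves +/-1e-16 rounding noise whose
    sign is meaningless (genuine oscillatory bumps are ~0.1 log10 units).
    """
    if ps.corrected is None:
        raise ValueError("run fit_background before peak detection")
    smoothed = boxcar_smooth(ps.corrected, 4)
    peaks = []
    for i in range(1, smoothed.size - 1):
        if smoothed[i] > smoothed[i - 1] and smoothed[i] > smoothed[i + 1] and smoothed[i] > min_height:
            peaks.append(
                {
                    "freq": float(ps.freqs[i]),
                    "corrected": float(ps.corrected[i]),
                    "smoothed": float(smoothed[i]),
                }
            )
    return replace(ps, peaks=peaks)


def group_peak_test(corrected_at_freq) -> dict:
    """One-sample two-sided t-test of per-electrode corrected power vs 0.

    Zero-variance convention (documented): if the sample SD is 0 the test is
    degenerate; p = 0 when the common value differs from 0, else t = 0 and
    p = 1.
    """
    values = np.asarray(corrected_at_freq, dtype=float)
    n = values.size
    if n < 2:
        raise ValueError("group peak test needs at least 2 electrodes")
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    if sd == 0.0:
        t = 0.0 if mean == 0.0 else float(np.inf) * np.sign(mean)
        p = 1.0 if mean == 0.0 else 0.0
    else:
        t = mean / (sd / np.sqrt(n))
        p = float(2.0 * spstats.t.sf(abs(t), df=n - 1))
    return {"t": float(t), "df": n - 1, "p": p, "mean": mean, "sd": sd}
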