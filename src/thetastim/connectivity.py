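"""Theta phase locking between the stimulation site and a target channel.

The phase-locking value (PLV) is the resultant length of the between-
channel phase-difference distribution; the mean offset is its circular
mean.  Chance levels are assessed by breaking the continuous phase series
into 500 ms epochs and permuting the pairing of epochs between channels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import as_rng, rayleigh_test, wrap_deg  # noqa: F401  (rayleigh re-exported)


@dataclass
class PLVResult:
    plv: float
    mean_offset_deg: float
    z: float
    n_epochs: int
    n_perm: int
    perm_mean: float
    perm_sd: float


def plv_offset(phase_a_deg, phase_b_deg, min_samples: int = 100) -> dict:
    """PLV and mean phase offset between two phase series (degrees).

    delta = wrap(a - b); plv = |mean unit vector at delta|; offset = its
    argument.  Series must be equally long and at least ``min_samples``.
    """
    a = np.asarray(phase_a_deg, dtype=float)
    b = np.asarray(phase_b_deg, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"phase series lengths differ: {a.shape} vs {b.shape}")
    if a.size < min_samples:
        raise ValueError(f"need at least {min_samples} samples, got {a.size}")
    m = np.exp(1j * np.deg2rad(a - b)).mean()
    return {"plv": float(np.abs(m)), "mean_offset_deg": float(wrap_deg(np.rad2deg(np.angle(m))))}


def _epoch_matrix(x: np.ndarray, epoch_len: int) -> np.ndarray:
    n_ep = x.size // epoch_len
    return x[: n_ep * epoch_len].reshape(n_ep, epoch_len)


def plv_perm_z(
    phase_a_deg,
    phase_b_deg,
    fs: float = 1000.0,
    epoch_len_ms: float = 500.0,
    n_perm: int = 500,
    seed=None,
) -> PLVResult:
    """Permutation z-score of epoch-mean PLV between two channels.

    The observed statistic is the mean over consecutive non-overlapping
    ``epoch_len_ms`` epochs of the per-epoch PLV; the null re-pairs channel
    B's epochs with channel A's at random (n_perm draws).
    """
    a = np.asarray(phase_a_deg, dtype=float)
    b = np.asarray(phase_b_deg, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    epoch_len = int(round(epoch_len_ms * fs / 1000.0))
    ea = _epoch_matrix(a, epoch_len)
    eb = _epoch_matrix(b, epoch_len)
    n_ep = ea.shape[0]
    if n_ep < 4:
        raise ValueError(f"need at least 4 epochs, got {n_ep}")
    za = np.exp(1j * np.deg2rad(ea))
    zb = np.exp(1j * np.deg2rad(eb))
    # PLV of every (a-epoch, b-epoch) pairing in one matrix product
    pair_plv = np.abs(za @ zb.conj().T) / epoch_len
    obs = float(np.trace(pair_plv) / n_ep)
    offsets = plv_offset(a[: n_ep * epoch_len], b[: n_ep * epoch_len])
    rng = as_rng(seed)
    null = np.empty(n_perm)
    rows = np.arange(n_ep)
    for k in range(n_perm):
        null[k] = pair_plv[rows, rng.permutation(n_ep)].mean()
    mu = float(null.mean())
    sd = float(null.std(ddof=1))
    if sd == 0.0:
        raise ValueError("permutation null has zero spread; z undefined")
    return PLVResult(
        plv=obs, mean_offset_deg=offsets["mean_offset_deg"], z=(obs - mu) / sd,
        n_epochs=n_ep, n_perm=n_perm, perm_mean=mu, perm_sd=sd,
    )
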