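"""Subject-level aggregation and mixed-effects inference.

Electrode-level permutation z-scores are averaged within subject and tested
against zero across subjects.  The binned peak/trough contrast is tested
with a linear mixed-effects model

    amplitude ~ phase + (phase | subject / electrode)

i.e. a fixed effect of phase (coded -0.5 / +0.5) with random intercepts and
slopes for subject and for electrode nested within subject, fitted by
maximum likelihood (REML is invalid for likelihood-ratio comparison of
fixed effects).  The contribution of phase is the likelihood-ratio
statistic of the full vs phase-free model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as spstats
from statsmodels.regression.mixed_linear_model import MixedLM

from .phase_amplitude import electrode_t_test

PHASE_CODES = {"peak": 0.5, "trough": -0.5}


@dataclass
class LmeResult:
    lrstat: float
    p: float
    beta_phase: float
    converged: bool
    structure: str  # "slopes" or "intercepts" (fallback)
    llf_full: float
    llf_reduced: float


def subject_mean_z(z_by_electrode, subject_map) -> tuple[pd.Series, dict]:
    """Unweighted per-subject mean of electrode z-scores plus a one-sample
    t-test of the subject means against zero.

    ``subject_map`` gives the subject of each electrode (same order as the
    z values); every electrode must be mapped.
    """
    z = np.asarray(z_by_electrode, dtype=float)
    subjects = pd.Series(list(subject_map))
    if len(subjects) != z.size:
        raise ValueError("one subject label per electrode is required")
    if subjects.isna().any():
        raise ValueError(f"unmapped electrode(s) at index {list(subjects[subjects.isna()].index)}")
    means = pd.Series(z).groupby(subjects).mean()
    return means, electrode_t_test(means.to_numpy())


def _code_phase(phase) -> np.ndarray:
    ph = pd.Series(list(phase))
    if set(ph.unique()) <= set(PHASE_CODES):
        return ph.map(PHASE_CODES).to_numpy(dtype=float)
    coded = ph.to_numpy(dtype=float)
    if not set(np.unique(coded)) <= {-0.5, 0.5}:
        raise ValueError("phase must be 'peak'/'trough' labels or +/-0.5 codes")
    return coded


def _fit_ml(df: pd.DataFrame, with_phase: bool, structure: str):
    fixed = "amplitude ~ phase" if with_phase else "amplitude ~ 1"
    if structure == "slopes":
        kwargs = dict(
            re_formula="~phase",
            vc_formula={"elec": "0 + C(electrode)", "elec_phase": "0 + C(electrode):phase"},
        )
    else:
        kwargs = dict(re_formula="~1", vc_formula={"elec": "0 + C(electrode)"})
    model = MixedLM.from_formula(fixed, groups="subject", data=df, **kwargs)
    best = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # single-optimizer likelihoods are noisy near the variance boundary
        # (enough to corrupt a 1-df LR statistic), so keep the best of two
        for method in ("powell", "lbfgs"):
            try:
                res = model.fit(reml=False, method=method, maxiter=500)
            except (np.linalg.LinAlgError, ValueError):
                continue
            if np.isfinite(res.llf) and (best is None or res.llf > best.llf):
                best = res
    return best


def fit_lme_lr(
    amplitude,
    phase,
    subject,
    electrode,
    one_sided: str = "plain",
    allow_fallback: bool = True,
) -> LmeResult:
    """Likelihood-ratio test for a fixed effect of stimulation phase.

    Fits the full model (fixed phase + random intercept/slope for subject
    and electrode-within-subject) and the reduced model without the fixed
    effect, both by ML, and returns LRStat = 2(ll_full - ll_reduced) with a
    one-sided p on 1 df.  ``one_sided='plain'`` uses the chi2(1) upper tail;
    ``'halved'`` uses the 50:50 mixture convention 0.5 * P(chi2_1 > LR).
    On convergence failure of the random-slope structure the model falls
    back to random intercepts only (reported in ``structure``).

    Requires >= 2 subjects, >= 2 electrodes, and both phase levels.
    """
    df = pd.DataFrame(
        {
            "amplitude": np.asarray(amplitude, dtype=float),
            "phase": _code_phase(phase),
            "subject": list(subject),
            "electrode": list(electrode),
        }
    )
    if df["subject"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 subjects")
    if df["electrode"].nunique() < 2:
        raise ValueError("mixed model requires at least 2 electrodes")
    if df["phase"].nunique() < 2:
        raise ValueError("both phase levels must be present")
    if one_sided not in ("plain", "halved"):
        raise ValueError("one_sided must be 'plain' or 'halved'")

    structures = ["slopes", "intercepts"] if allow_fallback else ["slopes"]
    for structure in structures:
        full = _fit_ml(df, with_phase=True, structure=structure)
        reduced = _fit_ml(df, with_phase=False, structure=structure)
        if full is None or reduced is None:
            continue
        lrstat = max(0.0, 2.0 * (full.llf - reduced.llf))
        p = float(spstats.chi2.sf(lrstat, df=1))
        if one_sided == "halved":
            p = 0.5 * p if lrstat > 0 else 0.5 + 0.5 * p
        return LmeResult(
            lrstat=float(lrstat),
            p=float(min(max(p, np.finfo(float).tiny), 1.0)),
            beta_phase=float(full.params["phase"]),
            converged=bool(full.converged and reduced.converged),
            structure=structure,
            llf_full=float(full.llf),
            llf_reduced=float(reduced.llf),
        )
    raise RuntimeError("mixed model could not be fitted under any random-effects structure")
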