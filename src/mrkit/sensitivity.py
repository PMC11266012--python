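"""Sensitivity analyses: Cochran's Q, Egger intercept test, leave-one-out.

Cochran's Q measures heterogeneity of the per-SNP estimates around the
pooled fit; it is always computed about the FIXED-effects estimate (for
IVW) or the Egger fit, because Q itself supplies the random-effects
overdispersion factor and must not be self-referential. The Egger
intercept test probes directional pleiotropy. Leave-one-out refits IVW
with each SNP removed in turn to detect single-variant dominance; each
refit is a fresh IVW call on the reduced set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .estimators import MRResult, ivw, mr_egger
from .harmonize import HarmonizedSet

__all__ = ["QResult", "LooResult", "cochran_q", "egger_intercept_test", "leave_one_out"]


@dataclass
class QResult:
    method: str  # "ivw" or "egger"
    Q: float
    df: int
    pval: float


@dataclass
class LooResult:
    omitted_snp: str
    result: MRResult


def cochran_q(h: HarmonizedSet, method: str = "ivw") -> QResult:
    """Heterogeneity Q with df = k-1 (IVW) or k-2 (Egger)."""
    if method == "ivw":
        if len(h) < 2:
            raise ValueError("Cochran's Q (IVW) needs k >= 2")
        res = ivw(h, effects_model="fixed")
        q, df = res.extra["Q"], res.extra["Q_df"]
    elif method == "egger":
        if len(h) < 3:
            raise ValueError("Cochran's Q (Egger) needs k >= 3")
        res = mr_egger(h)
        q, df = res.extra["Q"], res.extra["Q_df"]
    else:
        raise ValueError(f"unknown Q method: {method!r}")
    pval = float(stats.chi2.sf(q, df)) if q > 0 else 1.0
    return QResult(method=method, Q=q, df=df, pval=pval)


def egger_intercept_test(h: HarmonizedSet) -> tuple[float, float, float]:
    """(intercept, se, p) of the MR-Egger fit; p from t(k-2)."""
    res = mr_egger(h)
    return res.extra["intercept"], res.extra["intercept_se"], res.extra["intercept_p"]


def leave_one_out(
    h: HarmonizedSet, effects_model: str = "multiplicative_random"
) -> tuple[list[LooResult], dict]:
    """IVW with each SNP omitted in turn.

    Returns the k single-omission results plus stability flags:
    ``sign_stable`` (every reduced-set beta shares the full-set sign) and
    ``significance_stable`` (every reduced-set p stays on the same side of
    0.05 as the full set).
    """
    if len(h) < 3:
        raise ValueError("leave-one-out needs k >= 3 (k-1 must support IVW)")
    full = ivw(h, effects_model=effects_model)
    results = []
    for rec in h.records:
        reduced = HarmonizedSet(
            exposure_name=h.exposure_name,
            outcome_name=h.outcome_name,
            records=[r for r in h.records if r.snp_id != rec.snp_id],
        )
        results.append(LooResult(omitted_snp=rec.snp_id, result=ivw(reduced, effects_model=effects_model)))
    full_sign = math.copysign(1.0, full.beta)
    full_sig = full.pval < 0.05
    flags = {
        "sign_stable": all(math.copysign(1.0, lr.result.beta) == full_sign for lr in results),
        "significance_stable": all((lr.result.pval < 0.05) == full_sig for lr in results),
        "full_result": full,
    }
    return results, flags


def loo_to_frame(results: list[LooResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "omitted_snp": lr.omitted_snp,
                "beta": lr.result.beta,
                "se": lr.result.se,
                "pval": lr.result.pval,
            }
            for lr in results
        ]
    )
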