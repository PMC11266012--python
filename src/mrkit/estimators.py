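"""Univariable two-sample MR estimators.

Five estimators over a harmonized instrument set, each trading robustness
against efficiency under a different invalid-instrument model:

* **IVW** — inverse-variance weighted meta-analysis of per-SNP Wald
  ratios, equivalently weighted regression of outcome betas on exposure
  betas through the origin. The main analysis method; consistent only if
  all instruments are valid. Defaults to multiplicative random effects
  (the SE is inflated by sqrt(Q/(k-1)) when Cochran's Q exceeds its
  degrees of freedom, never deflated).
* **MR-Egger** — the same regression with a free intercept; the slope is
  consistent under the InSIDE assumption and the intercept measures
  directional pleiotropy.
* **Weighted median** — consistent when instruments carrying at least half
  the weight are valid.
* **Simple / weighted mode** — the mode of the smoothed Wald-ratio
  density; consistent when the largest group of instruments with a common
  ratio is valid.

For a binary outcome the betas are log odds ratios, so every result also
carries OR = exp(beta) with a 95% Wald CI.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedRecord, HarmonizedSet

__all__ = [
    "MRResult",
    "EffectClassification",
    "wald_ratio",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimator",
    "run_all_methods",
    "classify_effect",
    "results_to_frame",
]

Z95 = 1.96

METHOD_LABELS = {
    "ivw": "Inverse variance weighted",
    "egger": "MR Egger",
    "weighted_median": "Weighted median",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
    "wald": "Wald ratio",
}


@dataclass
class MRResult:
    """One estimator's causal estimate with OR-scale confidence interval."""

    method: str
    k: int
    beta: float
    se: float
    pval: float
    extra: dict = field(default_factory=dict)
    or_: float = field(init=False)
    ci_low: float = field(init=False)
    ci_high: float = field(init=False)

    def __post_init__(self) -> None:
        self.or_ = math.exp(self.beta)
        self.ci_low = math.exp(self.beta - Z95 * self.se)
        self.ci_high = math.exp(self.beta + Z95 * self.se)


@dataclass
class EffectClassification:
    """Risk/protective call from the IVW result.

    ``risk_factor`` when p < 0.05 and OR > 1; ``protective_factor`` when
    p < 0.05 and OR < 1; otherwise ``null``. ``loo_required`` flags the
    borderline band 0.04 < p < 0.05 where a leave-one-out analysis is run
    to confirm no single variant drives the signal.
    """

    label: str
    basis: MRResult
    loo_required: bool


def _norm_p(beta: float, se: float) -> float:
    if se <= 0:
        return 1.0
    return float(2.0 * stats.norm.sf(abs(beta) / se))


def _check_k(h: HarmonizedSet, minimum: int, method: str) -> None:
    if len(h) < minimum:
        raise ValueError(
            f"{method} needs at least {minimum} harmonized SNPs, got {len(h)}"
        )


def wald_ratio(r: HarmonizedRecord) -> MRResult:
    """Single-SNP causal estimate beta_out / beta_exp.

    The SE uses the first-order delta approximation se_out/|beta_exp|,
    which ignores exposure-side sampling error; adequate for the strong
    instruments that survive genome-wide selection.
    """
    if r.beta_exp == 0:
        raise ValueError(f"Wald ratio undefined for {r.snp_id}: beta_exp = 0")
    beta = r.beta_out / r.beta_exp
    se = r.se_out / abs(r.beta_exp)
    return MRResult(method="wald", k=1, beta=beta, se=se, pval=_norm_p(beta, se))


def _ivw_fixed(beta_exp, beta_out, se_out):
    w = 1.0 / se_out**2
    denom = float(np.sum(w * beta_exp**2))
    beta = float(np.sum(w * beta_exp * beta_out)) / denom
    se_fixed = denom ** -0.5
    q = float(np.sum(w * (beta_out - beta * beta_exp) ** 2))
    return beta, se_fixed, q


def ivw(h: HarmonizedSet, effects_model: str = "multiplicative_random") -> MRResult:
    """Inverse-variance weighted estimate (weighted regression through 0).

    ``effects_model`` is ``"fixed"`` or ``"multiplicative_random"``; the
    random-effects SE is the fixed SE times max(1, sqrt(Q/(k-1))).
    """
    if effects_model not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown effects model: {effects_model!r}")
    _check_k(h, 2, "IVW (use wald_ratio for a single SNP)")
    beta_exp, _, beta_out, se_out = h.arrays()
    beta, se_fixed, q = _ivw_fixed(beta_exp, beta_out, se_out)
    k = len(h)
    se = se_fixed
    if effects_model == "multiplicative_random":
        se = se_fixed * max(1.0, math.sqrt(q / (k - 1)))
    return MRResult(
        method="ivw",
        k=k,
        beta=beta,
        se=se,
        pval=_norm_p(beta, se),
        extra={"Q": q, "Q_df": k - 1, "effects_model": effects_model, "se_fixed": se_fixed},
    )


def mr_egger(h: HarmonizedSet) -> MRResult:
    """MR-Egger regression: weighted fit of beta_out on beta_exp with a
    free intercept, instruments oriented so all exposure betas are >= 0.

    The slope is the causal estimate; a nonzero intercept indicates
    directional pleiotropy. SEs carry the multiplicative overdispersion
    factor max(1, sqrt(Q/(k-2))) and p-values use t with k-2 df.
    """
    import statsmodels.api as sm

    _check_k(h, 3, "MR-Egger")
    beta_exp, _, beta_out, se_out = h.arrays()
    sign = np.where(beta_exp < 0, -1.0, 1.0)
    x = beta_exp * sign
    y = beta_out * sign
    w = 1.0 / se_out**2
    k = len(h)

    fit = sm.WLS(y, sm.add_constant(x), weights=w).fit()
    q_egger = float(np.sum(w * fit.resid**2))
    # statsmodels scales bse by sqrt(weighted MSE) = sqrt(Q/(k-2)); undo it
    # and re-apply the one-sided (never < 1) multiplicative factor.
    mse = q_egger / (k - 2)
    scale = max(1.0, math.sqrt(mse)) / math.sqrt(mse) if mse > 0 else 1.0
    b0, b1 = float(fit.params[0]), float(fit.params[1])
    se0, se1 = float(fit.bse[0]) * scale, float(fit.bse[1]) * scale

    def t_p(est, se):
        if se <= 0:
            return 1.0
        return float(2.0 * stats.t.sf(abs(est) / se, df=k - 2))

    return MRResult(
        method="egger",
        k=k,
        beta=b1,
        se=se1,
        pval=t_p(b1, se1),
        extra={
            "intercept": b0,
            "intercept_se": se0,
            "intercept_p": t_p(b0, se0),
            "Q": q_egger,
            "Q_df": k - 2,
        },
    )


def _ratios_and_weights(h: HarmonizedSet, weighted: bool = True):
    beta_exp, _, beta_out, se_out = h.arrays()
    if np.any(beta_exp == 0):
        raise ValueError("beta_exp = 0 makes a Wald ratio undefined")
    r = beta_out / beta_exp
    if weighted:
        w = beta_exp**2 / se_out**2
    else:
        w = np.ones_like(r)
    return r, w / np.sum(w)


def _weighted_median_point(r: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(r)
    r_s, w_s = r[order], w[order]
    w_s = w_s / np.sum(w_s)
    p = np.cumsum(w_s) - 0.5 * w_s
    return float(np.interp(0.5, p, r_s))


def _parametric_bootstrap(h: HarmonizedSet, point_fn, n_boot: int, seed: int) -> float:
    """SD of an estimator under resampling of the betas from their
    reported sampling distributions."""
    beta_exp, se_exp, beta_out, se_out = h.arrays()
    rng = np.random.default_rng(seed)
    ests = np.empty(n_boot)
    for b in range(n_boot):
        be = rng.normal(beta_exp, se_exp)
        bo = rng.normal(beta_out, se_out)
        be = np.where(be == 0, np.finfo(float).tiny, be)
        ests[b] = point_fn(be, bo, se_out)
    return float(np.std(ests, ddof=1))


def weighted_median(h: HarmonizedSet, n_boot: int = 1000, seed: int = 0) -> MRResult:
    """Weighted median of the per-SNP Wald ratios.

    Weights are proportional to the inverse variance of each ratio
    (beta_exp² / se_out²). The estimate interpolates the sorted ratios at
    cumulative mid-weight 0.5; the SE comes from a seeded parametric
    bootstrap.
    """
    _check_k(h, 3, "weighted median")
    r, w = _ratios_and_weights(h, weighted=True)
    beta = _weighted_median_point(r, w)

    def point(be, bo, se_out):
        rr = bo / be
        ww = be**2 / se_out**2
        return _weighted_median_point(rr, ww / np.sum(ww))

    se = _parametric_bootstrap(h, point, n_boot, seed)
    return MRResult(method="weighted_median", k=len(h), beta=beta, se=se, pval=_norm_p(beta, se))


def _mode_point(r: np.ndarray, w: np.ndarray, phi: float, grid_size: int = 512) -> float:
    sd = float(np.std(r, ddof=1)) if len(r) > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(r, [75, 25])))
    bw_scale = min(sd, iqr / 1.349)
    if bw_scale <= 0:
        bw_scale = sd  # all-tied quartiles but spread elsewhere
    h_bw = phi * 0.9 * bw_scale * len(r) ** (-1 / 5)
    if h_bw <= 0 or np.ptp(r) == 0:
        return float(r[0])
    half = 4.0 * max(sd, h_bw)
    grid = np.linspace(np.mean(r) - half, np.mean(r) + half, grid_size)
    dens = np.sum(w[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h_bw) ** 2), axis=1)
    return float(grid[np.argmax(dens)])


def mode_estimator(
    h: HarmonizedSet,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MRResult:
    """Mode-based estimate: argmax of the Gaussian-kernel density of the
    Wald ratios on a 512-point grid.

    Bandwidth is phi * 0.9 * min(sd, IQR/1.349) * k^(-1/5) (a Silverman
    rule scaled by ``phi``); ``weighted`` switches between equal and
    inverse-variance ratio weights. All-identical ratios short-circuit to
    the common value. SE from the seeded parametric bootstrap.
    """
    _check_k(h, 3, "mode estimator")
    r, w = _ratios_and_weights(h, weighted=weighted)
    beta = _mode_point(r, w, phi)

    def point(be, bo, se_out):
        rr = bo / be
        if weighted:
            ww = be**2 / se_out**2
        else:
            ww = np.ones_like(rr)
        return _mode_point(rr, ww / np.sum(ww), phi)

    se = _parametric_bootstrap(h, point, n_boot, seed)
    method = "weighted_mode" if weighted else "simple_mode"
    return MRResult(method=method, k=len(h), beta=beta, se=se, pval=_norm_p(beta, se))


def run_all_methods(
    h: HarmonizedSet,
    seed: int = 0,
    n_boot: int = 1000,
    effects_model: str = "multiplicative_random",
) -> tuple[list[MRResult], dict]:
    """Run the five-method panel, degrading gracefully for tiny sets.

    With k >= 3 all five estimators run; k = 2 yields IVW only and k = 1
    a single Wald ratio, each flagged in the returned info dict. The dict
    also carries ``direction_consistent``: whether every estimate shares
    one sign (the agreement check applied to the headline results).
    """
    k = len(h)
    if k == 0:
        raise ValueError("cannot run MR on an empty harmonized set")
    info: dict = {"degraded": None}
    if k == 1:
        results = [wald_ratio(h.records[0])]
        info["degraded"] = "single SNP: Wald ratio only"
    elif k == 2:
        results = [ivw(h, effects_model=effects_model)]
        info["degraded"] = "two SNPs: IVW only"
    else:
        ss = np.random.SeedSequence(seed)
        s_med, s_sm, s_wm = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))
        results = [
            ivw(h, effects_model=effects_model),
            mr_egger(h),
            weighted_median(h, n_boot=n_boot, seed=s_med),
            mode_estimator(h, weighted=False, n_boot=n_boot, seed=s_sm),
            mode_estimator(h, weighted=True, n_boot=n_boot, seed=s_wm),
        ]
    signs = {math.copysign(1.0, res.beta) for res in results}
    info["direction_consistent"] = len(signs) == 1
    return results, info


def classify_effect(ivw_result: MRResult) -> EffectClassification:
    """Risk/protective/null call from the headline IVW result."""
    if ivw_result.method != "ivw":
        raise ValueError(f"classification is defined on IVW results, got {ivw_result.method!r}")
    if ivw_result.pval < 0.05:
        label = "risk_factor" if ivw_result.or_ > 1 else "protective_factor"
    else:
        label = "null"
    loo_required = 0.04 < ivw_result.pval < 0.05
    return EffectClassification(label=label, basis=ivw_result, loo_required=loo_required)


def results_to_frame(
    results: list[MRResult], exposure: str = "", outcome: str = ""
) -> pd.DataFrame:
    """Tabular form of a result panel (one row per method)."""
    return pd.DataFrame(
        [
            {
                "exposure": exposure,
                "outcome": outcome,
                "method": res.method,
                "nsnp": res.k,
                "beta": res.beta,
                "se": res.se,
                "or": res.or_,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "pval": res.pval,
            }
            for res in results
        ]
    )
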