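"""Multivariable MR: each exposure's direct effect conditional on the rest.

Used here for correlated lipid fractions (HDL-C adjusted for LDL-C and
triglycerides; apoA1 adjusted for apoB): the instrument union across the
exposures is jointly clumped, every retained SNP is looked up and allele-
aligned in every exposure table and the outcome table, and the outcome
betas are regressed on the matrix of exposure betas with no intercept and
inverse-variance weights. Collinear exposures are a hard error rather than
a silent drop.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import DEFAULT_PALINDROME_EAF_WINDOW, align_outcome
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_BP,
    InstrumentSet,
    LDMatrix,
    ld_clump,
)
from .sumstats import SummaryStatTable

__all__ = ["MVMRInput", "MVMRResult", "build_mvmr_input", "mvmr_ivw"]

Z95 = 1.96


@dataclass
class MVMRInput:
    """Aligned effect matrices for a joint multi-exposure fit.

    ``beta_exp`` and ``se_exp`` are k x m (SNPs x exposures); the outcome
    vectors have length k. Everything refers to a common effect allele per
    SNP. Requires k > m.
    """

    exposure_names: list[str]
    snp_ids: list[str]
    beta_exp: np.ndarray
    se_exp: np.ndarray
    beta_out: np.ndarray
    se_out: np.ndarray
    dropped: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.beta_exp = np.asarray(self.beta_exp, dtype=float)
        self.se_exp = np.asarray(self.se_exp, dtype=float)
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        k, m = self.beta_exp.shape
        if m != len(self.exposure_names):
            raise ValueError("beta_exp width must match exposure_names")
        if k <= m:
            raise ValueError(f"need more SNPs than exposures (k={k}, m={m})")

    @property
    def k(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def m(self) -> int:
        return self.beta_exp.shape[1]


@dataclass
class MVMRResult:
    """Per-exposure conditional estimates from the joint weighted fit."""

    exposure_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    pval: np.ndarray
    k: int
    Q: float

    def to_frame(self, outcome: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "exposure": name,
                    "outcome": outcome,
                    "method": "mvmr_ivw",
                    "nsnp": self.k,
                    "beta": float(self.beta[i]),
                    "se": float(self.se[i]),
                    "or": math.exp(self.beta[i]),
                    "ci_low": math.exp(self.beta[i] - Z95 * self.se[i]),
                    "ci_high": math.exp(self.beta[i] + Z95 * self.se[i]),
                    "pval": float(self.pval[i]),
                }
                for i, name in enumerate(self.exposure_names)
            ]
        )


def build_mvmr_input(
    instrument_sets: dict[str, InstrumentSet],
    exposure_tables: dict[str, SummaryStatTable],
    outcome_table: SummaryStatTable,
    ld: LDMatrix | None = None,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    r2_max: float = DEFAULT_CLUMP_R2,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> MVMRInput:
    """Assemble the joint input from per-exposure instrument sets.

    The instrument union is jointly clumped with each SNP prioritized by
    its smallest p-value across exposures; SNPs missing from any exposure
    table or the outcome table — or failing allele alignment anywhere —
    are dropped and audited.
    """
    if len(instrument_sets) < 2:
        raise ValueError("MVMR needs at least two exposures")
    names = list(instrument_sets)
    if set(names) - set(exposure_tables):
        raise ValueError("every instrument set needs a matching exposure table")

    # Union keyed by snp_id, clump priority = min p across exposures.
    best: dict[str, object] = {}
    for iset in instrument_sets.values():
        for rec in iset:
            cur = best.get(rec.snp_id)
            if cur is None or rec.pval < cur.pval:
                best[rec.snp_id] = rec
    clumped = ld_clump(
        list(best.values()), ld=ld, window_bp=window_bp, r2_max=r2_max,
        exposure_name="+".join(names),
    )

    dropped: list[tuple[str, str]] = []
    snp_ids: list[str] = []
    rows_exp: list[list[float]] = []
    rows_se: list[list[float]] = []
    bo: list[float] = []
    so: list[float] = []
    for ref in clumped:
        lookups = []
        reason = None
        for name in names:
            rec = exposure_tables[name].get(ref.snp_id)
            if rec is None:
                reason = f"missing_from_exposure:{name}"
                break
            aligned = align_outcome(ref, rec, palindrome_eaf_window)
            if not aligned.retained:
                reason = f"{aligned.status}:{name}"
                break
            lookups.append((aligned.beta_out, aligned.se_out))
        if reason is None:
            out_rec = outcome_table.get(ref.snp_id)
            if out_rec is None:
                reason = "missing_from_outcome"
            else:
                aligned = align_outcome(ref, out_rec, palindrome_eaf_window)
                if not aligned.retained:
                    reason = f"{aligned.status}:outcome"
        if reason is not None:
            dropped.append((ref.snp_id, reason))
            continue
        snp_ids.append(ref.snp_id)
        rows_exp.append([b for b, _ in lookups])
        rows_se.append([s for _, s in lookups])
        bo.append(aligned.beta_out)
        so.append(aligned.se_out)

    if len(snp_ids) <= len(names):
        raise ValueError(
            f"only {len(snp_ids)} usable SNPs for {len(names)} exposures "
            f"after assembly (dropped: {len(dropped)})"
        )
    return MVMRInput(
        exposure_names=names,
        snp_ids=snp_ids,
        beta_exp=np.array(rows_exp),
        se_exp=np.array(rows_se),
        beta_out=np.array(bo),
        se_out=np.array(so),
        dropped=dropped,
    )


def _collinear_pairs(x: np.ndarray, names: list[str], tol: float = 0.9999) -> list[str]:
    cc = np.corrcoef(x, rowvar=False)
    pairs = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if abs(cc[i, j]) > tol:
                pairs.append(f"{names[i]}~{names[j]}")
    return pairs


def mvmr_ivw(inp: MVMRInput) -> MVMRResult:
    """Weighted multiple regression of outcome betas on exposure betas.

    No intercept, weights 1/se_out²; per-coefficient SEs carry the
    multiplicative factor max(1, sqrt(Q/(k-m))) and p-values use t(k-m).
    With m = 1 this reduces exactly to univariable IVW.
    """
    import statsmodels.api as sm

    x, y, w = inp.beta_exp, inp.beta_out, 1.0 / inp.se_out**2
    k, m = inp.k, inp.m
    if np.linalg.matrix_rank(x) < m:
        pairs = _collinear_pairs(x, inp.exposure_names)
        raise ValueError(
            "rank-deficient exposure matrix; collinear exposures: "
            + (", ".join(pairs) if pairs else "undetermined")
        )
    fit = sm.WLS(y, x, weights=w).fit()
    q = float(np.sum(w * fit.resid**2))
    mse = q / (k - m)
    scale = max(1.0, math.sqrt(mse)) / math.sqrt(mse) if mse > 0 else 1.0
    beta = np.asarray(fit.params, dtype=float)
    se = np.asarray(fit.bse, dtype=float) * scale
    pval = 2.0 * stats.t.sf(np.abs(beta) / se, df=k - m)
    return MVMRResult(
        exposure_names=list(inp.exposure_names),
        beta=beta,
        se=se,
        pval=np.asarray(pval, dtype=float),
        k=k,
        Q=q,
    )
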