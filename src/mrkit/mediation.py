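"""Two-step MR mediation with product-of-coefficients decomposition.

For an exposure X, mediator M and outcome Y, three IVW estimates are
combined:

* ``beta_all`` — total effect, X -> Y;
* ``beta1``   — step 1, X -> M;
* ``beta2``   — step 2, M -> Y, estimated after deleting from the
  mediator's instruments any SNP already used in step 1, so that the two
  steps use disjoint instruments;

and decomposed as

* ``beta12  = beta1 * beta2``            (mediated / indirect effect),
* ``beta_dir = beta_all - beta12``       (direct effect),
* ``beta_per = beta12 / beta_all``       (proportion mediated).

A mediating effect is declared only when both step IVW p-values are below
0.05. Derived quantities are carried at full precision and rounded (3
decimals) only at serialization. The delta-method SE of the product,
sqrt(beta1²·se2² + beta2²·se1²), is provided when the step SEs are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .estimators import MRResult, ivw
from .harmonize import HarmonizedSet, exclude_snps, harmonize
from .instruments import InstrumentSet, LDMatrix, select_instruments
from .sumstats import SummaryStatTable

__all__ = ["MediationResult", "two_step_mediation", "run_mediation", "mediation_to_frame"]


@dataclass
class MediationResult:
    """The full effect decomposition for one exposure-mediator-outcome chain."""

    beta_all: float
    beta1: float
    beta2: float
    beta12: float
    beta_dir: float
    beta_per: float | None
    exposure: str = ""
    mediator: str = ""
    outcome: str = ""
    se12: float | None = None
    mediation_declared: bool | None = None
    notes: list[str] = field(default_factory=list)


def two_step_mediation(
    beta_all: float,
    beta1: float,
    beta2: float,
    se1: float | None = None,
    se2: float | None = None,
    **names,
) -> MediationResult:
    """Decompose a total effect given the two step estimates.

    ``beta_per`` is undefined when ``beta_all`` is zero; that case is
    flagged in ``notes`` (beta_per set to None), not raised.
    """
    beta12 = beta1 * beta2
    beta_dir = beta_all - beta12
    notes: list[str] = []
    if beta_all == 0:
        beta_per = None
        notes.append("beta_per undefined: beta_all is zero")
    else:
        beta_per = beta12 / beta_all
    se12 = None
    if se1 is not None and se2 is not None:
        se12 = math.sqrt(beta1**2 * se2**2 + beta2**2 * se1**2)
    return MediationResult(
        beta_all=beta_all,
        beta1=beta1,
        beta2=beta2,
        beta12=beta12,
        beta_dir=beta_dir,
        beta_per=beta_per,
        se12=se12,
        notes=notes,
        **names,
    )


@dataclass
class MediationRun:
    """A MediationResult plus the three underlying IVW fits and sets."""

    result: MediationResult
    total: MRResult
    step1: MRResult
    step2: MRResult
    h_total: HarmonizedSet
    h_step1: HarmonizedSet
    h_step2: HarmonizedSet


def run_mediation(
    exposure_table: SummaryStatTable,
    mediator_table: SummaryStatTable,
    outcome_table: SummaryStatTable,
    ladder=(5e-8,),
    min_snps: int = 3,
    ld: LDMatrix | None = None,
    effects_model: str = "multiplicative_random",
    exposure_instruments: InstrumentSet | None = None,
    mediator_instruments: InstrumentSet | None = None,
) -> MediationRun:
    """Full two-step mediation from three summary-statistic tables.

    Instruments are selected per table (threshold ladder + clumping)
    unless pre-selected sets are supplied. Step 2 removes every SNP that
    instrumented step 1 before estimating the mediator-to-outcome effect;
    an empty step-2 set is a hard error.
    """
    exp_inst = exposure_instruments or select_instruments(
        exposure_table, ladder=ladder, min_snps=min_snps, ld=ld
    )
    med_inst = mediator_instruments or select_instruments(
        mediator_table, ladder=ladder, min_snps=min_snps, ld=ld
    )

    h_total = harmonize(exp_inst, outcome_table)
    h_step1 = harmonize(exp_inst, mediator_table)
    h_step2_full = harmonize(med_inst, outcome_table)
    step1_ids = set(exp_inst.snp_ids)
    h_step2 = exclude_snps(h_step2_full, step1_ids)
    if len(h_step2) == 0:
        raise ValueError(
            "no mediator instruments left for step 2 after removing the "
            f"{len(step1_ids)} step-1 SNPs"
        )

    total = ivw(h_total, effects_model=effects_model)
    step1 = ivw(h_step1, effects_model=effects_model)
    step2 = ivw(h_step2, effects_model=effects_model)

    result = two_step_mediation(
        beta_all=total.beta,
        beta1=step1.beta,
        beta2=step2.beta,
        se1=step1.se,
        se2=step2.se,
        exposure=exposure_table.trait_name,
        mediator=mediator_table.trait_name,
        outcome=outcome_table.trait_name,
    )
    result.mediation_declared = step1.pval < 0.05 and step2.pval < 0.05
    if not result.mediation_declared:
        result.notes.append(
            f"mediation not declared: step-1 p={step1.pval:.3g}, step-2 p={step2.pval:.3g}"
        )
    return MediationRun(
        result=result,
        total=total,
        step1=step1,
        step2=step2,
        h_total=h_total,
        h_step1=h_step1,
        h_step2=h_step2,
    )


def mediation_to_frame(results: list[MediationResult], decimals: int = 3) -> pd.DataFrame:
    """Serialize decompositions, rounding only here (display precision)."""
    rows = []
    for r in results:
        rows.append(
            {
                "exposure": r.exposure,
                "mediator": r.mediator,
                "outcome": r.outcome,
                "beta_all": round(r.beta_all, decimals),
                "beta1": round(r.beta1, decimals),
                "beta2": round(r.beta2, decimals),
                "beta12": round(r.beta12, decimals),
                "beta_dir": round(r.beta_dir, decimals),
                "beta_per": None if r.beta_per is None else round(r.beta_per, decimals),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "exposure", "mediator", "outcome",
            "beta_all", "beta1", "beta2", "beta12", "beta_dir", "beta_per",
        ],
    )
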