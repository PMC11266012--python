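"""Allele harmonization between exposure and outcome summary statistics.

Two-sample MR requires the exposure and outcome betas of every instrument
to refer to the same effect allele. For each instrument this module matches
alleles directly, after swapping roles (negating the outcome beta), or
after strand complementation (A<->T, C<->G). Palindromic variants (A/T or
C/G), whose strand cannot be resolved from alleles alone, are kept only
when effect-allele frequencies identify the orientation: both frequencies
on the same side of 0.5 and both outside an ambiguity window around 0.5
(default half-width 0.08); otherwise — including when either frequency is
missing — they are dropped. Irreconcilable allele sets are dropped as
mismatches. Every drop is audited, never silent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

from .instruments import InstrumentSet
from .sumstats import SummaryStatRecord, SummaryStatTable

__all__ = [
    "HarmonizedRecord",
    "HarmonizedSet",
    "harmonize",
    "exclude_snps",
    "DEFAULT_PALINDROME_EAF_WINDOW",
]

DEFAULT_PALINDROME_EAF_WINDOW = 0.08

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

STATUS_ALIGNED = "aligned"
STATUS_FLIPPED = "flipped"
STATUS_STRAND = "strand_corrected"
STATUS_DROP_PALINDROMIC = "dropped_palindromic"
STATUS_DROP_MISMATCH = "dropped_mismatch"
STATUS_DROP_MISSING = "dropped_missing_outcome"


@dataclass(frozen=True)
class HarmonizedRecord:
    """One instrument with exposure and outcome effects on a shared allele."""

    snp_id: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    status: str
    eaf_exp: float | None = None
    eaf_out: float | None = None

    @property
    def retained(self) -> bool:
        return not self.status.startswith("dropped")


@dataclass
class HarmonizedSet:
    """Retained instruments plus an audit trail of everything dropped."""

    exposure_name: str
    outcome_name: str
    records: list[HarmonizedRecord]
    dropped: list[HarmonizedRecord] = field(default_factory=list)
    excluded_snps: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate snp_id in harmonized set")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]

    def arrays(self):
        """(beta_exp, se_exp, beta_out, se_out) as float numpy arrays."""
        import numpy as np

        return (
            np.array([r.beta_exp for r in self.records], dtype=float),
            np.array([r.se_exp for r in self.records], dtype=float),
            np.array([r.beta_out for r in self.records], dtype=float),
            np.array([r.se_out for r in self.records], dtype=float),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = ["snp_id", "beta_exp", "se_exp", "beta_out", "se_out", "eaf_exp", "eaf_out", "status"]
        return pd.DataFrame(
            [{c: getattr(r, c) for c in cols} for r in self.records], columns=cols
        )


def _is_palindromic_pair(ea: str, oa: str) -> bool:
    return {ea, oa} in ({"A", "T"}, {"C", "G"})


def _ambiguous_freq(eaf: float | None, window: float) -> bool:
    return eaf is None or abs(eaf - 0.5) <= window


def align_outcome(
    exp_rec: SummaryStatRecord,
    out_rec: SummaryStatRecord,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedRecord:
    """Harmonize one outcome record onto the exposure's effect allele."""
    ea, oa = exp_rec.effect_allele, exp_rec.other_allele

    def build(beta_out, eaf_out, status):
        return HarmonizedRecord(
            snp_id=exp_rec.snp_id,
            beta_exp=exp_rec.beta,
            se_exp=exp_rec.se,
            beta_out=beta_out,
            se_out=out_rec.se,
            eaf_exp=exp_rec.eaf,
            eaf_out=eaf_out,
            status=status,
        )

    if _is_palindromic_pair(ea, oa):
        # Alleles alone cannot orient a palindromic SNP; the complement of
        # A/G is T/C, so an apparent match may be the opposite strand.
        if {out_rec.effect_allele, out_rec.other_allele} != {ea, oa}:
            return build(out_rec.beta, out_rec.eaf, STATUS_DROP_MISMATCH)
        w = palindrome_eaf_window
        if _ambiguous_freq(exp_rec.eaf, w) or _ambiguous_freq(out_rec.eaf, w):
            return build(out_rec.beta, out_rec.eaf, STATUS_DROP_PALINDROMIC)
        same_side = (exp_rec.eaf - 0.5) * (out_rec.eaf - 0.5) > 0
        if not same_side:
            return build(out_rec.beta, out_rec.eaf, STATUS_DROP_PALINDROMIC)
        # Frequency, not allele labels, orients a palindromic SNP: same-side
        # frequencies identify the outcome effect allele with the exposure's.
        return build(out_rec.beta, out_rec.eaf, STATUS_ALIGNED)

    o_ea, o_oa = out_rec.effect_allele, out_rec.other_allele
    if (o_ea, o_oa) == (ea, oa):
        return build(out_rec.beta, out_rec.eaf, STATUS_ALIGNED)
    if (o_ea, o_oa) == (oa, ea):
        eaf = None if out_rec.eaf is None else 1.0 - out_rec.eaf
        return build(-out_rec.beta, eaf, STATUS_FLIPPED)
    c_ea, c_oa = COMPLEMENT[o_ea], COMPLEMENT[o_oa]
    if (c_ea, c_oa) == (ea, oa):
        return build(out_rec.beta, out_rec.eaf, STATUS_STRAND)
    if (c_ea, c_oa) == (oa, ea):
        eaf = None if out_rec.eaf is None else 1.0 - out_rec.eaf
        return build(-out_rec.beta, eaf, STATUS_STRAND)
    return build(out_rec.beta, out_rec.eaf, STATUS_DROP_MISMATCH)


def harmonize(
    exposure: InstrumentSet,
    outcome: SummaryStatTable,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
) -> HarmonizedSet:
    """Align every instrument's outcome association to the exposure allele.

    Instruments absent from the outcome table, palindromic SNPs with
    ambiguous frequencies, and irreconcilable allele sets all end up in
    ``dropped`` with a status recording the reason; nothing raises.
    """
    records: list[HarmonizedRecord] = []
    dropped: list[HarmonizedRecord] = []
    for exp_rec in exposure:
        out_rec = outcome.get(exp_rec.snp_id)
        if out_rec is None:
            dropped.append(
                HarmonizedRecord(
                    snp_id=exp_rec.snp_id,
                    beta_exp=exp_rec.beta,
                    se_exp=exp_rec.se,
                    beta_out=float("nan"),
                    se_out=float("nan"),
                    eaf_exp=exp_rec.eaf,
                    status=STATUS_DROP_MISSING,
                )
            )
            continue
        rec = align_outcome(exp_rec, out_rec, palindrome_eaf_window)
        (records if rec.retained else dropped).append(rec)
    return HarmonizedSet(
        exposure_name=exposure.exposure_name,
        outcome_name=outcome.trait_name,
        records=records,
        dropped=dropped,
    )


def exclude_snps(hset: HarmonizedSet, snp_ids) -> HarmonizedSet:
    """Remove listed SNPs (audited); used to delete instruments shared
    between the two steps of a mediation analysis."""
    excluded = set(snp_ids)
    kept = [r for r in hset.records if r.snp_id not in excluded]
    removed = [r.snp_id for r in hset.records if r.snp_id in excluded]
    return HarmonizedSet(
        exposure_name=hset.exposure_name,
        outcome_name=hset.outcome_name,
        records=kept,
        dropped=list(hset.dropped),
        excluded_snps=list(hset.excluded_snps) + removed,
    )


def harmonized_set_from_arrays(
    beta_exp, se_exp, beta_out, se_out,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
    snp_ids=None,
) -> HarmonizedSet:
    """Build a HarmonizedSet directly from effect arrays (already aligned)."""
    k = len(beta_exp)
    if snp_ids is None:
        snp_ids = [f"snp{i + 1}" for i in range(k)]
    records = [
        HarmonizedRecord(
            snp_id=str(snp_ids[i]),
            beta_exp=float(beta_exp[i]),
            se_exp=float(se_exp[i]),
            beta_out=float(beta_out[i]),
            se_out=float(se_out[i]),
            status=STATUS_ALIGNED,
        )
        for i in range(k)
    ]
    return HarmonizedSet(exposure_name=exposure_name, outcome_name=outcome_name, records=records)
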