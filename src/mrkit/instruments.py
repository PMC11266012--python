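"""Instrument selection: p-value threshold ladder and greedy LD clumping.

Instruments are SNPs robustly associated with the exposure. Selection uses
a genome-wide significance ladder (5e-8, relaxed to 5e-6 then 5e-5 when too
few SNPs survive) followed by greedy LD clumping within a 10 Mb window at
an r-squared cutoff of 0.001: repeatedly keep the most significant
remaining SNP and discard everything nearby in high LD with it.

When no LD source is supplied, SNPs within the window on the same
chromosome are conservatively treated as correlated (distance-only
clumping). When a sparse LD source is supplied, absent pairs are assumed
unlinked (r² = 0), matching sparse LD exports that omit below-threshold
pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .sumstats import SummaryStatRecord, SummaryStatTable

__all__ = [
    "InstrumentSet",
    "LDMatrix",
    "select_by_pvalue",
    "ld_clump",
    "select_instruments",
    "DEFAULT_LADDER",
    "DEFAULT_CLUMP_WINDOW_BP",
    "DEFAULT_CLUMP_R2",
    "DEFAULT_MIN_SNPS",
]

DEFAULT_LADDER = (5e-8, 5e-6, 5e-5)
DEFAULT_CLUMP_WINDOW_BP = 10_000_000
DEFAULT_CLUMP_R2 = 0.001
# MR-Egger needs k-2 residual df, so three instruments is the practical floor.
DEFAULT_MIN_SNPS = 3


class LDMatrix:
    """Symmetric r² lookup keyed by SNP id pairs.

    Missing pairs return 0 (assumed unlinked). Construct from a dense
    labelled square TSV or a sparse three-column (snp_a, snp_b, r2) TSV.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), v in (pairs or {}).items():
            self._r2[frozenset((a, b))] = float(v)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    def set(self, a: str, b: str, value: float) -> None:
        self._r2[frozenset((a, b))] = float(value)

    @classmethod
    def from_dense_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        out = cls()
        ids = list(df.index)
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                v = float(df.loc[a, b])
                if v != 0.0:
                    out.set(a, b, v)
        return out

    @classmethod
    def from_sparse_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", dtype={"snp_a": str, "snp_b": str})
        out = cls()
        for row in df.itertuples(index=False):
            out.set(row.snp_a, row.snp_b, float(row.r2))
        return out


@dataclass
class InstrumentSet:
    """SNPs surviving selection for one exposure."""

    exposure_name: str
    records: list[SummaryStatRecord]
    threshold_used: float
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP
    clump_r2: float = DEFAULT_CLUMP_R2
    warning: str | None = None
    n_candidates: int = 0
    n_clumped_out: int = 0
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def snp_ids(self) -> list[str]:
        return [r.snp_id for r in self.records]


def _sort_key(rec: SummaryStatRecord):
    # Total order: significance first, genomic coordinates and id break ties
    # so clumping is invariant to input shuffling.
    return (rec.pval, rec.chrom, rec.pos, rec.snp_id)


def select_by_pvalue(
    table: SummaryStatTable,
    ladder=DEFAULT_LADDER,
    min_snps: int = DEFAULT_MIN_SNPS,
) -> tuple[list[SummaryStatRecord], float, str | None]:
    """Pick candidates below the first ladder threshold yielding >= min_snps.

    Returns (records, threshold_used, warning). When even the most relaxed
    rung yields fewer than ``min_snps`` candidates, whatever exists is
    returned with a warning string instead of raising.
    """
    if len(table) == 0:
        raise ValueError(f"empty summary-statistic table: {table.trait_name!r}")
    ladder = tuple(ladder)
    if not ladder or any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("threshold ladder must be non-empty and strictly increasing")
    if min_snps < 1:
        raise ValueError("min_snps must be >= 1")

    warning = None
    chosen = ladder[-1]
    candidates: list[SummaryStatRecord] = []
    for thr in ladder:
        candidates = [r for r in table if r.pval < thr]
        if len(candidates) >= min_snps:
            chosen = thr
            break
    else:
        warning = (
            f"only {len(candidates)} candidate(s) below the most relaxed "
            f"threshold {ladder[-1]:g} (wanted >= {min_snps})"
        )
    candidates.sort(key=_sort_key)
    return candidates, chosen, warning


def ld_clump(
    candidates: list[SummaryStatRecord],
    ld: LDMatrix | None = None,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    r2_max: float = DEFAULT_CLUMP_R2,
    exposure_name: str = "",
    threshold_used: float = float("nan"),
    warning: str | None = None,
) -> InstrumentSet:
    """Greedy p-value-ordered clumping.

    Repeatedly take the most significant remaining SNP and discard all
    remaining SNPs on the same chromosome within ``window_bp`` whose r²
    against it exceeds ``r2_max``. With ``ld=None`` every within-window
    pair is treated as correlated.
    """
    pool = sorted(candidates, key=_sort_key)
    kept: list[SummaryStatRecord] = []
    n_removed = 0
    while pool:
        lead = pool.pop(0)
        kept.append(lead)
        survivors = []
        for rec in pool:
            within = rec.chrom == lead.chrom and abs(rec.pos - lead.pos) <= window_bp
            if within:
                correlated = True if ld is None else ld.r2(lead.snp_id, rec.snp_id) > r2_max
            else:
                correlated = False
            if correlated:
                n_removed += 1
            else:
                survivors.append(rec)
        pool = survivors
    # Report in genomic order-of-significance (the greedy retention order).
    return InstrumentSet(
        exposure_name=exposure_name,
        records=kept,
        threshold_used=threshold_used,
        clump_window_bp=window_bp,
        clump_r2=r2_max,
        warning=warning,
        n_candidates=len(candidates),
        n_clumped_out=n_removed,
    )


def select_instruments(
    table: SummaryStatTable,
    ladder=DEFAULT_LADDER,
    min_snps: int = DEFAULT_MIN_SNPS,
    ld: LDMatrix | None = None,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
    r2_max: float = DEFAULT_CLUMP_R2,
) -> InstrumentSet:
    """Threshold ladder followed by LD clumping, in one call."""
    candidates, thr, warning = select_by_pvalue(table, ladder=ladder, min_snps=min_snps)
    return ld_clump(
        candidates,
        ld=ld,
        window_bp=window_bp,
        r2_max=r2_max,
        exposure_name=table.trait_name,
        threshold_used=thr,
        warning=warning,
    )
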