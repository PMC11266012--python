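"""GWAS summary-statistic containers and tab-separated IO.

The canonical on-disk dialect is a tab-separated file with a header row and
``NA`` for missing values, one row per SNP::

    snp  chrom  pos  effect_allele  other_allele  eaf  beta  se  pval  n

Betas are per-allele effects: log-odds for binary traits, SD units for
continuous traits. Only biallelic SNPs with A/C/G/T alleles are retained;
rows violating basic record invariants (non-positive SE, p-value outside
(0, 1], identical alleles, ...) are dropped on read and tallied rather than
raising, so that a single malformed row never sinks a whole GWAS file.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

import pandas as pd

__all__ = [
    "SummaryStatRecord",
    "SummaryStatTable",
    "read_sumstats",
    "write_sumstats",
    "DEFAULT_COLUMNS",
]

VALID_ALLELES = frozenset("ACGT")

#: Canonical column order of the TSV dialect.
DEFAULT_COLUMNS = (
    "snp",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

#: Columns that may be missing ("NA") without invalidating a record.
_OPTIONAL = {"eaf", "n"}


@dataclass(frozen=True)
class SummaryStatRecord:
    """One SNP's association with one trait.

    ``eaf`` is the effect-allele frequency; ``n`` the GWAS sample size.
    Both may be ``None`` (serialized as ``NA``).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    eaf: float | None = None
    n: float | None = None

    def invariant_violation(self) -> str | None:
        """Return the name of the first violated invariant, or None."""
        if self.effect_allele not in VALID_ALLELES or self.other_allele not in VALID_ALLELES:
            return "non_acgt_allele"
        if self.effect_allele == self.other_allele:
            return "identical_alleles"
        if not (self.se > 0) or not math.isfinite(self.se):
            return "nonpositive_se"
        if not (0 < self.pval <= 1):
            return "pval_out_of_range"
        if not math.isfinite(self.beta):
            return "nonfinite_beta"
        if self.eaf is not None and not (0 <= self.eaf <= 1):
            return "eaf_out_of_range"
        if self.n is not None and not (self.n > 0):
            return "nonpositive_n"
        if self.pos < 1:
            return "nonpositive_pos"
        return None

    def is_palindromic(self) -> bool:
        """A/T or C/G variants whose strand cannot be resolved from alleles."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass
class SummaryStatTable:
    """An ordered collection of per-SNP records for one trait."""

    trait_name: str
    records: list[SummaryStatRecord]
    metadata: dict = field(default_factory=dict)
    drop_tally: Counter = field(default_factory=Counter)

    def __post_init__(self) -> None:
        ids = [r.snp_id for r in self.records]
        if len(ids) != len(set(ids)):
            dup = next(s for s in ids if ids.count(s) > 1)
            raise ValueError(f"duplicate snp_id in table {self.trait_name!r}: {dup}")
        self._index = {r.snp_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def get(self, snp_id: str) -> SummaryStatRecord | None:
        return self._index.get(snp_id)

    def subset(self, snp_ids) -> "SummaryStatTable":
        wanted = set(snp_ids)
        return SummaryStatTable(
            trait_name=self.trait_name,
            records=[r for r in self.records if r.snp_id in wanted],
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "snp": r.snp_id,
                "chrom": r.chrom,
                "pos": r.pos,
                "effect_allele": r.effect_allele,
                "other_allele": r.other_allele,
                "eaf": r.eaf,
                "beta": r.beta,
                "se": r.se,
                "pval": r.pval,
                "n": r.n,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))


def _parse_optional_float(value) -> float | None:
    if value is None:
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    s = str(value).strip()
    if s in ("", "NA", "NaN", "nan", "."):
        return None
    return float(s)


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait_name: str | None = None,
) -> SummaryStatTable:
    """Read a TSV of GWAS summary statistics into a SummaryStatTable.

    Parameters
    ----------
    path
        Tab-separated file with a header row.
    column_map
        Mapping from canonical names (``snp``, ``chrom``, ``pos``, ...) to
        the names used in the file header. Unmapped canonical names are
        assumed to appear verbatim. Column order in the file is irrelevant.
    trait_name
        Defaults to the file stem.

    Rows violating record invariants are dropped and counted in the
    returned table's ``drop_tally``. A missing required column or an empty
    file is a hard error.
    """
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=False)
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise ValueError(f"empty summary-statistic file: {path}")
    rename = {column_map.get(name, name): name for name in DEFAULT_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    required_missing = [src for src in missing if rename[src] not in _OPTIONAL]
    if required_missing:
        raise ValueError(
            f"missing required column(s) {required_missing} in {path} "
            f"(header: {list(df.columns)})"
        )
    df = df.rename(columns=rename)
    for name in _OPTIONAL:
        if name not in df.columns:
            df[name] = None

    records: list[SummaryStatRecord] = []
    tally: Counter = Counter()
    for row in df.itertuples(index=False):
        try:
            rec = SummaryStatRecord(
                snp_id=str(row.snp),
                chrom=str(row.chrom),
                pos=int(float(row.pos)),
                effect_allele=str(row.effect_allele).upper(),
                other_allele=str(row.other_allele).upper(),
                beta=float(row.beta),
                se=float(row.se),
                pval=float(row.pval),
                eaf=_parse_optional_float(row.eaf),
                n=_parse_optional_float(row.n),
            )
        except (TypeError, ValueError):
            tally["unparseable_row"] += 1
            continue
        reason = rec.invariant_violation()
        if reason is not None:
            tally[reason] += 1
            continue
        if rec.snp_id in {r.snp_id for r in records}:
            tally["duplicate_snp_id"] += 1
            continue
        records.append(rec)

    if trait_name is None:
        import pathlib

        trait_name = pathlib.Path(path).stem
    return SummaryStatTable(trait_name=trait_name, records=records, drop_tally=tally)


def _fmt(value) -> str:
    if value is None:
        return "NA"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_sumstats(table: SummaryStatTable, path) -> str:
    """Write a table in the canonical TSV dialect; returns the path.

    Floats are serialized with ``repr`` so that read∘write is the identity
    on valid tables and repeated writes are byte-identical.
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty summary-statistic table")
    lines = ["\t".join(DEFAULT_COLUMNS)]
    for r in table:
        lines.append(
            "\t".join(
                [
                    r.snp_id,
                    r.chrom,
                    str(r.pos),
                    r.effect_allele,
                    r.other_allele,
                    _fmt(r.eaf),
                    _fmt(r.beta),
                    _fmt(r.se),
                    _fmt(r.pval),
                    _fmt(r.n),
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return str(path)


def flip_record(rec: SummaryStatRecord) -> SummaryStatRecord:
    """Swap the allele roles of a record (beta sign and eaf follow)."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=None if rec.eaf is None else 1.0 - rec.eaf,
    )
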