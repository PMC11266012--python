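"""Seeded generator of two-sample GWAS summary statistics with known truth.

Stands in for real GWAS downloads when exercising the MR machinery. Per
SNP j, a minor-allele frequency is drawn uniformly from ``maf_range``, an
instrument effect gamma_j from a normal instrument-strength distribution,
and a pleiotropic effect alpha_j per regime (none; balanced, mean-zero;
directional, nonzero mean; optionally correlated with gamma_j to violate
the InSIDE assumption). The true outcome association is

    Gamma_j = true_beta * gamma_j + alpha_j

and observed betas are the truths plus sampling noise with the standard
GWAS standard error for a standardized trait,

    se = (2 * n * maf * (1 - maf)) ** -0.5.

Samples are non-overlapping and SNPs independent (no LD is simulated;
clumping is exercised on hand-built LD fixtures instead). SNPs are placed
more than one clumping window apart so distance-only clumping keeps all of
them. With ``binary_outcome`` the same SE form is reused on the log-odds
scale as an approximation — adequate for method testing, not a
case-control power model. Identical seeds reproduce identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats import SummaryStatRecord, SummaryStatTable

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_two_sample",
    "simulate_mediation_chain",
]

ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("C", "T"), ("G", "A")]
PALINDROMIC_PAIRS = [("A", "T"), ("C", "G"), ("T", "A"), ("G", "C")]

#: Spacing between simulated SNPs; larger than the clumping window so that
#: independent simulated instruments survive even distance-only clumping.
_POS_SPACING_BP = 20_000_000
_N_CHROM = 22


@dataclass(frozen=True)
class SimulationConfig:
    """Generative parameters for one paired exposure/outcome GWAS.

    ``gamma_dist`` is the (mean, sd) of per-SNP exposure effects in SD
    units; ``pleiotropy`` is ``("none",)``, ``("balanced", sd)`` or
    ``("directional", mean, sd)``. ``inside_violation`` adds a component
    of alpha proportional to gamma, breaking the InSIDE assumption.
    Defaults mirror a well-powered European-ancestry GWAS pair: 100
    genome-wide-significant independent instruments, biobank-scale sample
    sizes, and common variants.
    """

    k: int = 100
    n_exp: int = 300_000
    n_out: int = 200_000
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_dist: tuple[float, float] = (0.2, 0.05)
    true_beta: float = 0.0
    pleiotropy: tuple = ("none",)
    inside_violation: bool = False
    binary_outcome: bool = False
    palindromic_frac: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.gamma_dist[1] < 0:
            raise ValueError("gamma sd must be >= 0")
        if self.pleiotropy[0] not in ("none", "balanced", "directional"):
            raise ValueError(f"unknown pleiotropy regime: {self.pleiotropy[0]!r}")
        if not (0 <= self.palindromic_frac <= 1):
            raise ValueError("palindromic_frac must be in [0, 1]")


@dataclass
class SimulationTruth:
    """Realized generative quantities for recovery tests."""

    config: SimulationConfig
    gamma: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    se_exp: np.ndarray
    se_out: np.ndarray
    snp_ids: list[str]
    extra: dict = field(default_factory=dict)


def _se(n: int, maf: np.ndarray) -> np.ndarray:
    return (2.0 * n * maf * (1.0 - maf)) ** -0.5


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats

    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _draw_alpha(rng: np.random.Generator, cfg: SimulationConfig, gamma: np.ndarray) -> np.ndarray:
    regime = cfg.pleiotropy[0]
    if regime == "none":
        alpha = np.zeros(cfg.k)
    elif regime == "balanced":
        alpha = rng.normal(0.0, cfg.pleiotropy[1], cfg.k)
    else:  # directional
        alpha = rng.normal(cfg.pleiotropy[1], cfg.pleiotropy[2], cfg.k)
    if cfg.inside_violation:
        alpha = alpha + 0.5 * (gamma - np.mean(gamma))
    return alpha


def _positions(k: int):
    for j in range(k):
        chrom = str(j % _N_CHROM + 1)
        pos = 1 + (j // _N_CHROM) * _POS_SPACING_BP
        yield chrom, pos


def _alleles(rng: np.random.Generator, k: int, palindromic_frac: float):
    out = []
    for _ in range(k):
        if rng.random() < palindromic_frac:
            out.append(PALINDROMIC_PAIRS[rng.integers(len(PALINDROMIC_PAIRS))])
        else:
            out.append(ALLELE_PAIRS[rng.integers(len(ALLELE_PAIRS))])
    return out


def _make_table(trait, snp_ids, positions, alleles, maf, beta, se, n, metadata=None):
    pvals = _pvals(beta, se)
    records = []
    for j, sid in enumerate(snp_ids):
        chrom, pos = positions[j]
        ea, oa = alleles[j]
        records.append(
            SummaryStatRecord(
                snp_id=sid,
                chrom=chrom,
                pos=pos,
                effect_allele=ea,
                other_allele=oa,
                eaf=float(maf[j]),
                beta=float(beta[j]),
                se=float(se[j]),
                pval=float(pvals[j]),
                n=float(n),
            )
        )
    return SummaryStatTable(trait_name=trait, records=records, metadata=dict(metadata or {}))


def simulate_two_sample(
    config: SimulationConfig,
    exposure_name: str = "exposure",
    outcome_name: str = "outcome",
) -> tuple[SummaryStatTable, SummaryStatTable, SimulationTruth]:
    """Generate one paired exposure/outcome summary-statistic set."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    k = config.k
    snp_ids = [f"rs{j + 1}" for j in range(k)]
    positions = list(_positions(k))
    alleles = _alleles(rng, k, config.palindromic_frac)
    maf = rng.uniform(*config.maf_range, k)
    gamma = rng.normal(config.gamma_dist[0], config.gamma_dist[1], k)
    alpha = _draw_alpha(rng, config, gamma)
    big_gamma = config.true_beta * gamma + alpha

    se_exp = _se(config.n_exp, maf)
    se_out = _se(config.n_out, maf)
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)

    meta = {"simulated": True, "seed": config.seed}
    exposure = _make_table(exposure_name, snp_ids, positions, alleles, maf, beta_exp, se_exp, config.n_exp, meta)
    outcome = _make_table(outcome_name, snp_ids, positions, alleles, maf, beta_out, se_out, config.n_out, meta)
    truth = SimulationTruth(
        config=config, gamma=gamma, alpha=alpha, maf=maf,
        se_exp=se_exp, se_out=se_out, snp_ids=snp_ids,
    )
    return exposure, outcome, truth


def simulate_mediation_chain(
    config_x_m: SimulationConfig,
    config_m_y: SimulationConfig,
    direct_effect: float,
    seed: int,
    overlap: int = 0,
    exposure_name: str = "exposure",
    mediator_name: str = "mediator",
    outcome_name: str = "outcome",
) -> tuple[SummaryStatTable, SummaryStatTable, SummaryStatTable, SimulationTruth]:
    """Generate an X -> M -> Y chain with known step effects.

    ``config_x_m.true_beta`` is beta1 (X on M) and ``config_m_y.true_beta``
    is beta2 (M on Y); the total X -> Y effect is direct_effect +
    beta1*beta2. ``config_x_m.k`` SNPs instrument the exposure and
    ``config_m_y.k`` the mediator, ``overlap`` of which are drawn from the
    exposure's instruments (given a direct mediator effect too), so step-2
    deduplication removes exactly ``overlap`` SNPs.

    All three tables cover the union of SNPs so every instrument can be
    looked up everywhere. Sample sizes and MAFs follow ``config_x_m`` for
    X and M and ``config_m_y.n_out`` for Y.
    """
    config_x_m.validate()
    config_m_y.validate()
    beta1 = config_x_m.true_beta
    beta2 = config_m_y.true_beta
    k_x, k_m = config_x_m.k, config_m_y.k
    if not (0 <= overlap <= min(k_x, k_m)):
        raise ValueError("overlap must be between 0 and min(k_x, k_m)")

    rng = np.random.default_rng(seed)
    k_total = k_x + (k_m - overlap)
    snp_ids = [f"rs{j + 1}" for j in range(k_total)]
    positions = list(_positions(k_total))
    alleles = _alleles(rng, k_total, config_x_m.palindromic_frac)
    maf = rng.uniform(*config_x_m.maf_range, k_total)

    # gamma_x: effect on X, nonzero for the first k_x SNPs.
    gamma_x = np.zeros(k_total)
    gamma_x[:k_x] = rng.normal(*config_x_m.gamma_dist, k_x)
    # The mediator's designated instruments are `overlap` SNPs shared with
    # the exposure's (associated with M through the causal path beta1) plus
    # the mediator-only SNPs, which carry a direct effect delta on M. Only
    # the latter survive step-2 deduplication, keeping both step estimates
    # free of each other's instruments.
    delta = np.zeros(k_total)
    delta[k_x:] = rng.normal(*config_m_y.gamma_dist, k_m - overlap)
    mediator_idx = list(range(k_x - overlap, k_x)) + list(range(k_x, k_total))

    effect_m = beta1 * gamma_x + delta
    effect_y = direct_effect * gamma_x + beta2 * effect_m

    n_x, n_m, n_y = config_x_m.n_exp, config_x_m.n_out, config_m_y.n_out
    se_x, se_m, se_y = _se(n_x, maf), _se(n_m, maf), _se(n_y, maf)
    beta_x = rng.normal(gamma_x, se_x)
    beta_m = rng.normal(effect_m, se_m)
    beta_y = rng.normal(effect_y, se_y)

    meta = {"simulated": True, "seed": seed}
    tab_x = _make_table(exposure_name, snp_ids, positions, alleles, maf, beta_x, se_x, n_x, meta)
    tab_m = _make_table(mediator_name, snp_ids, positions, alleles, maf, beta_m, se_m, n_m, meta)
    tab_y = _make_table(outcome_name, snp_ids, positions, alleles, maf, beta_y, se_y, n_y, meta)
    truth = SimulationTruth(
        config=config_x_m,
        gamma=gamma_x,
        alpha=np.zeros(k_total),
        maf=maf,
        se_exp=se_x,
        se_out=se_y,
        snp_ids=snp_ids,
        extra={
            "beta1": beta1,
            "beta2": beta2,
            "direct_effect": direct_effect,
            "total_effect": direct_effect + beta1 * beta2,
            "delta": delta,
            "mediator_snp_ids": [snp_ids[i] for i in mediator_idx],
            "overlap_snp_ids": [snp_ids[i] for i in range(k_x - overlap, k_x)],
            "config_m_y": config_m_y,
        },
    )
    return tab_x, tab_m, tab_y, truth
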