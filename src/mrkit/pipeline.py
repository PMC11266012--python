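"""Configuration-driven orchestration of a full summary-level MR study.

A study is: a forward screen (every exposure against the outcome), an
optional reverse screen with relaxed instrument thresholds (and per-trait
overrides), multivariable MR on named exposure groups, and two-step
mediation for configured exposure/mediator pairs. Pairs that fail hard
(e.g. no instruments) are logged and skipped, never fatal to the batch.
Every emitted number is recomputable from the run manifest (config + seed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .estimators import classify_effect, results_to_frame, run_all_methods
from .harmonize import harmonize
from .instruments import (
    DEFAULT_CLUMP_R2,
    DEFAULT_CLUMP_WINDOW_BP,
    DEFAULT_LADDER,
    DEFAULT_MIN_SNPS,
    LDMatrix,
    select_instruments,
)
from .mediation import mediation_to_frame, run_mediation, two_step_mediation
from .mvmr import build_mvmr_input, mvmr_ivw
from .sensitivity import cochran_q, egger_intercept_test, leave_one_out, loo_to_frame
from .sumstats import read_sumstats

logger = logging.getLogger("mrkit")

__all__ = ["AnalysisConfig", "run_screen", "run_full_study", "rederive_decomposition"]

#: Reverse-direction screens start one rung down the ladder: outcome GWAS
#: rarely yield enough genome-wide-significant instruments.
DEFAULT_REVERSE_LADDER = (5e-6, 5e-5)


@dataclass
class AnalysisConfig:
    """Declarative description of a study; loadable from YAML."""

    exposures: dict[str, str]  # name -> sumstats path
    outcome_name: str
    outcome_path: str
    direction: str = "forward"  # forward | reverse | both
    ladder: tuple = DEFAULT_LADDER
    reverse_ladder: tuple = DEFAULT_REVERSE_LADDER
    reverse_ladder_overrides: dict[str, tuple] = field(default_factory=dict)
    min_snps: int = DEFAULT_MIN_SNPS
    clump_window_bp: int = DEFAULT_CLUMP_WINDOW_BP
    clump_r2: float = DEFAULT_CLUMP_R2
    ld_path: str | None = None
    ld_format: str = "sparse"  # sparse | dense
    n_boot: int = 1000
    seed: int = 0
    effects_model: str = "multiplicative_random"
    mvmr_groups: dict[str, list[str]] = field(default_factory=dict)
    mediation_pairs: list[tuple[str, str]] = field(default_factory=list)
    outdir: str = "mr_results"
    fdr_column: bool = True

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        raw["ladder"] = tuple(raw.get("ladder", DEFAULT_LADDER))
        raw["reverse_ladder"] = tuple(raw.get("reverse_ladder", DEFAULT_REVERSE_LADDER))
        raw["reverse_ladder_overrides"] = {
            k: tuple(v) for k, v in raw.get("reverse_ladder_overrides", {}).items()
        }
        raw["mediation_pairs"] = [tuple(p) for p in raw.get("mediation_pairs", [])]
        return cls(**raw)

    def validate(self) -> None:
        for name, p in self.exposures.items():
            if not pathlib.Path(p).exists():
                raise FileNotFoundError(f"exposure {name!r}: no such file {p}")
        if not pathlib.Path(self.outcome_path).exists():
            raise FileNotFoundError(f"outcome: no such file {self.outcome_path}")
        if self.direction not in ("forward", "reverse", "both"):
            raise ValueError(f"direction must be forward/reverse/both, got {self.direction!r}")

    def config_hash(self) -> str:
        blob = json.dumps(self.__dict__, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def load_ld(self) -> LDMatrix | None:
        if self.ld_path is None:
            return None
        if self.ld_format == "dense":
            return LDMatrix.from_dense_tsv(self.ld_path)
        return LDMatrix.from_sparse_tsv(self.ld_path)


def _analyse_pair(
    exp_table, out_table, ladder, config: AnalysisConfig, ld, seed: int
) -> tuple[pd.DataFrame, dict, pd.DataFrame | None]:
    """Instruments -> harmonize -> five methods -> sensitivity -> classify."""
    inst = select_instruments(
        exp_table, ladder=ladder, min_snps=config.min_snps,
        ld=ld, window_bp=config.clump_window_bp, r2_max=config.clump_r2,
    )
    if len(inst) == 0:
        raise ValueError(f"no instruments for {exp_table.trait_name!r} ({inst.warning})")
    h = harmonize(inst, out_table)
    if len(h) == 0:
        raise ValueError(f"no harmonized SNPs for {exp_table.trait_name!r}")
    results, info = run_all_methods(
        h, seed=seed, n_boot=config.n_boot, effects_model=config.effects_model
    )
    frame = results_to_frame(results, exposure=exp_table.trait_name, outcome=out_table.trait_name)
    frame["threshold_used"] = inst.threshold_used
    extras: dict = {
        "exposure": exp_table.trait_name,
        "outcome": out_table.trait_name,
        "nsnp": len(h),
        "threshold_used": inst.threshold_used,
        "direction_consistent": info["direction_consistent"],
        "degraded": info["degraded"],
    }
    loo_frame = None
    if len(h) >= 3:
        q_ivw = cochran_q(h, "ivw")
        q_egg = cochran_q(h, "egger")
        icpt, icpt_se, icpt_p = egger_intercept_test(h)
        extras.update(
            q_ivw=q_ivw.Q, q_ivw_p=q_ivw.pval, q_egger=q_egg.Q, q_egger_p=q_egg.pval,
            egger_intercept=icpt, egger_intercept_se=icpt_se, egger_intercept_p=icpt_p,
        )
    ivw_res = next(r for r in results if r.method in ("ivw", "wald"))
    if ivw_res.method == "ivw":
        cls = classify_effect(ivw_res)
        extras.update(label=cls.label, ivw_p=ivw_res.pval, ivw_or=ivw_res.or_,
                      loo_required=cls.loo_required)
        if cls.loo_required and len(h) >= 3:
            loo_results, loo_flags = leave_one_out(h, effects_model=config.effects_model)
            extras.update(
                loo_sign_stable=loo_flags["sign_stable"],
                loo_significance_stable=loo_flags["significance_stable"],
            )
            loo_frame = loo_to_frame(loo_results)
    return frame, extras, loo_frame


def run_screen(config: AnalysisConfig, direction: str = "forward"):
    """Run every exposure-outcome pair in one direction.

    Returns (results DataFrame, classification DataFrame, skip list,
    dict of leave-one-out DataFrames keyed by trait).
    """
    config.validate()
    ld = config.load_ld()
    outcome = read_sumstats(config.outcome_path, trait_name=config.outcome_name)
    frames, class_rows, skipped, loo_tables = [], [], [], {}
    ss = np.random.SeedSequence(config.seed)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(len(config.exposures))]
    for (name, path), seed in zip(sorted(config.exposures.items()), seeds):
        table = read_sumstats(path, trait_name=name)
        if direction == "forward":
            exp_table, out_table, ladder = table, outcome, config.ladder
        else:
            ladder = config.reverse_ladder_overrides.get(name, config.reverse_ladder)
            exp_table, out_table = outcome, table
        try:
            frame, extras, loo = _analyse_pair(exp_table, out_table, ladder, config, ld, seed)
        except ValueError as exc:
            logger.warning("skipping %s (%s): %s", name, direction, exc)
            skipped.append({"trait": name, "direction": direction, "reason": str(exc)})
            continue
        extras["direction"] = direction
        frames.append(frame)
        class_rows.append(extras)
        if loo is not None:
            loo_tables[name] = loo
    results = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    classification = pd.DataFrame(class_rows)
    if config.fdr_column and not classification.empty and "ivw_p" in classification:
        from statsmodels.stats.multitest import multipletests

        mask = classification["ivw_p"].notna()
        fdr = pd.Series(np.nan, index=classification.index)
        if mask.any():
            fdr[mask] = multipletests(classification.loc[mask, "ivw_p"], method="fdr_bh")[1]
        # Informational only: classification labels always use the raw p.
        classification["ivw_p_fdr"] = fdr
    return results, classification, skipped, loo_tables


def run_full_study(config: AnalysisConfig) -> dict:
    """Forward screen, optional reverse screen, MVMR groups, mediation.

    Writes TSV reports plus a JSON manifest into ``config.outdir`` and
    returns the in-memory tables.
    """
    config.validate()
    outdir = pathlib.Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ld = config.load_ld()
    artifacts: dict = {}

    directions = {"forward": ["forward"], "reverse": ["reverse"], "both": ["forward", "reverse"]}[
        config.direction
    ]
    all_skips = []
    for direction in directions:
        results, classification, skipped, loo_tables = run_screen(config, direction)
        results.to_csv(outdir / f"results_{direction}.tsv", sep="\t", index=False)
        classification.to_csv(outdir / f"classification_{direction}.tsv", sep="\t", index=False)
        for trait, loo in loo_tables.items():
            loo.to_csv(outdir / f"loo_{direction}_{trait}.tsv", sep="\t", index=False)
        artifacts[f"results_{direction}"] = results
        artifacts[f"classification_{direction}"] = classification
        all_skips.extend(skipped)

    outcome = read_sumstats(config.outcome_path, trait_name=config.outcome_name)

    mvmr_frames = []
    for group_name, members in config.mvmr_groups.items():
        try:
            tables = {m: read_sumstats(config.exposures[m], trait_name=m) for m in members}
            isets = {
                m: select_instruments(
                    tables[m], ladder=config.ladder, min_snps=config.min_snps,
                    ld=ld, window_bp=config.clump_window_bp, r2_max=config.clump_r2,
                )
                for m in members
            }
            inp = build_mvmr_input(isets, tables, outcome, ld=ld,
                                   window_bp=config.clump_window_bp, r2_max=config.clump_r2)
            res = mvmr_ivw(inp)
            frame = res.to_frame(outcome=config.outcome_name)
            frame.insert(0, "group", group_name)
            mvmr_frames.append(frame)
        except (ValueError, KeyError) as exc:
            logger.warning("skipping MVMR group %s: %s", group_name, exc)
            all_skips.append({"trait": group_name, "direction": "mvmr", "reason": str(exc)})
    if mvmr_frames:
        mvmr_results = pd.concat(mvmr_frames, ignore_index=True)
        mvmr_results.to_csv(outdir / "results_mvmr.tsv", sep="\t", index=False)
        artifacts["mvmr"] = mvmr_results

    mediation_results = []
    for exp_name, med_name in config.mediation_pairs:
        try:
            run = run_mediation(
                read_sumstats(config.exposures[exp_name], trait_name=exp_name),
                read_sumstats(config.exposures[med_name], trait_name=med_name),
                outcome,
                ladder=config.ladder,
                min_snps=config.min_snps,
                ld=ld,
                effects_model=config.effects_model,
            )
        except (ValueError, KeyError) as exc:
            logger.warning("skipping mediation %s->%s: %s", exp_name, med_name, exc)
            all_skips.append(
                {"trait": f"{exp_name}->{med_name}", "direction": "mediation", "reason": str(exc)}
            )
            continue
        if run.result.mediation_declared:
            mediation_results.append(run.result)
        else:
            logger.info("mediation gate failed for %s->%s: %s",
                        exp_name, med_name, "; ".join(run.result.notes))
            all_skips.append(
                {"trait": f"{exp_name}->{med_name}", "direction": "mediation",
                 "reason": "; ".join(run.result.notes)}
            )
    if mediation_results:
        med_frame = mediation_to_frame(mediation_results)
        med_frame.to_csv(outdir / "results_mediation.tsv", sep="\t", index=False)
        artifacts["mediation"] = med_frame

    manifest = {
        "mrkit_version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": {kk: str(vv) for kk, vv in config.__dict__.items()},
        "skipped": all_skips,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    artifacts["skipped"] = all_skips
    artifacts["manifest"] = manifest
    return artifacts


def rederive_decomposition(inputs: pd.DataFrame, decimals: int = 3) -> pd.DataFrame:
    """Recompute the mediated/direct/proportion columns from step betas.

    ``inputs`` needs columns beta_all, beta1, beta2 (plus optional
    exposure/mediator/outcome labels); returns the full decomposition
    table rounded to display precision.
    """
    results = []
    for row in inputs.itertuples(index=False):
        results.append(
            two_step_mediation(
                beta_all=float(row.beta_all),
                beta1=float(row.beta1),
                beta2=float(row.beta2),
                exposure=str(getattr(row, "exposure", "")),
                mediator=str(getattr(row, "mediator", "")),
                outcome=str(getattr(row, "outcome", "")),
            )
        )
    return mediation_to_frame(results, decimals=decimals)
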