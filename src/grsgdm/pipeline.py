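"""End-to-end orchestration: simulate/load -> QC -> score -> classify -> analyze.

A run directory contains, for one cohort and configuration:

* ``qc_hwe.tsv``        — per-SNP HWE screen of the genotyped panel SNPs
* ``qc_call_rates.tsv`` — per-SNP call rates and their median
* ``scores.csv``        — per-sample FPG and T2D scores (complete-case)
* ``categories.csv``    — WHO 2013 diagnostic subgroup per sample
* ``table3_like.tsv``   — per-group clinical/score summaries and contrasts
* ``table4_like.tsv``   — score-glucose regression grid
* ``figure3_like.tsv``  — per-group mean score with 95% CI and markers
* ``group_summary.tsv`` — median/IQR and mean/SD table per group
* ``run.log``           — n bookkeeping at every filter, seed, config hash

Re-running with the same configuration reproduces every non-log output
byte-for-byte.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import classify as _classify
from . import genotype_io, qc_hwe, scoring, stats
from .panel import (Panel, apply_exclusions, load_exclusion_rules, load_panel,
                    packaged_exclusions, packaged_panel, resolve_proxies)
from .synthetic import SimConfig, simulate_cohort, write_cohort

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration for one pipeline run.

    Either ``sim`` (a synthetic-cohort config) or explicit ``genotypes``/
    ``phenotypes`` paths must be given.
    """

    out_dir: str = "run"
    seed: int = 0
    cohort: str = "HAPO"
    sim: Optional[SimConfig] = None
    genotypes: Optional[str] = None
    genotype_format: str = "tsv"
    phenotypes: Optional[str] = None
    fpg_panel_path: Optional[str] = None
    t2d_panel_path: Optional[str] = None
    exclusions_path: Optional[str] = None
    control_2h_bound: float = _classify.CONTROL_2H_BOUND
    merge_dual_postload: bool = False
    bonferroni_clinical: int = 24
    bonferroni_gs: int = 16
    hwe_alpha: float = 0.05

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        sim = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim is not None:
            for key in ("fpg_gs_postload_effects", "t2d_gs_glucose_effects",
                        "bmi_glucose_effects"):
                if key in sim and isinstance(sim[key], list):
                    sim[key] = tuple(sim[key])
            sim.setdefault("seed", cfg.seed)
            cfg.sim = SimConfig(**sim)
        return cfg

    def validate(self) -> None:
        if self.sim is None and (self.genotypes is None or self.phenotypes is None):
            raise PipelineError("config", "either sim or genotypes+phenotypes "
                                          "must be configured")
        for label, p in (("genotypes", self.genotypes),
                         ("phenotypes", self.phenotypes),
                         ("fpg_panel_path", self.fpg_panel_path),
                         ("t2d_panel_path", self.t2d_panel_path),
                         ("exclusions_path", self.exclusions_path)):
            if p is not None and not Path(p).exists():
                raise PipelineError("config", f"{label} file not found: {p}")


def _load_panels(cfg: RunConfig) -> tuple[Panel, Panel]:
    def one(name, path):
        if path is not None:
            panel = load_panel(path, name)
        else:
            panel = packaged_panel(name)
        if cfg.exclusions_path is not None:
            rules = load_exclusion_rules(cfg.exclusions_path, panel_key=name)
            panel = apply_exclusions(panel, rules, on_missing="warn")
        return resolve_proxies(panel, cfg.cohort)

    return one("FPG", cfg.fpg_panel_path), one("T2D", cfg.t2d_panel_path)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute all stages; returns the populated run directory."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("grsgdm")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    fpg_panel, t2d_panel = _load_panels(cfg)
    logger.info("panels: FPG %d SNPs, T2D %d SNPs (cohort %s)",
                fpg_panel.n_snps, t2d_panel.n_snps, cfg.cohort)

    # --- inputs -----------------------------------------------------------
    try:
        if cfg.sim is not None:
            sim = cfg.sim
            cohort = simulate_cohort(sim, panels=(fpg_panel, t2d_panel))
            write_cohort(cohort, out / "cohort", sim)
            gm_union = cohort.genotypes
            phenotypes = cohort.phenotypes
            logger.info("simulated cohort: %d samples (seed %d, config %s)",
                        gm_union.n_samples, sim.seed, sim.config_hash())
        else:
            frames = []
            gm_union = None
            for panel in (fpg_panel, t2d_panel):
                gm = genotype_io.read_genotypes(cfg.genotypes,
                                                cfg.genotype_format, panel)
                frames.append(gm)
            # merge on union of rsids
            df = frames[0].to_dataframe()
            for gm in frames[1:]:
                extra = gm.to_dataframe()
                for col in extra.columns:
                    if col not in df.columns:
                        df[col] = extra[col]
            gm_union = genotype_io.GenotypeMatrix(
                [str(s) for s in df.index], list(df.columns), df.to_numpy())
            phenotypes = pd.read_csv(cfg.phenotypes, comment="#")
            phenotypes["sample_id"] = phenotypes["sample_id"].astype(str)
            logger.info("read %d samples x %d panel SNPs; %d phenotype rows",
                        gm_union.n_samples, gm_union.n_snps, len(phenotypes))
    except Exception as exc:
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError("input", str(exc)) from exc

    # --- genotyping QC ----------------------------------------------------
    try:
        qc = genotype_io.call_rates(gm_union)
        qc_df = qc.to_dataframe()
        qc_df.to_csv(out / "qc_call_rates.tsv", sep="\t", index=False)
        logger.info("median call rate %.4f over %d SNPs", qc.median_call_rate,
                    gm_union.n_snps)
        results, rules = qc_hwe.hwe_screen(gm_union, alpha=cfg.hwe_alpha)
        qc_hwe.hwe_table(results).to_csv(out / "qc_hwe.tsv", sep="\t",
                                         index=False)
        if rules:
            logger.warning("HWE screen flags %d SNP(s): %s", len(rules),
                           [r.rsid for r in rules])
    except Exception as exc:
        raise PipelineError("qc", str(exc)) from exc

    # --- scoring ----------------------------------------------------------
    try:
        fpg_scores = scoring.score_cohort(gm_union, fpg_panel)
        t2d_scores = scoring.score_cohort(gm_union, t2d_panel)
        scores = scoring.scores_frame(fpg_scores, t2d_scores)
        scores.to_csv(out / "scores.csv", index=False)
        n_dropped = int((~(scores["fpg_complete"] & scores["t2d_complete"])).sum())
        logger.info("scores: %d samples, %d with an incomplete panel",
                    len(scores), n_dropped)
    except Exception as exc:
        raise PipelineError("score", str(exc)) from exc

    # --- classification ---------------------------------------------------
    try:
        categories = _classify.classify_cohort(
            phenotypes, control_2h_bound=cfg.control_2h_bound,
            merge_dual_postload=cfg.merge_dual_postload)
        cat_df = pd.DataFrame({"sample_id": phenotypes["sample_id"],
                               "category": categories.values})
        cat_df.to_csv(out / "categories.csv", index=False)
        logger.info("categories: %s",
                    categories.value_counts().to_dict())
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc

    # --- analysis ---------------------------------------------------------
    try:
        t3 = stats.table3_like(phenotypes, categories, scores,
                               m_clinical=cfg.bonferroni_clinical,
                               m_gs=cfg.bonferroni_gs)
        t3.to_csv(out / "table3_like.tsv", sep="\t", index=False)
        t4 = stats.table4_like(phenotypes, scores, m=cfg.bonferroni_clinical)
        t4.to_csv(out / "table4_like.tsv", sep="\t", index=False)
        f3 = stats.figure3_like(categories, scores, m_gs=cfg.bonferroni_gs)
        f3.to_csv(out / "figure3_like.tsv", sep="\t", index=False)
        summary = _classify.tabulate_groups(phenotypes, categories, scores)
        summary.to_csv(out / "group_summary.tsv", sep="\t")
    except Exception as exc:
        raise PipelineError("analyze", str(exc)) from exc

    logger.info("run complete: %s", out)
    return out


def make_report(run_dir) -> str:
    """Human-readable per-category score summary for a completed run."""
    run_dir = Path(run_dir)
    f3_path = run_dir / "figure3_like.tsv"
    if not f3_path.exists():
        raise PipelineError("report", f"missing {f3_path}; run the pipeline first")
    f3 = pd.read_csv(f3_path, sep="\t")
    lines = ["Mean genetic score by WHO 2013 diagnostic category",
             "(error bounds are 95% CIs; stars: raw p vs controls "
             "<0.05/<0.01/<0.001; + survives Bonferroni)", ""]
    for score, grp in f3.groupby("score", sort=False):
        lines.append(f"{score}:")
        for _, row in grp.iterrows():
            if row["n"] == 0:
                lines.append(f"  {row['category']:>14}: n=0")
                continue
            ci = (f" [{row['ci_low']:.2f}, {row['ci_high']:.2f}]"
                  if pd.notna(row["ci_low"]) else "")
            mark = str(row["stars"]) if pd.notna(row["stars"]) else ""
            if bool(row.get("bonferroni_significant", False)):
                mark += "+"
            lines.append(f"  {row['category']:>14}: n={int(row['n']):>5}  "
                         f"mean={row['mean']:.2f}{ci} {mark}")
        lines.append("")
    text = "\n".join(lines)
    (run_dir / "report.txt").write_text(text, encoding="utf-8")
    return text
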