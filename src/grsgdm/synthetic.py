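"""Synthetic genotype-phenotype cohorts with the structure the analysis assumes.

Individual-level data behind the original cohorts are access-controlled,
so this module generates cohorts that reproduce the *statistical*
assumptions of the analysis rather than any real participant:

* Genotypes are drawn independently per SNP under Hardy-Weinberg
  equilibrium at the panel effect-allele frequencies (linkage
  equilibrium between panel SNPs; loci shared between the two panels are
  simulated as one physical genotype, i.e. one draw per rsid).
* Fasting plasma glucose is built additively from the published
  per-allele effects, so the population regression slope of FPG on the
  FPG score is exactly sum(beta)/N per score unit.  The residual
  variance is solved so the FPG score explains exactly
  ``gs_variance_explained`` (default 6%) of FPG variance.
* The T2D genetic value enters all three glucose measures through its
  component orthogonal to the FPG score (closed-form HWE projection over
  the shared loci), so it associates with glucose without disturbing the
  FPG-score slope.
* 1-hour and 2-hour glucose carry their own linear loadings on both
  genetic values plus residuals correlated across the triplet (default
  correlation 0.5), which reproduces the qualitative attenuation of the
  score-glucose associations under mutual glucose adjustment.
* BMI (lognormal), age (bounded integer) and SBP are generated with
  small couplings to glucose so case groups show the expected covariate
  gradients; setting ``gs_variance_explained = 0`` zeroes every genetic
  loading, giving the null configuration used for calibration checks.

A representative cohort mirrors the population; the case-control style
keeps all WHO 2013 cases and draws three eligible controls per case
(controls defined by FPG < 5.6 mmol/L and/or 2-h glucose < 7.8 mmol/L).
The per-sample latent genetic values are emitted in a separate truth
table that the analysis pipeline never reads.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .classify import classify_cohort
from .genotype_io import GenotypeMatrix
from .panel import Panel, packaged_panel
from .scoring import score_moments

# DIP-style control eligibility bounds (mmol/L)
CC_CONTROL_FPG_BOUND = 5.6
CC_CONTROL_2H_BOUND = 7.8


@dataclass
class SimConfig:
    """Generative parameters for a synthetic cohort.

    Defaults encode the study conditions: a representative cohort of
    n = 2,628, the FPG score explaining 6% of FPG variance, glucose
    centres/spreads anchored to the control-group medians and IQRs, and
    a genotype missingness rate matching the reported median call rate
    0.992.
    """

    n_samples: int = 2628
    cohort_style: str = "representative"   # or "case_control_3to1"
    cohort: str = "HAPO"                   # proxy resolution for panels
    seed: int = 0
    gs_variance_explained: float = 0.06
    fpg_mean: float = 4.5                  # mmol/L
    fpg_sd: float = 0.35                   # total SD used only when r2 = 0
    glu_1h_mean: float = 7.1
    glu_1h_sd: float = 1.5
    glu_2h_mean: float = 5.8
    glu_2h_sd: float = 1.05
    # residual correlation between (FPG, 1-h, 2-h) glucose
    glucose_residual_corr: float = 0.5
    # mmol/L per FPG-GS unit on (1-h, 2-h) glucose
    fpg_gs_postload_effects: tuple[float, float] = (0.060, 0.032)
    # mmol/L per T2D-GS unit (orthogonalised) on (FPG, 1-h, 2-h)
    t2d_gs_glucose_effects: tuple[float, float, float] = (0.004, 0.043, 0.030)
    # covariates
    bmi_log_median: float = 23.5           # kg/m², lognormal median
    bmi_log_sigma: float = 0.18
    bmi_glucose_effects: tuple[float, float, float] = (0.010, 0.040, 0.030)
    age_mean: float = 31.0
    age_sd: float = 5.0
    sbp_mean: float = 108.0
    sbp_sd: float = 9.0
    sbp_fpg_effect: float = 4.0            # mmHg per mmol/L FPG deviation
    missing_rate: float = 0.008
    panel_paths: Optional[dict] = None     # override packaged panels

    def __post_init__(self):
        if not 0 <= self.gs_variance_explained < 1:
            raise ValueError("gs_variance_explained must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")
        if not -1 < self.glucose_residual_corr < 1:
            raise ValueError("glucose residual correlation must lie in (-1, 1)")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("fpg_gs_postload_effects", "t2d_gs_glucose_effects",
                    "bmi_glucose_effects"):
            if key in doc and isinstance(doc[key], list):
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def to_yaml(self, path) -> None:
        doc = asdict(self)
        for k, v in doc.items():
            if isinstance(v, tuple):
                doc[k] = list(v)
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix
    phenotypes: pd.DataFrame
    truth: pd.DataFrame


def load_config_panels(cfg: SimConfig) -> tuple[Panel, Panel]:
    if cfg.panel_paths:
        from .panel import load_panel, resolve_proxies
        fpg = resolve_proxies(load_panel(cfg.panel_paths["fpg"], "FPG"), cfg.cohort)
        t2d = resolve_proxies(load_panel(cfg.panel_paths["t2d"], "T2D"), cfg.cohort)
        return fpg, t2d
    return (packaged_panel("FPG", cohort=cfg.cohort),
            packaged_panel("T2D", cohort=cfg.cohort))


def _union_frequencies(panels: Sequence[Panel]) -> dict[str, float]:
    """rsid -> effect-allele frequency over the union of panels.

    A shared rsid must carry a consistent frequency (and is drawn once).
    """
    freqs: dict[str, float] = {}
    for panel in panels:
        for e in panel.scoreable_entries():
            if e.rsid in freqs and abs(freqs[e.rsid] - e.eaf) > 1e-9:
                raise ValueError(
                    f"shared rsid {e.rsid} has inconsistent frequencies "
                    f"{freqs[e.rsid]} vs {e.eaf} across panels")
            freqs[e.rsid] = e.eaf
    return freqs


def score_cross_covariance(fpg_panel: Panel, t2d_panel: Panel) -> float:
    """Closed-form HWE covariance between the two scores via shared rsids."""
    scale_f = fpg_panel.n_snps / fpg_panel.sum_beta()
    scale_t = t2d_panel.n_snps / t2d_panel.sum_beta()
    t2d_by_rsid = {e.rsid: e for e in t2d_panel.scoreable_entries()}
    cov = 0.0
    for e in fpg_panel.scoreable_entries():
        other = t2d_by_rsid.get(e.rsid)
        if other is not None:
            cov += (scale_f * e.beta) * (scale_t * other.beta) \
                   * 2 * e.eaf * (1 - e.eaf)
    return cov


def simulate_genotypes(panel: Panel, n: int, seed: int,
                       missing_rate: float = 0.0) -> GenotypeMatrix:
    """HWE genotypes for one panel: dosage ~ Binomial(2, eaf) per SNP."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    entries = panel.scoreable_entries()
    eafs = np.array([e.eaf for e in entries])
    dos = rng.binomial(2, eafs, size=(n, len(entries))).astype(float)
    if missing_rate > 0:
        dos[rng.random(dos.shape) < missing_rate] = np.nan
    ids = [f"S{i:06d}" for i in range(1, n + 1)]
    return GenotypeMatrix(ids, [e.rsid for e in entries], dos)


def _simulate_union_genotypes(panels: Sequence[Panel], n: int,
                              rng: np.random.Generator) -> GenotypeMatrix:
    freqs = _union_frequencies(panels)
    rsids = list(freqs)
    eafs = np.array([freqs[r] for r in rsids])
    dos = rng.binomial(2, eafs, size=(n, len(rsids))).astype(float)
    ids = [f"S{i:06d}" for i in range(1, n + 1)]
    return GenotypeMatrix(ids, rsids, dos)


def _genetic_values(gm: GenotypeMatrix, panel: Panel) -> np.ndarray:
    """Score values from a complete genotype matrix (vectorised)."""
    betas = np.array([e.beta for e in panel.scoreable_entries()])
    cols = [gm.snp_ids.index(r) for r in panel.rsids]
    dos = gm.dosages[:, cols]
    if np.isnan(dos).any():
        raise ValueError("phenotype simulation needs complete genotypes")
    return panel.n_snps * (dos @ betas) / betas.sum()


def _residual_sds(cfg: SimConfig, fpg_panel: Panel, t2d_panel: Panel,
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Solve residual SDs for the glucose triplet; return (loadings_f,
    loadings_t_orth, residual_sds, var_t_orth)."""
    _, sd_f = score_moments(fpg_panel)
    _, sd_t = score_moments(t2d_panel)
    var_f, var_t = sd_f**2, sd_t**2
    cov = score_cross_covariance(fpg_panel, t2d_panel)
    var_orth = var_t - cov**2 / var_f

    slope_f = fpg_panel.sum_beta() / fpg_panel.n_snps  # mmol/L per GS unit
    r2 = cfg.gs_variance_explained
    if r2 == 0:
        lf = np.zeros(3)
        lt = np.zeros(3)
        resid = np.array([cfg.fpg_sd, cfg.glu_1h_sd, cfg.glu_2h_sd])
        return lf, lt, resid, var_orth

    lf = np.array([slope_f, *cfg.fpg_gs_postload_effects])
    lt = np.array(cfg.t2d_gs_glucose_effects)
    bmi_eff = np.array(cfg.bmi_glucose_effects)
    var_bmi = _lognormal_var(cfg.bmi_log_median, cfg.bmi_log_sigma)

    # total FPG variance implied by the variance-explained target
    explained_f = slope_f**2 * var_f
    totals = np.array([explained_f / r2, cfg.glu_1h_sd**2, cfg.glu_2h_sd**2])
    resid_var = (totals - lf**2 * var_f - lt**2 * var_orth
                 - bmi_eff**2 * var_bmi)
    if (resid_var <= 0).any():
        bad = ["fpg", "glu_1h", "glu_2h"][int(np.argmin(resid_var))]
        raise ValueError(
            f"unsolvable residual variance for {bad}: genetic + covariate "
            f"loadings exceed the target total variance")
    return lf, lt, np.sqrt(resid_var), var_orth


def _lognormal_var(median: float, sigma: float) -> float:
    mu = np.log(median)
    return float(np.exp(2 * mu + sigma**2) * (np.exp(sigma**2) - 1))


def _lognormal_mean(median: float, sigma: float) -> float:
    return float(median * np.exp(sigma**2 / 2))


def simulate_phenotypes(gm: GenotypeMatrix, fpg_panel: Panel, t2d_panel: Panel,
                        cfg: SimConfig, seed: Optional[int] = None,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate the phenotype table (and truth table) for complete genotypes.

    Returns ``(phenotypes, truth)``: phenotypes has columns
    ``sample_id fpg glu_1h glu_2h bmi age sbp``; truth carries the latent
    genetic values and the category labels implied at generation time.
    """
    rng = np.random.default_rng(cfg.seed + 1 if seed is None else seed)
    n = gm.n_samples
    g_f = _genetic_values(gm, fpg_panel)
    g_t = _genetic_values(gm, t2d_panel)

    mu_f, sd_f = score_moments(fpg_panel)
    mu_t, _ = score_moments(t2d_panel)
    cov = score_cross_covariance(fpg_panel, t2d_panel)
    # component of the T2D value orthogonal to the FPG score (population proj.)
    g_t_orth = (g_t - mu_t) - (cov / sd_f**2) * (g_f - mu_f)

    lf, lt, resid_sd, _ = _residual_sds(cfg, fpg_panel, t2d_panel)

    # covariates
    bmi = np.exp(rng.normal(np.log(cfg.bmi_log_median), cfg.bmi_log_sigma, n))
    bmi_centred = bmi - _lognormal_mean(cfg.bmi_log_median, cfg.bmi_log_sigma)
    age = np.clip(np.round(rng.normal(cfg.age_mean, cfg.age_sd, n)), 18, 45)
    bmi_eff = (np.array(cfg.bmi_glucose_effects)
               if cfg.gs_variance_explained > 0 else np.zeros(3))

    corr = cfg.glucose_residual_corr
    R = np.full((3, 3), corr)
    np.fill_diagonal(R, 1.0)
    chol = np.linalg.cholesky(R)
    eps = rng.standard_normal((n, 3)) @ chol.T * resid_sd

    means = np.array([cfg.fpg_mean, cfg.glu_1h_mean, cfg.glu_2h_mean])
    glucose = (means
               + np.outer(g_f - mu_f, lf)
               + np.outer(g_t_orth, lt)
               + np.outer(bmi_centred, bmi_eff)
               + eps)
    glucose = np.clip(glucose, 0.1, None)  # glucose is physically positive

    fpg = glucose[:, 0]
    sbp = (rng.normal(cfg.sbp_mean, cfg.sbp_sd, n)
           + cfg.sbp_fpg_effect * (fpg - cfg.fpg_mean))

    phenotypes = pd.DataFrame({
        "sample_id": gm.sample_ids,
        "fpg": fpg, "glu_1h": glucose[:, 1], "glu_2h": glucose[:, 2],
        "bmi": bmi, "age": age.astype(int), "sbp": sbp,
    })
    truth = pd.DataFrame({
        "sample_id": gm.sample_ids,
        "fpg_gs_true": g_f, "t2d_gs_true": g_t, "t2d_gs_orth": g_t_orth,
        "category_true": classify_cohort(phenotypes).values,
    })
    return phenotypes, truth


def simulate_cohort(cfg: SimConfig,
                    panels: Optional[tuple[Panel, Panel]] = None,
                    ) -> SyntheticCohort:
    """Full cohort draw: genotypes (with missingness), phenotypes, truth.

    Phenotypes are generated from the pre-missingness genotypes, then
    missing calls are injected at ``cfg.missing_rate``, so score
    completeness filtering downstream behaves as in real data.
    """
    fpg_panel, t2d_panel = panels or load_config_panels(cfg)
    rng = np.random.default_rng(cfg.seed)
    gm = _simulate_union_genotypes([fpg_panel, t2d_panel], cfg.n_samples, rng)
    phenotypes, truth = simulate_phenotypes(
        gm, fpg_panel, t2d_panel, cfg, seed=int(rng.integers(2**31)))
    if cfg.missing_rate > 0:
        dos = gm.dosages.copy()
        dos[rng.random(dos.shape) < cfg.missing_rate] = np.nan
        gm = GenotypeMatrix(gm.sample_ids, gm.snp_ids, dos)
    cohort = SyntheticCohort(gm, phenotypes, truth)
    if cfg.cohort_style == "case_control_3to1":
        cohort = sample_cohort(cohort, "case_control_3to1",
                               seed=int(rng.integers(2**31)))
    return cohort


def sample_cohort(full: SyntheticCohort, style: str, seed: int,
                  ) -> SyntheticCohort:
    """Apply the cohort ascertainment design.

    ``representative`` returns the cohort unchanged.  ``case_control_3to1``
    keeps every WHO 2013 case and draws exactly three eligible controls
    per case (without GDM, and FPG < 5.6 mmol/L and/or 2-h < 7.8 mmol/L);
    an insufficient control pool is an error reporting the deficit.
    """
    if style == "representative":
        return full
    if style != "case_control_3to1":
        raise ValueError(f"unknown cohort style {style!r}")
    ph = full.phenotypes.reset_index(drop=True)
    cat = classify_cohort(ph)
    is_case = cat.isin(["fasting_only", "one_hour_only", "two_hour_only",
                        "combined", "unclassified"]) & (
        (ph["fpg"] >= 5.1) | (ph["glu_1h"] >= 10.0) | (ph["glu_2h"] >= 8.5))
    eligible_control = (~is_case) & (
        (ph["fpg"] < CC_CONTROL_FPG_BOUND) | (ph["glu_2h"] < CC_CONTROL_2H_BOUND))
    n_cases = int(is_case.sum())
    n_need = 3 * n_cases
    pool = np.flatnonzero(eligible_control.to_numpy())
    if len(pool) < n_need:
        raise ValueError(
            f"control pool too small: need {n_need} controls for {n_cases} "
            f"cases, have {len(pool)} (deficit {n_need - len(pool)})")
    rng = np.random.default_rng(seed)
    controls = rng.choice(pool, size=n_need, replace=False)
    keep = np.sort(np.concatenate([np.flatnonzero(is_case.to_numpy()),
                                   controls]))
    ids = [full.genotypes.sample_ids[i] for i in keep]
    gm = GenotypeMatrix(ids, list(full.genotypes.snp_ids),
                        full.genotypes.dosages[keep])
    return SyntheticCohort(gm, ph.iloc[keep].reset_index(drop=True),
                           full.truth.reset_index(drop=True).iloc[keep]
                           .reset_index(drop=True))


def write_cohort(cohort: SyntheticCohort, outdir, cfg: SimConfig) -> None:
    """Write genotypes.tsv, phenotypes.csv and truth.csv with provenance headers.

    The truth file holds the latent generative values; pipeline stages
    never read it.
    """
    from pathlib import Path
    from .genotype_io import write_genotypes_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    header = f"# seed={cfg.seed} config_hash={cfg.config_hash()}\n"
    write_genotypes_tsv(cohort.genotypes, outdir / "genotypes.tsv")
    for name, df in (("phenotypes.csv", cohort.phenotypes),
                     ("truth.csv", cohort.truth)):
        with open(outdir / name, "w", encoding="utf-8") as fh:
            fh.write(header)
            df.to_csv(fh, index=False)
    cfg.to_yaml(outdir / "sim_config.yaml")
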