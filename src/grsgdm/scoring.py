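"""Weighted genetic score construction.

The score for an individual is

    GS = N * sum_i(a_i * beta_i) / sum_i(beta_i)

where a_i is the number of trait-raising (or risk) alleles carried at
SNP i (0, 1 or 2), beta_i its published per-allele weight, and N the
number of SNPs in the panel.  The N/sum(beta) rescaling makes the score
read as an effective risk-allele count: it is bounded by [0, 2N], and an
individual heterozygous at every SNP scores exactly N regardless of the
weights.

Scores are computed for individuals with complete data at all panel SNPs
only; any missing dosage yields a null score (no imputation variant is
offered).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .genotype_io import GenotypeMatrix
from .panel import Panel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneticScoreResult:
    sample_id: str
    panel_name: str
    score: Optional[float]
    n_snps_used: int
    complete: bool


def _panel_weights(panel: Panel) -> tuple[np.ndarray, np.ndarray]:
    entries = panel.scoreable_entries()
    if len(entries) != panel.n_snps:
        bad = [e.rsid for e in panel.entries if not e.scoreable]
        raise ValueError(f"panel {panel.name} has non-scoreable entries {bad}; "
                         f"apply exclusions before scoring")
    betas = np.array([e.beta for e in entries])
    eafs = np.array([e.eaf for e in entries])
    return betas, eafs


def compute_score(dosages: Union[Mapping[str, float], Sequence[float]],
                  panel: Panel, sample_id: str = "") -> GeneticScoreResult:
    """Score one individual from a dosage vector keyed by panel rsids.

    ``dosages`` is either a mapping rsid -> dosage (missing keys or NaN
    values count as missing) or a sequence aligned with ``panel.entries``.
    A single missing dosage gives a null score with ``complete=False``.
    """
    betas, _ = _panel_weights(panel)
    if isinstance(dosages, Mapping):
        vec = np.array([float(dosages.get(r, np.nan)) for r in panel.rsids])
    else:
        vec = np.asarray(dosages, dtype=float)
        if vec.shape != (panel.n_snps,):
            raise ValueError(f"dosage vector length {vec.size} != panel size "
                             f"{panel.n_snps}")
    called = ~np.isnan(vec)
    if not np.isin(vec[called], (0.0, 1.0, 2.0)).all():
        raise ValueError(f"dosages outside {{0,1,2}}: "
                         f"{vec[called][~np.isin(vec[called], (0.0, 1.0, 2.0))]}")
    n_used = int(called.sum())
    if n_used < panel.n_snps:
        return GeneticScoreResult(sample_id, panel.name, None, n_used, False)
    score = panel.n_snps * float(vec @ betas) / float(betas.sum())
    return GeneticScoreResult(sample_id, panel.name, score, n_used, True)


def score_cohort(gm: GenotypeMatrix, panel: Panel) -> list[GeneticScoreResult]:
    """Score every sample in the matrix; one result per sample.

    Raises before any scoring if a panel rsid has no column in the matrix.
    """
    missing = [r for r in panel.rsids if r not in gm.snp_ids]
    if missing:
        raise ValueError(f"panel {panel.name} rsids absent from genotype "
                         f"matrix: {missing}")
    betas, _ = _panel_weights(panel)
    sub = gm.subset_snps(list(panel.rsids))
    called = ~np.isnan(sub.dosages)
    complete = called.all(axis=1)
    raw = np.where(np.isnan(sub.dosages), 0.0, sub.dosages) @ betas
    scores = panel.n_snps * raw / betas.sum()
    results = [
        GeneticScoreResult(sid, panel.name,
                           float(scores[i]) if complete[i] else None,
                           int(called[i].sum()), bool(complete[i]))
        for i, sid in enumerate(sub.sample_ids)
    ]
    n_inc = int((~complete).sum())
    logger.info("panel %s: scored %d samples (%d complete, %d incomplete)",
                panel.name, len(results), len(results) - n_inc, n_inc)
    return results


def score_moments(panel: Panel) -> tuple[float, float]:
    """Closed-form population mean and SD of the score under HWE.

    With independent SNPs and dosage_i ~ Binomial(2, p_i),
    mean = 2N * sum(p beta) / sum(beta) and
    var  = (N / sum(beta))² * sum(2 p (1-p) beta²).
    """
    betas, eafs = _panel_weights(panel)
    scale = panel.n_snps / betas.sum()
    mean = 2 * scale * float(eafs @ betas)
    var = scale**2 * float((2 * eafs * (1 - eafs) * betas**2).sum())
    return mean, math.sqrt(var)


def scores_frame(fpg: Sequence[GeneticScoreResult],
                 t2d: Sequence[GeneticScoreResult]) -> pd.DataFrame:
    """Join per-panel results into the output table.

    Columns: ``sample_id fpg_gs t2d_gs fpg_complete t2d_complete``; scores
    at full float precision (reports round later).
    """
    def frame(results, prefix):
        return pd.DataFrame({
            "sample_id": [r.sample_id for r in results],
            f"{prefix}_gs": [r.score if r.score is not None else np.nan
                             for r in results],
            f"{prefix}_complete": [r.complete for r in results],
        })

    out = frame(fpg, "fpg").merge(frame(t2d, "t2d"), on="sample_id", how="outer")
    return out[["sample_id", "fpg_gs", "t2d_gs", "fpg_complete", "t2d_complete"]]
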