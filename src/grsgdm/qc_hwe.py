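"""Hardy-Weinberg equilibrium screening of panel SNPs.

Each SNP's genotype counts are tested against the HWE expectation
(p², 2pq, q² at the allele frequency estimated from the counts
themselves).  The default test is the 1-df Pearson goodness-of-fit chi²
without continuity correction; an exact test (full enumeration of the
conditional distribution of heterozygote counts given allele counts) is
available for small samples via ``method="exact"``.

Raw P values are Bonferroni-corrected over the m SNPs screened together,
and a SNP is flagged for exclusion when its corrected P falls below the
familywise alpha (default 0.05).  Monomorphic SNPs are never excluded:
the test is undefined there and exclusion would silently shrink the
panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import lgamma, log, exp
from typing import Literal, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import GenotypeMatrix
from .panel import ExclusionRule


@dataclass(frozen=True)
class HweResult:
    rsid: str
    n_hom_effect: int
    n_het: int
    n_hom_other: int
    chi2: float
    p_raw: float
    p_bonferroni: float
    excluded: bool
    monomorphic: bool = False


def hwe_chi2(n_hom_effect: int, n_het: int, n_hom_other: int,
             ) -> tuple[float, float, bool]:
    """1-df Pearson goodness-of-fit chi² against HWE proportions.

    Returns ``(chi2, p_raw, monomorphic)``.  A monomorphic SNP (one allele
    absent) gets chi2 = 0, p = 1 and the flag set.
    """
    counts = (n_hom_effect, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError(f"negative genotype count: {counts}")
    n = sum(counts)
    if n < 1:
        raise ValueError("HWE test requires at least one called genotype")
    p_hat = (2 * n_hom_effect + n_het) / (2 * n)
    if p_hat in (0.0, 1.0):
        return 0.0, 1.0, True
    q_hat = 1 - p_hat
    expected = np.array([p_hat**2, 2 * p_hat * q_hat, q_hat**2]) * n
    observed = np.array(counts, dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1)), False


def hwe_exact(n_hom_effect: int, n_het: int, n_hom_other: int,
              ) -> tuple[float, float, bool]:
    """Exact HWE test by enumerating heterozygote counts given allele counts.

    The P value sums the conditional probabilities of all heterozygote
    counts no more probable than the observed one (the standard exact SNP
    HWE test).  Returned in the same shape as :func:`hwe_chi2`, with the
    chi² slot carrying the observed heterozygote count's probability-based
    statistic set to NaN (the exact test has no chi² statistic).
    """
    n = n_hom_effect + n_het + n_hom_other
    if n < 1:
        raise ValueError("HWE test requires at least one called genotype")
    n_eff = 2 * n_hom_effect + n_het  # effect-allele count
    n_oth = 2 * n - n_eff
    if n_eff == 0 or n_oth == 0:
        return float("nan"), 1.0, True
    rare = min(n_eff, n_oth)
    # heterozygote count shares the parity of the rare allele count
    hets = range(rare % 2, rare + 1, 2)

    def logprob(h: int) -> float:
        # P(het = h | allele counts) up to a constant: n! 2^h /
        # (hom_r! h! hom_c!) with hom_r = (rare - h)/2, hom_c = n - (rare+h)/2
        hom_r = (rare - h) // 2
        hom_c = n - hom_r - h
        return (h * log(2.0) - lgamma(hom_r + 1) - lgamma(h + 1)
                - lgamma(hom_c + 1))

    lps = np.array([logprob(h) for h in hets])
    probs = np.exp(lps - lps.max())
    probs /= probs.sum()
    obs_idx = (n_het - rare % 2) // 2
    p = float(probs[probs <= probs[obs_idx] * (1 + 1e-12)].sum())
    return float("nan"), min(1.0, p), False


def hwe_screen(gm: GenotypeMatrix, alpha: float = 0.05,
               method: Literal["chi2", "exact"] = "chi2",
               ) -> tuple[list[HweResult], list[ExclusionRule]]:
    """Test every SNP in the matrix and emit Bonferroni-based exclusions.

    m for the Bonferroni correction is the number of SNPs screened (the
    candidate panel size).  A SNP is excluded when min(1, m * p_raw) <
    alpha; monomorphic SNPs are retained regardless.
    """
    if gm.n_snps == 0 or gm.n_samples == 0:
        raise ValueError("HWE screen requires a non-empty genotype matrix")
    test = hwe_chi2 if method == "chi2" else hwe_exact
    m = gm.n_snps
    results: list[HweResult] = []
    rules: list[ExclusionRule] = []
    for j, rsid in enumerate(gm.snp_ids):
        col = gm.dosages[:, j]
        col = col[~np.isnan(col)]
        n2 = int((col == 2).sum())
        n1 = int((col == 1).sum())
        n0 = int((col == 0).sum())
        chi2, p_raw, mono = test(n2, n1, n0)
        p_bonf = min(1.0, m * p_raw)
        excluded = (p_bonf < alpha) and not mono
        results.append(HweResult(rsid, n2, n1, n0, chi2, p_raw, p_bonf,
                                 excluded, mono))
        if excluded:
            rules.append(ExclusionRule(rsid=rsid, reason="hwe_failure",
                                       note=f"HWE P(Bonferroni x{m}) = {p_bonf:.3g}"))
    return results, rules


def hwe_table(results: list[HweResult]) -> pd.DataFrame:
    """Results as the TSV-ready table (one row per SNP)."""
    return pd.DataFrame([{
        "rsid": r.rsid, "n_hom_effect": r.n_hom_effect, "n_het": r.n_het,
        "n_hom_other": r.n_hom_other, "chi2": r.chi2, "p_raw": r.p_raw,
        "p_bonferroni": r.p_bonferroni, "excluded": r.excluded,
        "monomorphic": r.monomorphic,
    } for r in results])
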