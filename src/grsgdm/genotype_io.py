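"""Genotype input, effect-allele alignment, and genotyping QC metrics.

Genotypes are held as effect-allele dosages — the number of copies (0, 1
or 2) of the panel's trait-raising/risk allele carried by each sample —
with missing calls stored as NaN.  Hard calls only; fractional imputed
dosages are out of scope.

VCF input is matched to the panel by rsid.  Alleles are aligned to the
panel first as written, then by reverse complement (a strand flip).
Palindromic variants (A/T or C/G pairs) cannot be oriented from alleles
alone; by default they are a hard error, or with
``palindrome_policy="freq"`` they are oriented by comparing the sample
allele frequency with the panel frequency.  Neither shipped panel
contains a palindromic variant, so the default never fires on them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd

from .panel import Panel

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class GenotypeError(ValueError):
    """Unreadable or unalignable genotype input."""


def _revcomp_allele(a: str) -> str:
    return _COMPLEMENT[a]


@dataclass
class GenotypeMatrix:
    """Effect-allele dosages, samples by SNPs.

    ``dosages`` is float (n_samples, n_snps); entries are 0/1/2 or NaN for
    a missing call.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise GenotypeError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs")
        called = self.dosages[~np.isnan(self.dosages)]
        if called.size and not np.isin(called, (0.0, 1.0, 2.0)).all():
            bad = called[~np.isin(called, (0.0, 1.0, 2.0))]
            raise GenotypeError(f"dosages outside {{0,1,2,missing}}: {bad[:5]}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def column(self, rsid: str) -> np.ndarray:
        try:
            j = self.snp_ids.index(rsid)
        except ValueError:
            raise KeyError(rsid) from None
        return self.dosages[:, j]

    def row(self, sample_id: str) -> dict[str, float]:
        i = self.sample_ids.index(sample_id)
        return dict(zip(self.snp_ids, self.dosages[i]))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.dosages, index=pd.Index(self.sample_ids, name="sample_id"),
                            columns=self.snp_ids)

    def subset_snps(self, rsids: Sequence[str]) -> "GenotypeMatrix":
        cols = [self.snp_ids.index(r) for r in rsids]
        return GenotypeMatrix(list(self.sample_ids), list(rsids),
                              self.dosages[:, cols].copy())


@dataclass
class QcReport:
    """Genotyping QC metrics: per-SNP call rates and duplicate concordance."""

    per_snp_call_rate: dict[str, float]
    median_call_rate: float
    duplicate_concordance: Optional[float] = None
    n_duplicate_pairs: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"rsid": list(self.per_snp_call_rate),
                           "call_rate": list(self.per_snp_call_rate.values())})
        return df


def write_genotypes_tsv(gm: GenotypeMatrix, path) -> None:
    """Dosage TSV: rows = samples, columns = rsids, cells in {0,1,2,NA}."""
    df = gm.to_dataframe()
    out = df.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep="\t")


def _read_tsv(path, panel: Panel) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                     keep_default_na=False)
    df = df.replace({"NA": np.nan, "": np.nan})
    extra = [c for c in df.columns if c not in set(panel.rsids)]
    if extra:
        logger.info("ignoring %d file SNP(s) not in panel %s", len(extra),
                    panel.name)
    keep = [r for r in panel.rsids if r in df.columns]
    df = df[keep]
    try:
        dos = df.astype(float).to_numpy()
    except ValueError as exc:
        raise GenotypeError(f"{path}: non-numeric dosage cell: {exc}") from exc
    return GenotypeMatrix([str(s) for s in df.index], keep, dos)


def _orient_vcf_site(rsid: str, ref: str, alt: str, effect: str, other: str,
                     alt_freq: Optional[float], panel_eaf: Optional[float],
                     palindrome_policy: str) -> Optional[bool]:
    """Return True if ALT counts effect alleles, False if REF does.

    Resolution order: alleles as written, then reverse complement; A/T and
    C/G pairs fall through to the palindrome policy.
    """
    if {ref, alt} == {effect, other} and _revcomp_allele(ref) != alt:
        return alt == effect
    rc_ref, rc_alt = _revcomp_allele(ref), _revcomp_allele(alt)
    if {rc_ref, rc_alt} == {effect, other} and _revcomp_allele(ref) != alt:
        return rc_alt == effect
    if _revcomp_allele(ref) == alt and {ref, alt} == {effect, other}:
        # palindromic: strand unknowable from alleles
        if palindrome_policy == "freq":
            if alt_freq is None or panel_eaf is None:
                raise GenotypeError(
                    f"{rsid}: palindromic site and no frequency available "
                    f"to orient it")
            # ALT counts effect alleles iff the sample ALT frequency sits
            # closer to the panel effect-allele frequency than to 1 - eaf
            return abs(alt_freq - panel_eaf) <= abs(alt_freq - (1 - panel_eaf))
        raise GenotypeError(
            f"{rsid}: palindromic alleles {ref}/{alt} cannot be oriented; "
            f"use palindrome_policy='freq' to resolve by frequency")
    return None


def _read_vcf(path, panel: Panel, palindrome_policy: str) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise GenotypeError("cyvcf2 is required for VCF input") from exc
    by_rsid = {e.rsid: e for e in panel.entries if e.scoreable}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    columns: dict[str, np.ndarray] = {}
    n_ignored = 0
    for rec in vcf:
        rsid = rec.ID
        entry = by_rsid.get(rsid)
        if entry is None:
            n_ignored += 1
            continue
        if len(rec.ALT) != 1:
            raise GenotypeError(f"{rsid}: multi-allelic site not supported")
        ref, alt = rec.REF, rec.ALT[0]
        gts = rec.genotype.array()  # (n_samples, ploidy+1)
        alleles = gts[:, :2].astype(float)
        alleles[alleles < 0] = np.nan  # missing
        alt_count = alleles.sum(axis=1)
        with np.errstate(invalid="ignore"):
            af = np.nanmean(alt_count) / 2 if np.isfinite(alt_count).any() else None
        alt_is_effect = _orient_vcf_site(
            rsid, ref, alt, entry.effect_allele, entry.other_allele,
            af, entry.eaf, palindrome_policy)
        if alt_is_effect is None:
            raise GenotypeError(
                f"{rsid}: VCF alleles {ref}/{alt} match neither panel alleles "
                f"{entry.effect_allele}/{entry.other_allele} nor their "
                f"complements")
        columns[rsid] = alt_count if alt_is_effect else 2.0 - alt_count
    if n_ignored:
        logger.info("ignoring %d VCF record(s) not in panel %s", n_ignored,
                    panel.name)
    keep = [r for r in panel.rsids if r in columns]
    dos = (np.column_stack([columns[r] for r in keep])
           if keep else np.empty((len(samples), 0)))
    return GenotypeMatrix(samples, keep, dos)


def read_genotypes(path, format: Literal["vcf", "tsv"], panel: Panel,
                   palindrome_policy: Literal["fail", "freq"] = "fail",
                   ) -> GenotypeMatrix:
    """Read genotypes restricted to panel SNPs, re-encoded as effect-allele dosage.

    TSV input is already effect-allele dosage keyed by rsid; VCF genotypes
    are aligned to the panel's effect allele (see module docstring).  File
    SNPs absent from the panel are ignored with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise GenotypeError(f"genotype file not found: {path}")
    if format == "tsv":
        return _read_tsv(path, panel)
    if format == "vcf":
        return _read_vcf(path, panel, palindrome_policy)
    raise GenotypeError(f"unknown genotype format {format!r}")


def call_rates(gm: GenotypeMatrix) -> QcReport:
    """Per-SNP call rate (called / total samples) and their median."""
    if gm.n_samples == 0:
        raise GenotypeError("call rates undefined for zero samples")
    called = (~np.isnan(gm.dosages)).mean(axis=0)
    per_snp = dict(zip(gm.snp_ids, called.astype(float)))
    return QcReport(per_snp_call_rate=per_snp,
                    median_call_rate=float(np.median(called)))


def duplicate_concordance(gm: GenotypeMatrix,
                          pairs: Sequence[tuple[str, str]],
                          ) -> tuple[float, int, list[tuple[str, str]]]:
    """Concordance of jointly-called genotypes pooled over duplicate pairs.

    Returns ``(concordance, n_pairs_used, flagged_pairs)`` where flagged
    pairs had no jointly-called genotype and were excluded from pooling.
    Raises if a named sample is absent.
    """
    idx = {s: i for i, s in enumerate(gm.sample_ids)}
    agree = total = 0
    flagged: list[tuple[str, str]] = []
    n_used = 0
    for a, b in pairs:
        for s in (a, b):
            if s not in idx:
                raise GenotypeError(f"duplicate pair names absent sample {s!r}")
        da, db = gm.dosages[idx[a]], gm.dosages[idx[b]]
        joint = ~np.isnan(da) & ~np.isnan(db)
        if not joint.any():
            flagged.append((a, b))
            logger.warning("duplicate pair (%s, %s) has no jointly-called "
                           "genotypes; excluded", a, b)
            continue
        agree += int((da[joint] == db[joint]).sum())
        total += int(joint.sum())
        n_used += 1
    if total == 0:
        raise GenotypeError("no jointly-called genotypes in any duplicate pair")
    return agree / total, n_used, flagged


def qc_report(gm: GenotypeMatrix,
              pairs: Optional[Sequence[tuple[str, str]]] = None) -> QcReport:
    """Full QC report: call rates plus (optionally) duplicate concordance."""
    rep = call_rates(gm)
    if pairs:
        conc, n_used, _ = duplicate_concordance(gm, pairs)
        rep.duplicate_concordance = conc
        rep.n_duplicate_pairs = n_used
    return rep
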