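"""SNP weight panels for the fasting-glucose and type 2 diabetes scores.

A panel is an ordered collection of variants, each carrying the allele to
which its published per-allele effect (beta) is aligned, that allele's
population frequency, and the beta itself: mmol/L per allele for the
fasting plasma glucose (FPG) panel, log odds ratio per allele for the
type 2 diabetes (T2D) panel.  Betas are aligned to the trait-raising /
risk allele, so all weights are positive.

Two panels ship as packaged data (15 FPG SNPs, 38 T2D SNPs) together with
the pre-exclusion candidate panels (16 and 41 SNPs) whose extra rows are
the variants dropped for Hardy-Weinberg failure or a BMI-primary effect.
Those candidate rows carry no published beta/frequency and are marked
non-scoreable.

Some variants were genotyped through a high-LD proxy in the representative
cohort; :func:`resolve_proxies` swaps in the proxy's identity, alleles and
frequency while keeping the index variant's beta, as the original analysis
did.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Optional, Sequence

import yaml

logger = logging.getLogger(__name__)

VALID_ALLELES = frozenset("ACGT")

#: reasons a candidate variant may be dropped before scoring
EXCLUSION_REASONS = ("hwe_failure", "bmi_primary_effect", "other")

PANEL_COLUMNS = [
    "rsid", "proxy_rsid", "chrom", "pos", "locus",
    "effect_allele", "other_allele", "eaf", "beta", "source",
    "proxy_effect_allele", "proxy_other_allele", "proxy_eaf",
]


class PanelValidationError(ValueError):
    """A panel file or entry violates the panel contract."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One weighted variant of a score panel.

    ``beta`` is the per-allele weight aligned to ``effect_allele``; ``eaf``
    is that allele's frequency.  Entries from a candidate file that only
    name an excluded variant have ``beta is None`` / ``eaf is None`` and are
    non-scoreable.
    """

    rsid: str
    chrom: str
    pos: Optional[int]
    locus: str
    effect_allele: Optional[str]
    other_allele: Optional[str]
    eaf: Optional[float]
    beta: Optional[float]
    source: str = ""
    proxy_rsid: Optional[str] = None
    proxy_effect_allele: Optional[str] = None
    proxy_other_allele: Optional[str] = None
    proxy_eaf: Optional[float] = None

    @property
    def scoreable(self) -> bool:
        return self.beta is not None and self.eaf is not None

    @property
    def has_proxy(self) -> bool:
        return self.proxy_rsid is not None

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G allele pair: strand orientation unresolvable from alleles."""
        comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
        if self.effect_allele is None or self.other_allele is None:
            return False
        return comp[self.effect_allele] == self.other_allele

    def validate(self, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if not self.rsid:
            raise PanelValidationError(f"empty rsid{where}")
        if self.scoreable:
            for label, allele in (("effect", self.effect_allele),
                                  ("other", self.other_allele)):
                if allele not in VALID_ALLELES:
                    raise PanelValidationError(
                        f"{self.rsid}: {label} allele {allele!r} not one of "
                        f"A/C/G/T{where}")
            if self.effect_allele == self.other_allele:
                raise PanelValidationError(
                    f"{self.rsid}: effect and other allele identical{where}")
            if not self.beta > 0:
                raise PanelValidationError(
                    f"{self.rsid}: beta {self.beta} must be > 0 (weights are "
                    f"aligned to the raising/risk allele){where}")
            if not 0 < self.eaf < 1:
                raise PanelValidationError(
                    f"{self.rsid}: effect-allele frequency {self.eaf} outside "
                    f"(0, 1){where}")


@dataclass(frozen=True)
class ExclusionRule:
    rsid: str
    reason: str
    note: str = ""

    def __post_init__(self):
        if self.reason not in EXCLUSION_REASONS:
            raise PanelValidationError(
                f"exclusion reason {self.reason!r} not in {EXCLUSION_REASONS}")


@dataclass(frozen=True)
class Panel:
    """An ordered, validated SNP weight panel."""

    name: str  # "FPG" or "T2D"
    entries: tuple[SnpPanelEntry, ...]

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.rsid in seen:
                raise PanelValidationError(f"duplicate rsid {e.rsid} in panel")
            seen.add(e.rsid)

    @property
    def n_snps(self) -> int:
        return len(self.entries)

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(e.rsid for e in self.entries)

    @property
    def units(self) -> str:
        """Units of the per-allele weights (metadata only)."""
        return "mmol/L per allele" if self.name == "FPG" else "log(OR) per allele"

    def scoreable_entries(self) -> tuple[SnpPanelEntry, ...]:
        return tuple(e for e in self.entries if e.scoreable)

    def sum_beta(self) -> float:
        return sum(e.beta for e in self.scoreable_entries())

    def entry(self, rsid: str) -> SnpPanelEntry:
        for e in self.entries:
            if e.rsid == rsid:
                return e
        raise KeyError(rsid)


def _opt(value: str) -> Optional[str]:
    value = value.strip()
    return value or None


def load_panel(path, name: str, allow_incomplete: bool = False) -> Panel:
    """Load and validate a panel TSV.

    Parameters
    ----------
    path : path-like
        Tab-separated file with header ``PANEL_COLUMNS`` (the three proxy
        detail columns may be absent).
    name : str
        Panel label, conventionally ``"FPG"`` or ``"T2D"``.
    allow_incomplete : bool
        Accept rows with empty eaf/beta (candidate files listing excluded
        variants without published weights).  Default False: every row must
        be fully populated and valid.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise PanelValidationError(f"{path}: empty panel file")
    header = lines[0].rstrip("\n").split("\t")
    required = PANEL_COLUMNS[:10]
    if header[: len(required)] != required:
        raise PanelValidationError(
            f"{path}: header {header[:10]} does not match expected {required}")
    idx = {col: i for i, col in enumerate(header)}
    entries = []
    for rownum, line in enumerate(lines[1:], start=2):
        fields = line.rstrip("\n").split("\t")
        # pad optional trailing columns
        fields += [""] * (len(header) - len(fields))
        if len(fields) > len(header):
            raise PanelValidationError(
                f"{path}: row {rownum} has {len(fields)} fields, header has "
                f"{len(header)}")

        def get(col):
            return fields[idx[col]].strip() if col in idx else ""

        eaf_s, beta_s = get("eaf"), get("beta")
        incomplete = not eaf_s or not beta_s
        if incomplete and not allow_incomplete:
            raise PanelValidationError(
                f"{path}: row {rownum} ({get('rsid')}) missing eaf/beta; "
                f"pass allow_incomplete=True for candidate files")
        try:
            entry = SnpPanelEntry(
                rsid=get("rsid"),
                proxy_rsid=_opt(get("proxy_rsid")),
                chrom=get("chrom"),
                pos=int(get("pos")) if get("pos") else None,
                locus=get("locus"),
                effect_allele=_opt(get("effect_allele")),
                other_allele=_opt(get("other_allele")),
                eaf=float(eaf_s) if eaf_s else None,
                beta=float(beta_s) if beta_s else None,
                source=get("source"),
                proxy_effect_allele=_opt(get("proxy_effect_allele")),
                proxy_other_allele=_opt(get("proxy_other_allele")),
                proxy_eaf=float(get("proxy_eaf")) if get("proxy_eaf") else None,
            )
        except ValueError as exc:
            raise PanelValidationError(f"{path}: row {rownum}: {exc}") from exc
        entry.validate(row=rownum)
        entries.append(entry)
    if not entries:
        raise PanelValidationError(f"{path}: panel has no entries")
    return Panel(name=name, entries=tuple(entries))


def write_panel(panel: Panel, path) -> None:
    """Write a panel TSV that :func:`load_panel` round-trips field-for-field."""
    def fmt(v):
        if v is None:
            return ""
        if isinstance(v, float):
            return f"{v:g}"
        return str(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(PANEL_COLUMNS) + "\n")
        for e in panel.entries:
            fh.write("\t".join(fmt(getattr(e, col)) for col in PANEL_COLUMNS) + "\n")


def apply_exclusions(panel: Panel, rules: Iterable[ExclusionRule],
                     on_missing: Literal["fail", "warn"] = "fail") -> Panel:
    """Return a new panel without the variants named by ``rules``.

    The input panel is unchanged.  A rule naming an rsid absent from the
    panel raises by default (``on_missing="warn"`` logs instead).  Each
    applied exclusion is logged.
    """
    rules = list(rules)
    by_rsid = {r.rsid: r for r in rules}
    present = set(panel.rsids)
    for r in rules:
        if r.rsid not in present:
            msg = f"exclusion rule names {r.rsid}, absent from panel {panel.name}"
            if on_missing == "fail":
                raise PanelValidationError(msg)
            logger.warning(msg)
    kept = []
    for e in panel.entries:
        rule = by_rsid.get(e.rsid)
        if rule is None:
            kept.append(e)
        else:
            logger.info("panel %s: excluding %s (%s%s)", panel.name, e.rsid,
                        rule.reason, f": {rule.note}" if rule.note else "")
    return Panel(name=panel.name, entries=tuple(kept))


def resolve_proxies(panel: Panel, cohort: str) -> Panel:
    """Swap each proxied variant's identity for its proxy in the HAPO-style cohort.

    For ``cohort="HAPO"`` every entry with a proxy has its rsid, alleles and
    frequency replaced by the proxy's, while the beta is retained unchanged
    (the published weight is reused for the proxy).  Any other cohort label
    returns the panel unchanged.  Panel size and all betas are invariant.
    """
    if cohort.upper() != "HAPO":
        return panel
    resolved = []
    for e in panel.entries:
        if not e.has_proxy:
            resolved.append(e)
            continue
        if (e.proxy_effect_allele is None or e.proxy_other_allele is None
                or e.proxy_eaf is None):
            raise PanelValidationError(
                f"{e.rsid}: proxy {e.proxy_rsid} requested but proxy "
                f"alleles/frequency are absent")
        resolved.append(replace(
            e,
            rsid=e.proxy_rsid,
            effect_allele=e.proxy_effect_allele,
            other_allele=e.proxy_other_allele,
            eaf=e.proxy_eaf,
            proxy_rsid=None,
            proxy_effect_allele=None,
            proxy_other_allele=None,
            proxy_eaf=None,
        ))
    return Panel(name=panel.name, entries=tuple(resolved))


def load_exclusion_rules(path, panel_key: Optional[str] = None) -> list[ExclusionRule]:
    """Read exclusion rules from YAML.

    Accepts either a flat list under ``exclusions`` or a mapping of panel
    key (``fpg``/``t2d``) to lists, in which case ``panel_key`` selects one.
    """
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    block = doc["exclusions"]
    if isinstance(block, dict):
        if panel_key is None:
            raise ValueError("exclusions file is keyed by panel; pass panel_key")
        block = block.get(panel_key.lower(), [])
    return [ExclusionRule(rsid=d["rsid"], reason=d["reason"],
                          note=d.get("note", "")) for d in block]


def _data_path(filename: str):
    return resources.files("grsgdm.data").joinpath(filename)


def packaged_panel(name: str, candidates: bool = False,
                   cohort: Optional[str] = None) -> Panel:
    """Load a packaged panel by name ("FPG" or "T2D").

    ``candidates=True`` returns the pre-exclusion candidate panel (16 or 41
    variants, the excluded ones non-scoreable).  ``cohort`` optionally
    resolves proxies ("HAPO") on the post-exclusion panel.
    """
    key = name.upper()
    if key not in ("FPG", "T2D"):
        raise ValueError(f"unknown panel {name!r}; expected FPG or T2D")
    stem = key.lower() + ("_candidates" if candidates else "_panel")
    with resources.as_file(_data_path(stem + ".tsv")) as p:
        panel = load_panel(p, key, allow_incomplete=candidates)
    if cohort is not None and not candidates:
        panel = resolve_proxies(panel, cohort)
    return panel


def packaged_exclusions(name: str) -> list[ExclusionRule]:
    """The shipped footnote exclusions for a panel ("FPG" or "T2D")."""
    with resources.as_file(_data_path("default_exclusions.yaml")) as p:
        return load_exclusion_rules(p, panel_key=name)
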