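"""WHO 2013 gestational-diabetes diagnostic subgroups from OGTT triplets.

The WHO 2013 (IADPSG 2010) case thresholds are fasting plasma glucose
(FPG) >= 5.1 mmol/L, 1-hour glucose >= 10.0 mmol/L and 2-hour glucose
>= 8.5 mmol/L after a 75 g oral glucose load, all inclusive.  Cases are
split into mutually exclusive analysis groups:

* ``fasting_only``  — FPG >= 5.1, 1-h < 10, 2-h < 8.5
* ``one_hour_only`` — 1-h >= 10, FPG < 5.1, 2-h < 8.5
* ``two_hour_only`` — 2-h >= 8.5, FPG < 5.1, 1-h < 10
* ``combined``      — FPG >= 5.1 and (1-h >= 10 or 2-h >= 8.5)

Controls require FPG < 5.1, 1-h < 10 and 2-h below a configurable bound:
7.8 mmol/L by default (the stricter of the two bounds the source
analyses state; the alternative 8.5 makes controls the complement of the
case groups).  Everything else is ``unclassified`` — under the default
bound that is the 7.8 <= 2-h < 8.5 non-case band, plus women with both
post-load values raised but a normal FPG, whose grouping the published
definitions leave open (``merge_dual_postload=True`` folds them into a
broadened combined group instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np
import pandas as pd

FPG_THRESHOLD = 5.1      # mmol/L, case criterion
ONE_HOUR_THRESHOLD = 10.0
TWO_HOUR_THRESHOLD = 8.5
CONTROL_2H_BOUND = 7.8   # mmol/L, default control upper bound

CASE_GROUPS = ("fasting_only", "one_hour_only", "two_hour_only", "combined")


class GdmCategory(str, Enum):
    CONTROL = "control"
    FASTING_ONLY = "fasting_only"
    ONE_HOUR_ONLY = "one_hour_only"
    TWO_HOUR_ONLY = "two_hour_only"
    COMBINED = "combined"
    UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class PhenotypeRecord:
    """OGTT glucose triplet (mmol/L) plus optional covariates for one pregnancy."""

    sample_id: str
    fpg: float
    glu_1h: float
    glu_2h: float
    bmi: Optional[float] = None   # kg/m², pre-pregnancy
    age: Optional[float] = None   # years
    sbp: Optional[float] = None   # mmHg


def assign_category(rec: PhenotypeRecord,
                    control_2h_bound: float = CONTROL_2H_BOUND,
                    merge_dual_postload: bool = False) -> GdmCategory:
    """Assign the diagnostic subgroup for one complete glucose triplet."""
    for name in ("fpg", "glu_1h", "glu_2h"):
        v = getattr(rec, name)
        if v is None or not np.isfinite(v):
            raise ValueError(f"{rec.sample_id or 'record'}: missing or "
                             f"non-finite glucose value {name}")
    return _categorise(rec.fpg, rec.glu_1h, rec.glu_2h, control_2h_bound,
                       merge_dual_postload)


def _categorise(fpg: float, g1: float, g2: float, control_2h_bound: float,
                merge_dual_postload: bool) -> GdmCategory:
    fast = fpg >= FPG_THRESHOLD
    one = g1 >= ONE_HOUR_THRESHOLD
    two = g2 >= TWO_HOUR_THRESHOLD
    if fast:
        return GdmCategory.COMBINED if (one or two) else GdmCategory.FASTING_ONLY
    if one and two:
        return (GdmCategory.COMBINED if merge_dual_postload
                else GdmCategory.UNCLASSIFIED)
    if one:
        return GdmCategory.ONE_HOUR_ONLY
    if two:
        return GdmCategory.TWO_HOUR_ONLY
    if g2 < control_2h_bound:
        return GdmCategory.CONTROL
    return GdmCategory.UNCLASSIFIED


def classify_cohort(phenotypes: pd.DataFrame,
                    control_2h_bound: float = CONTROL_2H_BOUND,
                    merge_dual_postload: bool = False) -> pd.Series:
    """Vectorised category assignment for a phenotype table.

    ``phenotypes`` needs columns ``fpg``, ``glu_1h``, ``glu_2h``.  Returns a
    Series of category strings aligned with the input index.
    """
    for col in ("fpg", "glu_1h", "glu_2h"):
        if col not in phenotypes.columns:
            raise ValueError(f"phenotype table lacks column {col!r}")
        if phenotypes[col].isna().any():
            bad = phenotypes.index[phenotypes[col].isna()][:5].tolist()
            raise ValueError(f"missing {col} for records {bad}")
    fpg = phenotypes["fpg"].to_numpy(float)
    g1 = phenotypes["glu_1h"].to_numpy(float)
    g2 = phenotypes["glu_2h"].to_numpy(float)
    fast, one, two = (fpg >= FPG_THRESHOLD, g1 >= ONE_HOUR_THRESHOLD,
                      g2 >= TWO_HOUR_THRESHOLD)
    dual = ~fast & one & two
    out = np.select(
        [fast & (one | two),
         fast,
         dual,
         one,
         two,
         g2 < control_2h_bound],
        [GdmCategory.COMBINED.value,
         GdmCategory.FASTING_ONLY.value,
         (GdmCategory.COMBINED.value if merge_dual_postload
          else GdmCategory.UNCLASSIFIED.value),
         GdmCategory.ONE_HOUR_ONLY.value,
         GdmCategory.TWO_HOUR_ONLY.value,
         GdmCategory.CONTROL.value],
        default=GdmCategory.UNCLASSIFIED.value,
    )
    return pd.Series(out, index=phenotypes.index, name="category")


def is_gdm_case(category: pd.Series) -> pd.Series:
    return category.isin(CASE_GROUPS)


_CLINICAL = ["fpg", "glu_1h", "glu_2h", "age", "bmi", "sbp"]
_SCORES = ["fpg_gs", "t2d_gs"]


def tabulate_groups(phenotypes: pd.DataFrame, categories: pd.Series,
                    scores: Optional[pd.DataFrame] = None) -> pd.DataFrame:
    """Per-group summary: median (IQR) of clinical variables, mean (SD) of scores.

    One column per category (all six always emitted, empty ones with n=0);
    rows are ``<var>_median/_q1/_q3/_n`` for clinical variables present in
    the input and ``<gs>_mean/_sd/_n`` for scores when given (joined on
    ``sample_id``).
    """
    df = phenotypes.copy()
    df["category"] = categories.values
    if scores is not None:
        df = df.merge(scores, on="sample_id", how="left")
    rows: dict[str, dict[str, float]] = {}
    order = [c.value for c in GdmCategory]
    for cat in order:
        grp = df[df["category"] == cat]
        col: dict[str, float] = {"n": len(grp)}
        for var in _CLINICAL:
            if var not in df.columns:
                continue
            vals = grp[var].dropna()
            col[f"{var}_n"] = len(vals)
            if len(vals):
                col[f"{var}_median"] = float(vals.median())
                col[f"{var}_q1"] = float(vals.quantile(0.25))
                col[f"{var}_q3"] = float(vals.quantile(0.75))
            else:
                col[f"{var}_median"] = col[f"{var}_q1"] = col[f"{var}_q3"] = np.nan
        for var in _SCORES:
            if var not in df.columns:
                continue
            vals = grp[var].dropna()
            col[f"{var}_n"] = len(vals)
            col[f"{var}_mean"] = float(vals.mean()) if len(vals) else np.nan
            col[f"{var}_sd"] = (float(vals.std(ddof=1)) if len(vals) > 1
                                else np.nan)
        rows[cat] = col
    return pd.DataFrame(rows)
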