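"""Subgroup comparisons of the surveillance score.

Stratified DSS means over child/mother characteristics with rank-sum
significance testing, plus the small derived covariates used throughout:
the postpartum-depression flag from the Edinburgh Postnatal Depression
Scale (total >= 10 or a nonzero self-harm item) and the prematurity
categories from gestational age.

The Mann-Whitney U test is implemented with midranks throughout: an exact
two-sided p by full enumeration of label arrangements for small samples
(combined n <= 20), and a tie-corrected normal approximation with
continuity correction otherwise.  Score data are heavily tied at 0, so the
tie handling is not optional.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

CHILD_COLUMNS = (
    "child_id", "sex", "gestational_age", "birth_weight", "birth_order",
    "maternal_age", "maternal_education", "epds_total", "epds_q10", "dev_tracking",
)

#: stratification bins used in the figure-style subgroup analyses
BIRTH_WEIGHT_BINS = (1.0, 2.5, 3.0, 3.5, 4.0, 4.5, 6.0)
MATERNAL_AGE_BINS = (18.0, 40.0, 50.0)

EDUCATION_LEVELS = ("academic", "tertiary", "high_school", "elementary")


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class PretermCategory(str, Enum):
    EXTREMELY_PRETERM = "extremely_preterm"
    VERY_PRETERM = "very_preterm"
    LATE_PRETERM = "late_preterm"
    EARLY_TERM = "early_term"
    FULL_TERM = "full_term"


@dataclass(frozen=True)
class ChildCovariates:
    """Covariate record for one child; unknown values are ``None``."""

    child_id: str
    sex: Sex
    gestational_age: float | None = None
    birth_weight: float | None = None
    birth_order: int | None = None
    maternal_age: float | None = None
    maternal_education: str | None = None
    epds_total: int | None = None
    epds_q10: int | None = None
    dev_tracking: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sex", Sex(self.sex))
        ga, bw = self.gestational_age, self.birth_weight
        if ga is not None and not 20 <= ga <= 45:
            raise ValueError(f"child {self.child_id!r}: gestational age {ga} outside [20, 45] weeks")
        if bw is not None and not 0.3 <= bw <= 7:
            raise ValueError(f"child {self.child_id!r}: birth weight {bw} outside [0.3, 7] kg")


@dataclass(frozen=True)
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    u_statistic: float     # U of sample a; U_a + U_b == n_a * n_b
    p_value: float


def load_children(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"child_id": str})
    missing = set(CHILD_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"children file {path}: missing columns {sorted(missing)}")
    frame["dev_tracking"] = frame["dev_tracking"].astype(int).astype(bool)
    return frame


def ppd_flag(epds_total: float | None, epds_q10: float | None) -> bool | None:
    """Postpartum-depression screen: total >= 10 or nonzero self-harm item.

    ``None`` (unknown) when both inputs are missing.
    """
    total_known = epds_total is not None and not (
        isinstance(epds_total, float) and math.isnan(epds_total))
    q10_known = epds_q10 is not None and not (
        isinstance(epds_q10, float) and math.isnan(epds_q10))
    if not total_known and not q10_known:
        return None
    flag = False
    if total_known and epds_total >= 10:
        flag = True
    if q10_known and epds_q10 != 0:
        flag = True
    return flag


def ppd_flag_series(children: pd.DataFrame) -> pd.Series:
    """Vectorized :func:`ppd_flag` over a children table (nullable boolean)."""
    total, q10 = children["epds_total"], children["epds_q10"]
    flag = (total >= 10).fillna(False) | ((q10 != 0) & q10.notna())
    out = flag.astype("boolean")
    out[total.isna() & q10.isna()] = pd.NA
    return out.rename("ppd")


def preterm_category(gestational_age: float) -> PretermCategory:
    """Prematurity category from gestational age in completed weeks."""
    ga = float(gestational_age)
    if math.isnan(ga):
        raise ValueError("gestational age is missing")
    if ga < 27:
        return PretermCategory.EXTREMELY_PRETERM
    if ga < 32:
        return PretermCategory.VERY_PRETERM
    if ga < 37:
        return PretermCategory.LATE_PRETERM
    if ga < 39:
        return PretermCategory.EARLY_TERM
    return PretermCategory.FULL_TERM


def drop_preterm(children: pd.DataFrame) -> pd.DataFrame:
    """Children born at >= 37 completed weeks with known gestational age.

    Every subgroup analysis except the gestational-age stratification runs
    on this restriction.
    """
    ga = children["gestational_age"]
    return children.loc[ga.notna() & (ga >= 37)]


def _exact_p(ranks: np.ndarray, n_a: int, u_obs: float) -> float:
    """Two-sided exact p for U by full enumeration of label arrangements."""
    n = ranks.size
    base = n_a * (n_a + 1) / 2.0
    us = [sum(combo) - base for combo in combinations(ranks, n_a)]
    us = np.asarray(us)
    total = us.size
    tol = 1e-9
    p_low = np.count_nonzero(us <= u_obs + tol) / total
    p_high = np.count_nonzero(us >= u_obs - tol) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def mann_whitney(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    exact_max_n: int = 20,
    label_a: str = "a",
    label_b: str = "b",
) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two samples.

    Midranks are used throughout.  For combined n <= ``exact_max_n`` the
    p-value is exact (enumeration of all label arrangements of the midranked
    pooled sample); otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    if n <= exact_max_n:
        p = _exact_p(ranks, n_a, u_a)
    else:
        mu = n_a * n_b / 2.0
        _, tie_counts = np.unique(pooled, return_counts=True)
        tie_term = float((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
        if var <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / math.sqrt(var)
            p = min(1.0, 2.0 * sps.norm.sf(max(z, 0.0)))
    return GroupComparison(
        group_a=label_a, group_b=label_b, n_a=n_a, n_b=n_b,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        u_statistic=float(u_a), p_value=float(p),
    )


def pearson(x: Sequence[float], y: Sequence[float]) -> float | None:
    """Product-moment correlation; ``None`` if either input has zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError(f"length mismatch: {x.size} vs {y.size}")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    return float(sps.pearsonr(x, y).statistic)


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class Stratifier:
    """How to split children into strata for a subgroup comparison.

    Either ``bins`` (numeric edges, right-open except the last bin) or
    ``categories`` (explicit ordered category values) on ``column``.
    Values outside the bins fall into no stratum and are excluded; children
    missing the column are excluded from this stratification only.
    """

    column: str
    bins: tuple[float, ...] | None = None
    categories: tuple[str, ...] | None = None

    def assign(self, values: pd.Series) -> pd.Series:
        if (self.bins is None) == (self.categories is None):
            raise ValueError("exactly one of bins/categories must be given")
        if self.bins is not None:
            labels = [f"{lo:g}-{hi:g}" for lo, hi in zip(self.bins, self.bins[1:])]
            return pd.cut(values, bins=list(self.bins), labels=labels,
                          right=False, include_lowest=True).astype(object)
        cats = pd.Series(values, copy=True).astype(object)
        cats[~cats.isin(self.categories)] = None
        return cats

    def ordered_strata(self) -> list[str]:
        if self.bins is not None:
            return [f"{lo:g}-{hi:g}" for lo, hi in zip(self.bins, self.bins[1:])]
        return list(self.categories)


def stratified_means(
    scores: pd.DataFrame,
    children: pd.DataFrame,
    stratifier: Stratifier,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-stratum DSS means with pairwise rank-sum significance.

    ``scores`` is a :func:`dss.scoring.score_table` result.  Only defined
    cells (``n_attempts > 0``) enter.  Returns ``(means, comparisons)``:
    means has one row per (window, group, stratum) — empty strata are kept
    with n=0, never dropped silently — and comparisons holds the
    Mann-Whitney results with significance stars for each requested pair
    (default: consecutive strata).
    """
    strata = stratifier.assign(children[stratifier.column])
    members = children.assign(stratum=strata).dropna(subset=["stratum"])
    merged = scores.loc[scores["n_attempts"] > 0].merge(
        members[["child_id", "stratum"]], on="child_id", how="inner"
    )
    order = stratifier.ordered_strata()
    if pairs is None:
        pairs = list(zip(order, order[1:]))

    mean_rows, cmp_rows = [], []
    for (ws, we, grp), cell in merged.groupby(
        ["window_start", "window_end", "group"], sort=True
    ):
        by_stratum = {s: sub["dss"].to_numpy() for s, sub in cell.groupby("stratum")}
        for s in order:
            vals = by_stratum.get(s, np.empty(0))
            mean_rows.append({
                "window_start": ws, "window_end": we, "group": grp, "stratum": s,
                "n": int(vals.size),
                "mean_dss": float(vals.mean()) if vals.size else np.nan,
            })
        for s_a, s_b in pairs:
            va, vb = by_stratum.get(s_a, np.empty(0)), by_stratum.get(s_b, np.empty(0))
            if va.size == 0 or vb.size == 0:
                cmp_rows.append({
                    "window_start": ws, "window_end": we, "group": grp,
                    "stratum_a": s_a, "stratum_b": s_b, "n_a": int(va.size),
                    "n_b": int(vb.size), "u_statistic": np.nan,
                    "p_value": np.nan, "stars": "",
                })
                continue
            comp = mann_whitney(va, vb, label_a=str(s_a), label_b=str(s_b))
            cmp_rows.append({
                "window_start": ws, "window_end": we, "group": grp,
                "stratum_a": s_a, "stratum_b": s_b, "n_a": comp.n_a, "n_b": comp.n_b,
                "u_statistic": comp.u_statistic, "p_value": comp.p_value,
                "stars": significance_stars(comp.p_value),
            })
    return pd.DataFrame(mean_rows), pd.DataFrame(cmp_rows)


def subgroup_analysis(
    scores: pd.DataFrame,
    children: pd.DataFrame,
    stratifier: Stratifier,
    pairs: Sequence[tuple[str, str]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified means with the cohort's prematurity exclusion applied.

    All stratifications run on term-born children (gestational age >= 37
    weeks, known) — except stratification *by* gestational age, the one
    analysis that keeps preterm children.
    """
    if stratifier.column != "gestational_age":
        children = drop_preterm(children)
        assert (children["gestational_age"] >= 37).all(), "preterm exclusion violated"
    return stratified_means(scores, children, stratifier, pairs=pairs)
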