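"""Milestone attainment scores (DMAS, LMAS) and their aggregation (DSS).

For a milestone evaluated at age ``a``:

* **DMAS** (discrete milestone attainment score) is 0 when the milestone is
  attained and otherwise the index (1-4) of the severity bracket containing
  ``a`` — i.e. failure when <75%, 75-90%, 90-95% or >95% of same-age peers
  attain the milestone.
* **LMAS** (linearized milestone attainment score) removes the
  discontinuities of DMAS: it is the unique continuous piecewise-linear
  function of age that is 0 at ``t0``, equals ``i`` at the upper end of
  bracket ``i`` and is linear within each bracket,

      LMAS(a) = (i - 1) + (a - a_min) / (a_max - a_min),

  where ``(a_min, a_max]`` is the bracket containing ``a``.  Attained
  milestones score 0 under both variants.

The **DSS** (developmental surveillance score) of an attempt set — selected
by an evaluation window and a domain group — is the arithmetic mean of the
per-attempt scores; repeated attempts of the same milestone each count.
An empty selection is *undefined* (``None`` / NaN with attempt count 0),
which is materially different from 0 ("everything attained").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .scale import (
    GROUP_DOMAINS,
    DevelopmentalScale,
    Domain,
    DomainGroup,
    MilestoneDefinition,
    bracket_of,
)

logger = logging.getLogger(__name__)

ATTEMPT_COLUMNS = ("child_id", "milestone_id", "age_months", "attained", "source")

#: year-of-life windows used in the subgroup analyses; the last one is
#: closed at 36 months so the final scheduled visit is included.
YEAR_WINDOWS: tuple[tuple[float, float], ...] = ((0.0, 12.0), (12.0, 24.0), (24.0, 36.0))


class Source(str, Enum):
    OBSERVED = "observed"
    PARENT_REPORT = "parent_report"


class Method(str, Enum):
    DMAS = "dmas"
    LMAS = "lmas"


@dataclass(frozen=True)
class AttemptRecord:
    """One evaluation of one milestone at one age with a binary outcome.

    Attainments documented by parent report count the same as observed
    attainments.
    """

    child_id: str
    milestone_id: str
    age: float
    attained: bool
    source: Source = Source.OBSERVED

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValueError(f"attempt {self.milestone_id!r}: negative age {self.age}")
        object.__setattr__(self, "source", Source(self.source))


@dataclass(frozen=True)
class ScoredAttempt:
    attempt: AttemptRecord
    dmas: int
    lmas: float


@dataclass(frozen=True)
class ScoreQuery:
    """Attempt selection: an age window crossed with a domain group.

    ``window`` is half-open ``[start, end)`` unless ``closed_end`` is set
    (used for windows ending at the last assessment age, 36 months).
    ``domains`` may be a :class:`DomainGroup` or an iterable of
    :class:`Domain`.
    """

    window: tuple[float, float]
    domains: frozenset[Domain]
    method: Method = Method.LMAS
    closed_end: bool = False

    def __post_init__(self) -> None:
        start, end = self.window
        if not start < end:
            raise ValueError(f"window start must precede end, got {self.window}")
        doms = self.domains
        if isinstance(doms, (DomainGroup, str)) and not isinstance(doms, frozenset):
            doms = GROUP_DOMAINS[DomainGroup(doms)]
        else:
            doms = frozenset(Domain(d) for d in doms)
        if not doms:
            raise ValueError("query domains must be nonempty")
        object.__setattr__(self, "domains", doms)
        object.__setattr__(self, "method", Method(self.method))


def score_dmas(m: MilestoneDefinition, age: float, attained: bool) -> int:
    """Discrete score: 0 if attained, else the severity bracket of ``age``."""
    if attained:
        return 0
    return bracket_of(m, age)


def score_lmas(m: MilestoneDefinition, age: float, attained: bool) -> float:
    """Linearized score in [0, 4], continuous in age on [t0, t100].

    The age is clamped to [t0, t100].  Within a degenerate bracket
    (zero-width, from a step-like attainment curve) the right-limit value —
    the bracket index — is returned.
    """
    if attained:
        return 0.0
    i = bracket_of(m, age)
    bounds = (m.t0, m.t75, m.t90, m.t95, m.t100)
    a_min, a_max = bounds[i - 1], bounds[i]
    if a_max == a_min:
        return float(i)
    a = min(max(age, m.t0), m.t100)
    return (i - 1) + (a - a_min) / (a_max - a_min)


def _scale_arrays(scale: DevelopmentalScale) -> pd.DataFrame:
    frame = scale.to_frame()
    return frame.set_index("milestone_id")


def score_frame(attempts: pd.DataFrame, scale: DevelopmentalScale) -> pd.DataFrame:
    """Vectorized scoring of an attempts table.

    Returns a copy of ``attempts`` with ``domain``, ``dmas`` and ``lmas``
    columns appended.  Any attempt referencing a milestone absent from the
    scale raises a ``KeyError`` naming it.
    """
    unknown = set(attempts["milestone_id"]) - set(scale.milestones)
    if unknown:
        raise KeyError(f"attempts reference unknown milestones: {sorted(unknown)}")
    if attempts.empty:
        out = attempts.copy()
        out["domain"] = pd.Series(dtype=object)
        out["dmas"] = pd.Series(dtype=int)
        out["lmas"] = pd.Series(dtype=float)
        return out

    ref = _scale_arrays(scale)
    idx = ref.index.get_indexer(attempts["milestone_id"])
    thr = ref[["t0", "t75", "t90", "t95", "t100"]].to_numpy(dtype=float)[idx]
    t0, t100 = thr[:, 0], thr[:, 4]
    uppers = thr[:, 1:]                       # t75, t90, t95, t100
    a = np.clip(attempts["age_months"].to_numpy(dtype=float), t0, t100)

    # bracket index: smallest i with a <= upper_i, upgraded to the highest
    # bracket whose closed upper bound equals a (degenerate-bracket rule)
    base = 1 + (uppers < a[:, None]).sum(axis=1)
    hit = uppers == a[:, None]
    any_hit = hit.any(axis=1)
    highest_hit = 4 - hit[:, ::-1].argmax(axis=1)
    bracket = np.where(any_hit, highest_hit, np.minimum(base, 4))

    lows = thr[:, :4]                         # t0, t75, t90, t95
    a_min = np.take_along_axis(lows, bracket[:, None] - 1, axis=1)[:, 0]
    a_max = np.take_along_axis(uppers, bracket[:, None] - 1, axis=1)[:, 0]
    width = a_max - a_min
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(width > 0, (a - a_min) / np.where(width > 0, width, 1.0), 1.0)
    lmas = (bracket - 1) + frac

    attained = attempts["attained"].to_numpy(dtype=bool)
    out = attempts.copy()
    out["domain"] = ref["domain"].to_numpy()[idx]
    out["dmas"] = np.where(attained, 0, bracket).astype(int)
    out["lmas"] = np.where(attained, 0.0, lmas)
    return out


def _select(scored: pd.DataFrame, query: ScoreQuery) -> pd.DataFrame:
    start, end = query.window
    ages = scored["age_months"]
    in_window = (ages >= start) & ((ages <= end) if query.closed_end else (ages < end))
    in_domain = scored["domain"].isin([d.value for d in query.domains])
    return scored.loc[in_window & in_domain]


def dss(
    attempts: pd.DataFrame | Iterable[AttemptRecord],
    scale: DevelopmentalScale,
    query: ScoreQuery,
) -> float | None:
    """Mean per-attempt score over the query's window and domain group.

    Returns ``None`` (undefined) when no attempt matches — deliberately
    distinct from 0.0, which states that every matching attempt was attained.
    """
    frame = attempts_to_frame(attempts) if not isinstance(attempts, pd.DataFrame) else attempts
    scored = score_frame(frame, scale)
    sel = _select(scored, query)
    if sel.empty:
        return None
    return float(sel[query.method.value].mean())


def attempts_to_frame(records: Iterable[AttemptRecord]) -> pd.DataFrame:
    rows = [
        (r.child_id, r.milestone_id, r.age, bool(r.attained), r.source.value)
        for r in records
    ]
    return pd.DataFrame(rows, columns=list(ATTEMPT_COLUMNS))


def load_attempts(path: str | Path) -> pd.DataFrame:
    """Read an attempts CSV (child_id,milestone_id,age_months,attained,source)."""
    frame = pd.read_csv(path, dtype={"child_id": str, "milestone_id": str})
    missing = set(ATTEMPT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"attempts file {path}: missing columns {sorted(missing)}")
    frame["attained"] = frame["attained"].astype(int).astype(bool)
    bad_source = set(frame["source"].unique()) - {s.value for s in Source}
    if bad_source:
        raise ValueError(f"attempts file {path}: unknown source tokens {sorted(bad_source)}")
    if (frame["age_months"] < 0).any():
        raise ValueError(f"attempts file {path}: negative ages present")
    return frame


def score_table(
    attempts: pd.DataFrame,
    scale: DevelopmentalScale,
    children: Sequence[str] | None = None,
    windows: Sequence[tuple[float, float]] = YEAR_WINDOWS,
    groups: Sequence[DomainGroup] = (DomainGroup.MOTOR, DomainGroup.LANGUAGE_SOCIAL),
    method: Method = Method.LMAS,
) -> pd.DataFrame:
    """Per-child DSS grid over windows x domain groups, in long form.

    Columns: ``child_id, window_start, window_end, group, n_attempts, dss``.
    Cells with no matching attempt keep ``dss`` NaN with ``n_attempts`` 0 —
    undefined, never imputed.  A window ending at the final listed end age
    is closed there (so 36-month evaluations belong to the third year).
    """
    method = Method(method)
    scored = score_frame(attempts, scale)
    if children is None:
        children = sorted(scored["child_id"].unique())
    group_of = {d.value: g for g, ds in GROUP_DOMAINS.items() for d in ds}
    scored = scored.assign(group=scored["domain"].map(lambda d: group_of[d].value))
    last_end = max(w[1] for w in windows) if len(windows) else None

    pieces = []
    for start, end in windows:
        closed = end == last_end
        ages = scored["age_months"]
        in_w = (ages >= start) & ((ages <= end) if closed else (ages < end))
        sub = scored.loc[in_w]
        agg = (
            sub.groupby(["child_id", "group"], sort=False)[method.value]
            .agg(n_attempts="size", dss="mean")
            .reset_index()
        )
        agg.insert(1, "window_start", start)
        agg.insert(2, "window_end", end)
        pieces.append(agg)
    got = pd.concat(pieces, ignore_index=True) if pieces else pd.DataFrame(
        columns=["child_id", "window_start", "window_end", "group", "n_attempts", "dss"]
    )

    full = pd.MultiIndex.from_product(
        [list(children), [f"{s}:{e}" for s, e in windows], [g.value for g in groups]],
        names=["child_id", "window", "group"],
    ).to_frame(index=False)
    full[["window_start", "window_end"]] = (
        full.pop("window").str.split(":", expand=True).astype(float)
    )
    out = full.merge(got, how="left", on=["child_id", "window_start", "window_end", "group"])
    out["n_attempts"] = out["n_attempts"].fillna(0).astype(int)
    return out[["child_id", "window_start", "window_end", "group", "n_attempts", "dss"]]
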