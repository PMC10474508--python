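"""Age-normed developmental scale: milestones, attainment-age thresholds, brackets.

A milestone is a discrete skill ("walks alone") evaluated as attained or
failed at a well-child visit.  A population scale assigns each milestone the
ages by which 75%, 90% and 95% of children attain it, here denoted
``t75``, ``t90``, ``t95``.  Together with the minimal and maximal assessment
ages ``t0`` and ``t100`` they partition the assessment range into four
consecutive severity brackets:

    b1 = [t0, t75],  b2 = (t75, t90],  b3 = (t90, t95],  b4 = (t95, t100]

A failure in bracket ``i`` is a failure at an age by which most peers have
already attained the milestone; the higher the bracket, the more severe.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Callable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: days-to-months conversion used throughout (mean Gregorian month)
DAYS_PER_MONTH = 30.4375


class Domain(str, Enum):
    """The four developmental domains of the milestone battery."""

    GROSS_MOTOR = "gross_motor"
    FINE_MOTOR = "fine_motor"
    LANGUAGE = "language"
    PERSONAL_SOCIAL = "personal_social"


class DomainGroup(str, Enum):
    """Aggregated domain groups used for scoring and trajectories.

    Fine and gross motor are pooled into ``motor``; language and
    personal-social are pooled into ``language_social`` (the social domain
    has few milestones and develops interdependently with language).
    """

    MOTOR = "motor"
    LANGUAGE_SOCIAL = "language_social"


GROUP_DOMAINS: Mapping[DomainGroup, frozenset[Domain]] = {
    DomainGroup.MOTOR: frozenset({Domain.FINE_MOTOR, Domain.GROSS_MOTOR}),
    DomainGroup.LANGUAGE_SOCIAL: frozenset({Domain.LANGUAGE, Domain.PERSONAL_SOCIAL}),
}


def domain_group(domain: Domain | str) -> DomainGroup:
    """Return the aggregation group a domain belongs to."""
    d = Domain(domain)
    for group, members in GROUP_DOMAINS.items():
        if d in members:
            return group
    raise ValueError(f"domain {d!r} belongs to no group")  # pragma: no cover


def days_to_months(days: float) -> float:
    """Convert an age in days to fractional months."""
    return days / DAYS_PER_MONTH


SCALE_COLUMNS = ("milestone_id", "domain", "t0", "t75", "t90", "t95", "t100")


@dataclass(frozen=True)
class MilestoneDefinition:
    """One milestone's domain and the age thresholds defining its brackets.

    Ages are fractional months.  Thresholds must be finite, non-negative and
    non-decreasing: t0 <= t75 <= t90 <= t95 <= t100.
    """

    milestone_id: str
    domain: Domain
    t0: float
    t75: float
    t90: float
    t95: float
    t100: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", Domain(self.domain))
        ts = self.thresholds
        if not all(math.isfinite(t) for t in ts):
            raise ValueError(f"milestone {self.milestone_id!r}: non-finite threshold in {ts}")
        if ts[0] < 0:
            raise ValueError(f"milestone {self.milestone_id!r}: negative t0 {ts[0]}")
        if any(a > b for a, b in zip(ts, ts[1:])):
            raise ValueError(
                f"milestone {self.milestone_id!r}: thresholds not non-decreasing: {ts}"
            )

    @property
    def thresholds(self) -> tuple[float, float, float, float, float]:
        return (self.t0, self.t75, self.t90, self.t95, self.t100)

    @property
    def group(self) -> DomainGroup:
        return domain_group(self.domain)


@dataclass(frozen=True)
class AgeBracket:
    """One of the four severity brackets of a milestone.

    Bracket 1 is closed at both ends ([t0, t75]); brackets 2-4 are
    low-open / high-closed.  A bracket with ``low == high`` is degenerate
    (arises from step-like attainment curves) and is permitted but flagged.
    """

    index: int
    low: float
    high: float

    @property
    def degenerate(self) -> bool:
        return self.low == self.high


def brackets(m: MilestoneDefinition) -> tuple[AgeBracket, AgeBracket, AgeBracket, AgeBracket]:
    """The four consecutive age brackets of a milestone, tiling [t0, t100]."""
    t0, t75, t90, t95, t100 = m.thresholds
    bs = (
        AgeBracket(1, t0, t75),
        AgeBracket(2, t75, t90),
        AgeBracket(3, t90, t95),
        AgeBracket(4, t95, t100),
    )
    for b in bs:
        if b.degenerate:
            logger.warning(
                "milestone %s: degenerate bracket %d at age %g months",
                m.milestone_id, b.index, b.low,
            )
    return bs


def bracket_of(m: MilestoneDefinition, age: float) -> int:
    """Index (1..4) of the bracket containing ``age``.

    Ages outside [t0, t100] are clamped to the nearest endpoint, so the map
    is total.  An age exactly equal to one or more bracket upper bounds
    resolves to the highest-index bracket whose (closed) upper bound equals
    it, which keeps the map well defined for degenerate brackets.
    """
    uppers = (m.t75, m.t90, m.t95, m.t100)
    a = min(max(age, m.t0), m.t100)
    for i in (4, 3, 2, 1):
        if a == uppers[i - 1]:
            return i
    for i in (1, 2, 3):
        if a <= uppers[i - 1]:
            return i
    return 4


@dataclass
class DevelopmentalScale:
    """A collection of milestones keyed by ``milestone_id``."""

    milestones: dict[str, MilestoneDefinition] = field(default_factory=dict)

    @classmethod
    def from_milestones(cls, items: Sequence[MilestoneDefinition]) -> "DevelopmentalScale":
        seen: dict[str, MilestoneDefinition] = {}
        for m in items:
            if m.milestone_id in seen:
                raise ValueError(f"duplicate milestone_id {m.milestone_id!r}")
            seen[m.milestone_id] = m
        return cls(milestones=seen)

    def __len__(self) -> int:
        return len(self.milestones)

    def __iter__(self) -> Iterator[MilestoneDefinition]:
        return iter(self.milestones.values())

    def __getitem__(self, milestone_id: str) -> MilestoneDefinition:
        try:
            return self.milestones[milestone_id]
        except KeyError:
            raise KeyError(f"unknown milestone {milestone_id!r}") from None

    def __contains__(self, milestone_id: str) -> bool:
        return milestone_id in self.milestones

    def domains(self) -> set[Domain]:
        return {m.domain for m in self}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (m.milestone_id, m.domain.value, m.t0, m.t75, m.t90, m.t95, m.t100)
            for m in self
        ]
        return pd.DataFrame(rows, columns=list(SCALE_COLUMNS))

    def save(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_scale(path: str | Path) -> DevelopmentalScale:
    """Load and validate a scale CSV.

    Expected header: ``milestone_id,domain,t0,t75,t90,t95,t100`` with ages in
    decimal months and domain tokens from :class:`Domain`.  Every row must
    pass the :class:`MilestoneDefinition` invariants; a violation raises a
    ``ValueError`` naming the offending milestone.  A header-only file loads
    as an empty scale with a logged warning (permits incremental builds).
    """
    frame = pd.read_csv(path, dtype={"milestone_id": str})
    missing = set(SCALE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"scale file {path}: missing columns {sorted(missing)}")
    if frame.empty:
        logger.warning("scale file %s contains no milestones", path)
        return DevelopmentalScale()
    items = []
    for row in frame.itertuples(index=False):
        mid = str(row.milestone_id)
        try:
            dom = Domain(row.domain)
        except ValueError:
            raise ValueError(f"milestone {mid!r}: unknown domain token {row.domain!r}") from None
        items.append(
            MilestoneDefinition(
                milestone_id=mid,
                domain=dom,
                t0=float(row.t0),
                t75=float(row.t75),
                t90=float(row.t90),
                t95=float(row.t95),
                t100=float(row.t100),
            )
        )
    return DevelopmentalScale.from_milestones(items)


def thresholds_from_curve(
    curve: Callable[[np.ndarray], np.ndarray] | np.ndarray,
    grid: np.ndarray,
    milestone_id: str = "<unnamed>",
) -> tuple[float, float, float]:
    """Derive (t75, t90, t95) from an attainment-probability curve.

    ``curve`` is either a vectorized function of age or an array of
    attainment probabilities evaluated on ``grid``.  It must be
    non-decreasing on the grid and reach 0.95 before the grid ends.  Each
    threshold is the smallest grid age at which the curve reaches the
    corresponding level, so the outputs are non-decreasing and accurate to
    one grid spacing.
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(curve(grid) if callable(curve) else curve, dtype=float)
    if values.shape != grid.shape:
        raise ValueError(f"milestone {milestone_id!r}: curve/grid shape mismatch")
    if np.any(np.diff(values) < -1e-9):
        raise ValueError(f"milestone {milestone_id!r}: attainment curve is not non-decreasing")
    out = []
    for level in (0.75, 0.90, 0.95):
        hits = np.nonzero(values >= level)[0]
        if hits.size == 0:
            raise ValueError(
                f"milestone {milestone_id!r}: attainment curve never reaches {level:.2f}"
            )
        out.append(float(grid[hits[0]]))
    return tuple(out)  # type: ignore[return-value]
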