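"""Developmental trajectory vectors (DTVs): per-age-step DSS series.

The first 36 months are partitioned into 7 age steps — 1-3, 3-6, 6-9, 9-12,
12-18, 18-24 and 24-36 months — matching the well-child visit schedule.  A
child's trajectory in one domain group is the vector of its 7 per-step DSS
values; children missing any step are excluded from trajectory analyses
(no imputation).

Binning conventions: step intervals are half-open ``[low, high)`` with the
final step closed at 36 months; evaluations before 1 month of age (the
post-discharge contact) fold into step 1; attempts are binned by the age at
which they were actually evaluated, since the score is age-dependent by
construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .scale import DevelopmentalScale, DomainGroup, GROUP_DOMAINS
from .scoring import Method, score_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AgeStep:
    index: int
    low: float
    high: float


AGE_STEPS: tuple[AgeStep, ...] = (
    AgeStep(1, 1.0, 3.0),
    AgeStep(2, 3.0, 6.0),
    AgeStep(3, 6.0, 9.0),
    AgeStep(4, 9.0, 12.0),
    AgeStep(5, 12.0, 18.0),
    AgeStep(6, 18.0, 24.0),
    AgeStep(7, 24.0, 36.0),
)

STEP_COLUMNS = tuple(f"step{i}" for i in range(1, 8))
DTV_COLUMNS = ("child_id", "group") + STEP_COLUMNS + ("complete",)


@dataclass(frozen=True)
class TrajectoryVector:
    """A child's 7 per-step DSS values for one domain group."""

    child_id: str
    domain_group: DomainGroup
    values: tuple[float | None, ...]

    def __post_init__(self) -> None:
        if len(self.values) != len(AGE_STEPS):
            raise ValueError(f"trajectory needs {len(AGE_STEPS)} values, got {len(self.values)}")

    @property
    def complete(self) -> bool:
        return all(v is not None and not np.isnan(v) for v in self.values)


def assign_step(age: float) -> int | None:
    """Age step (1..7) containing ``age``, or ``None`` beyond 36 months."""
    if age < 0:
        raise ValueError(f"negative age {age}")
    if age < AGE_STEPS[0].high:          # includes the pre-1-month fold-in
        return 1
    if age > AGE_STEPS[-1].high:
        return None
    if age == AGE_STEPS[-1].high:
        return AGE_STEPS[-1].index
    for step in AGE_STEPS[1:]:
        if step.low <= age < step.high:
            return step.index
    return None  # pragma: no cover


def build_dtvs(
    attempts: pd.DataFrame,
    scale: DevelopmentalScale,
    group: DomainGroup,
    method: Method = Method.LMAS,
) -> pd.DataFrame:
    """One trajectory row per child appearing in ``attempts``.

    Columns ``step1..step7`` hold the per-step DSS restricted to ``group``
    (NaN where the child has no scoreable attempt in the step) and
    ``complete`` is True iff all 7 are defined.
    """
    group = DomainGroup(group)
    method = Method(method)
    scored = score_frame(attempts, scale)
    domains = {d.value for d in GROUP_DOMAINS[group]}
    sub = scored.loc[scored["domain"].isin(domains)].copy()
    children = sorted(scored["child_id"].unique())

    sub["step"] = [assign_step(a) for a in sub["age_months"]]
    sub = sub.dropna(subset=["step"])
    sub["step"] = sub["step"].astype(int)
    per_step = (
        sub.groupby(["child_id", "step"], sort=False)[method.value].mean().reset_index()
    )
    wide = per_step.pivot(index="child_id", columns="step", values=method.value)
    wide = wide.reindex(index=children, columns=range(1, 8))
    wide.columns = list(STEP_COLUMNS)
    wide = wide.reset_index()
    wide.insert(1, "group", group.value)
    wide["complete"] = wide[list(STEP_COLUMNS)].notna().all(axis=1)
    return wide


def filter_complete(dtvs: pd.DataFrame) -> pd.DataFrame:
    """Keep only complete trajectories; log how many children were excluded."""
    keep = dtvs["complete"].astype(bool)
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.warning(
            "excluded %d of %d children with incomplete trajectories",
            n_excluded, len(dtvs),
        )
    if keep.sum() == 0:
        logger.warning("no complete trajectories remain")
    return dtvs.loc[keep].reset_index(drop=True)


def dtvs_to_records(dtvs: pd.DataFrame) -> list[TrajectoryVector]:
    """Typed view of a trajectory table."""
    out = []
    for row in dtvs.itertuples(index=False):
        values = tuple(
            None if pd.isna(v) else float(v)
            for v in (getattr(row, c) for c in STEP_COLUMNS)
        )
        out.append(TrajectoryVector(str(row.child_id), DomainGroup(row.group), values))
    return out


def save_dtvs(dtvs: pd.DataFrame, path) -> None:
    dtvs.to_csv(path, index=False)


def load_dtvs(path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"child_id": str})
    missing = set(DTV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trajectory file {path}: missing columns {sorted(missing)}")
    frame["complete"] = frame["complete"].astype(bool)
    return frame
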