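"""Synthetic surveillance scale and cohort generator.

No public milestone-attainment dataset accompanies the scoring method, so
this module generates one with the statistical structure the analysis
assumes:

* a **scale** of 59 milestones across the 4 domains, each with a logistic
  attainment-rate curve of age from which the 75/90/95% age thresholds are
  derived (logistic is the minimal monotone sigmoid stand-in for empirical
  attainment curves);
* a **visit schedule** at 1, 2, 4, 6, 9, 12, 18, 24 and 36 months with
  per-visit dropout, each milestone evaluated at its nominal ("due") visit
  or, after a missed visit, at the next one attended; a failed milestone is
  re-attempted once at the following attended visit;
* **children** with covariates approximating published well-child cohort
  marginals (sex, gestational age, birth weight, birth order, maternal age
  and education, EPDS-based postpartum-depression screen) whose effects act
  additively on a latent developmental *pace deficit*;
* **trajectory archetypes** planted per child: ``adequate`` (no deficit),
  ``catching_up`` (early deficit resolving by 12 months), ``worsening``
  (deficit growing with age) and an ``other`` bump (mid-infancy deficit
  that recovers) — so clustering recovery can be tested against a known
  truth.

Delays follow a developmental-quotient model: a child with pace deficit
``f`` at age ``a`` behaves like an undelayed child of age ``(1 - f) * a``,
so the attainment probability for milestone *m* is
``curve_m(a - f(a) * a)``.  Deficits are dimensionless fractions, which
keeps their effect comparable across the steep early-infancy curves and
the shallow toddler-age curves.  Everything is driven by one seed;
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cohort_stats import EDUCATION_LEVELS
from .scale import (
    DevelopmentalScale,
    Domain,
    DomainGroup,
    MilestoneDefinition,
    domain_group,
    thresholds_from_curve,
)
from .trajectory import AGE_STEPS

logger = logging.getLogger(__name__)

ARCHETYPES = ("adequate", "catching_up", "worsening", "other")

#: default split of the 59-milestone battery across domains
DOMAIN_ALLOCATION = {
    Domain.GROSS_MOTOR: 15,
    Domain.FINE_MOTOR: 15,
    Domain.LANGUAGE: 17,
    Domain.PERSONAL_SOCIAL: 12,
}

_DOMAIN_PREFIX = {
    Domain.GROSS_MOTOR: "gm",
    Domain.FINE_MOTOR: "fm",
    Domain.LANGUAGE: "lg",
    Domain.PERSONAL_SOCIAL: "ps",
}

#: step holding a single milestone per group, mirroring the real battery
SINGLE_MILESTONE_STEP = {DomainGroup.MOTOR: 5, DomainGroup.LANGUAGE_SOCIAL: 3}

TRUTH_COLUMNS = ("child_id", "archetype", "param1", "param2", "ability_noise", "cov_deficit")


@dataclass(frozen=True)
class CovariateEffects:
    """Additive pace deficits (dimensionless fractions), by covariate.

    Signs follow the expected subgroup orderings: male children, lower
    gestational age, extreme birth weight, lower maternal education, older
    mothers, postpartum depression and higher birth order all slow the
    latent pace.  A deficit of 0.02 means developing 2% slower than the
    population norm.
    """

    male: float = 0.02
    gestational_week: float = 0.012    # per completed week below 40
    birth_weight: float = 0.01         # x (birth_weight - 3.4 kg)^2
    education_step: float = 0.01       # per level below academic
    older_mother: float = 0.012        # mothers aged >= 40
    ppd: float = 0.02
    birth_order: float = 0.004         # per elder sibling

    @classmethod
    def none(cls) -> "CovariateEffects":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic cohort."""

    n_children: int
    n_milestones: int = 59
    seed: int = 0
    #: P(adequate), P(catching_up), P(worsening); remainder is the "other" bump
    archetype_mixture: tuple[float, float, float] = (0.75, 0.13, 0.04)
    covariate_effects: CovariateEffects = field(default_factory=CovariateEffects)
    visit_ages: tuple[float, ...] = (1, 2, 4, 6, 9, 12, 18, 24, 36)
    retention: float = 0.95            # per-visit attendance probability
    age_jitter_sd: float = 0.15        # months, evaluation-age noise
    max_retries: int = 1
    ability_noise_sd: float = 0.03     # pace-deficit fraction, constant per child
    parent_report_rate: float = 0.08   # attained milestones documented by parent
    attain_at_due: float = 0.99        # typical attainment prob. at the due visit

    def __post_init__(self) -> None:
        if self.n_children < 1:
            raise ValueError("n_children must be positive")
        if self.n_milestones < 4:
            raise ValueError("need at least one milestone per domain (n_milestones >= 4)")
        if not 0 < self.retention <= 1:
            raise ValueError(f"retention must be in (0, 1], got {self.retention}")
        mix = self.archetype_mixture
        if len(mix) != 3 or any(p < 0 for p in mix) or sum(mix) > 1 + 1e-12:
            raise ValueError(f"archetype mixture must be 3 probabilities summing to <= 1: {mix}")
        if not 0 < self.attain_at_due < 1:
            raise ValueError("attain_at_due must be in (0, 1)")


def _rng(config: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stream]))


def _allocate_domains(n_milestones: int) -> list[Domain]:
    """Largest-remainder allocation of milestones to domains, >= 1 each."""
    total = sum(DOMAIN_ALLOCATION.values())
    shares = {d: n_milestones * c / total for d, c in DOMAIN_ALLOCATION.items()}
    counts = {d: max(1, int(s)) for d, s in shares.items()}
    while sum(counts.values()) < n_milestones:
        d = max(shares, key=lambda d: shares[d] - counts[d])
        counts[d] += 1
    while sum(counts.values()) > n_milestones:
        d = min(shares, key=lambda d: shares[d] - counts[d])
        if counts[d] > 1:
            counts[d] -= 1
        else:  # pragma: no cover - only when n_milestones < 4, rejected earlier
            raise ValueError("infeasible domain allocation")
    out: list[Domain] = []
    for d in DOMAIN_ALLOCATION:
        out.extend([d] * counts[d])
    return out


def _visits_in_step(step_index: int, visit_ages: Sequence[float]) -> list[float]:
    step = AGE_STEPS[step_index - 1]
    last = step_index == len(AGE_STEPS)
    return [v for v in visit_ages if step.low <= v < step.high or (last and v == step.high)]


def _step_schedule(count: int, group: DomainGroup, visit_ages: Sequence[float]) -> list[int]:
    """Due-step indices for a group's milestones.

    The group's single-milestone step receives exactly one milestone when
    the battery is large enough to also cover every other step; remaining
    milestones cycle through the other steps in order.
    """
    steppable = [s.index for s in AGE_STEPS if _visits_in_step(s.index, visit_ages)]
    single = SINGLE_MILESTONE_STEP[group]
    if count >= len(steppable) and single in steppable:
        rest = [s for s in steppable if s != single]
        return [single] + [rest[i % len(rest)] for i in range(count - 1)]
    return [steppable[i % len(steppable)] for i in range(count)]


def generate_scale(
    config: SimulationConfig,
) -> tuple[DevelopmentalScale, pd.DataFrame]:
    """Synthesize a scale and its per-milestone logistic curves.

    Each milestone gets a nominal due visit inside its age step, a logistic
    attainment curve positioned so that attainment probability at the due
    visit is ``config.attain_at_due`` for an undelayed child, and thresholds
    t75/t90/t95 read off the curve on a 0.01-month grid.  t0 and t100 (the
    minimal and maximal assessment ages) are set at the 25% and 99.5%
    attainment ages, with t0 clamped at birth.

    Returns the validated scale and a curves table
    (``milestone_id, domain, group, step, due_visit, mid, slope``).
    """
    rng = _rng(config, 0)
    domains = _allocate_domains(config.n_milestones)
    by_group: dict[DomainGroup, list[Domain]] = {g: [] for g in DomainGroup}
    for d in domains:
        by_group[domain_group(d)].append(d)

    grid = np.arange(0.0, 48.0, 0.01)
    q_due = float(logit(config.attain_at_due))
    milestones: list[MilestoneDefinition] = []
    curve_rows = []
    counter = {d: 0 for d in Domain}
    for group, members in by_group.items():
        steps = _step_schedule(len(members), group, config.visit_ages)
        visit_cycle: dict[int, int] = {}
        for domain, step in zip(members, steps):
            visits = _visits_in_step(step, config.visit_ages)
            pick = visit_cycle.get(step, 0)
            visit_cycle[step] = pick + 1
            v = float(visits[pick % len(visits)])
            # slope grows with age (toddler skills emerge over months, early
            # reflexive skills over weeks) and stays below v / logit(p_due)
            # so the 50%-attainment age is after birth
            slope = 0.08 + 0.10 * v
            mid = v - slope * q_due + rng.normal(0.0, 0.1 * slope)
            counter[domain] += 1
            mid_id = f"{_DOMAIN_PREFIX[domain]}{counter[domain]:02d}"
            t75, t90, t95 = thresholds_from_curve(
                expit((grid - mid) / slope), grid, milestone_id=mid_id
            )
            t0 = max(0.0, mid + slope * math.log(0.25 / 0.75))
            t100 = mid + slope * math.log(0.995 / 0.005)
            milestones.append(
                MilestoneDefinition(mid_id, domain, t0, t75, t90, t95, t100)
            )
            curve_rows.append({
                "milestone_id": mid_id, "domain": domain.value, "group": group.value,
                "step": step, "due_visit": v, "mid": mid, "slope": slope,
            })
    scale = DevelopmentalScale.from_milestones(milestones)
    curves = pd.DataFrame(curve_rows).sort_values("milestone_id", ignore_index=True)
    return scale, curves


def attainment_probability(
    curves: pd.DataFrame, milestone_id: str, ages: np.ndarray, delays: np.ndarray | float = 0.0
) -> np.ndarray:
    """P(attained) for one milestone at given ages and latent delays."""
    row = curves.set_index("milestone_id").loc[milestone_id]
    return expit((np.asarray(ages, dtype=float) - delays - row["mid"]) / row["slope"])


def _delay_at(
    ages: np.ndarray,
    codes: np.ndarray,
    param1: np.ndarray,
    param2: np.ndarray,
    noise: np.ndarray,
    cov_deficit: np.ndarray,
) -> np.ndarray:
    """Total latent delay (months) of each child at the given ages.

    The delay is ``f(a) * a`` with the pace deficit ``f`` composed of an
    archetype term, constant per-child noise and the covariate deficit.
    Archetype terms: 0 adequate (none); 1 catching-up (deficit ``param1``
    at birth decaying exponentially, time constant 3 months, hard zero at
    12 months); 2 worsening (deficit growing from 0 to ``param1`` at 36
    months); 3 other (a Gaussian bump of height ``param1`` centered at
    ``param2`` months, sd 2.5 months).
    """
    f = np.zeros_like(ages, dtype=float)
    f = np.where(
        codes == 1,
        param1 * np.exp(-ages / 3.0) * np.clip(12.0 - ages, 0.0, 1.0), f)
    f = np.where(codes == 2, param1 * ages / 36.0, f)
    f = np.where(codes == 3, param1 * np.exp(-((ages - param2) ** 2) / (2 * 2.5**2)), f)
    return (f + noise + cov_deficit) * ages


def _draw_children(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = config.n_children
    child_id = np.array([f"c{i:06d}" for i in range(n)])
    male = rng.random(n) < 0.512

    ga_cat = rng.choice(5, size=n, p=(0.002, 0.006, 0.062, 0.243, 0.687))
    ga_lo = np.array([23, 27, 32, 37, 39])[ga_cat]
    ga_hi = np.array([26, 31, 36, 38, 42])[ga_cat]
    gestational_age = rng.integers(ga_lo, ga_hi + 1).astype(float)

    birth_weight = np.round(np.clip(rng.normal(3.25, 0.42, n), 1.0, 6.0), 3)
    birth_order = rng.choice([1, 2, 3, 4, 5], size=n, p=(0.36, 0.33, 0.19, 0.08, 0.04))
    older = rng.random(n) < 0.14
    maternal_age = np.round(np.clip(
        np.where(older, rng.normal(43.0, 2.0, n), rng.normal(29.0, 4.5, n)), 18.0, 50.0), 1)
    education = rng.choice(EDUCATION_LEVELS, size=n, p=(0.44, 0.15, 0.38, 0.03))

    epds_total = np.minimum(np.round(rng.gamma(2.0, 2.0, n)), 30.0)
    epds_q10 = np.where(rng.random(n) < 0.006, rng.integers(1, 4, n), 0).astype(float)
    epds_missing = rng.random(n) < 0.15
    epds_total[epds_missing] = np.nan
    epds_q10[epds_missing] = np.nan

    return pd.DataFrame({
        "child_id": child_id,
        "sex": np.where(male, "male", "female"),
        "gestational_age": gestational_age,
        "birth_weight": birth_weight,
        "birth_order": birth_order,
        "maternal_age": maternal_age,
        "maternal_education": education,
        "epds_total": epds_total,
        "epds_q10": epds_q10,
    })


def generate_cohort(
    scale: DevelopmentalScale,
    curves: pd.DataFrame,
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate covariates, visit attendance and milestone attempts.

    Returns ``(children, attempts, truth)``; ``truth`` carries the planted
    archetype and delay parameters per child for recovery tests.
    """
    rng = _rng(config, 1)
    n = config.n_children
    eff = config.covariate_effects
    children = _draw_children(config, rng)

    male = children["sex"].to_numpy() == "male"

    # archetype per child; the worsening archetype is sex-linked (male
    # excess, as reported for late-rising trajectory groups), compensated
    # from the adequate mass so the marginal mixture is preserved
    mix = config.archetype_mixture
    p_other = max(0.0, 1.0 - sum(mix))
    pw = mix[2] * np.where(male, 1.55, 0.423)
    pa = 1.0 - mix[1] - p_other - pw
    u = rng.random(n)
    codes = (
        (u >= pa).astype(int)
        + (u >= pa + mix[1]).astype(int)
        + (u >= pa + mix[1] + pw).astype(int)
    )
    param1 = np.zeros(n)
    param1 = np.where(codes == 1, rng.uniform(1.2, 1.6, n), param1)
    param1 = np.where(codes == 2, rng.uniform(0.50, 0.70, n), param1)
    param1 = np.where(codes == 3, rng.uniform(0.40, 0.60, n), param1)
    param2 = np.where(codes == 3, rng.uniform(6.0, 9.0, n), 0.0)
    noise = rng.normal(0.0, config.ability_noise_sd, n) if config.ability_noise_sd else np.zeros(n)

    ga = children["gestational_age"].to_numpy(dtype=float)
    bw = children["birth_weight"].to_numpy(dtype=float)
    order = children["birth_order"].to_numpy(dtype=float)
    mage = children["maternal_age"].to_numpy(dtype=float)
    edu_rank = children["maternal_education"].map(
        {lvl: i for i, lvl in enumerate(EDUCATION_LEVELS)}).to_numpy(dtype=float)
    ppd = (
        (children["epds_total"].fillna(0) >= 10)
        | (children["epds_q10"].fillna(0) != 0)
    ).to_numpy()
    cov_deficit = (
        eff.male * male
        + eff.gestational_week * np.clip(40.0 - ga, 0.0, None)
        + eff.birth_weight * (bw - 3.4) ** 2
        + eff.education_step * edu_rank
        + eff.older_mother * (mage >= 40)
        + eff.ppd * ppd
        + eff.birth_order * (order - 1)
    )

    tracking_prob = np.array([0.01, 0.05, 0.25, 0.05])[codes]
    children["dev_tracking"] = (rng.random(n) < tracking_prob).astype(int)

    visit_ages = np.asarray(config.visit_ages, dtype=float)
    n_visits = visit_ages.size
    attend = rng.random((n, n_visits)) < config.retention
    # next_attended[:, j]: first attended visit index >= j (sentinel n_visits)
    next_attended = np.full((n, n_visits + 1), n_visits, dtype=int)
    for j in range(n_visits - 1, -1, -1):
        next_attended[:, j] = np.where(attend[:, j], j, next_attended[:, j + 1])

    due_index = {
        row.milestone_id: int(np.nonzero(visit_ages == row.due_visit)[0][0])
        for row in curves.itertuples(index=False)
    }
    mid = dict(zip(curves["milestone_id"], curves["mid"]))
    slope = dict(zip(curves["milestone_id"], curves["slope"]))
    child_ids = children["child_id"].to_numpy()

    blocks = []

    def _attempt_block(milestone: str, visit_idx: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Evaluate ``milestone`` for children in ``mask`` at their visit; returns attained."""
        idx = np.nonzero(mask)[0]
        ages = visit_ages[visit_idx[idx]]
        if config.age_jitter_sd:
            # families arrive at or shortly after the scheduled age, never
            # before — keeps an evaluation inside its visit's age step; the
            # final visit is capped at the end of the surveillance window
            jit = np.abs(rng.normal(0.0, config.age_jitter_sd, idx.size))
            ages = ages + np.minimum(jit, 3 * config.age_jitter_sd)
            ages = np.minimum(ages, float(visit_ages[-1]))
        delays = _delay_at(ages, codes[idx], param1[idx], param2[idx],
                           noise[idx], cov_deficit[idx])
        p = expit((ages - delays - mid[milestone]) / slope[milestone])
        attained = rng.random(idx.size) < p
        source = np.where(
            attained & (rng.random(idx.size) < config.parent_report_rate),
            "parent_report", "observed",
        )
        blocks.append(pd.DataFrame({
            "child_id": child_ids[idx],
            "milestone_id": milestone,
            "age_months": np.round(ages, 4),
            "attained": attained,
            "source": source,
        }))
        out = np.zeros(n, dtype=bool)
        out[idx] = attained
        return out

    for m in scale:
        j_due = due_index[m.milestone_id]
        first = next_attended[:, j_due]
        mask = first < n_visits
        visit_idx = np.minimum(first, n_visits - 1)
        attained = _attempt_block(m.milestone_id, visit_idx, mask)
        failed = mask & ~attained
        for _ in range(config.max_retries):
            if not failed.any():
                break
            nxt = next_attended[np.arange(n), np.minimum(visit_idx + 1, n_visits)]
            mask_r = failed & (nxt < n_visits)
            visit_idx = np.minimum(nxt, n_visits - 1)
            attained = _attempt_block(m.milestone_id, visit_idx, mask_r)
            failed = mask_r & ~attained

    attempts = pd.concat(blocks, ignore_index=True) if blocks else pd.DataFrame(
        columns=["child_id", "milestone_id", "age_months", "attained", "source"])
    attempts = attempts.sort_values(
        ["child_id", "age_months", "milestone_id"], kind="stable", ignore_index=True)
    attempts["attained"] = attempts["attained"].astype(int)

    truth = pd.DataFrame({
        "child_id": child_ids,
        "archetype": np.array(ARCHETYPES)[codes],
        "param1": np.round(param1, 6),
        "param2": np.round(param2, 6),
        "ability_noise": np.round(noise, 6),
        "cov_deficit": np.round(cov_deficit, 6),
    })
    return children, attempts, truth


def planted_truth_writer(truth: pd.DataFrame, path: str | Path) -> None:
    """Write the planted-truth table (header always present)."""
    cols = [c for c in TRUTH_COLUMNS if c in truth.columns] or list(TRUTH_COLUMNS)
    frame = truth if not truth.empty else pd.DataFrame(columns=cols)
    frame.to_csv(path, index=False, columns=cols)


def load_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"child_id": str, "archetype": str})


def simulate(config: SimulationConfig, out_dir: str | Path | None = None):
    """Generate scale + cohort; optionally write the four CSVs to ``out_dir``."""
    scale, curves = generate_scale(config)
    children, attempts, truth = generate_cohort(scale, curves, config)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        scale.save(out / "scale.csv")
        curves.to_csv(out / "curves.csv", index=False)
        children.to_csv(out / "children.csv", index=False)
        attempts.to_csv(out / "attempts.csv", index=False)
        planted_truth_writer(truth, out / "truth.csv")
    return scale, curves, children, attempts, truth
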