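import numpy as np
import pandas as pd
import pytest

from dss import DomainGroup, MilestoneDefinition, DevelopmentalScale, score_table
from dss.synthetic_cohort import SimulationConfig, simulate


@pytest.fixture
def walk():
    """A gross-motor milestone with the worked-example thresholds."""
    return MilestoneDefinition("walk", "gross_motor", t0=2, t75=6, t90=9, t95=12, t100=18)


@pytest.fixture
def toy_scale(walk):
    """A small four-domain scale for filter and aggregation tests."""
    return DevelopmentalScale.from_milestones([
        walk,
        MilestoneDefinition("pincer", "fine_motor", 6, 9, 10, 11, 14),
        MilestoneDefinition("babbles", "language", 4, 8, 10, 12, 16),
        MilestoneDefinition("smiles", "personal_social", 0.5, 2, 3, 4, 6),
    ])


def random_milestone(rng: np.random.Generator, degenerate: bool = False) -> MilestoneDefinition:
    """A random valid milestone; optionally with repeated thresholds."""
    ts = np.sort(rng.uniform(0, 40, 5))
    if degenerate and rng.random() < 0.5:
        i = rng.integers(0, 4)
        ts[i + 1] = ts[i]
    return MilestoneDefinition(f"m{rng.integers(1e9)}", "language", *ts)


@pytest.fixture(scope="session")
def archetype_cohort():
    """n=2,000 cohort with planted trajectory archetypes (default conditions)."""
    cfg = SimulationConfig(n_children=2000, seed=20240601)
    scale, curves, children, attempts, truth = simulate(cfg)
    return {
        "config": cfg, "scale": scale, "curves": curves,
        "children": children, "attempts": attempts, "truth": truth,
    }


@pytest.fixture(scope="session")
def big_cohort():
    """n=10,000 cohort used for covariate-effect recovery checks."""
    cfg = SimulationConfig(n_children=10000, seed=987654)
    scale, curves, children, attempts, truth = simulate(cfg)
    scores = score_table(attempts, scale)
    return {
        "config": cfg, "scale": scale, "curves": curves, "children": children,
        "attempts": attempts, "truth": truth, "scores": scores,
    }
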