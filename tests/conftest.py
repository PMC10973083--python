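import dataclasses

import pytest

from vinesim import generate_fixture
from vinesim.config import CaseStudyConfig
from vinesim.distributions import DistributionSpec
from vinesim.trees import DecisionTreeSpec


@pytest.fixture(scope="session")
def leithaberg():
    return generate_fixture("leithaberg_like", seed=1)


@pytest.fixture(scope="session")
def palatinate():
    return generate_fixture("palatinate_like", seed=1)


@pytest.fixture(scope="session")
def tarnave():
    return generate_fixture("tarnave_like", seed=1)


@pytest.fixture(scope="session")
def all_styles(leithaberg, palatinate, tarnave):
    return {
        "leithaberg_like": leithaberg,
        "palatinate_like": palatinate,
        "tarnave_like": tarnave,
    }


def quiet_adaptation(cfg: CaseStudyConfig, no_pests: bool = True) -> CaseStudyConfig:
    """A copy of cfg in which no concern can ever fire (null-dynamics setting)."""
    adaptation = dataclasses.replace(
        cfg.adaptation,
        yield_concern_events=10**9,
        soil_loss_concern=float("inf"),
        biodiversity_concern=float("inf"),
    )
    cfg = dataclasses.replace(cfg, adaptation=adaptation)
    if no_pests:
        # the pest concern has no threshold (two high-abundance years fire it),
        # so silence it at the source for null-dynamics checks
        ecology = dataclasses.replace(cfg.ecology, lobesia_baseline=0.0)
        cfg = dataclasses.replace(cfg, ecology=ecology)
    return cfg


def tiny_config(name="tiny", n=6, **tree_overrides) -> CaseStudyConfig:
    """A minimal hand-built config for fast, targeted engine tests.

    Default trees: everyone vegetated (every), spontaneous, no pesticides,
    no pheromone. Individual trees can be overridden by keyword with either a
    DecisionTreeSpec or a raw root node mapping.
    """
    trees = {
        "arrangement": {"value": "every"},
        "vegetation_type": {"value": "spontaneous"},
        "insecticide_freq": {"value": 0},
        "pheromone": {"value": False},
        "fungicide_freqs": {"value": [0, 0]},
    }
    for key, value in tree_overrides.items():
        trees[key] = value.root if isinstance(value, DecisionTreeSpec) else value
    return CaseStudyConfig(
        name=name,
        landcover_shares={
            "urban": 0.05,
            "viticulture": 0.265,
            "other_agriculture": 0.30,
            "forest": 0.22,
            "semi_natural": 0.115,
            "wetland_water": 0.05,
        },
        n_winegrowers=n,
        attribute_distributions={
            "area_ha": DistributionSpec("uniform", {"low": 2.0, "high": 4.0}),
            "slope_pct": DistributionSpec("uniform", {"low": 0.0, "high": 20.0}),
            "water_shortage": DistributionSpec("bernoulli", {"p": 0.5}),
            "soil_problem": DistributionSpec("bernoulli", {"p": 0.3}),
            "management_type": DistributionSpec(
                "categorical", {"values": ["organic", "conventional"], "probs": [0.5, 0.5]}
            ),
        },
        decision_trees={k: DecisionTreeSpec(k, v) for k, v in trees.items()},
    )
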