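"""Synthetic case-study configurations emulating the three regional contrasts.

The three styles encode the qualitative regional differences reported for the
reference (no-policy, no-climate-change) situation:

* ``leithaberg_like`` — no bare-soil inter-rows, no insecticide use, moderate
  pheromone uptake, copper-/sulfur-based fungicides dominate, steep slopes.
* ``palatinate_like`` — no bare soil, no insecticide, the highest pheromone
  dispenser share, synthetic fungicides dominate, gentler slopes.
* ``tarnave_like`` — the only style with bare-soil inter-rows and positive
  insecticide frequencies, low pheromone uptake, spontaneous vegetation
  dominates among vegetated inter-rows.

These are illustrative stand-ins for the empirically derived regional decision
trees and attribute statistics, which are pluggable through the config format
rather than hard-coded. The seed perturbs the behaviour-share leaves within
bands that preserve every qualitative contrast above, so replicated landscapes
differ while remaining recognisably "regional".
"""

from __future__ import annotations

import numpy as np

from .config import CaseStudyConfig, validate_config
from .distributions import DistributionSpec
from .trees import DecisionTreeSpec

__all__ = ["FIXTURE_STYLES", "generate_fixture"]

FIXTURE_STYLES = ("leithaberg_like", "palatinate_like", "tarnave_like")


def _dist(kind: str, **params) -> DistributionSpec:
    return DistributionSpec(kind=kind, params=params)


def _leaf(value) -> dict:
    return {"value": value}


def _dleaf(dist: dict) -> dict:
    return {"distribution": dist}


def _jitter(rng: np.random.Generator, p: float, width: float, lo: float, hi: float) -> float:
    """Perturb probability *p* by up to ±width, clipped to [lo, hi]."""
    return float(np.clip(p + rng.uniform(-width, width), lo, hi))


def generate_fixture(style: str, seed: int) -> CaseStudyConfig:
    """Create a complete, valid case-study config in one of the three styles.

    Deterministic in ``(style, seed)``.

    Raises
    ------
    ValueError
        If *style* is not one of :data:`FIXTURE_STYLES`.
    """
    if style not in FIXTURE_STYLES:
        raise ValueError(f"unknown fixture style {style!r}; choose from {FIXTURE_STYLES}")
    rng = np.random.default_rng([int(seed), 0xF1D0])

    if style == "leithaberg_like":
        p_every = _jitter(rng, 0.60, 0.05, 0.45, 0.75)
        p_seed_org = _jitter(rng, 0.70, 0.05, 0.55, 0.85)
        p_seed_conv = _jitter(rng, 0.50, 0.05, 0.35, 0.65)
        p_pher = _jitter(rng, 0.58, 0.04, 0.45, 0.70)
        cfg = CaseStudyConfig(
            name=f"leithaberg_like (seed {seed})",
            landcover_shares={
                "urban": 0.05,
                "viticulture": 0.265,
                "other_agriculture": 0.30,
                "forest": 0.22,
                "semi_natural": 0.115,
                "wetland_water": 0.05,
            },
            n_winegrowers=50,
            attribute_distributions={
                "area_ha": _dist("truncnorm", mu=3.0, sigma=2.0, low=0.5, high=10.0),
                "slope_pct": _dist("truncnorm", mu=12.0, sigma=8.0, low=0.0, high=35.0),
                "water_shortage": _dist("bernoulli", p=0.5),
                "soil_problem": _dist("bernoulli", p=0.3),
                "management_type": _dist(
                    "categorical", values=["organic", "conventional"], probs=[0.35, 0.65]
                ),
            },
            decision_trees={
                # no bare-soil inter-rows in this style
                "arrangement": DecisionTreeSpec(
                    "arrangement",
                    _dleaf({"every": p_every, "every_second": round(1 - p_every, 12)}),
                ),
                "vegetation_type": DecisionTreeSpec(
                    "vegetation_type",
                    {
                        "attribute": "management_type",
                        "op": "in",
                        "categories": ["organic"],
                        "if_true": _dleaf(
                            {"seed_mixture": p_seed_org, "spontaneous": round(1 - p_seed_org, 12)}
                        ),
                        "if_false": _dleaf(
                            {"seed_mixture": p_seed_conv, "spontaneous": round(1 - p_seed_conv, 12)}
                        ),
                    },
                ),
                # insecticides are not used in this style
                "insecticide_freq": DecisionTreeSpec("insecticide_freq", _leaf(0)),
                "pheromone": DecisionTreeSpec(
                    "pheromone", _dleaf({True: p_pher, False: round(1 - p_pher, 12)})
                ),
                # copper/sulfur-leaning fungicide programme
                "fungicide_freqs": DecisionTreeSpec(
                    "fungicide_freqs",
                    {
                        "attribute": "management_type",
                        "op": "in",
                        "categories": ["organic"],
                        "if_true": _leaf([0, 8]),
                        "if_false": _leaf([2, 6]),
                    },
                ),
            },
            expert_ranges={
                "share_seed_mixture": (0.80, 0.90),
                "share_pheromone": (0.85, 0.95),
                "mean_insecticide_freq": (0.0, 0.0),
                "share_bare": (0.0, 0.05),
            },
        )
    elif style == "palatinate_like":
        p_every = _jitter(rng, 0.70, 0.05, 0.55, 0.85)
        p_seed = _jitter(rng, 0.65, 0.05, 0.50, 0.80)
        p_pher = _jitter(rng, 0.85, 0.04, 0.78, 0.95)
        cfg = CaseStudyConfig(
            name=f"palatinate_like (seed {seed})",
            landcover_shares={
                "urban": 0.08,
                "viticulture": 0.265,
                "other_agriculture": 0.25,
                "forest": 0.30,
                "semi_natural": 0.085,
                "wetland_water": 0.02,
            },
            n_winegrowers=50,
            attribute_distributions={
                "area_ha": _dist("truncnorm", mu=4.0, sigma=2.5, low=0.5, high=12.0),
                "slope_pct": _dist("truncnorm", mu=6.0, sigma=4.0, low=0.0, high=25.0),
                "water_shortage": _dist("bernoulli", p=0.3),
                "soil_problem": _dist("bernoulli", p=0.25),
                "management_type": _dist(
                    "categorical", values=["organic", "conventional"], probs=[0.2, 0.8]
                ),
            },
            decision_trees={
                "arrangement": DecisionTreeSpec(
                    "arrangement",
                    _dleaf({"every": p_every, "every_second": round(1 - p_every, 12)}),
                ),
                "vegetation_type": DecisionTreeSpec(
                    "vegetation_type",
                    _dleaf({"seed_mixture": p_seed, "spontaneous": round(1 - p_seed, 12)}),
                ),
                "insecticide_freq": DecisionTreeSpec("insecticide_freq", _leaf(0)),
                # highest pheromone-dispenser share of the three styles
                "pheromone": DecisionTreeSpec(
                    "pheromone", _dleaf({True: p_pher, False: round(1 - p_pher, 12)})
                ),
                # synthetic-leaning fungicide programme
                "fungicide_freqs": DecisionTreeSpec(
                    "fungicide_freqs",
                    {
                        "attribute": "management_type",
                        "op": "in",
                        "categories": ["organic"],
                        "if_true": _leaf([1, 7]),
                        "if_false": _leaf([8, 2]),
                    },
                ),
            },
            expert_ranges={
                "share_seed_mixture": (0.55, 0.75),
                "share_pheromone": (0.80, 0.95),
                "mean_insecticide_freq": (0.0, 0.0),
                "share_bare": (0.0, 0.05),
            },
        )
    else:  # tarnave_like
        p_bare = _jitter(rng, 0.45, 0.05, 0.30, 0.60)
        p_half = _jitter(rng, 0.35, 0.05, 0.20, 0.50)
        p_spont = _jitter(rng, 0.70, 0.05, 0.55, 0.85)
        p_pher = _jitter(rng, 0.30, 0.04, 0.20, 0.40)
        rest = round(1 - p_bare - p_half, 12)
        cfg = CaseStudyConfig(
            name=f"tarnave_like (seed {seed})",
            landcover_shares={
                "urban": 0.04,
                "viticulture": 0.265,
                "other_agriculture": 0.35,
                "forest": 0.20,
                "semi_natural": 0.125,
                "wetland_water": 0.02,
            },
            n_winegrowers=50,
            attribute_distributions={
                "area_ha": _dist("truncnorm", mu=2.5, sigma=1.5, low=0.5, high=8.0),
                "slope_pct": _dist("truncnorm", mu=10.0, sigma=6.0, low=0.0, high=30.0),
                "water_shortage": _dist("bernoulli", p=0.4),
                "soil_problem": _dist("bernoulli", p=0.45),
                "management_type": _dist(
                    "categorical", values=["organic", "conventional"], probs=[0.1, 0.9]
                ),
            },
            decision_trees={
                # bare-soil inter-rows are common only in this style
                "arrangement": DecisionTreeSpec(
                    "arrangement",
                    _dleaf({"bare": p_bare, "every_second": p_half, "every": rest}),
                ),
                "vegetation_type": DecisionTreeSpec(
                    "vegetation_type",
                    _dleaf({"spontaneous": p_spont, "seed_mixture": round(1 - p_spont, 12)}),
                ),
                # the only style with positive insecticide frequencies
                "insecticide_freq": DecisionTreeSpec(
                    "insecticide_freq",
                    {
                        "attribute": "management_type",
                        "op": "in",
                        "categories": ["organic"],
                        "if_true": _leaf(0),
                        "if_false": _dleaf({2: 0.3, 5: 0.4, 8: 0.3}),
                    },
                ),
                "pheromone": DecisionTreeSpec(
                    "pheromone", _dleaf({True: p_pher, False: round(1 - p_pher, 12)})
                ),
                "fungicide_freqs": DecisionTreeSpec(
                    "fungicide_freqs",
                    {
                        "attribute": "management_type",
                        "op": "in",
                        "categories": ["organic"],
                        "if_true": _leaf([0, 6]),
                        "if_false": _leaf([5, 3]),
                    },
                ),
            },
            expert_ranges={
                "share_seed_mixture": (0.10, 0.35),
                "share_pheromone": (0.15, 0.35),
                "mean_insecticide_freq": (1.0, 4.0),
                "share_bare": (0.30, 0.60),
            },
        )

    violations = validate_config(cfg)
    if violations:  # pragma: no cover - guards fixture construction itself
        raise AssertionError(f"fixture {style!r} invalid: {violations}")
    return cfg
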