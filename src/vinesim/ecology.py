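"""Ecological impact functions linking vineyard behaviour to its environment.

Per vineyard and year the model tracks soil loss, the predation rate of
*Lobesia botrana* pupae by natural enemies, a binary high-pest-abundance
flag, vascular plant and spider species richness, and cumulative counters of
yield-potential increase/decrease events. The exact field coefficients are
configurable (:class:`~vinesim.config.EcologyParams`); the functional forms
are multiplicative attenuation and lookup tables constrained to the
directions the links must satisfy:

* soil loss decreases with vegetation cover, increases with slope and with
  wetter years;
* predation is highest under spontaneous vegetation and attenuated by every
  pesticide application;
* pest pressure falls with pheromone dispensers, insecticides and predation,
  and rises in warmer years;
* plant richness: seed mixture > spontaneous > bare, full cover > half;
* spider richness gains from vegetated cover and loses per insecticide
  application.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import VEGETATED_FRACTION, BehaviourState, WinegrowerAgent
from .config import EcologyParams

__all__ = [
    "EcologicalState",
    "soil_loss",
    "predation_rate",
    "lobesia_high_prob",
    "plant_richness",
    "spider_richness",
    "landscape_aesthetics",
    "update_yield_events",
]


@dataclass
class EcologicalState:
    """Per-vineyard, per-year ecological impacts."""

    soil_loss: float = 0.0  # t/ha/yr
    predation_rate: float = 0.0  # fraction of sentinel pupae consumed
    lobesia_high: bool = False
    plant_richness: float = 0.0
    spider_richness: float = 0.0
    yield_up_events: int = 0  # cumulative, monotone non-decreasing
    yield_down_events: int = 0


def soil_loss(
    behaviour: BehaviourState,
    slope_pct: float,
    precip_code: int,
    params: EcologyParams,
) -> float:
    """Annual soil loss (t/ha/yr) of one vineyard.

    ``base * (1 + slope/100)**exponent * cover_factor * precip_multiplier``;
    flat slopes give the minimal slope term (exactly the base product).
    """
    if precip_code not in (-1, 0, 1):
        raise ValueError(f"invalid precipitation code {precip_code!r}")
    if slope_pct < 0:
        raise ValueError("slope_pct must be >= 0")
    cover = {
        "bare": params.soil_cover_bare,
        "every_second": params.soil_cover_every_second,
        "every": params.soil_cover_every,
    }[behaviour.arrangement]
    slope_term = (1.0 + slope_pct / 100.0) ** params.soil_slope_exponent
    return params.soil_base_rate * slope_term * cover * params.soil_precip_mult[precip_code]


def predation_rate(behaviour: BehaviourState, params: EcologyParams) -> float:
    """Fraction of sentinel pupae predated, in [0, 1].

    Base rate by vegetation type, attenuated once per insecticide and per
    fungicide application (both classes).
    """
    base = params.predation_base[behaviour.vegetation_type]
    rate = (
        base
        * params.predation_insecticide_atten ** behaviour.insecticide_freq
        * params.predation_fungicide_atten ** behaviour.fungicide_total
    )
    return float(np.clip(rate, 0.0, 1.0))


def lobesia_high_prob(
    behaviour: BehaviourState,
    predation: float,
    temp_code: int,
    params: EcologyParams,
) -> float:
    """Probability that the vineyard sees high *L. botrana* abundance this year."""
    if temp_code not in (0, 1, 2):
        raise ValueError(f"invalid temperature code {temp_code!r}")
    if not 0.0 <= predation <= 1.0:
        raise ValueError("predation must lie in [0, 1]")
    p = (
        params.lobesia_baseline
        * (params.lobesia_pheromone_factor if behaviour.pheromone else 1.0)
        * params.lobesia_insecticide_factor ** behaviour.insecticide_freq
        * (1.0 - params.lobesia_predation_weight * predation)
        * params.lobesia_warm_mult[temp_code]
    )
    return float(np.clip(p, 0.0, 1.0))


def plant_richness(behaviour: BehaviourState, params: EcologyParams) -> float:
    """Vascular plant richness score from the (type, arrangement) lookup."""
    key = (behaviour.vegetation_type, behaviour.arrangement)
    if key not in params.plant_richness:  # defensive: invariants forbid this
        key = ("none", "bare")
    return float(params.plant_richness[key])


def spider_richness(behaviour: BehaviourState, params: EcologyParams) -> float:
    """Spider richness: base + cover bonus - insecticide penalty, floored at 0."""
    score = (
        params.spider_base
        + params.spider_cover_bonus * VEGETATED_FRACTION[behaviour.arrangement]
        - params.spider_insecticide_penalty * behaviour.insecticide_freq
    )
    return max(0.0, float(score))


def landscape_aesthetics(agents) -> float:
    """Area-weighted share of vegetated inter-rows across the landscape.

    ``sum(area * vegetated_fraction) / sum(area)`` with fraction 1, 0.5, 0
    for every, every-second and bare arrangements. Invariant under agent
    re-ordering and under rescaling all areas by a common factor.
    """
    agents = list(agents)
    if not agents:
        raise ValueError("landscape_aesthetics of an empty agent list")
    total = sum(a.area_ha for a in agents)
    vegetated = sum(
        a.area_ha * VEGETATED_FRACTION[a.behaviour.arrangement] for a in agents
    )
    return vegetated / total


def update_yield_events(
    agent: WinegrowerAgent,
    eco: EcologicalState,
    lobesia_high: bool,
    pheromone_newly_adopted: bool,
) -> tuple[int, int]:
    """Yield-potential event increments for this year: ``(up, down)``.

    Down-events: vegetated inter-rows on a water-short vineyard (competition
    for water/nutrients) and a high-pest year each add one. Up-events: the
    year a pheromone dispenser is newly adopted adds one. Counters on *eco*
    are cumulative and never decrease.
    """
    up = 1 if pheromone_newly_adopted else 0
    down = 0
    if agent.behaviour.arrangement != "bare" and agent.water_shortage:
        down += 1
    if lobesia_high:
        down += 1
    eco.yield_up_events += up
    eco.yield_down_events += down
    return up, down
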