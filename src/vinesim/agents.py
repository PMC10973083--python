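"""Winegrower agents: heterogeneous attributes and tree-set initial behaviours.

Each vineyard parcel is held by one winegrower. Static attributes (area,
slope, water shortage, soil problem, management type) are drawn from the
configured distributions; the five initial behaviours come from the
configured decision trees. The behaviour state couples inter-row arrangement
with vegetation type: a bare arrangement implies no vegetation and vice
versa, with the arrangement tree taking precedence on conflict because the
arrangement is the physically prior choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .config import AGENT_ATTRIBUTES, BEHAVIOUR_TREES, CaseStudyConfig
from .landscape import VineyardParcel
from .trees import TreeStructureError, evaluate_tree

__all__ = [
    "ARRANGEMENTS",
    "VEGETATION_TYPES",
    "BehaviourState",
    "WinegrowerAgent",
    "init_agents",
    "behaviour_shares",
    "agents_to_frame",
]

ARRANGEMENTS = ("bare", "every_second", "every")
VEGETATION_TYPES = ("none", "spontaneous", "seed_mixture")

#: Vegetated fraction of inter-rows per arrangement (used by several impacts).
VEGETATED_FRACTION = {"bare": 0.0, "every_second": 0.5, "every": 1.0}


@dataclass
class BehaviourState:
    """The five modelled behaviours of one vineyard.

    Invariant: ``vegetation_type == "none"`` iff ``arrangement == "bare"``.
    """

    arrangement: str = "every"
    vegetation_type: str = "spontaneous"
    insecticide_freq: int = 0
    pheromone: bool = False
    fungicide_synthetic_freq: int = 0
    fungicide_copper_sulfur_freq: int = 0

    def check(self) -> None:
        if self.arrangement not in ARRANGEMENTS:
            raise ValueError(f"bad arrangement {self.arrangement!r}")
        if self.vegetation_type not in VEGETATION_TYPES:
            raise ValueError(f"bad vegetation_type {self.vegetation_type!r}")
        if (self.arrangement == "bare") != (self.vegetation_type == "none"):
            raise ValueError(
                f"arrangement {self.arrangement!r} inconsistent with "
                f"vegetation_type {self.vegetation_type!r}"
            )
        for f in ("insecticide_freq", "fungicide_synthetic_freq", "fungicide_copper_sulfur_freq"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")

    @property
    def fungicide_total(self) -> int:
        return self.fungicide_synthetic_freq + self.fungicide_copper_sulfur_freq

    def copy(self) -> "BehaviourState":
        return replace(self)


@dataclass
class WinegrowerAgent:
    """One vineyard-holding decision maker."""

    id: int
    parcel_id: int
    area_ha: float
    slope_pct: float
    water_shortage: bool
    soil_problem: bool
    management_type: str
    behaviour: BehaviourState = field(default_factory=BehaviourState)
    obligations: set = field(default_factory=set)
    blocked_options: set = field(default_factory=set)
    concerns: set = field(default_factory=set)

    def attributes(self) -> dict:
        """Attribute mapping seen by decision trees."""
        return {a: getattr(self, a) for a in AGENT_ATTRIBUTES}


def _coerce_behaviour(arrangement: str, vegetation_type: str) -> tuple[str, str]:
    """Resolve arrangement/vegetation-type conflicts; arrangement wins."""
    if arrangement == "bare":
        return arrangement, "none"
    if vegetation_type == "none":
        # vegetated arrangement but the type tree said none: fall back to
        # spontaneous (volunteer) vegetation, the no-cost default
        return arrangement, "spontaneous"
    return arrangement, vegetation_type


def init_agents(
    parcels: Sequence[VineyardParcel],
    cfg: CaseStudyConfig,
    seed: int,
) -> list[WinegrowerAgent]:
    """Create one agent per parcel with attributes and tree-set behaviours.

    Pure function of ``(parcels, cfg, seed)``. The parcel's drawn area is the
    agent's ``area_ha``; the remaining attributes come from
    ``cfg.attribute_distributions`` and the behaviours from the five decision
    trees, with the bare/none coupling enforced.
    """
    if len(parcels) != cfg.n_winegrowers:
        raise ValueError(
            f"{len(parcels)} parcels for {cfg.n_winegrowers} winegrowers"
        )
    rng = np.random.default_rng([int(seed), 0xA6E7])
    agents: list[WinegrowerAgent] = []
    for parcel in parcels:
        attrs = {"area_ha": float(parcel.area_ha)}
        for name in ("slope_pct", "water_shortage", "soil_problem", "management_type"):
            attrs[name] = cfg.attribute_distributions[name].sample(rng)
        if isinstance(attrs["slope_pct"], np.floating):
            attrs["slope_pct"] = float(attrs["slope_pct"])

        drawn = {}
        for behaviour in BEHAVIOUR_TREES:
            tree = cfg.decision_trees.get(behaviour)
            if tree is None:
                raise TreeStructureError(f"missing decision tree for {behaviour!r}")
            drawn[behaviour] = evaluate_tree(tree, attrs, rng)
        arrangement, veg_type = _coerce_behaviour(
            drawn["arrangement"], drawn["vegetation_type"]
        )
        fungicides = drawn["fungicide_freqs"]
        behaviour = BehaviourState(
            arrangement=arrangement,
            vegetation_type=veg_type,
            insecticide_freq=int(drawn["insecticide_freq"]),
            pheromone=bool(drawn["pheromone"]),
            fungicide_synthetic_freq=int(fungicides[0]),
            fungicide_copper_sulfur_freq=int(fungicides[1]),
        )
        behaviour.check()
        agents.append(
            WinegrowerAgent(
                id=parcel.id,
                parcel_id=parcel.id,
                behaviour=behaviour,
                **attrs,
            )
        )
    return agents


def behaviour_shares(agents: Sequence[WinegrowerAgent]) -> dict[str, float]:
    """The seven behaviour indicators, as fractions or means over agents.

    ``share_seed_mixture`` is the share of *vegetated* vineyards whose
    vegetation is a seed mixture (0.0 when no vineyard is vegetated), from
    which the spontaneous share follows as its complement.
    """
    if not agents:
        raise ValueError("behaviour_shares of an empty agent list")
    n = len(agents)
    arr = [a.behaviour.arrangement for a in agents]
    vegetated = [a for a in agents if a.behaviour.arrangement != "bare"]
    n_veg = len(vegetated)
    return {
        "share_every": sum(x == "every" for x in arr) / n,
        "share_bare": sum(x == "bare" for x in arr) / n,
        "share_seed_mixture": (
            sum(a.behaviour.vegetation_type == "seed_mixture" for a in vegetated) / n_veg
            if n_veg
            else 0.0
        ),
        "mean_insecticide_freq": sum(a.behaviour.insecticide_freq for a in agents) / n,
        "share_pheromone": sum(a.behaviour.pheromone for a in agents) / n,
        "mean_fungicide_copper_sulfur": (
            sum(a.behaviour.fungicide_copper_sulfur_freq for a in agents) / n
        ),
        "mean_fungicide_synthetic": (
            sum(a.behaviour.fungicide_synthetic_freq for a in agents) / n
        ),
    }


def agents_to_frame(agents: Iterable[WinegrowerAgent]) -> pd.DataFrame:
    """Roster export: one row per agent with all attributes and behaviours."""
    rows = []
    for a in agents:
        row = {"id": a.id, "parcel_id": a.parcel_id}
        row.update(a.attributes())
        b = a.behaviour
        row.update(
            arrangement=b.arrangement,
            vegetation_type=b.vegetation_type,
            insecticide_freq=b.insecticide_freq,
            pheromone=b.pheromone,
            fungicide_synthetic_freq=b.fungicide_synthetic_freq,
            fungicide_copper_sulfur_freq=b.fungicide_copper_sulfur_freq,
            obligations=";".join(sorted(a.obligations)),
            blocked_options=";".join(sorted(a.blocked_options)),
        )
        rows.append(row)
    return pd.DataFrame(rows)
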