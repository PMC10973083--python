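"""Climate and policy scenario drivers.

Climate is coded annually and qualitatively: temperature 0 (baseline),
1 (warmer) or 2 (a lot warmer); precipitation -1 (drier), 0 (no change) or
1 (wetter). The default climate-change scenario fixes the ten-year code rows
(temperature 1,2,1,2,... and precipitation 1,-1,1,0,1,-1,0,-1,-1,0).

Seven policy scenarios regulate inter-row management or pesticide use; 100%
compliance is assumed and exactly one policy applies per run. A policy is
announced at its start year — obligations and blocked options register
immediately, since winegrowers are aware of a regulation before it takes
effect — while the forced behaviour change lands the following year.

* ``NA`` no new policy
* ``CS`` compulsory vegetation in every inter-row on slopes > 10%
* ``CW`` compulsory vegetation (every or every-second, random) where there is
  no water-shortage problem
* ``CA`` compulsory vegetation (every or every-second, random) everywhere
* ``NI`` insecticide ban (use set to 0, increases blocked for all)
* ``PO`` pheromone dispensers obligatory
* ``FR`` total fungicide applications reduced by one (increases blocked)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agents import WinegrowerAgent

__all__ = [
    "POLICY_IDS",
    "OPTION_CATALOGUE",
    "ClimateScenario",
    "PolicyScenario",
    "ForcedChange",
    "default_climate_change",
    "baseline_climate",
    "apply_policy_start",
    "apply_forced_change",
    "dominant_cover_type",
    "allowed_options",
]

POLICY_IDS = ("NA", "CS", "CW", "CA", "NI", "PO", "FR")

#: Every behaviour-change option an agent could take; policies subtract from it.
OPTION_CATALOGUE = frozenset(
    {
        "add_vegetation",
        "remove_vegetation",
        "switch_vegetation_type",
        "adopt_pheromone",
        "increase_insecticide",
        "decrease_insecticide",
        "increase_fungicide",
        "decrease_fungicide",
    }
)


@dataclass(frozen=True)
class ClimateScenario:
    """Coded annual temperature and precipitation rows of equal length."""

    temp_codes: tuple
    precip_codes: tuple
    name: str = "custom"

    def __post_init__(self):
        if len(self.temp_codes) != len(self.precip_codes):
            raise ValueError("temperature and precipitation rows differ in length")
        if any(t not in (0, 1, 2) for t in self.temp_codes):
            raise ValueError("temperature codes must be in {0, 1, 2}")
        if any(p not in (-1, 0, 1) for p in self.precip_codes):
            raise ValueError("precipitation codes must be in {-1, 0, 1}")

    @property
    def horizon(self) -> int:
        return len(self.temp_codes)


@dataclass(frozen=True)
class PolicyScenario:
    """One of the seven policy rules, implemented from ``start_year``."""

    id: str
    start_year: int = 1  # policies are implemented at the beginning of a run

    def __post_init__(self):
        if self.id not in POLICY_IDS:
            raise ValueError(f"unknown policy id {self.id!r}; choose from {POLICY_IDS}")
        if self.start_year < 1:
            raise ValueError("start_year must be >= 1")


@dataclass(frozen=True)
class ForcedChange:
    """A policy-mandated behaviour change taking effect the following year."""

    agent_id: int
    kind: str  # "set_arrangement" | "set_insecticide_zero" | "set_pheromone" | "fungicide_minus_one"
    value: object = None


def default_climate_change(horizon: int = 10) -> ClimateScenario:
    """The ten-year climate-change scenario with its fixed code rows."""
    if horizon != 10:
        raise ValueError("the default climate-change scenario is defined for 10 years")
    return ClimateScenario(
        temp_codes=(1, 2, 1, 2, 1, 2, 1, 2, 1, 2),
        precip_codes=(1, -1, 1, 0, 1, -1, 0, -1, -1, 0),
        name="change",
    )


def baseline_climate(horizon: int = 10) -> ClimateScenario:
    """No-change reference: all codes zero for *horizon* years."""
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    return ClimateScenario(
        temp_codes=(0,) * horizon, precip_codes=(0,) * horizon, name="baseline"
    )


def dominant_cover_type(agents: Sequence[WinegrowerAgent]) -> str:
    """The vegetation type held by more of the currently vegetated vineyards.

    Tie or no vegetated vineyard at all -> ``"seed_mixture"`` (fixed,
    documented tie-break).
    """
    spont = sum(a.behaviour.vegetation_type == "spontaneous" for a in agents)
    seed = sum(a.behaviour.vegetation_type == "seed_mixture" for a in agents)
    return "spontaneous" if spont > seed else "seed_mixture"


def apply_policy_start(
    policy: PolicyScenario,
    agents: Sequence[WinegrowerAgent],
    rng: np.random.Generator,
) -> tuple[list[ForcedChange], list[dict]]:
    """Register a policy on *agents* and schedule its forced changes.

    Mutates obligations and blocked options in place (these bind from the
    start year); returns the forced behaviour changes to apply at
    ``start_year + 1`` plus an obligation log (one record per marked agent).
    Idempotent: re-applying the same policy changes nothing further.

    The vegetation policies choose "every" vs "every_second" randomly per
    agent (CW/CA; CS mandates "every"), and a previously bare vineyard
    adopts the dominant vegetation type at the landscape scale.
    """
    changes: list[ForcedChange] = []
    log: list[dict] = []
    marker = f"policy_{policy.id}"

    def mark(agent: WinegrowerAgent, blocked: set[str]) -> bool:
        fresh = marker not in agent.obligations
        agent.obligations.add(marker)
        agent.blocked_options |= blocked
        if fresh:
            log.append({"agent_id": agent.id, "policy": policy.id, "year": policy.start_year})
        return fresh

    if policy.id == "NA":
        return changes, log

    if policy.id in ("CS", "CW", "CA"):
        dominant = dominant_cover_type(agents)
        for agent in agents:
            if policy.id == "CS":
                selected = agent.slope_pct > 10.0  # strictly above 10%
            elif policy.id == "CW":
                selected = not agent.water_shortage
            else:
                selected = True
            if not selected:
                continue
            fresh = mark(agent, {"remove_vegetation"})
            if not fresh:
                continue
            if policy.id == "CS":
                target = "every"
            else:
                target = "every" if rng.integers(2) == 0 else "every_second"
            veg_type = (
                dominant
                if agent.behaviour.arrangement == "bare"
                else agent.behaviour.vegetation_type
            )
            changes.append(
                ForcedChange(agent.id, "set_arrangement", (target, veg_type))
            )
    elif policy.id == "NI":
        for agent in agents:
            # the increase option is removed for the whole population
            agent.blocked_options.add("increase_insecticide")
            if agent.behaviour.insecticide_freq > 0:
                if mark(agent, set()):
                    changes.append(ForcedChange(agent.id, "set_insecticide_zero"))
    elif policy.id == "PO":
        for agent in agents:
            if not agent.behaviour.pheromone:
                if mark(agent, set()):
                    changes.append(ForcedChange(agent.id, "set_pheromone"))
    elif policy.id == "FR":
        for agent in agents:
            if mark(agent, {"increase_fungicide"}):
                changes.append(ForcedChange(agent.id, "fungicide_minus_one"))
    return changes, log


def apply_forced_change(agent: WinegrowerAgent, change: ForcedChange) -> bool:
    """Apply one scheduled change to *agent*; True if pheromone was newly adopted.

    The fungicide decrement removes a synthetic application first, then a
    copper/sulfur one (configurable framing: synthetic reduction is the Green
    Deal priority), flooring at zero.
    """
    b = agent.behaviour
    if change.kind == "set_arrangement":
        target, veg_type = change.value
        b.arrangement = target
        b.vegetation_type = veg_type if target != "bare" else "none"
    elif change.kind == "set_insecticide_zero":
        b.insecticide_freq = 0
    elif change.kind == "set_pheromone":
        newly = not b.pheromone
        b.pheromone = True
        return newly
    elif change.kind == "fungicide_minus_one":
        if b.fungicide_synthetic_freq > 0:
            b.fungicide_synthetic_freq -= 1
        elif b.fungicide_copper_sulfur_freq > 0:
            b.fungicide_copper_sulfur_freq -= 1
    else:
        raise ValueError(f"unknown forced change {change.kind!r}")
    b.check()
    return False


def allowed_options(agent: WinegrowerAgent) -> frozenset:
    """The full option catalogue minus the agent's blocked options."""
    return OPTION_CATALOGUE - agent.blocked_options
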