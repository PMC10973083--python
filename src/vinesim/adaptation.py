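"""The three behaviour-change channels of a winegrower.

1. **Policy awareness** — handled by the scenarios module: obligations and
   blocked options register at the policy's start year, the forced change
   lands the year after.
2. **Climate sensing** — winegrowers react to the year's qualitative codes
   on the fly, mostly via pesticide frequencies: a much-warmer year adds an
   insecticide application where insecticides are already used; a drier year
   drops one fungicide application; a wetter year adds one. The fungicide
   class follows the management type (organic -> copper/sulfur, conventional
   -> synthetic).
3. **Deliberation** — at the start of a year winegrowers reflect on last
   year's ecological outcomes; an active concern (yield, soil, pest or
   biodiversity, in that priority) is answered with at most one remedy per
   year, and only if the remedy is among the agent's allowed options.

All thresholds use strict comparisons where a boundary is possible; see
:class:`~vinesim.config.AdaptationParams` for the tunables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .agents import WinegrowerAgent
from .config import AdaptationParams
from .scenarios import allowed_options, dominant_cover_type

__all__ = [
    "ConcernState",
    "sense_climate_and_adapt",
    "update_concerns",
    "deliberate",
]


@dataclass
class ConcernState:
    """Rolling evidence one agent deliberates on."""

    yield_down_window: list = field(default_factory=list)  # per-year down increments
    last_soil_loss: float = 0.0
    init_plant_richness: float | None = None
    init_spider_richness: float | None = None
    last_plant_richness: float = 0.0
    last_spider_richness: float = 0.0
    lobesia_history: list = field(default_factory=list)  # per-year booleans
    concerns: set = field(default_factory=set)


def sense_climate_and_adapt(
    agent: WinegrowerAgent,
    temp_code: int,
    precip_code: int,
    params: AdaptationParams,
) -> list[str]:
    """Apply the on-the-fly climate rules to *agent*; return change labels.

    Baseline codes (0, 0) leave the behaviour untouched. All changes are
    filtered through the agent's allowed options; frequencies floor at 0.
    """
    if temp_code not in (0, 1, 2):
        raise ValueError(f"invalid temperature code {temp_code!r}")
    if precip_code not in (-1, 0, 1):
        raise ValueError(f"invalid precipitation code {precip_code!r}")
    rules = params.climate_rules
    options = allowed_options(agent)
    b = agent.behaviour
    changed: list[str] = []

    if temp_code == 2 and b.insecticide_freq > 0 and "increase_insecticide" in options:
        b.insecticide_freq += int(rules.get("much_warmer_insecticide_delta", 1))
        changed.append("insecticide+1")

    organic = agent.management_type == "organic"
    cls = "fungicide_copper_sulfur_freq" if organic else "fungicide_synthetic_freq"
    if precip_code == -1 and "decrease_fungicide" in options:
        delta = int(rules.get("drier_fungicide_delta", -1))
        current = getattr(b, cls)
        new = max(0, current + delta)
        if new != current:
            setattr(b, cls, new)
            changed.append(f"{cls}{delta:+d}")
    elif precip_code == 1 and "increase_fungicide" in options:
        delta = int(rules.get("wetter_fungicide_delta", 1))
        if delta:
            setattr(b, cls, getattr(b, cls) + delta)
            changed.append(f"{cls}{delta:+d}")
    b.check()
    return changed


def update_concerns(
    agent: WinegrowerAgent,
    state: ConcernState,
    params: AdaptationParams,
) -> ConcernState:
    """Re-evaluate the agent's active concern set from its rolling evidence.

    * yield: down-events within the rolling window >= threshold;
    * soil: last year's soil loss strictly above the threshold;
    * biodiversity: plant or spider richness dropped since initialisation by
      at least the threshold;
    * pest: high *L. botrana* abundance in each of the last two years.
    """
    concerns: set[str] = set()
    window = state.yield_down_window[-params.yield_concern_window :]
    if sum(window) >= params.yield_concern_events:
        concerns.add("yield")
    if state.last_soil_loss > params.soil_loss_concern:
        concerns.add("soil")
    if state.init_plant_richness is not None:
        drop = max(
            state.init_plant_richness - state.last_plant_richness,
            state.init_spider_richness - state.last_spider_richness,
        )
        if drop >= params.biodiversity_concern:
            concerns.add("biodiversity")
    if len(state.lobesia_history) >= 2 and all(state.lobesia_history[-2:]):
        concerns.add("pest")
    state.concerns = concerns
    agent.concerns = set(concerns)
    return state


def deliberate(
    agent: WinegrowerAgent,
    state: ConcernState,
    all_agents: Sequence[WinegrowerAgent],
    rng: np.random.Generator,
    params: AdaptationParams,
) -> str | None:
    """Resolve at most one concern with its remedy; return a change label.

    Concerns are visited in the configured priority order; the first whose
    remedy is applicable *and* allowed is executed, then deliberation stops
    for the year. Remedies:

    * yield — adopt a pheromone dispenser if absent (raises yield potential
      and lowers pest pressure); otherwise scale vegetation back one level,
      which only applies from full cover (every -> every_second) and only if
      removing vegetation is not blocked by an obligation;
    * soil — step vegetation cover up one level; a previously bare vineyard
      adopts the dominant vegetation type at the landscape scale;
    * pest — switch the vegetation type to spontaneous (the higher natural
      predation rate);
    * biodiversity — drop one pesticide application (insecticide first, then
      synthetic fungicide, then copper/sulfur).
    """
    options = allowed_options(agent)
    b = agent.behaviour
    for concern in params.concern_priority:
        if concern not in state.concerns:
            continue
        if concern == "yield":
            if not b.pheromone and "adopt_pheromone" in options:
                b.pheromone = True
                return "adopt_pheromone"
            if b.arrangement == "every" and "remove_vegetation" in options:
                b.arrangement = "every_second"
                return "arrangement_down"
        elif concern == "soil":
            if b.arrangement == "bare" and "add_vegetation" in options:
                b.arrangement = "every_second"
                b.vegetation_type = dominant_cover_type(all_agents)
                b.check()
                return "arrangement_up"
            if b.arrangement == "every_second" and "add_vegetation" in options:
                b.arrangement = "every"
                return "arrangement_up"
        elif concern == "pest":
            if (
                b.arrangement != "bare"
                and b.vegetation_type != "spontaneous"
                and "switch_vegetation_type" in options
            ):
                b.vegetation_type = "spontaneous"
                return "vegetation_type_spontaneous"
        elif concern == "biodiversity":
            if b.insecticide_freq > 0 and "decrease_insecticide" in options:
                b.insecticide_freq -= 1
                return "insecticide-1"
            if b.fungicide_total > 0 and "decrease_fungicide" in options:
                if b.fungicide_synthetic_freq > 0:
                    b.fungicide_synthetic_freq -= 1
                else:
                    b.fungicide_copper_sulfur_freq -= 1
                return "fungicide-1"
    return None
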