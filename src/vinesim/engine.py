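"""Annual simulation loop coupling winegrowers, scenarios and ecology.

One run advances a single case study for ``horizon`` years (default 10, one
time step per year). The within-year ordering is fixed: policy registration
and policy-forced changes first, then on-the-fly climate adaptation, then
deliberation on *last* year's ecological outcomes, and finally this year's
ecology — so the ecological state of a year always reflects the year's final
behaviour, and deliberation always looks backwards. Year 1 computes ecology
before any deliberation can occur (there is no history yet).

Randomness is a single seed split into named substreams (landscape, parcels,
agents, policy, deliberation, lobesia), so adding a draw in one module never
perturbs another; a run is bit-identical under a fixed
``(config, climate, policy, seed)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adaptation import ConcernState, deliberate, sense_climate_and_adapt, update_concerns
from .agents import behaviour_shares, init_agents
from .config import CaseStudyConfig
from .ecology import (
    EcologicalState,
    landscape_aesthetics,
    lobesia_high_prob,
    plant_richness,
    predation_rate,
    soil_loss,
    spider_richness,
    update_yield_events,
)
from .landscape import carve_parcels, generate_abstract_landscape
from .scenarios import (
    ClimateScenario,
    ForcedChange,
    PolicyScenario,
    apply_forced_change,
    apply_policy_start,
)

__all__ = ["RunResult", "run", "indicators", "INDICATOR_NAMES"]

#: The thirteen mean-over-time-steps indicators plus the two end-of-run totals.
INDICATOR_NAMES = (
    "share_every",
    "share_bare",
    "share_seed_mixture",
    "mean_insecticide_freq",
    "share_pheromone",
    "mean_fungicide_copper_sulfur",
    "mean_fungicide_synthetic",
    "aesthetics",
    "mean_soil_loss",
    "mean_plant_richness",
    "mean_spider_richness",
    "mean_predation_rate",
    "share_lobesia_high",
    "yield_up_total",
    "yield_down_total",
)


@dataclass
class RunResult:
    """Trajectories, decision log and metadata of one simulation run."""

    trajectories: pd.DataFrame  # one row per (year, agent)
    yearly: pd.DataFrame  # one row per year, landscape-level aggregates
    decision_log: pd.DataFrame  # (year, agent_id, channel, change)
    obligation_log: pd.DataFrame
    horizon: int
    seed: int
    policy: str
    climate: str
    config_name: str


def _stream(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), tag])


def run(
    cfg: CaseStudyConfig,
    climate: ClimateScenario,
    policy: PolicyScenario,
    seed: int,
    horizon: int = 10,
) -> RunResult:
    """Execute one complete run; pure function of its arguments.

    Raises
    ------
    ValueError
        If the climate scenario length differs from *horizon*.
    """
    if climate.horizon != horizon:
        raise ValueError(
            f"climate scenario length {climate.horizon} != horizon {horizon}"
        )
    grid = generate_abstract_landscape(
        cfg.landcover_shares, cfg.grid_cells, seed=seed, cell_size_m=cfg.cell_size_m
    )
    parcels = carve_parcels(
        grid, cfg.n_winegrowers, cfg.attribute_distributions["area_ha"], seed=seed
    )
    agents = init_agents(parcels, cfg, seed=seed)
    agents.sort(key=lambda a: a.id)

    rng_policy = _stream(seed, 0x501C)  # policy random arrangement choices
    rng_delib = _stream(seed, 0xDE1B)
    rng_lobesia = _stream(seed, 0x10BE)

    eco_states = {a.id: EcologicalState() for a in agents}
    concern_states = {a.id: ConcernState() for a in agents}
    pending: list[ForcedChange] = []
    pending_year: int | None = None

    traj_rows: list[dict] = []
    yearly_rows: list[dict] = []
    decision_rows: list[dict] = []
    obligation_rows: list[dict] = []

    for year in range(1, horizon + 1):
        temp_code = climate.temp_codes[year - 1]
        precip_code = climate.precip_codes[year - 1]
        newly_pheromone: set[int] = set()

        # (1) policy: register at start year; forced changes land next year
        if year == policy.start_year:
            pending, oblog = apply_policy_start(policy, agents, rng_policy)
            pending_year = year + 1
            obligation_rows.extend(oblog)
        if pending and pending_year == year:
            for change in pending:
                agent = next(a for a in agents if a.id == change.agent_id)
                if apply_forced_change(agent, change):
                    newly_pheromone.add(agent.id)
                decision_rows.append(
                    {"year": year, "agent_id": agent.id, "channel": "policy",
                     "change": change.kind}
                )
            pending = []

        # (2) on-the-fly climate adaptation
        for agent in agents:
            for label in sense_climate_and_adapt(
                agent, temp_code, precip_code, cfg.adaptation
            ):
                decision_rows.append(
                    {"year": year, "agent_id": agent.id, "channel": "climate",
                     "change": label}
                )

        # (3) deliberation on last year's ecology (needs at least one year)
        if year > 1:
            for agent in agents:
                state = update_concerns(agent, concern_states[agent.id], cfg.adaptation)
                label = deliberate(agent, state, agents, rng_delib, cfg.adaptation)
                if label is not None:
                    if label == "adopt_pheromone":
                        newly_pheromone.add(agent.id)
                    decision_rows.append(
                        {"year": year, "agent_id": agent.id,
                         "channel": "deliberation", "change": label}
                    )

        # (4) ecology of the year's final behaviour
        for agent in agents:
            eco = eco_states[agent.id]
            eco.soil_loss = soil_loss(
                agent.behaviour, agent.slope_pct, precip_code, cfg.ecology
            )
            eco.predation_rate = predation_rate(agent.behaviour, cfg.ecology)
            p_high = lobesia_high_prob(
                agent.behaviour, eco.predation_rate, temp_code, cfg.ecology
            )
            eco.lobesia_high = bool(rng_lobesia.random() < p_high)
            eco.plant_richness = plant_richness(agent.behaviour, cfg.ecology)
            eco.spider_richness = spider_richness(agent.behaviour, cfg.ecology)
            up, down = update_yield_events(
                agent, eco, eco.lobesia_high, agent.id in newly_pheromone
            )

            cs = concern_states[agent.id]
            cs.yield_down_window.append(down)
            cs.yield_down_window = cs.yield_down_window[-cfg.adaptation.yield_concern_window:]
            cs.last_soil_loss = eco.soil_loss
            if cs.init_plant_richness is None:
                cs.init_plant_richness = eco.plant_richness
                cs.init_spider_richness = eco.spider_richness
            cs.last_plant_richness = eco.plant_richness
            cs.last_spider_richness = eco.spider_richness
            cs.lobesia_history.append(eco.lobesia_high)

            b = agent.behaviour
            traj_rows.append(
                {
                    "year": year, "agent_id": agent.id,
                    "arrangement": b.arrangement,
                    "vegetation_type": b.vegetation_type,
                    "insecticide_freq": b.insecticide_freq,
                    "pheromone": b.pheromone,
                    "fungicide_synthetic_freq": b.fungicide_synthetic_freq,
                    "fungicide_copper_sulfur_freq": b.fungicide_copper_sulfur_freq,
                    "soil_loss": eco.soil_loss,
                    "predation_rate": eco.predation_rate,
                    "lobesia_high": eco.lobesia_high,
                    "plant_richness": eco.plant_richness,
                    "spider_richness": eco.spider_richness,
                    "yield_up_events": eco.yield_up_events,
                    "yield_down_events": eco.yield_down_events,
                }
            )

        # (5) record landscape-level aggregates of the year
        shares = behaviour_shares(agents)
        year_row = {"year": year, **shares}
        year_row["aesthetics"] = landscape_aesthetics(agents)
        year_row["mean_soil_loss"] = float(
            np.mean([eco_states[a.id].soil_loss for a in agents])
        )
        year_row["mean_plant_richness"] = float(
            np.mean([eco_states[a.id].plant_richness for a in agents])
        )
        year_row["mean_spider_richness"] = float(
            np.mean([eco_states[a.id].spider_richness for a in agents])
        )
        year_row["mean_predation_rate"] = float(
            np.mean([eco_states[a.id].predation_rate for a in agents])
        )
        year_row["share_lobesia_high"] = float(
            np.mean([eco_states[a.id].lobesia_high for a in agents])
        )
        yearly_rows.append(year_row)

    return RunResult(
        trajectories=pd.DataFrame(traj_rows),
        yearly=pd.DataFrame(yearly_rows),
        decision_log=pd.DataFrame(
            decision_rows, columns=["year", "agent_id", "channel", "change"]
        ),
        obligation_log=pd.DataFrame(
            obligation_rows, columns=["agent_id", "policy", "year"]
        ),
        horizon=horizon,
        seed=int(seed),
        policy=policy.id,
        climate=climate.name,
        config_name=cfg.name,
    )


def indicators(result: RunResult) -> dict[str, float]:
    """Aggregate a run into the fifteen outcome indicators.

    Thirteen indicators are arithmetic means over years of per-year
    landscape aggregates; the two yield-event totals are per-vineyard means
    of the final cumulative counters. Derived indicators
    (``share_every_second``, ``share_spontaneous``) follow from the partition
    identities and are included for convenience.
    """
    if len(result.yearly) != result.horizon:
        raise ValueError("incomplete trajectory: yearly records != horizon")
    out: dict[str, float] = {}
    for name in INDICATOR_NAMES[:13]:
        out[name] = float(result.yearly[name].mean())
    final = result.trajectories[result.trajectories["year"] == result.horizon]
    out["yield_up_total"] = float(final["yield_up_events"].mean())
    out["yield_down_total"] = float(final["yield_down_events"].mean())
    out["share_every_second"] = 1.0 - out["share_every"] - out["share_bare"]
    out["share_spontaneous"] = 1.0 - out["share_seed_mixture"]
    return out
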