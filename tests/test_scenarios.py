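"""Climate codes and policy mechanics per the scenario rules."""

import numpy as np
import pytest

from vinesim.agents import BehaviourState, WinegrowerAgent
from vinesim.scenarios import (
    OPTION_CATALOGUE,
    ClimateScenario,
    PolicyScenario,
    allowed_options,
    apply_forced_change,
    apply_policy_start,
    baseline_climate,
    default_climate_change,
    dominant_cover_type,
)


def _agent(i=0, **kw):
    defaults = dict(
        id=i, parcel_id=i, area_ha=2.0, slope_pct=5.0, water_shortage=False,
        soil_problem=False, management_type="conventional",
        behaviour=BehaviourState(),
    )
    defaults.update(kw)
    return WinegrowerAgent(**defaults)


def _apply_all(policy, agents, seed=0):
    changes, log = apply_policy_start(policy, agents, np.random.default_rng(seed))
    newly = set()
    for ch in agents:
        pass
    for change in changes:
        agent = next(a for a in agents if a.id == change.agent_id)
        if apply_forced_change(agent, change):
            newly.add(agent.id)
    return changes, log, newly


class TestClimate:
    def test_default_change_rows(self):
        clim = default_climate_change()
        assert clim.temp_codes == (1, 2, 1, 2, 1, 2, 1, 2, 1, 2)
        assert clim.precip_codes == (1, -1, 1, 0, 1, -1, 0, -1, -1, 0)

    def test_default_change_code_counts(self):
        clim = default_climate_change()
        assert clim.temp_codes.count(2) == 5  # much warmer years
        assert clim.precip_codes.count(1) == 3  # wetter
        assert clim.precip_codes.count(-1) == 4  # drier
        assert clim.precip_codes.count(0) == 3  # normal

    def test_baseline_all_zero(self):
        clim = baseline_climate(10)
        assert sum(clim.temp_codes) + sum(clim.precip_codes) == 0
        assert baseline_climate(1).temp_codes == (0,)

    def test_invalid_codes_rejected(self):
        with pytest.raises(ValueError):
            ClimateScenario(temp_codes=(3,), precip_codes=(0,))
        with pytest.raises(ValueError):
            ClimateScenario(temp_codes=(0, 0), precip_codes=(0,))

    def test_unknown_policy_rejected(self):
        with pytest.raises(ValueError, match="unknown policy"):
            PolicyScenario("XX")


class TestSlopePolicy:
    def test_strictly_above_ten_percent(self):
        agents = [_agent(i, slope_pct=s) for i, s in enumerate([5, 10, 10.1, 15])]
        changes, log, _ = _apply_all(PolicyScenario("CS"), agents)
        obliged = {a.id for a in agents if "policy_CS" in a.obligations}
        assert obliged == {2, 3}
        assert {c.agent_id for c in changes} == {2, 3}

    def test_forces_every_and_blocks_removal(self):
        agent = _agent(0, slope_pct=20, behaviour=BehaviourState(arrangement="every_second"))
        _apply_all(PolicyScenario("CS"), [agent])
        assert agent.behaviour.arrangement == "every"
        assert "remove_vegetation" not in allowed_options(agent)

    def test_previously_bare_adopts_dominant_type(self):
        bare = _agent(0, slope_pct=20,
                      behaviour=BehaviourState(arrangement="bare", vegetation_type="none"))
        others = [
            _agent(i, behaviour=BehaviourState(vegetation_type="spontaneous"))
            for i in range(1, 4)
        ]
        _apply_all(PolicyScenario("CS"), [bare] + others)
        assert bare.behaviour.arrangement == "every"
        assert bare.behaviour.vegetation_type == "spontaneous"


class TestWaterAndAllPolicies:
    def test_cw_targets_no_shortage(self):
        wet = _agent(0, water_shortage=False,
                     behaviour=BehaviourState(arrangement="bare", vegetation_type="none"))
        dry = _agent(1, water_shortage=True,
                     behaviour=BehaviourState(arrangement="bare", vegetation_type="none"))
        _apply_all(PolicyScenario("CW"), [wet, dry])
        assert wet.behaviour.arrangement in ("every", "every_second")
        assert dry.behaviour.arrangement == "bare"

    def test_ca_targets_everyone_random_arrangement(self):
        agents = [
            _agent(i, behaviour=BehaviourState(arrangement="bare", vegetation_type="none"))
            for i in range(40)
        ]
        _apply_all(PolicyScenario("CA"), agents, seed=3)
        arrangements = {a.behaviour.arrangement for a in agents}
        assert "bare" not in arrangements
        assert arrangements == {"every", "every_second"}  # random per-agent choice


class TestPesticidePolicies:
    def test_insecticide_ban_zeroes_next_year(self):
        user = _agent(0, behaviour=BehaviourState(insecticide_freq=7))
        clean = _agent(1)
        changes, _, _ = _apply_all(PolicyScenario("NI"), [user, clean])
        assert user.behaviour.insecticide_freq == 0
        assert {c.agent_id for c in changes} == {0}
        # increase blocked for the whole population, users or not
        for a in (user, clean):
            assert "increase_insecticide" not in allowed_options(a)

    def test_pheromone_obligation(self):
        off = _agent(0, behaviour=BehaviourState(pheromone=False))
        on = _agent(1, behaviour=BehaviourState(pheromone=True))
        changes, _, newly = _apply_all(PolicyScenario("PO"), [off, on])
        assert off.behaviour.pheromone and on.behaviour.pheromone
        assert newly == {0}  # only the fresh adoption counts as an adoption event

    def test_fungicide_reduction_total_minus_one(self):
        agent = _agent(0, behaviour=BehaviourState(
            fungicide_synthetic_freq=8, fungicide_copper_sulfur_freq=2))
        _apply_all(PolicyScenario("FR"), [agent])
        assert agent.behaviour.fungicide_total == 9
        assert agent.behaviour.fungicide_synthetic_freq == 7  # synthetic first
        assert "increase_fungicide" not in allowed_options(agent)

    def test_fungicide_reduction_falls_back_to_copper(self):
        agent = _agent(0, behaviour=BehaviourState(fungicide_copper_sulfur_freq=3))
        _apply_all(PolicyScenario("FR"), [agent])
        assert agent.behaviour.fungicide_copper_sulfur_freq == 2

    def test_fungicide_reduction_floors_at_zero(self):
        agent = _agent(0)
        _apply_all(PolicyScenario("FR"), [agent])
        assert agent.behaviour.fungicide_total == 0


class TestDominantCover:
    def test_majority(self):
        agents = [
            _agent(i, behaviour=BehaviourState(vegetation_type="spontaneous"))
            for i in range(6)
        ] + [
            _agent(6 + i, behaviour=BehaviourState(vegetation_type="seed_mixture"))
            for i in range(4)
        ]
        assert dominant_cover_type(agents) == "spontaneous"

    def test_single_vegetated(self):
        agents = [_agent(0, behaviour=BehaviourState(vegetation_type="seed_mixture"))]
        assert dominant_cover_type(agents) == "seed_mixture"

    def test_tie_breaks_to_seed_mixture(self):
        agents = [
            _agent(0, behaviour=BehaviourState(vegetation_type="spontaneous")),
            _agent(1, behaviour=BehaviourState(vegetation_type="seed_mixture")),
        ]
        assert dominant_cover_type(agents) == "seed_mixture"

    def test_no_vegetated_fallback(self):
        agents = [_agent(0, behaviour=BehaviourState(arrangement="bare", vegetation_type="none"))]
        assert dominant_cover_type(agents) == "seed_mixture"


class TestOptions:
    def test_unmarked_agent_has_full_catalogue(self):
        assert allowed_options(_agent(0)) == OPTION_CATALOGUE

    def test_blocked_option_excluded(self):
        agent = _agent(0)
        agent.blocked_options.add("increase_insecticide")
        assert "increase_insecticide" not in allowed_options(agent)

    def test_policy_application_idempotent(self):
        agents = [_agent(i, slope_pct=20) for i in range(5)]
        rng = np.random.default_rng(0)
        changes1, log1 = apply_policy_start(PolicyScenario("CS"), agents, rng)
        changes2, log2 = apply_policy_start(PolicyScenario("CS"), agents, rng)
        assert changes1 and log1
        assert changes2 == [] and log2 == []

    def test_na_is_noop(self):
        agent = _agent(0, behaviour=BehaviourState(insecticide_freq=4))
        changes, log = apply_policy_start(
            PolicyScenario("NA"), [agent], np.random.default_rng(0)
        )
        assert changes == [] and log == []
        assert agent.behaviour.insecticide_freq == 4
        assert allowed_options(agent) == OPTION_CATALOGUE
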