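"""Ecological impact functions: closed forms, orderings and properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vinesim.agents import BehaviourState, WinegrowerAgent
from vinesim.config import EcologyParams
from vinesim.ecology import (
    EcologicalState,
    landscape_aesthetics,
    lobesia_high_prob,
    plant_richness,
    predation_rate,
    soil_loss,
    spider_richness,
    update_yield_events,
)

P = EcologyParams()


def _b(**kw):
    defaults = dict(arrangement="every", vegetation_type="spontaneous")
    defaults.update(kw)
    return BehaviourState(**defaults)


def _agent(**kw):
    defaults = dict(
        id=0, parcel_id=0, area_ha=2.0, slope_pct=5.0, water_shortage=False,
        soil_problem=False, management_type="conventional", behaviour=_b(),
    )
    defaults.update(kw)
    return WinegrowerAgent(**defaults)


@st.composite
def ecology_params(draw):
    """Random EcologyParams honouring every configured ordering constraint."""
    c_every = draw(st.floats(0.05, 0.5))
    c_half = c_every + draw(st.floats(0.05, 0.5))
    c_bare = c_half + draw(st.floats(0.05, 0.5))
    p_none = draw(st.floats(0.01, 0.3))
    p_seed = p_none + draw(st.floats(0.02, 0.3))
    p_spont = p_seed + draw(st.floats(0.02, 0.3))
    drier = draw(st.floats(0.3, 1.0))
    wetter = draw(st.floats(1.0, 2.0))
    w1 = draw(st.floats(1.0, 1.3))
    w2 = w1 + draw(st.floats(0.0, 0.5))
    r_none = draw(st.floats(1.0, 8.0))
    r_sp_half = r_none + draw(st.floats(0.5, 5.0))
    r_sp_full = r_sp_half + draw(st.floats(0.5, 5.0))
    r_se_half = r_sp_half + draw(st.floats(0.5, 5.0))
    r_se_full = max(r_sp_full, r_se_half) + draw(st.floats(0.5, 5.0))
    return EcologyParams(
        soil_base_rate=draw(st.floats(0.5, 20.0)),
        soil_slope_exponent=draw(st.floats(0.5, 3.0)),
        soil_cover_bare=c_bare,
        soil_cover_every_second=c_half,
        soil_cover_every=c_every,
        soil_precip_mult={-1: drier, 0: 1.0, 1: wetter},
        predation_base={"none": p_none, "spontaneous": p_spont, "seed_mixture": p_seed},
        predation_insecticide_atten=draw(st.floats(0.2, 1.0)),
        predation_fungicide_atten=draw(st.floats(0.5, 1.0)),
        lobesia_baseline=draw(st.floats(0.0, 1.0)),
        lobesia_pheromone_factor=draw(st.floats(0.0, 0.99)),
        lobesia_insecticide_factor=draw(st.floats(0.0, 0.99)),
        lobesia_predation_weight=draw(st.floats(0.0, 1.0)),
        lobesia_warm_mult={0: 1.0, 1: w1, 2: w2},
        plant_richness={
            ("none", "bare"): r_none,
            ("spontaneous", "every_second"): r_sp_half,
            ("spontaneous", "every"): r_sp_full,
            ("seed_mixture", "every_second"): r_se_half,
            ("seed_mixture", "every"): r_se_full,
        },
        spider_base=draw(st.floats(1.0, 15.0)),
        spider_insecticide_penalty=draw(st.floats(0.1, 3.0)),
        spider_cover_bonus=draw(st.floats(0.5, 10.0)),
    )


class TestSoilLoss:
    def test_flat_slope_closed_form(self):
        loss = soil_loss(_b(arrangement="bare", vegetation_type="none"), 0.0, 0, P)
        assert loss == pytest.approx(P.soil_base_rate * P.soil_cover_bare)

    def test_cover_ordering(self):
        bare = soil_loss(_b(arrangement="bare", vegetation_type="none"), 10, 0, P)
        half = soil_loss(_b(arrangement="every_second"), 10, 0, P)
        full = soil_loss(_b(arrangement="every"), 10, 0, P)
        assert bare > half > full

    def test_monotone_in_slope(self):
        losses = [soil_loss(_b(), s, 0, P) for s in np.linspace(0, 30, 31)]
        assert all(b >= a for a, b in zip(losses, losses[1:]))

    def test_precipitation_ordering(self):
        wet = soil_loss(_b(), 10, 1, P)
        normal = soil_loss(_b(), 10, 0, P)
        dry = soil_loss(_b(), 10, -1, P)
        assert wet >= normal >= dry

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="precipitation"):
            soil_loss(_b(), 10, 2, P)


class TestPredation:
    def test_vegetation_ordering_without_pesticides(self):
        spont = predation_rate(_b(vegetation_type="spontaneous"), P)
        seed = predation_rate(_b(vegetation_type="seed_mixture"), P)
        bare = predation_rate(_b(arrangement="bare", vegetation_type="none"), P)
        assert spont > seed > bare

    def test_attenuation_closed_form(self):
        r0 = predation_rate(_b(insecticide_freq=0), P)
        r1 = predation_rate(_b(insecticide_freq=1), P)
        assert r1 == pytest.approx(r0 * P.predation_insecticide_atten)

    def test_heavy_insecticide_drives_rate_to_zero(self):
        assert predation_rate(_b(insecticide_freq=500), P) == pytest.approx(0.0, abs=1e-12)

    def test_fungicides_also_attenuate(self):
        base = predation_rate(_b(), P)
        sprayed = predation_rate(_b(fungicide_synthetic_freq=5, fungicide_copper_sulfur_freq=5), P)
        assert sprayed == pytest.approx(base * P.predation_fungicide_atten**10)


class TestLobesia:
    def test_pheromone_strictly_lowers(self):
        off = lobesia_high_prob(_b(pheromone=False), 0.3, 0, P)
        on = lobesia_high_prob(_b(pheromone=True), 0.3, 0, P)
        assert on < off

    def test_full_predation_forces_zero(self):
        params = EcologyParams(lobesia_predation_weight=1.0)
        assert lobesia_high_prob(_b(), 1.0, 0, params) == 0.0

    def test_warm_year_ordering(self):
        probs = [lobesia_high_prob(_b(), 0.2, code, P) for code in (0, 1, 2)]
        assert probs[0] <= probs[1] <= probs[2]

    def test_invalid_code(self):
        with pytest.raises(ValueError, match="temperature"):
            lobesia_high_prob(_b(), 0.2, 3, P)

    def test_bernoulli_share_matches_probability(self):
        """The high-abundance indicator is the mean of Bernoulli draws with this p."""
        p = lobesia_high_prob(_b(pheromone=True), 0.3, 1, P)
        rng = np.random.default_rng(123)
        draws = rng.random(10_000) < p
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs(draws.mean() - p) <= 3 * se


class TestRichness:
    def test_bare_is_minimum_plant_richness(self):
        bare = plant_richness(_b(arrangement="bare", vegetation_type="none"), P)
        assert bare == min(P.plant_richness.values())

    def test_seed_mixture_above_spontaneous(self):
        seed = plant_richness(_b(vegetation_type="seed_mixture"), P)
        spont = plant_richness(_b(vegetation_type="spontaneous"), P)
        assert seed > spont

    def test_reducing_cover_never_raises_richness(self):
        for veg in ("spontaneous", "seed_mixture"):
            full = plant_richness(_b(arrangement="every", vegetation_type=veg), P)
            half = plant_richness(_b(arrangement="every_second", vegetation_type=veg), P)
            assert half <= full

    def test_spider_base_when_bare_unsprayed(self):
        b = _b(arrangement="bare", vegetation_type="none")
        assert spider_richness(b, P) == P.spider_base

    def test_spider_insecticide_penalty_exact(self):
        r0 = spider_richness(_b(insecticide_freq=0), P)
        r1 = spider_richness(_b(insecticide_freq=1), P)
        assert r0 - r1 == pytest.approx(P.spider_insecticide_penalty)
        assert spider_richness(_b(insecticide_freq=10_000), P) == 0.0

    def test_vegetated_beats_bare(self):
        veg = spider_richness(_b(arrangement="every"), P)
        bare = spider_richness(_b(arrangement="bare", vegetation_type="none"), P)
        assert veg > bare


class TestAesthetics:
    def test_all_every_is_one(self):
        agents = [_agent(id=i) for i in range(3)]
        assert landscape_aesthetics(agents) == 1.0

    def test_equal_area_symmetry(self):
        a = _agent(id=0)
        b = _agent(id=1, behaviour=_b(arrangement="bare", vegetation_type="none"))
        assert landscape_aesthetics([a, b]) == 0.5

    def test_weighted_mean(self):
        a = _agent(id=0, area_ha=2.0, behaviour=_b(arrangement="every_second"))
        b = _agent(id=1, area_ha=2.0, behaviour=_b(arrangement="bare", vegetation_type="none"))
        assert landscape_aesthetics([a, b]) == 0.25

    def test_order_and_scale_invariance(self):
        agents = [
            _agent(id=0, area_ha=1.0),
            _agent(id=1, area_ha=3.0, behaviour=_b(arrangement="every_second")),
            _agent(id=2, area_ha=2.0, behaviour=_b(arrangement="bare", vegetation_type="none")),
        ]
        base = landscape_aesthetics(agents)
        assert landscape_aesthetics(agents[::-1]) == base
        for a in agents:
            a.area_ha *= 7.0
        assert landscape_aesthetics(agents) == pytest.approx(base)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            landscape_aesthetics([])


class TestYieldEvents:
    def test_quiet_year_no_events(self):
        agent = _agent(behaviour=_b(arrangement="bare", vegetation_type="none"))
        eco = EcologicalState()
        assert update_yield_events(agent, eco, False, False) == (0, 0)
        assert (eco.yield_up_events, eco.yield_down_events) == (0, 0)

    def test_competition_and_pest_both_count(self):
        agent = _agent(water_shortage=True)
        eco = EcologicalState()
        assert update_yield_events(agent, eco, True, False) == (0, 2)

    def test_pheromone_adoption_year_counts_up(self):
        agent = _agent(behaviour=_b(pheromone=True))
        eco = EcologicalState()
        up, _ = update_yield_events(agent, eco, False, True)
        assert up >= 1

    def test_counters_monotone(self):
        agent = _agent(water_shortage=True)
        eco = EcologicalState()
        seen = []
        for lob in (True, False, True, True):
            update_yield_events(agent, eco, lob, False)
            seen.append((eco.yield_up_events, eco.yield_down_events))
        assert seen == sorted(seen)


@settings(max_examples=150, deadline=None, derandomize=True)
@given(params=ecology_params(), slope=st.floats(0, 35), freq=st.integers(0, 12))
def test_orderings_hold_for_randomized_params(params, slope, freq):
    """Every printed direction holds for any valid coefficient draw."""
    assert params.validate() == []
    bare = _b(arrangement="bare", vegetation_type="none", insecticide_freq=freq)
    half = _b(arrangement="every_second", insecticide_freq=freq)
    full = _b(arrangement="every", insecticide_freq=freq)
    # soil: cover and precipitation directions
    assert (
        soil_loss(bare, slope, 0, params)
        > soil_loss(half, slope, 0, params)
        > soil_loss(full, slope, 0, params)
    )
    assert soil_loss(full, slope, 1, params) >= soil_loss(full, slope, -1, params)
    # predation: spontaneous > seed mixture > bare at zero pesticides
    clean = dict(insecticide_freq=0)
    assert (
        predation_rate(_b(vegetation_type="spontaneous", **clean), params)
        > predation_rate(_b(vegetation_type="seed_mixture", **clean), params)
        > predation_rate(_b(arrangement="bare", vegetation_type="none", **clean), params)
    )
    # plant richness: seed mixture > spontaneous > none
    assert (
        plant_richness(_b(vegetation_type="seed_mixture"), params)
        > plant_richness(_b(vegetation_type="spontaneous"), params)
        > plant_richness(_b(arrangement="bare", vegetation_type="none"), params)
    )
    # lobesia: monotone directions
    p_off = lobesia_high_prob(_b(pheromone=False), 0.5, 1, params)
    p_on = lobesia_high_prob(_b(pheromone=True), 0.5, 1, params)
    assert p_on <= p_off
    codes = [lobesia_high_prob(_b(), 0.5, c, params) for c in (0, 1, 2)]
    assert codes[0] <= codes[1] <= codes[2]
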