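# Methods

## Scope and entities

`vinesim` couples a population of winegrower agents to the ecological state
of their vineyards on an abstract regional landscape and advances the system
annually for a 10-year horizon. Longer horizons would drag in processes the
model deliberately excludes (land-use competition, farm succession, market
prices), so 10 years is the default and the scenario definitions assume it.

Entities: a land-cover grid (six classes), vineyard parcels (elongated
axis-aligned rectangles on viticulture cells), winegrower agents (one per
parcel), a per-vineyard ecological state, and two exogenous drivers (a coded
climate scenario and one policy scenario per run).

## Landscape generation

The grid is square (default 100 x 100 cells of 100 m, i.e. 10 km x 10 km,
1 ha per cell). Class shares are converted to exact cell quotas by
largest-remainder rounding, so realized fractions sit within one cell of the
request — far inside the ±0.005 tolerance the generator promises. Layout is
competitive region growing: each class seeds one random cell and claims
random frontier cells, classes drawn with probability proportional to their
remaining deficit; an exhausted frontier restarts from a fresh unassigned
cell. This yields contiguous blobs (tests bound the component count) rather
than pixel noise. Configurations keep the viticultural share inside the
26–27% band that makes the three regional landscapes comparable; validation
enforces the band.

Parcels are 1 x k cell runs, k = max(3, round(area_ha / cell_area)), so the
aspect ratio is always >= 3 (vineyards read as elongated rectangles).
Placement is seeded rejection sampling over viticulture cells with an
exhaustive deterministic fallback; an infeasible request fails naming the
achievable parcel count. The drawn area (not the integer footprint) is the
agent's `area_ha` attribute.

## Agent initialisation

Attributes are sampled from per-attribute distribution specs (uniform,
truncated normal, Bernoulli, categorical — the minimal family needed to
express "generated randomly at the individual level" with landscape-level
statistics). Initial behaviours come from five declarative decision trees
(arrangement, vegetation type, insecticide frequency, pheromone use, and a
fungicide tree whose leaves emit a `[synthetic, copper_sulfur]` pair).
Distribution leaves let a tree reproduce expert-reported population shares
without survey microdata. On an arrangement/vegetation-type conflict the
arrangement wins (it is the physically prior choice): bare forces type
`none`; a vegetated arrangement with a `none` draw falls back to
spontaneous vegetation.

## Ecological impact functions

Coefficients live in `EcologyParams`; the forms encode only directions that
are robustly documented, so better regional coefficients can be dropped in
via configuration. Defaults (units in brackets):

| Parameter | Default | Meaning |
|---|---|---|
| `soil_base_rate` | 5.0 [t/ha/yr] | bare, flat, normal-precipitation erosion |
| `soil_slope_exponent` | 2.0 | slope term `(1 + slope/100)^e` |
| `soil_cover_*` | 1.0 / 0.5 / 0.2 | bare / every-2nd / every cover factors |
| `soil_precip_mult` | 0.7 / 1.0 / 1.4 | drier / normal / wetter multiplier |
| `predation_base` | 0.2 / 0.45 / 0.6 | none / seed mixture / spontaneous |
| `predation_*_atten` | 0.8, 0.97 | per insecticide / fungicide application |
| `lobesia_baseline` | 0.5 | P(high abundance), unmanaged reference |
| `lobesia_pheromone_factor` | 0.4 | mating-disruption multiplier |
| `lobesia_insecticide_factor` | 0.7 | per application |
| `lobesia_predation_weight` | 0.8 | `1 - w * predation` term |
| `lobesia_warm_mult` | 1.0 / 1.1 / 1.25 | temperature codes 0 / 1 / 2 |
| `plant_richness` | 5 … 30 | lookup by (type, arrangement) |
| `spider_base`, bonus, penalty | 8, 6, 1.5 | base + cover bonus − per-application penalty |

The soil slope term was chosen over a linear factor because it is exact at
flat slope, bounded, and monotone without additional constants. The
high-abundance indicator is realized as one seeded Bernoulli draw per
vineyard-year; its share over vineyards is the landscape indicator.
Yield potential is tracked as event counters, not quantities: vegetated
inter-rows on a water-short vineyard and a high-pest year each add a
decrease event; newly adopting a pheromone dispenser adds an increase event.
Landscape aesthetics is strictly the area-weighted share of vegetated
inter-rows.

Validation enforces every ordering (cover factors, predation bases, richness
table, warm multipliers) for *any* user-supplied coefficients, and property
tests re-check the directional conclusions under 1000 randomized valid
parameterizations, so the qualitative results do not hinge on the default
numbers.

## Scenarios

Climate is coded annually and qualitatively (growers reason in qualitative
terms): temperature 0/1/2 (baseline/warmer/much warmer), precipitation
−1/0/1. The default change scenario fixes the decade's rows —
temperature `1212121212`, precipitation `1,−1,1,0,1,−1,0,−1,−1,0` — i.e. 5
much-warmer years, 3 wetter, 4 drier, 3 normal. The reference scenario is
all zeros.

Policies (one per run, 100% compliance): obligations and option blocks
register at the start year (growers know a regulation before it binds); the
forced behaviour lands the following year. CS selects slopes strictly above
10% and mandates vegetation in every inter-row; CW (no water shortage) and
CA (everyone) choose every vs every-2nd uniformly at random per agent; a
previously bare vineyard adopts the dominant vegetation type among currently
vegetated vineyards (tie, or no vegetated vineyard: seed mixture — an
arbitrary but fixed tie-break). NI zeroes insecticide use and blocks
increases population-wide; PO sets pheromone use to true; FR removes one
fungicide application (synthetic first, matching the pesticide-reduction
policy framing; configurable in code) and blocks increases.

## Adaptation

Concern thresholds (`AdaptationParams`): a yield concern needs >= 2
yield-decrease events within a 3-year rolling window; a soil concern needs
last year's loss strictly above 20 t/ha/yr; a biodiversity concern needs a
plant- or spider-richness drop since initialisation of >= 5; a pest concern
needs high abundance in both of the last two years. The thresholds are not
empirically anchored; they are fixed, documented, and configurable, and the
null-dynamics test (all thresholds unreachable, baseline climate, no
policy) verifies behaviours then never move.

Deliberation answers the highest-priority active concern (yield > soil >
pest > biodiversity, configurable) whose remedy is applicable and allowed,
at most one change per agent-year: yield → adopt a pheromone dispenser if
absent, else scale cover down one level (only from full cover, and never
against an obligation); soil → step cover up, bare vineyards adopting the
dominant type; pest → switch to spontaneous vegetation (higher predation);
biodiversity → drop one pesticide application. The fall-through when a
higher-priority remedy is unavailable is what produces the model's indirect
policy effects: under a vegetation mandate, water-short growers accumulate
yield concerns and adopt dispensers; under a universal pheromone obligation
the adoption remedy is exhausted, so pest-concerned growers switch their
vegetation type instead.

Climate sensing applies the smallest integer steps consistent with the
intended directions: +1 insecticide application in much-warmer years (users
only), ∓1 fungicide application in drier/wetter years, class keyed to
management type (organic → copper/sulfur). All three channels are filtered
through the agent's allowed options.

## Engine ordering and randomness

Within a year: policy (registration, then pending forced changes) → climate
sensing → deliberation on last year's ecology → ecology of the year's final
behaviour → recording. The ordering is a design choice: it guarantees the
recorded ecological state always reflects the behaviour actually practised
that year, and that reflection is strictly retrospective.

One integer seed drives everything, split into fixed named substreams
(landscape, parcels, agent attributes/trees, policy choices, deliberation,
pest draws), so runs are bit-identical under identical inputs and adding a
consumer in one module does not perturb the others.

## Experiment layer

`run_design` executes the factorial (replicate *r* uses seed
`base_seed + r`) into a tidy table; `compare_scenarios` tests each scenario
cell against the no-policy/baseline reference per indicator with a
two-sided unpaired rank-sum test, flagging strictly below alpha = 0.01 with
no multiple-testing correction (each comparison is reported individually).
The test is exact for combined sizes up to 20: the classical rank-sum
distribution without ties, full enumeration of the permutation distribution
of the midrank statistic with ties; larger samples use the tie-corrected
normal approximation. `expert_validation` labels an indicator within /
close / outside its expert range, "close" meaning within the range expanded
by 10% of its width (the notion of "close" is not standardised; the
fraction is a parameter). `ofat_sensitivity` sweeps one dotted parameter
path at a time (ecology or adaptation coefficients, or the policy start
year) and reports per-indicator means per grid point and ranges per sweep.

## Fixtures: what they emulate, and what they do not

The three styles reproduce the qualitative regional contrasts: insecticide
use and bare-soil inter-rows only in `tarnave_like`; the highest pheromone
share in `palatinate_like`; copper/sulfur-leaning fungicides in
`leithaberg_like` versus synthetic-leaning in `palatinate_like`; steeper
slopes in `leithaberg_like`. Defaults: 50 winegrowers per region, a
100 x 100 grid, and behaviour-share leaves centred on the regional levels
with a small seed-dependent jitter that never crosses a qualitative
contrast. The numeric tree thresholds, attribute distributions and expert
ranges are illustrative stand-ins for survey-derived regional values, which
the config format accepts as drop-in replacements. Consequently, passing
tests demonstrate the *mechanisms* (policy mechanics, adaptation channels,
ecological directions, statistical machinery), not the empirical magnitudes
of any real region; quantitative regional claims require the empirically
estimated trees and coefficients.

## Numerical choices and degenerate inputs

Probabilities clamp to [0, 1]; pesticide frequencies floor at 0; strict
inequalities at every concern threshold and at the 10% slope cut; leaf and
share sums are checked to 1e-9; the dominant-cover tie-break is fixed to
seed mixture; a single-class landscape, an empty agent list and an
infeasible parcel request are rejected with named errors. Problem sizes
throughout the test suite (50 agents, 100 x 100 cells, 10 replicates, the
420-run full factorial) were chosen as the package's reference desk scale:
they complete in a couple of minutes while matching the factorial structure
of the full experimental design.

## Known limitations

* No neighbourhood or social-imitation effects beyond observing the
  dominant cover type (no empirical support was available for more).
* One policy per run; no policy combinations, compliance stochasticity or
  enforcement costs.
* Ecology is annual and phenomenological — no vine phenology, disease
  epidemiology or weather time series below the yearly codes.
* Yield is an event counter, not a quantity; economic outcomes are out of
  scope.
* The bundled coefficients honour documented orderings but are not
  field-calibrated.
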