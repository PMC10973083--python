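"""Case-study configuration: parameter containers, YAML I/O and validation.

A case study (one winegrowing region) is fully described by a
:class:`CaseStudyConfig`: land-cover shares for the abstract landscape,
the number of winegrowers, per-attribute sampling distributions, one decision
tree per behaviour, ecological coefficients, adaptation thresholds and
optional expert ranges used for output validation. Everything downstream is a
pure function of a config, a scenario and a seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .distributions import DistributionSpec, spec_from_dict
from .trees import DecisionTreeSpec

__all__ = [
    "COVER_CLASSES",
    "BEHAVIOUR_TREES",
    "AGENT_ATTRIBUTES",
    "EcologyParams",
    "AdaptationParams",
    "CaseStudyConfig",
    "ConfigError",
    "ValidationError",
    "load_case_config",
    "save_case_config",
    "validate_config",
]

#: The six land use/cover classes of the abstract landscape.
COVER_CLASSES = (
    "urban",
    "viticulture",
    "other_agriculture",
    "forest",
    "semi_natural",
    "wetland_water",
)

#: The five behaviours, one decision tree each. The fungicide tree emits a
#: ``[synthetic, copper_sulfur]`` pair of annual application frequencies.
BEHAVIOUR_TREES = (
    "arrangement",
    "vegetation_type",
    "insecticide_freq",
    "pheromone",
    "fungicide_freqs",
)

#: Winegrower attributes drawn at initialisation and usable in decision trees.
AGENT_ATTRIBUTES = (
    "area_ha",
    "slope_pct",
    "water_shortage",
    "soil_problem",
    "management_type",
)

#: Permitted band for the viticultural share of the landscape.
VITICULTURE_SHARE_BAND = (0.26, 0.27)


class ConfigError(ValueError):
    """Raised when a config file cannot be parsed into a CaseStudyConfig."""


class ValidationError(ValueError):
    """Raised when a parsed config violates one or more invariants."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


@dataclass(frozen=True)
class EcologyParams:
    """Coefficients linking behaviours to ecological impacts.

    All coefficients are configurable so that region- or literature-specific
    values can be dropped in; the defaults honour the qualitative orderings
    the links must satisfy (see :func:`validate`).

    Soil loss follows a multiplicative form: a base rate (t/ha/yr on flat,
    bare ground under normal precipitation), a bounded slope term
    ``(1 + slope_pct/100) ** soil_slope_exponent``, a cover factor per
    inter-row arrangement and a precipitation multiplier per annual code.
    Predation, pest pressure and richness use attenuation/lookup forms.
    """

    # --- soil loss ---
    soil_base_rate: float = 5.0  # t/ha/yr, flat bare soil, normal year
    soil_slope_exponent: float = 2.0
    soil_cover_bare: float = 1.0
    soil_cover_every_second: float = 0.5
    soil_cover_every: float = 0.2
    soil_precip_mult: dict = field(
        default_factory=lambda: {-1: 0.7, 0: 1.0, 1: 1.4}
    )
    # --- predation of L. botrana pupae ---
    predation_base: dict = field(
        default_factory=lambda: {"none": 0.20, "spontaneous": 0.60, "seed_mixture": 0.45}
    )
    predation_insecticide_atten: float = 0.80  # per application, in (0, 1]
    predation_fungicide_atten: float = 0.97  # per application, in (0, 1]
    # --- L. botrana high-abundance probability ---
    lobesia_baseline: float = 0.5
    lobesia_pheromone_factor: float = 0.4
    lobesia_insecticide_factor: float = 0.7
    lobesia_predation_weight: float = 0.8
    lobesia_warm_mult: dict = field(
        default_factory=lambda: {0: 1.0, 1: 1.1, 2: 1.25}
    )
    # --- vascular plant richness lookup (vegetation_type, arrangement) ---
    plant_richness: dict = field(
        default_factory=lambda: {
            ("none", "bare"): 5.0,
            ("spontaneous", "every_second"): 15.0,
            ("spontaneous", "every"): 20.0,
            ("seed_mixture", "every_second"): 22.0,
            ("seed_mixture", "every"): 30.0,
        }
    )
    # --- spider richness ---
    spider_base: float = 8.0
    spider_insecticide_penalty: float = 1.5  # per application
    spider_cover_bonus: float = 6.0  # x vegetated fraction (1 / 0.5 / 0)

    def validate(self) -> list[str]:
        """Check orderings and ranges; return the list of violations."""
        errs: list[str] = []
        if self.soil_base_rate < 0:
            errs.append("ecology.soil_base_rate must be >= 0")
        if not self.soil_cover_bare > self.soil_cover_every_second > self.soil_cover_every:
            errs.append("ecology soil cover factors must order bare > every_second > every")
        if set(self.soil_precip_mult) != {-1, 0, 1}:
            errs.append("ecology.soil_precip_mult must have codes -1, 0, 1")
        elif not (
            self.soil_precip_mult[1] >= self.soil_precip_mult[0] >= self.soil_precip_mult[-1]
        ):
            errs.append("ecology precipitation multipliers must order wetter >= normal >= drier")
        pb = self.predation_base
        if set(pb) != {"none", "spontaneous", "seed_mixture"}:
            errs.append("ecology.predation_base must key none/spontaneous/seed_mixture")
        elif not pb["spontaneous"] > pb["seed_mixture"] > pb["none"]:
            errs.append(
                "ecology predation base must order spontaneous > seed_mixture > none"
            )
        for name in ("predation_insecticide_atten", "predation_fungicide_atten"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                errs.append(f"ecology.{name} must lie in (0, 1]")
        for name in (
            "lobesia_baseline",
            "lobesia_pheromone_factor",
            "lobesia_insecticide_factor",
            "lobesia_predation_weight",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                errs.append(f"ecology.{name} must lie in [0, 1]")
        wm = self.lobesia_warm_mult
        if set(wm) != {0, 1, 2}:
            errs.append("ecology.lobesia_warm_mult must have codes 0, 1, 2")
        elif not (wm[2] >= wm[1] >= wm[0]):
            errs.append("ecology warm multipliers must be non-decreasing in temperature code")
        pr = self.plant_richness
        needed = {
            ("none", "bare"),
            ("spontaneous", "every_second"),
            ("spontaneous", "every"),
            ("seed_mixture", "every_second"),
            ("seed_mixture", "every"),
        }
        if set(pr) != needed:
            errs.append("ecology.plant_richness must cover the five (type, arrangement) cells")
        else:
            for arr in ("every_second", "every"):
                if not pr[("seed_mixture", arr)] > pr[("spontaneous", arr)] > pr[("none", "bare")]:
                    errs.append(
                        "ecology plant richness must order seed_mixture > spontaneous > none"
                    )
                    break
            for typ in ("spontaneous", "seed_mixture"):
                if not pr[(typ, "every")] > pr[(typ, "every_second")]:
                    errs.append("ecology plant richness must order every > every_second")
                    break
        if self.spider_base < 0 or self.spider_insecticide_penalty < 0 or self.spider_cover_bonus < 0:
            errs.append("ecology spider coefficients must be >= 0")
        return errs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["plant_richness"] = {f"{t}|{a}": v for (t, a), v in self.plant_richness.items()}
        d["soil_precip_mult"] = {str(k): v for k, v in self.soil_precip_mult.items()}
        d["lobesia_warm_mult"] = {str(k): v for k, v in self.lobesia_warm_mult.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "EcologyParams":
        d = dict(d)
        if "plant_richness" in d:
            d["plant_richness"] = {
                tuple(k.split("|")): v for k, v in d["plant_richness"].items()
            }
        for key in ("soil_precip_mult", "lobesia_warm_mult"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


@dataclass(frozen=True)
class AdaptationParams:
    """Thresholds and rules of the three behaviour-change channels.

    ``yield_concern_window``/``yield_concern_events``: a yield concern fires
    when at least that many yield-decrease events fall inside the rolling
    window (years). ``soil_loss_concern`` (t/ha/yr) and
    ``biodiversity_concern`` (species-richness drop since initialisation) use
    strict ``>``/``>=`` comparisons as documented in the adaptation module.
    ``climate_rules`` holds the integer behaviour deltas triggered by annual
    climate codes.
    """

    yield_concern_window: int = 3
    yield_concern_events: int = 2
    soil_loss_concern: float = 20.0  # t/ha/yr, strict >
    biodiversity_concern: float = 5.0  # richness drop since init, >=
    climate_rules: dict = field(
        default_factory=lambda: {
            "much_warmer_insecticide_delta": 1,
            "drier_fungicide_delta": -1,
            "wetter_fungicide_delta": 1,
        }
    )
    #: Concern priority, highest first; one change per agent per year.
    concern_priority: tuple = ("yield", "soil", "pest", "biodiversity")

    def validate(self) -> list[str]:
        errs = []
        if self.yield_concern_window < 1:
            errs.append("adaptation.yield_concern_window must be >= 1")
        if self.yield_concern_events < 0:
            errs.append("adaptation.yield_concern_events must be >= 0")
        if self.soil_loss_concern < 0:
            errs.append("adaptation.soil_loss_concern must be >= 0")
        if self.biodiversity_concern < 0:
            errs.append("adaptation.biodiversity_concern must be >= 0")
        if set(self.concern_priority) != {"yield", "soil", "pest", "biodiversity"}:
            errs.append("adaptation.concern_priority must permute the four concerns")
        return errs

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["concern_priority"] = list(self.concern_priority)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AdaptationParams":
        d = dict(d)
        if "concern_priority" in d:
            d["concern_priority"] = tuple(d["concern_priority"])
        return cls(**d)


@dataclass(frozen=True)
class CaseStudyConfig:
    """Everything needed to initialise and run one regional model."""

    name: str
    landcover_shares: dict
    n_winegrowers: int
    attribute_distributions: dict  # attribute name -> DistributionSpec
    decision_trees: dict  # behaviour name -> DecisionTreeSpec
    ecology: EcologyParams = field(default_factory=EcologyParams)
    adaptation: AdaptationParams = field(default_factory=AdaptationParams)
    expert_ranges: dict = field(default_factory=dict)  # indicator -> (low, high)
    grid_cells: int = 100  # grid is grid_cells x grid_cells
    cell_size_m: float = 100.0

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "landcover_shares": dict(self.landcover_shares),
            "n_winegrowers": self.n_winegrowers,
            "attribute_distributions": {
                k: v.to_dict() for k, v in self.attribute_distributions.items()
            },
            "decision_trees": {k: v.root for k, v in self.decision_trees.items()},
            "ecology": self.ecology.to_dict(),
            "adaptation": self.adaptation.to_dict(),
            "expert_ranges": {k: list(v) for k, v in self.expert_ranges.items()},
            "grid_cells": self.grid_cells,
            "cell_size_m": self.cell_size_m,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CaseStudyConfig":
        try:
            return cls(
                name=d["name"],
                landcover_shares={k: float(v) for k, v in d["landcover_shares"].items()},
                n_winegrowers=int(d["n_winegrowers"]),
                attribute_distributions={
                    k: spec_from_dict(v) for k, v in d["attribute_distributions"].items()
                },
                decision_trees={
                    k: DecisionTreeSpec(behaviour=k, root=v)
                    for k, v in d["decision_trees"].items()
                },
                ecology=EcologyParams.from_dict(d.get("ecology", {})),
                adaptation=AdaptationParams.from_dict(d.get("adaptation", {})),
                expert_ranges={
                    k: tuple(v) for k, v in d.get("expert_ranges", {}).items()
                },
                grid_cells=int(d.get("grid_cells", 100)),
                cell_size_m=float(d.get("cell_size_m", 100.0)),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(f"malformed case-study config: {exc}") from exc


def validate_config(cfg: CaseStudyConfig) -> list[str]:
    """Check every invariant of *cfg*; return all violations (empty when valid).

    Pure reporting operation: never raises, never mutates.
    """
    errs: list[str] = []
    shares = cfg.landcover_shares
    unknown = set(shares) - set(COVER_CLASSES)
    if unknown:
        errs.append(f"landcover_shares: unknown classes {sorted(unknown)}")
    missing = set(COVER_CLASSES) - set(shares)
    if missing:
        errs.append(f"landcover_shares: missing classes {sorted(missing)}")
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        errs.append(f"landcover_shares: shares sum ≠ 1 (got {total:.6g})")
    if any(v < 0 for v in shares.values()):
        errs.append("landcover_shares: negative share")
    vit = shares.get("viticulture")
    lo, hi = VITICULTURE_SHARE_BAND
    if vit is not None and not lo <= vit <= hi:
        errs.append(
            f"landcover_shares.viticulture = {vit:.4g} outside the 26–27% band"
        )
    if cfg.n_winegrowers < 1:
        errs.append("n_winegrowers must be >= 1")
    for attr in AGENT_ATTRIBUTES:
        spec = cfg.attribute_distributions.get(attr)
        if spec is None:
            errs.append(f"attribute_distributions: missing {attr!r}")
        else:
            errs.extend(f"attribute_distributions.{attr}: {e}" for e in spec.validate())
    for behaviour in BEHAVIOUR_TREES:
        tree = cfg.decision_trees.get(behaviour)
        if tree is None:
            errs.append(f"decision_trees: missing tree for behaviour {behaviour!r}")
        else:
            errs.extend(tree.validate(set(AGENT_ATTRIBUTES)))
    extra = set(cfg.decision_trees) - set(BEHAVIOUR_TREES)
    if extra:
        errs.append(f"decision_trees: unknown behaviours {sorted(extra)}")
    errs.extend(cfg.ecology.validate())
    errs.extend(cfg.adaptation.validate())
    for name, rng_ in cfg.expert_ranges.items():
        if len(rng_) != 2 or rng_[0] > rng_[1]:
            errs.append(f"expert_ranges.{name}: low must be <= high")
    if cfg.grid_cells < 10:
        errs.append("grid_cells must be >= 10")
    return errs


def load_case_config(path: str | Path) -> CaseStudyConfig:
    """Load and validate a case-study config from a YAML (or JSON) file.

    Raises
    ------
    ConfigError
        If the file cannot be parsed into the config schema.
    ValidationError
        Listing every violated invariant.
    """
    path = Path(path)
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        line = f" at line {mark.line + 1}" if mark is not None else ""
        raise ConfigError(f"cannot parse {path}{line}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    cfg = CaseStudyConfig.from_dict(raw)
    violations = validate_config(cfg)
    if violations:
        raise ValidationError(violations)
    return cfg


def save_case_config(cfg: CaseStudyConfig, path: str | Path) -> None:
    """Write *cfg* to YAML so that :func:`load_case_config` round-trips it."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
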