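"""Experiment layer: factorial scenario runs, comparisons, validation, OFAT.

The full experimental design crosses case studies x seven policies x two
climate scenarios, with 10 replicate runs per cell to absorb stochasticity
(replicate *r* uses seed ``base_seed + r``). Scenario effects are assessed
per indicator with exact unpaired rank-sum tests against the no-policy,
no-climate-change reference at a per-comparison alpha of 0.01 (no
multiple-testing correction). Behaviour indicators can additionally be
checked against ranges elicited from regional experts, and a
one-factor-at-a-time (OFAT) sweep quantifies sensitivity to weakly grounded
parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .config import CaseStudyConfig
from .engine import indicators, run
from .scenarios import PolicyScenario, baseline_climate, default_climate_change
from .stats import rank_sum_test

__all__ = [
    "ExperimentDesign",
    "run_design",
    "compare_scenarios",
    "ofat_sensitivity",
    "OfatResult",
    "expert_validation",
]


def _climate(name: str, horizon: int):
    if name == "baseline":
        return baseline_climate(horizon)
    if name == "change":
        return default_climate_change(horizon)
    raise ValueError(f"unknown climate scenario {name!r}")


@dataclass(frozen=True)
class ExperimentDesign:
    """A factorial design over configs, policies, climates and replicates."""

    configs: Sequence[CaseStudyConfig]
    policies: Sequence[str] = ("NA", "CS", "CW", "CA", "NI", "PO", "FR")
    climates: Sequence[str] = ("baseline", "change")
    replicates: int = 10
    base_seed: int = 0
    horizon: int = 10
    policy_start_year: int = 1

    def __post_init__(self):
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2 for any statistical comparison")

    @property
    def n_runs(self) -> int:
        return len(self.configs) * len(self.policies) * len(self.climates) * self.replicates


def run_design(design: ExperimentDesign) -> pd.DataFrame:
    """Execute the complete factorial; one tidy row per run and indicator.

    Columns: config, policy, climate, replicate, seed, indicator, value.
    Deterministic in the design (including ``base_seed``).
    """
    rows: list[dict] = []
    for cfg in design.configs:
        for policy_id in design.policies:
            policy = PolicyScenario(policy_id, start_year=design.policy_start_year)
            for climate_name in design.climates:
                climate = _climate(climate_name, design.horizon)
                for rep in range(design.replicates):
                    seed = design.base_seed + rep
                    try:
                        result = run(cfg, climate, policy, seed, design.horizon)
                    except Exception as exc:
                        raise RuntimeError(
                            f"run failed: config={cfg.name!r} policy={policy_id} "
                            f"climate={climate_name} replicate={rep} seed={seed}"
                        ) from exc
                    for name, value in indicators(result).items():
                        rows.append(
                            {
                                "config": cfg.name,
                                "policy": policy_id,
                                "climate": climate_name,
                                "replicate": rep,
                                "seed": seed,
                                "indicator": name,
                                "value": value,
                            }
                        )
    return pd.DataFrame(rows)


def compare_scenarios(
    results: pd.DataFrame,
    reference: tuple[str, str] = ("NA", "baseline"),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Rank-sum test every non-reference scenario cell against the reference.

    Returns one row per (config, indicator, policy, climate) with the
    two-sided p-value and a strict ``p < alpha`` significance flag.

    Raises
    ------
    ValueError
        If the reference cell is missing or has fewer than two replicates.
    """
    ref_policy, ref_climate = reference
    rows: list[dict] = []
    for config_name, cfg_tbl in results.groupby("config", sort=False):
        ref_tbl = cfg_tbl[
            (cfg_tbl["policy"] == ref_policy) & (cfg_tbl["climate"] == ref_climate)
        ]
        if ref_tbl.empty or ref_tbl["replicate"].nunique() < 2:
            raise ValueError(
                f"reference cell {reference} missing or underpopulated for "
                f"config {config_name!r}"
            )
        for indicator_name, ind_tbl in cfg_tbl.groupby("indicator", sort=False):
            ref_values = ind_tbl[
                (ind_tbl["policy"] == ref_policy) & (ind_tbl["climate"] == ref_climate)
            ]["value"].to_numpy()
            scenario_cells = ind_tbl.groupby(["policy", "climate"], sort=False)
            for (policy_id, climate_name), cell in scenario_cells:
                if (policy_id, climate_name) == reference:
                    continue
                p = rank_sum_test(cell["value"].to_numpy(), ref_values)
                rows.append(
                    {
                        "config": config_name,
                        "indicator": indicator_name,
                        "policy": policy_id,
                        "climate": climate_name,
                        "p_value": p,
                        "significant": p < alpha,
                    }
                )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class OfatResult:
    """Sweep table plus per-indicator ranges of a one-factor-at-a-time scan."""

    sweep: pd.DataFrame  # (parameter, grid_value, indicator, mean_value)
    ranges: pd.DataFrame  # (parameter, indicator, low, high, range)


def _set_parameter(cfg: CaseStudyConfig, path: str, value: float):
    """Return (cfg, policy_start) with the dotted parameter path set to value."""
    scope, _, name = path.partition(".")
    if scope == "policy" and name == "start_year":
        return cfg, int(round(value))
    if scope in ("ecology", "adaptation"):
        section = getattr(cfg, scope)
        if not hasattr(section, name):
            raise KeyError(f"unknown parameter path {path!r}")
        if isinstance(getattr(section, name), int):
            value = int(round(value))
        new_section = dataclasses.replace(section, **{name: value})
        return dataclasses.replace(cfg, **{scope: new_section}), None
    raise KeyError(f"unknown parameter path {path!r}")


def ofat_sensitivity(
    cfg: CaseStudyConfig,
    parameters: Sequence[tuple[str, float, float, int]],
    policy: str = "NA",
    climate: str = "baseline",
    replicates: int = 3,
    base_seed: int = 0,
    horizon: int = 10,
) -> OfatResult:
    """Sweep each parameter over its grid while holding everything else fixed.

    *parameters* is a list of ``(dotted_path, low, high, steps)``; paths may
    address ``ecology.*`` or ``adaptation.*`` coefficients or
    ``policy.start_year``. For each grid point every indicator's mean across
    replicates is recorded; the per-indicator range over the sweep summarises
    sensitivity.
    """
    sweep_rows: list[dict] = []
    for path, low, high, steps in parameters:
        _set_parameter(cfg, path, low)  # fail fast on unknown paths
        grid = np.linspace(low, high, int(steps)) if steps > 1 else np.array([low])
        for value in grid:
            swept_cfg, start_year = _set_parameter(cfg, path, float(value))
            pol = PolicyScenario(policy, start_year=start_year or 1)
            clim = _climate(climate, horizon)
            acc: dict[str, list[float]] = {}
            for rep in range(replicates):
                result = run(swept_cfg, clim, pol, base_seed + rep, horizon)
                for name, v in indicators(result).items():
                    acc.setdefault(name, []).append(v)
            for name, values in acc.items():
                sweep_rows.append(
                    {
                        "parameter": path,
                        "grid_value": float(value),
                        "indicator": name,
                        "mean_value": float(np.mean(values)),
                    }
                )
    sweep = pd.DataFrame(sweep_rows)
    ranges = (
        sweep.groupby(["parameter", "indicator"], sort=False)["mean_value"]
        .agg(low="min", high="max")
        .reset_index()
    )
    ranges["range"] = ranges["high"] - ranges["low"]
    return OfatResult(sweep=sweep, ranges=ranges)


def expert_validation(
    values: dict[str, float],
    expert_ranges: dict[str, tuple[float, float]],
    epsilon_frac: float = 0.1,
) -> dict[str, str]:
    """Label each indicator against its expert range.

    ``within`` when ``low <= value <= high`` (closed interval); ``close``
    when inside the range expanded by ``epsilon_frac`` of its width on both
    sides; ``outside`` otherwise; ``no-range`` when experts provided none.
    """
    labels: dict[str, str] = {}
    for name, value in values.items():
        rng = expert_ranges.get(name)
        if rng is None:
            labels[name] = "no-range"
            continue
        low, high = rng
        if low <= value <= high:
            labels[name] = "within"
            continue
        eps = epsilon_frac * (high - low)
        labels[name] = "close" if (low - eps) <= value <= (high + eps) else "outside"
    return labels
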