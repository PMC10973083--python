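"""Small declarative distribution specs used to draw winegrower attributes.

Attribute heterogeneity is configured, not hard-coded: each attribute of a
winegrower (vineyard area, slope, water shortage, soil problem, management
type) is described in the case-study configuration by one of four spec kinds
and sampled at initialisation time from a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
from scipy import stats

__all__ = ["DistributionSpec", "spec_from_dict"]


@dataclass(frozen=True)
class DistributionSpec:
    """One attribute distribution: uniform, truncated normal, Bernoulli or categorical.

    Parameters
    ----------
    kind
        ``"uniform"`` (low, high), ``"truncnorm"`` (mu, sigma, low, high),
        ``"bernoulli"`` (p) or ``"categorical"`` (values, probs).
    params
        Keyword parameters of the chosen kind, as listed above.
    """

    kind: str
    params: dict = field(default_factory=dict)

    _KINDS = ("uniform", "truncnorm", "bernoulli", "categorical")

    def validate(self) -> list[str]:
        """Return a list of human-readable problems (empty when valid)."""
        errs: list[str] = []
        if self.kind not in self._KINDS:
            return [f"unknown distribution kind {self.kind!r}"]
        p = self.params
        if self.kind == "uniform":
            if not {"low", "high"} <= p.keys():
                errs.append("uniform requires low/high")
            elif p["low"] > p["high"]:
                errs.append("uniform low > high")
        elif self.kind == "truncnorm":
            missing = {"mu", "sigma", "low", "high"} - p.keys()
            if missing:
                errs.append(f"truncnorm missing {sorted(missing)}")
            else:
                if p["sigma"] <= 0:
                    errs.append("truncnorm sigma must be > 0")
                if p["low"] > p["high"]:
                    errs.append("truncnorm low > high")
        elif self.kind == "bernoulli":
            if "p" not in p:
                errs.append("bernoulli requires p")
            elif not 0.0 <= p["p"] <= 1.0:
                errs.append("bernoulli p outside [0, 1]")
        elif self.kind == "categorical":
            values = p.get("values")
            probs = p.get("probs")
            if not values or probs is None or len(values) != len(probs):
                errs.append("categorical requires matching values/probs")
            elif abs(sum(probs) - 1.0) > 1e-9:
                errs.append(f"categorical probs sum to {sum(probs):.6g}, not 1")
            elif any(q < 0 for q in probs):
                errs.append("categorical probs must be non-negative")
        return errs

    def sample(self, rng: np.random.Generator, size: int | None = None) -> Any:
        """Draw from the distribution using *rng*; scalar when size is None."""
        p = self.params
        if self.kind == "uniform":
            return rng.uniform(p["low"], p["high"], size=size)
        if self.kind == "truncnorm":
            a = (p["low"] - p["mu"]) / p["sigma"]
            b = (p["high"] - p["mu"]) / p["sigma"]
            return stats.truncnorm.rvs(
                a, b, loc=p["mu"], scale=p["sigma"], size=size, random_state=rng
            )
        if self.kind == "bernoulli":
            draw = rng.random(size) < p["p"]
            return bool(draw) if size is None else draw
        if self.kind == "categorical":
            values: Sequence = p["values"]
            idx = rng.choice(len(values), size=size, p=p["probs"])
            if size is None:
                return values[int(idx)]
            return [values[int(i)] for i in idx]
        raise ValueError(f"unknown distribution kind {self.kind!r}")

    def to_dict(self) -> dict:
        return {"kind": self.kind, **self.params}


def spec_from_dict(d: dict) -> DistributionSpec:
    """Build a :class:`DistributionSpec` from its serialized mapping."""
    d = dict(d)
    kind = d.pop("kind")
    return DistributionSpec(kind=kind, params=d)
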