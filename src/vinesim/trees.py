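"""Declarative decision trees that set winegrowers' initial behaviours.

Empirically derived decision trees (one per behaviour) map a winegrower's
attributes to an initial behaviour value. Trees are data, not code, so the
region-specific trees can be swapped through configuration files. An internal
node tests one agent attribute against a threshold or category set; a leaf
either holds a fixed value or a categorical distribution over values, which
lets population-level behaviour shares reported by regional experts be matched
without the underlying survey data.

Serialized node forms::

    {"attribute": "slope_pct", "op": ">", "threshold": 10,
     "if_true": <node>, "if_false": <node>}
    {"attribute": "management_type", "op": "in", "categories": ["organic"],
     "if_true": <node>, "if_false": <node>}
    {"value": "every_second"}                       # fixed leaf
    {"distribution": {"bare": 0.3, "every": 0.7}}   # stochastic leaf

Leaf values may be scalars or lists (the fungicide tree emits a
``[synthetic, copper_sulfur]`` pair covering both fungicide classes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np

__all__ = ["DecisionTreeSpec", "TreeStructureError", "evaluate_tree"]

_COMPARATORS = {
    ">": lambda a, t: a > t,
    ">=": lambda a, t: a >= t,
    "<": lambda a, t: a < t,
    "<=": lambda a, t: a <= t,
    "==": lambda a, t: a == t,
}


class TreeStructureError(ValueError):
    """Raised when a decision tree is malformed or references unknown data."""


@dataclass(frozen=True)
class DecisionTreeSpec:
    """A finite rooted decision tree for one behaviour.

    Parameters
    ----------
    behaviour
        Name of the behaviour the tree decides (e.g. ``"arrangement"``).
    root
        Nested node mapping in the serialized form documented in the module
        docstring.
    """

    behaviour: str
    root: dict

    def validate(self, known_attributes: set[str] | None = None) -> list[str]:
        """Return all structural problems found in the tree (empty when valid)."""
        errs: list[str] = []
        self._walk(self.root, errs, known_attributes, depth=0)
        return errs

    def _walk(self, node: Any, errs: list[str], attrs: set[str] | None, depth: int) -> None:
        prefix = f"tree {self.behaviour!r}"
        if depth > 64:
            errs.append(f"{prefix}: depth exceeds 64 (cycle or runaway nesting)")
            return
        if not isinstance(node, dict):
            errs.append(f"{prefix}: node is not a mapping: {node!r}")
            return
        if "value" in node:
            return
        if "distribution" in node:
            dist = node["distribution"]
            if not isinstance(dist, dict) or not dist:
                errs.append(f"{prefix}: empty distribution leaf")
                return
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                errs.append(f"{prefix}: leaf distribution sums to {total:.6g}, not 1")
            if any(p < 0 for p in dist.values()):
                errs.append(f"{prefix}: negative leaf probability")
            return
        # internal node
        attr = node.get("attribute")
        op = node.get("op")
        if attr is None or op is None:
            errs.append(f"{prefix}: internal node missing attribute/op: {node!r}")
            return
        if attrs is not None and attr not in attrs:
            errs.append(f"{prefix}: unknown attribute {attr!r}")
        if op == "in":
            if "categories" not in node:
                errs.append(f"{prefix}: 'in' node missing categories")
        elif op in _COMPARATORS:
            if "threshold" not in node:
                errs.append(f"{prefix}: {op!r} node missing threshold")
        else:
            errs.append(f"{prefix}: unknown comparator {op!r}")
        for branch in ("if_true", "if_false"):
            if branch not in node:
                errs.append(f"{prefix}: internal node missing {branch!r} child")
            else:
                self._walk(node[branch], errs, attrs, depth + 1)

    def to_dict(self) -> dict:
        return {"behaviour": self.behaviour, "root": self.root}


def evaluate_tree(
    tree: DecisionTreeSpec, attributes: dict[str, Any], rng: np.random.Generator
) -> Any:
    """Descend *tree* using *attributes* and return the leaf's behaviour value.

    The descent is deterministic; only a distribution leaf consumes randomness
    (one categorical draw from *rng*).

    Raises
    ------
    TreeStructureError
        If a node is malformed or references an attribute absent from
        *attributes*.
    """
    node = tree.root
    depth = 0
    while True:
        depth += 1
        if depth > 64:
            raise TreeStructureError(f"tree {tree.behaviour!r}: descent exceeded depth 64")
        if not isinstance(node, dict):
            raise TreeStructureError(f"tree {tree.behaviour!r}: malformed node {node!r}")
        if "value" in node:
            return node["value"]
        if "distribution" in node:
            dist = node["distribution"]
            values = list(dist.keys())
            probs = np.asarray(list(dist.values()), dtype=float)
            probs = probs / probs.sum()
            return values[int(rng.choice(len(values), p=probs))]
        attr = node.get("attribute")
        op = node.get("op")
        if attr is None or op is None:
            raise TreeStructureError(f"tree {tree.behaviour!r}: malformed node {node!r}")
        if attr not in attributes:
            raise TreeStructureError(
                f"tree {tree.behaviour!r}: attribute {attr!r} missing on agent"
            )
        value = attributes[attr]
        if op == "in":
            taken = value in node["categories"]
        elif op in _COMPARATORS:
            try:
                taken = bool(_COMPARATORS[op](value, node["threshold"]))
            except TypeError as exc:
                raise TreeStructureError(
                    f"tree {tree.behaviour!r}: cannot compare {attr}={value!r} "
                    f"with {node['threshold']!r}"
                ) from exc
        else:
            raise TreeStructureError(f"tree {tree.behaviour!r}: unknown comparator {op!r}")
        branch = "if_true" if taken else "if_false"
        if branch not in node:
            raise TreeStructureError(f"tree {tree.behaviour!r}: missing {branch!r} child")
        node = node[branch]
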