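"""Vegetation-index computation from per-ROI band means.

The registry is data-driven: a YAML file maps index names to arithmetic
formulas over the four band means (``green``, ``red``, ``red_edge``,
``nir``).  Formulas are evaluated by a small guarded arithmetic interpreter
(no ``eval``): only +, -, *, /, **, unary minus, ``sqrt``, band names and
numeric constants are admitted, and any division whose denominator falls
below ``EPS_DENOMINATOR`` in magnitude yields the NaN undefined-value
sentinel rather than an infinity, so downstream correlation code stays
well-defined.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Dict, Iterable, List, Mapping

import yaml

__all__ = [
    "VIDefinition",
    "VIRegistry",
    "compute_vi",
    "compute_all_vis",
    "default_registry",
    "EPS_DENOMINATOR",
]

#: denominators smaller than this in magnitude mark the index undefined
EPS_DENOMINATOR = 1e-9

_ALLOWED_BANDS = ("green", "red", "red_edge", "nir")


class UndefinedIndex(ArithmeticError):
    """Internal signal: a formula hit a degenerate denominator."""


@dataclass(frozen=True)
class VIDefinition:
    """A named vegetation-index formula over the four band means."""

    name: str
    formula: str

    def __post_init__(self) -> None:
        # validate eagerly so registry loading fails fast on bad formulas
        _compile_checked(self.formula)


def _compile_checked(formula: str) -> ast.Expression:
    tree = ast.parse(formula, mode="eval")
    for node in ast.walk(tree):
        if isinstance(node, ast.Name):
            if node.id not in _ALLOWED_BANDS and node.id != "sqrt":
                raise ValueError(f"formula references unknown name {node.id!r}")
        elif isinstance(node, ast.Call):
            if not (isinstance(node.func, ast.Name) and node.func.id == "sqrt"):
                raise ValueError("only sqrt() calls are allowed in formulas")
        elif isinstance(
            node,
            (
                ast.Expression, ast.BinOp, ast.UnaryOp, ast.Constant,
                ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow,
                ast.USub, ast.UAdd, ast.Load,
            ),
        ):
            continue
        else:
            raise ValueError(
                f"disallowed syntax in formula {formula!r}: {type(node).__name__}"
            )
    return tree


def _eval_node(node: ast.AST, env: Mapping[str, float]) -> float:
    if isinstance(node, ast.Expression):
        return _eval_node(node.body, env)
    if isinstance(node, ast.Constant):
        return float(node.value)
    if isinstance(node, ast.Name):
        return float(env[node.id])
    if isinstance(node, ast.UnaryOp):
        v = _eval_node(node.operand, env)
        return -v if isinstance(node.op, ast.USub) else v
    if isinstance(node, ast.Call):  # sqrt, validated at compile time
        v = _eval_node(node.args[0], env)
        if v < 0:
            raise UndefinedIndex("sqrt of negative value")
        return math.sqrt(v)
    if isinstance(node, ast.BinOp):
        left = _eval_node(node.left, env)
        right = _eval_node(node.right, env)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        if isinstance(node.op, ast.Pow):
            return left ** right
        if isinstance(node.op, ast.Div):
            if abs(right) < EPS_DENOMINATOR:
                raise UndefinedIndex("denominator below epsilon")
            return left / right
    raise AssertionError(f"unreachable node {type(node).__name__}")  # pragma: no cover


def compute_vi(defn: VIDefinition, means: Mapping[str, float]) -> float:
    """Evaluate one index on a mapping of band means.

    Returns NaN (the undefined-value sentinel) when a denominator falls
    below the epsilon guard; raises ``KeyError`` if a referenced band is
    absent from ``means``.
    """
    tree = _compile_checked(defn.formula)
    for node in ast.walk(tree):
        if isinstance(node, ast.Name) and node.id in _ALLOWED_BANDS:
            if node.id not in means:
                raise KeyError(f"band {node.id!r} missing for index {defn.name!r}")
    try:
        return float(_eval_node(tree, means))
    except UndefinedIndex:
        return float("nan")


class VIRegistry:
    """An ordered, name-unique collection of VI definitions."""

    def __init__(self, definitions: Iterable[VIDefinition] = ()):
        self._defs: Dict[str, VIDefinition] = {}
        for d in definitions:
            self.add(d)

    def add(self, defn: VIDefinition) -> None:
        if defn.name in self._defs:
            raise ValueError(f"duplicate index name {defn.name!r}")
        self._defs[defn.name] = defn

    def __len__(self) -> int:
        return len(self._defs)

    def __iter__(self):
        return iter(self._defs.values())

    def __contains__(self, name: str) -> bool:
        return name in self._defs

    def names(self) -> List[str]:
        return list(self._defs)

    @classmethod
    def from_yaml(cls, path: Path | str) -> "VIRegistry":
        with Path(path).open() as fh:
            mapping = yaml.safe_load(fh)
        return cls(VIDefinition(name, str(f)) for name, f in mapping.items())


def default_registry() -> VIRegistry:
    """The packaged 21-entry registry of four-band indices."""
    source = resources.files("ndwti.data").joinpath("vi_registry.yaml")
    mapping = yaml.safe_load(source.read_text())
    return VIRegistry(VIDefinition(name, str(f)) for name, f in mapping.items())


def compute_all_vis(
    registry: VIRegistry, means: Mapping[str, float]
) -> Dict[str, float]:
    """Evaluate every registry entry, preserving registry order.

    Undefined values propagate as NaN sentinels; entries are never silently
    dropped.
    """
    return {d.name: compute_vi(d, means) for d in registry}
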