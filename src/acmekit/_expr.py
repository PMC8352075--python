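"""Safe compilation of rate expressions.

Rate laws may be supplied as plain text (e.g. in a YAML model file) using the
continuum coordinates, time ``t``, declared parameters, arithmetic and a small
whitelist of functions.  Compilation is a deterministic AST walk; anything
outside the whitelist is rejected with the offending symbol named.
"""

from __future__ import annotations

import ast
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = ["RateFunction", "rate_expression_compile", "ExpressionError", "hill_rate"]


class ExpressionError(ValueError):
    """Raised when a rate expression cannot be compiled."""


def hill_rate(x, r0: float, r1: float, n: float):
    """Saturating Hill regulation rate ``r0 + r1 * x**n / (1 + x**n)``.

    Monotone non-decreasing in ``x`` for ``r1 >= 0``; equals ``r0`` at
    ``x = 0`` and saturates at ``r0 + r1``.
    """
    xn = np.power(np.asarray(x, dtype=float), n)
    return r0 + r1 * xn / (1.0 + xn)


def _indicator(cond):
    return np.asarray(cond).astype(float)


_FUNCTIONS: dict[str, Callable] = {
    "exp": np.exp,
    "log": np.log,
    "sqrt": np.sqrt,
    "pow": np.power,
    "min": np.minimum,
    "max": np.maximum,
    "abs": np.abs,
    "hill": hill_rate,
    "indicator": _indicator,
}

_CONSTANTS = {"pi": math.pi, "e": math.e}

_ALLOWED_NODES = (
    ast.Expression,
    ast.BinOp,
    ast.UnaryOp,
    ast.Add,
    ast.Sub,
    ast.Mult,
    ast.Div,
    ast.Pow,
    ast.Mod,
    ast.USub,
    ast.UAdd,
    ast.Call,
    ast.Name,
    ast.Load,
    ast.Constant,
    ast.Compare,
    ast.Lt,
    ast.LtE,
    ast.Gt,
    ast.GtE,
    ast.Eq,
    ast.NotEq,
    ast.BoolOp,
    ast.And,
    ast.Or,
)


@dataclass(frozen=True)
class RateFunction:
    """A rate law ``r(x, t)`` evaluable on arrays of grid coordinates.

    Wraps either a compiled expression (round-trippable to config files) or a
    plain Python callable.  ``coords`` is the tuple of per-axis coordinate
    arrays; scalar coordinates broadcast as usual.
    """

    fn: Callable = field(repr=False)
    expression: str | None = None
    time_dependent: bool = False
    parameters: Mapping[str, float] = field(default_factory=dict)

    def __call__(self, coords: Sequence, t: float = 0.0):
        return self.fn(coords, t)


def as_rate(obj, symbols: Sequence[str] = ("x",), parameters: Mapping[str, float] | None = None) -> RateFunction:
    """Coerce a number, text expression, callable or RateFunction to a RateFunction."""
    if isinstance(obj, RateFunction):
        return obj
    if isinstance(obj, str):
        return rate_expression_compile(obj, symbols, parameters)
    if isinstance(obj, (int, float)):
        c = float(obj)
        return RateFunction(
            fn=lambda coords, t, _c=c: np.full_like(np.asarray(coords[0], dtype=float), _c),
            expression=repr(c),
            time_dependent=False,
        )
    if callable(obj):
        # Assume possibly time dependent: the caller may wrap explicitly to
        # declare autonomy and enable operator precomputation.
        return RateFunction(fn=obj, expression=None, time_dependent=True)
    raise TypeError(f"cannot interpret {obj!r} as a rate function")


def _free_names(tree: ast.AST) -> set[str]:
    return {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}


def rate_expression_compile(
    expr: str,
    symbols: Sequence[str] = ("x",),
    parameters: Mapping[str, float] | None = None,
) -> RateFunction:
    """Compile a rate expression to a function of ``(coords, t)``.

    ``symbols`` are the continuum coordinate names in axis order (the aliases
    ``x``, ``y``, ``z`` are bound to the first three axes when not already
    taken).  ``parameters`` are fixed named constants.  ``^`` is accepted as
    the power operator.  Unknown symbols raise :class:`ExpressionError` naming
    the symbol.
    """
    parameters = dict(parameters or {})
    source = expr.replace("^", "**")
    try:
        tree = ast.parse(source, mode="eval")
    except SyntaxError as exc:  # pragma: no cover - message path
        raise ExpressionError(f"syntax error in rate expression {expr!r}: {exc}") from exc

    for node in ast.walk(tree):
        if not isinstance(node, _ALLOWED_NODES):
            raise ExpressionError(
                f"disallowed construct {type(node).__name__!r} in rate expression {expr!r}"
            )
        if isinstance(node, ast.Call):
            if not isinstance(node.func, ast.Name) or node.func.id not in _FUNCTIONS:
                name = getattr(node.func, "id", ast.dump(node.func))
                raise ExpressionError(f"unknown function {name!r} in rate expression {expr!r}")
        if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric constant {node.value!r} in {expr!r}")

    axis_names: dict[str, int] = {name: i for i, name in enumerate(symbols)}
    for i, alias in enumerate(("x", "y", "z")):
        if i < len(symbols) and alias not in axis_names and alias not in parameters:
            axis_names[alias] = i

    known = set(axis_names) | set(parameters) | set(_FUNCTIONS) | set(_CONSTANTS) | {"t"}
    unknown = _free_names(tree) - known
    if unknown:
        raise ExpressionError(
            f"unknown symbol(s) {sorted(unknown)} in rate expression {expr!r}; "
            f"allowed: coordinates {sorted(axis_names)}, t, parameters {sorted(parameters)}"
        )

    code = compile(tree, "<rate>", "eval")
    time_dependent = "t" in _free_names(tree)
    base_ns = dict(_FUNCTIONS)
    base_ns.update(_CONSTANTS)
    base_ns.update(parameters)

    def fn(coords, t, _code=code, _ns=base_ns, _axes=axis_names):
        ns = dict(_ns)
        for name, axis in _axes.items():
            ns[name] = coords[axis]
        ns["t"] = t
        out = eval(_code, {"__builtins__": {}}, ns)  # noqa: S307 - AST whitelisted above
        return np.broadcast_to(np.asarray(out, dtype=float), np.shape(coords[0])).copy() \
            if np.shape(out) != np.shape(coords[0]) else np.asarray(out, dtype=float)

    return RateFunction(fn=fn, expression=expr, time_dependent=time_dependent, parameters=parameters)
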