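"""Restricted arithmetic expression grammar for rate-law formulas.

Expressions may use + - * / ^ (or **), parentheses, numeric literals,
bare symbols (species and parameter names), and the functions pow, exp,
log, sqrt.  Anything else is rejected at parse time, so user-supplied
kinetics can never execute general code.
"""

from __future__ import annotations

import ast
import math
from typing import Callable, Iterable, Mapping

_ALLOWED_FUNCS: dict[str, Callable[..., float]] = {
    "pow": pow,
    "exp": math.exp,
    "log": math.log,
    "sqrt": math.sqrt,
}

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div, ast.Pow)
_ALLOWED_UNARY = (ast.UAdd, ast.USub)


class ExpressionError(ValueError):
    """Raised for a malformed or disallowed rate-law expression."""


def _normalize(text: str) -> str:
    # '^' is the conventional power operator in SBML L3 / COPASI formulas.
    return text.replace("**", "\x00").replace("^", "**").replace("\x00", "**")


def _validate(node: ast.AST, source: str) -> None:
    if isinstance(node, ast.Expression):
        _validate(node.body, source)
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(f"operator not allowed in {source!r}")
        _validate(node.left, source)
        _validate(node.right, source)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise ExpressionError(f"unary operator not allowed in {source!r}")
        _validate(node.operand, source)
    elif isinstance(node, ast.Call):
        if not isinstance(node.func, ast.Name) or node.func.id not in _ALLOWED_FUNCS:
            raise ExpressionError(f"function call not allowed in {source!r}")
        if node.keywords:
            raise ExpressionError(f"keyword arguments not allowed in {source!r}")
        for arg in node.args:
            _validate(arg, source)
    elif isinstance(node, ast.Name):
        pass
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric literal in {source!r}")
    else:
        raise ExpressionError(
            f"construct {type(node).__name__} not allowed in {source!r}"
        )


class Expression:
    """A validated arithmetic expression over named symbols."""

    def __init__(self, source: str):
        self.source = source
        try:
            tree = ast.parse(_normalize(source), mode="eval")
        except SyntaxError as exc:
            raise ExpressionError(f"cannot parse expression {source!r}: {exc}") from exc
        _validate(tree, source)
        self._symbols = frozenset(
            n.id for n in ast.walk(tree) if isinstance(n, ast.Name)
        ) - set(_ALLOWED_FUNCS)
        self._code = compile(tree, "<rate-law>", "eval")

    @property
    def symbols(self) -> frozenset[str]:
        return self._symbols

    def check_bound(self, available: Iterable[str]) -> None:
        missing = self._symbols - set(available)
        if missing:
            raise ExpressionError(
                f"unbound symbols {sorted(missing)} in {self.source!r}"
            )

    def __call__(self, env: Mapping[str, float]) -> float:
        missing = self._symbols - env.keys()
        if missing:
            raise ExpressionError(
                f"unbound symbols {sorted(missing)} in {self.source!r}"
            )
        try:
            return float(eval(self._code, {"__builtins__": {}, **_ALLOWED_FUNCS}, dict(env)))
        except ZeroDivisionError as exc:
            raise ExpressionError(
                f"division by zero evaluating {self.source!r}"
            ) from exc

    def __repr__(self) -> str:  # pragma: no cover
        return f"Expression({self.source!r})"
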