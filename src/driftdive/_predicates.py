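"""Tiny safe evaluator for declarative rule predicates.

Rule files express conditions over dive-shape variables as plain Python
expressions (``"mdepthbias > 0 and ps1 > ps2"``).  Only comparisons,
boolean connectives, basic arithmetic, numeric literals and known variable
names are admitted; anything else is a configuration error.
"""

from __future__ import annotations

import ast
from typing import Mapping

__all__ = ["Predicate", "PredicateError"]


class PredicateError(ValueError):
    """A rule predicate is malformed or names an unknown variable."""


_ALLOWED_NODES = (
    ast.Expression,
    ast.BoolOp, ast.And, ast.Or,
    ast.UnaryOp, ast.Not, ast.USub, ast.UAdd,
    ast.BinOp, ast.Add, ast.Sub, ast.Mult, ast.Div,
    ast.Compare, ast.Lt, ast.LtE, ast.Gt, ast.GtE, ast.Eq, ast.NotEq,
    ast.Name, ast.Load, ast.Constant,
)


class Predicate:
    """A compiled boolean expression over named numeric variables."""

    def __init__(self, expression: str):
        self.expression = expression
        try:
            tree = ast.parse(expression, mode="eval")
        except SyntaxError as exc:
            raise PredicateError(f"cannot parse predicate {expression!r}: {exc}") from exc
        for node in ast.walk(tree):
            if not isinstance(node, _ALLOWED_NODES):
                raise PredicateError(
                    f"disallowed syntax {type(node).__name__!r} in {expression!r}"
                )
            if isinstance(node, ast.Constant) and not isinstance(node.value, (int, float)):
                raise PredicateError(f"non-numeric literal in {expression!r}")
        self.names = sorted(
            {n.id for n in ast.walk(tree) if isinstance(n, ast.Name)}
        )
        self._code = compile(tree, "<predicate>", "eval")

    def __call__(self, variables: Mapping[str, float]) -> bool:
        missing = [n for n in self.names if n not in variables]
        if missing:
            raise PredicateError(
                f"predicate {self.expression!r} references unknown variables {missing}"
            )
        return bool(eval(self._code, {"__builtins__": {}}, dict(variables)))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Predicate({self.expression!r})"
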