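"""Tiny arithmetic expression language for functional sequence parameters.

Sequence objects may define numeric attributes as arithmetic expressions over
named quantities: the sequence global parameters, attributes of sibling
objects, attributes of the enclosing block/group, and the special token ``ID``
(the unique increasing id of the enclosing group or block).  This lets a
single block-group prototype describe, e.g., the phase-encode gradient of
every repetition of a Cartesian sequence.

The language is deliberately small: ``+ - * /``, unary minus, parentheses and
numeric literals.  Evaluation is pure; unknown identifiers raise.
"""

from __future__ import annotations

import ast
from typing import Mapping

__all__ = ["Expression", "ExpressionError", "eval_expression"]


class ExpressionError(ValueError):
    """Malformed expression or unknown symbol."""


_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)
_ALLOWED_UNARY = (ast.USub, ast.UAdd)


def _validate(node: ast.AST, text: str) -> None:
    if isinstance(node, ast.Expression):
        _validate(node.body, text)
    elif isinstance(node, ast.BinOp):
        if not isinstance(node.op, _ALLOWED_BINOPS):
            raise ExpressionError(f"operator not allowed in {text!r}")
        _validate(node.left, text)
        _validate(node.right, text)
    elif isinstance(node, ast.UnaryOp):
        if not isinstance(node.op, _ALLOWED_UNARY):
            raise ExpressionError(f"operator not allowed in {text!r}")
        _validate(node.operand, text)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ExpressionError(f"non-numeric literal in {text!r}")
    elif isinstance(node, ast.Name):
        pass
    else:
        raise ExpressionError(
            f"construct {type(node).__name__} not allowed in {text!r}"
        )


class Expression:
    """A parsed arithmetic expression over named numeric symbols."""

    __slots__ = ("text", "_tree", "names")

    def __init__(self, text: str):
        self.text = text
        try:
            self._tree = ast.parse(text, mode="eval")
        except SyntaxError as exc:  # pragma: no cover - message only
            raise ExpressionError(f"cannot parse {text!r}: {exc}") from None
        _validate(self._tree, text)
        self.names = frozenset(
            n.id for n in ast.walk(self._tree) if isinstance(n, ast.Name)
        )

    def __call__(self, context: Mapping[str, float]) -> float:
        return self._eval(self._tree.body, context)

    def _eval(self, node: ast.AST, ctx: Mapping[str, float]) -> float:
        if isinstance(node, ast.BinOp):
            left = self._eval(node.left, ctx)
            right = self._eval(node.right, ctx)
            if isinstance(node.op, ast.Add):
                return left + right
            if isinstance(node.op, ast.Sub):
                return left - right
            if isinstance(node.op, ast.Mult):
                return left * right
            # division; a zero divisor is a genuine arithmetic error
            if right == 0:
                raise ZeroDivisionError(f"division by zero in {self.text!r}")
            return left / right
        if isinstance(node, ast.UnaryOp):
            value = self._eval(node.operand, ctx)
            return -value if isinstance(node.op, ast.USub) else value
        if isinstance(node, ast.Constant):
            return float(node.value)
        if isinstance(node, ast.Name):
            try:
                return float(ctx[node.id])
            except KeyError:
                raise ExpressionError(
                    f"unknown symbol {node.id!r} in {self.text!r}"
                ) from None
        raise ExpressionError(f"unexpected node in {self.text!r}")

    def __repr__(self) -> str:  # pragma: no cover
        return f"Expression({self.text!r})"


def eval_expression(expr, context: Mapping[str, float]) -> float:
    """Evaluate ``expr`` (an :class:`Expression` or source text) in ``context``."""
    if not isinstance(expr, Expression):
        expr = Expression(str(expr))
    return expr(context)
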