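"""Safe arithmetic expressions over named parameters.

Used for derived MPT parameters (e.g. ``(D_A + D_B) / 2``) and for derived
quantities in constraint specifications (e.g. ``d_B_pleasant - d_A_pleasant``).
Only +, -, *, /, unary minus, numeric literals and parameter names are
admitted; anything else raises at compile time, never at evaluation time.
"""

from __future__ import annotations

import ast
from dataclasses import dataclass, field
from typing import Any, Mapping

_ALLOWED_BINOPS = (ast.Add, ast.Sub, ast.Mult, ast.Div)


@dataclass(frozen=True)
class Expression:
    """A compiled arithmetic expression over named parameters."""

    source: str
    names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        tree = _parse(self.source)
        object.__setattr__(self, "names", tuple(sorted(_collect_names(tree))))
        object.__setattr__(self, "_tree", tree)

    def __call__(self, values: Mapping[str, Any]):
        missing = [n for n in self.names if n not in values]
        if missing:
            raise KeyError(f"expression {self.source!r} missing parameter(s): {missing}")
        return _eval(self._tree, values)  # type: ignore[attr-defined]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.source


def _parse(source: str) -> ast.expr:
    try:
        tree = ast.parse(source, mode="eval").body
    except SyntaxError as exc:
        raise ValueError(f"invalid expression {source!r}: {exc.msg}") from exc
    _validate(tree, source)
    return tree


def _validate(node: ast.expr, source: str) -> None:
    if isinstance(node, ast.BinOp) and isinstance(node.op, _ALLOWED_BINOPS):
        _validate(node.left, source)
        _validate(node.right, source)
    elif isinstance(node, ast.UnaryOp) and isinstance(node.op, (ast.USub, ast.UAdd)):
        _validate(node.operand, source)
    elif isinstance(node, ast.Constant):
        if not isinstance(node.value, (int, float)):
            raise ValueError(f"non-numeric constant in expression {source!r}")
    elif isinstance(node, ast.Name):
        pass
    else:
        raise ValueError(
            f"unsupported syntax {type(node).__name__!r} in expression {source!r}; "
            "only +, -, *, /, numbers and parameter names are allowed"
        )


def _collect_names(node: ast.expr) -> set[str]:
    return {n.id for n in ast.walk(node) if isinstance(n, ast.Name)}


def _eval(node: ast.expr, values: Mapping[str, Any]):
    if isinstance(node, ast.BinOp):
        left = _eval(node.left, values)
        right = _eval(node.right, values)
        if isinstance(node.op, ast.Add):
            return left + right
        if isinstance(node.op, ast.Sub):
            return left - right
        if isinstance(node.op, ast.Mult):
            return left * right
        return left / right
    if isinstance(node, ast.UnaryOp):
        operand = _eval(node.operand, values)
        return -operand if isinstance(node.op, ast.USub) else +operand
    if isinstance(node, ast.Constant):
        return node.value
    return values[node.id]  # ast.Name
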