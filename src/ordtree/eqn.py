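"""Read and write MPT models in the EQN text format.

EQN is the plain-text interchange format used by the MPT community's tools
(multiTree, HMMTree, MPTinR, TreeBUGS).  Each line names a tree, a response
category and one branch term — a product of factors, each a parameter ``p``,
its complement ``(1-p)``, or a numeric constant::

    source_A  A  D*d
    source_A  A  D*(1-d)*g
    ...

Dialect accepted here: an optional leading line containing only a line count,
blank lines, and ``#`` comments.  Derived parameters (deterministic functions
of free parameters) are carried in structured comments so models like the
Bell-style 2HTSM round-trip losslessly::

    # derived: D_New = (D_A + D_B) / 2
"""

from __future__ import annotations

import re
from pathlib import Path

from .expressions import Expression
from .model import Branch, Factor, MPTModel, StructuralError, Tree

__all__ = ["parse_eqn", "write_eqn", "read_eqn_file", "write_eqn_file", "EqnFormatError"]

_DERIVED_RE = re.compile(r"^#\s*derived\s*:\s*(\w+)\s*=\s*(.+)$")
_COMPLEMENT_RE = re.compile(r"^\(\s*1\s*-\s*([A-Za-z_]\w*)\s*\)$")
_NAME_RE = re.compile(r"^[A-Za-z_]\w*$")


class EqnFormatError(ValueError):
    """Raised for unparseable EQN input; carries the offending line number."""

    def __init__(self, message: str, line: int):
        super().__init__(f"line {line}: {message}")
        self.line = line


def _parse_factor(token: str, line_no: int) -> Factor:
    token = token.strip()
    match = _COMPLEMENT_RE.match(token)
    if match:
        return Factor(name=match.group(1), complement=True)
    if _NAME_RE.match(token):
        return Factor(name=token)
    try:
        value = float(token)
    except ValueError:
        raise EqnFormatError(
            f"cannot parse branch factor {token!r} (expected a parameter, (1-parameter), or a number)",
            line_no,
        ) from None
    if not 0.0 <= value <= 1.0:
        raise EqnFormatError(f"constant factor {value} outside [0, 1]", line_no)
    return Factor(constant=value)


def _parse_term(term: str, line_no: int) -> tuple[Factor, ...]:
    # split on '*' outside parentheses; terms here only nest one level: (1-p)
    parts: list[str] = []
    depth = 0
    current = ""
    for ch in term:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise EqnFormatError(f"unbalanced parentheses in {term!r}", line_no)
        if ch == "*" and depth == 0:
            parts.append(current)
            current = ""
        else:
            current += ch
    if depth != 0:
        raise EqnFormatError(f"unbalanced parentheses in {term!r}", line_no)
    parts.append(current)
    if any(not p.strip() for p in parts):
        raise EqnFormatError(f"empty factor in branch term {term!r}", line_no)
    return tuple(_parse_factor(p, line_no) for p in parts)


def parse_eqn(text: str, name: str = "mpt", validate: bool = True) -> MPTModel:
    """Parse EQN text into an :class:`~ordtree.model.MPTModel`.

    Raises :class:`EqnFormatError` for malformed lines and
    :class:`~ordtree.model.StructuralError` when a tree's branch products do
    not sum to one identically (checked at quasi-random parameter points).
    """
    derived: dict[str, Expression] = {}
    rows: list[tuple[str, str, tuple[Factor, ...]]] = []
    lines = text.splitlines()
    first_content = True
    for i, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            match = _DERIVED_RE.match(line)
            if match:
                derived[match.group(1)] = Expression(match.group(2).strip())
            continue
        tokens = line.split(None, 2)
        if first_content and len(tokens) == 1:
            first_content = False
            try:
                int(tokens[0])
                continue  # count header, ignored
            except ValueError:
                raise EqnFormatError(f"cannot parse line {line!r}", i) from None
        first_content = False
        if len(tokens) != 3:
            raise EqnFormatError(
                f"expected 'tree category branch-term', got {line!r}", i
            )
        tree_name, category, term = tokens
        rows.append((tree_name, category, _parse_term(term, i)))
    if not rows:
        raise EqnFormatError("no branch lines found", len(lines) or 1)

    tree_order: list[str] = []
    tree_categories: dict[str, list[str]] = {}
    tree_branches: dict[str, list[Branch]] = {}
    param_order: list[str] = []
    for tree_name, category, factors in rows:
        if tree_name not in tree_categories:
            tree_order.append(tree_name)
            tree_categories[tree_name] = []
            tree_branches[tree_name] = []
        if category not in tree_categories[tree_name]:
            tree_categories[tree_name].append(category)
        tree_branches[tree_name].append(Branch(category, factors))
        for factor in factors:
            if factor.name is not None and factor.name not in param_order and factor.name not in derived:
                param_order.append(factor.name)

    trees = tuple(
        Tree(t, tuple(tree_categories[t]), tuple(tree_branches[t])) for t in tree_order
    )
    model = MPTModel(parameters=tuple(param_order), trees=trees, derived=derived, name=name)
    if validate:
        model.validate_branch_sums()
    return model


def write_eqn(model: MPTModel, count_header: bool = False) -> str:
    """Serialize a model to EQN text (inverse of :func:`parse_eqn`)."""
    lines: list[str] = []
    for name, expr in model.derived.items():
        lines.append(f"# derived: {name} = {expr.source}")
    body = [
        f"{tree.name} {branch.category} {'*'.join(f.to_eqn() for f in branch.factors)}"
        for tree in model.trees
        for branch in tree.branches
    ]
    if count_header:
        lines = [str(len(body))] + lines
    return "\n".join(lines + body) + "\n"


def read_eqn_file(path: str | Path, name: str | None = None) -> MPTModel:
    path = Path(path)
    return parse_eqn(path.read_text(), name=name or path.stem)


def write_eqn_file(model: MPTModel, path: str | Path, count_header: bool = False) -> None:
    Path(path).write_text(write_eqn(model, count_header=count_header))
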