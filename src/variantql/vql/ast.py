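"""AST node types for the variant query language, plus the canonical
serializer.

Canonical form uses uppercase keywords and straight single quotes;
``parse(serialize(parse(x)))`` is structurally equal to ``parse(x)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "FieldRef",
    "ResolvedFieldRef",
    "Comparison",
    "Logical",
    "Not",
    "SelectStmt",
    "CreateSelection",
    "CreateSetOp",
    "Drop",
    "ImportWordset",
    "field_label",
    "serialize_ast",
    "walk_filter",
]

COMPARISON_OPS = (
    "=", "!=", "<", "<=", ">", ">=",
    "~", "IN", "NOT IN", "IN WORDSET", "IS NULL", "IS NOT NULL",
)


@dataclass(frozen=True)
class FieldRef:
    """A field reference as written: bare ``name``, ``ann.name`` or
    ``samples['X'].name``."""

    name: str
    namespace: Optional[str] = None  # 'ann' | 'sample' | None (bare)
    sample: Optional[str] = None

    def __post_init__(self):
        if self.namespace == "sample" and not self.sample:
            raise ValueError("sample namespace requires a sample name")


@dataclass(frozen=True)
class ResolvedFieldRef(FieldRef):
    """A FieldRef bound to the store schema by the validator."""

    category: str = "core"  # core | info | annotation | sample
    column: str = ""
    value_type: str = "string"


@dataclass(frozen=True)
class Comparison:
    field: FieldRef
    op: str
    value: object = None  # literal | tuple of literals | wordset name

    def __post_init__(self):
        if self.op not in COMPARISON_OPS:
            raise ValueError(f"unknown comparison operator {self.op!r}")


@dataclass(frozen=True)
class Logical:
    op: str  # 'AND' | 'OR'
    children: tuple

    def __post_init__(self):
        if self.op not in ("AND", "OR"):
            raise ValueError(f"unknown logical operator {self.op!r}")
        if len(self.children) < 2:
            raise ValueError("logical node needs >= 2 children")


@dataclass(frozen=True)
class Not:
    child: object


@dataclass(frozen=True)
class SelectStmt:
    select_list: tuple
    source: str = "variants"
    filter: object = None
    order_by: tuple = ()  # of (FieldRef, 'ASC'|'DESC')
    limit: Optional[int] = None
    offset: Optional[int] = None

    kind = "select"

    def __post_init__(self):
        if not self.select_list:
            raise ValueError("select list must not be empty")


@dataclass(frozen=True)
class CreateSelection:
    """CREATE name FROM source [WHERE ...] [INTERSECT 'file.bed']"""

    name: str
    source: str = "variants"
    filter: object = None
    bed_path: Optional[str] = None

    @property
    def kind(self) -> str:
        return "create_from_bed" if self.bed_path else "create_selection"


@dataclass(frozen=True)
class CreateSetOp:
    """CREATE name = left (& | '|' | -) right"""

    name: str
    left: str
    op: str
    right: str

    kind = "create_from_setop"

    def __post_init__(self):
        if self.op not in ("&", "|", "-"):
            raise ValueError(f"unknown set operator {self.op!r}")


@dataclass(frozen=True)
class Drop:
    target: str  # 'selection' | 'wordset'
    name: str

    kind = "drop"


@dataclass(frozen=True)
class ImportWordset:
    """IMPORT WORDSET 'file.txt' AS name"""

    path: str
    name: str

    kind = "import_wordset"


def walk_filter(node):
    """Yield every Comparison leaf of a filter tree."""
    if node is None:
        return
    if isinstance(node, Comparison):
        yield node
    elif isinstance(node, Not):
        yield from walk_filter(node.child)
    elif isinstance(node, Logical):
        for child in node.children:
            yield from walk_filter(child)
    else:  # pragma: no cover - defensive
        raise TypeError(f"not a filter node: {node!r}")


# ---------------------------------------------------------------------------
# serialization


def _quote(text: str) -> str:
    return "'" + str(text).replace("'", "''") + "'"


def field_label(ref: FieldRef) -> str:
    """The user-facing column label for a field reference, as written."""
    if ref.namespace == "sample":
        return f"samples[{_quote(ref.sample)}].{ref.name}"
    if ref.namespace == "ann":
        return f"ann.{ref.name}"
    return ref.name


def _value_text(value) -> str:
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, (int, float)):
        return repr(value)
    return _quote(value)


def _filter_text(node, parent_prec: int = 0) -> str:
    # precedence: OR=1 < AND=2 < NOT=3 < comparison=4
    if isinstance(node, Comparison):
        label = field_label(node.field)
        if node.op in ("IS NULL", "IS NOT NULL"):
            return f"{label} {node.op}"
        if node.op in ("IN", "NOT IN"):
            items = ", ".join(_value_text(v) for v in node.value)
            return f"{label} {node.op} ({items})"
        if node.op == "IN WORDSET":
            return f"{label} IN WORDSET {_quote(node.value)}"
        return f"{label} {node.op} {_value_text(node.value)}"
    if isinstance(node, Not):
        text = f"NOT {_filter_text(node.child, 3)}"
        return f"({text})" if parent_prec > 3 else text
    if isinstance(node, Logical):
        prec = 2 if node.op == "AND" else 1
        text = f" {node.op} ".join(_filter_text(c, prec) for c in node.children)
        return f"({text})" if parent_prec >= prec else text
    raise TypeError(f"not a filter node: {node!r}")


def serialize_ast(ast) -> str:
    """Render any statement AST back to canonical VQL text."""
    if isinstance(ast, SelectStmt):
        parts = [
            "SELECT " + ", ".join(field_label(f) for f in ast.select_list),
            "FROM " + ast.source,
        ]
        if ast.filter is not None:
            parts.append("WHERE " + _filter_text(ast.filter))
        if ast.order_by:
            keys = ", ".join(
                field_label(f) + ("" if d == "ASC" else " DESC")
                for f, d in ast.order_by
            )
            parts.append("ORDER BY " + keys)
        if ast.limit is not None:
            parts.append(f"LIMIT {ast.limit}")
            if ast.offset is not None:
                parts.append(f"OFFSET {ast.offset}")
        return " ".join(parts)
    if isinstance(ast, CreateSelection):
        parts = [f"CREATE {ast.name} FROM {ast.source}"]
        if ast.filter is not None:
            parts.append("WHERE " + _filter_text(ast.filter))
        if ast.bed_path is not None:
            parts.append("INTERSECT " + _quote(ast.bed_path))
        return " ".join(parts)
    if isinstance(ast, CreateSetOp):
        return f"CREATE {ast.name} = {ast.left} {ast.op} {ast.right}"
    if isinstance(ast, Drop):
        return f"DROP {ast.target.upper()} {ast.name}"
    if isinstance(ast, ImportWordset):
        return f"IMPORT WORDSET {_quote(ast.path)} AS {ast.name}"
    raise TypeError(f"not a statement: {ast!r}")
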