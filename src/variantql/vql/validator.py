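"""Semantic validation: binds field references to the store catalogue,
type-checks literals and verifies that samples, selections and wordsets
exist.

Bare field names resolve core-namespace first, then INFO, then the
annotation namespace — so both ``impact`` and ``ann.impact`` reach the
same annotation column when no core/INFO field shadows the name.
"""

from __future__ import annotations

from dataclasses import replace

from .ast import (
    Comparison,
    CreateSelection,
    CreateSetOp,
    Drop,
    FieldRef,
    ImportWordset,
    Logical,
    Not,
    ResolvedFieldRef,
    SelectStmt,
    field_label,
)
from .parser import KEYWORDS

__all__ = ["validate_ast", "VqlValidationError"]

_NUMERIC = {"int", "float"}


class VqlValidationError(ValueError):
    pass


class _Schema:
    def __init__(self, store):
        self.by_category: dict[str, dict] = {}
        for f in store.field_catalogue():
            self.by_category.setdefault(f["category"], {})[f["name"]] = f
        self.samples = set(store.sample_names())
        self.selections = set(store.selection_names())
        self.wordsets = set(store.wordset_names())

    def resolve(self, ref: FieldRef) -> ResolvedFieldRef:
        if ref.namespace == "sample":
            if ref.sample not in self.samples:
                raise VqlValidationError(f"unknown sample {ref.sample!r}")
            f = self.by_category.get("sample", {}).get(ref.name)
            if f is None:
                raise VqlValidationError(
                    f"unknown sample field {ref.name!r}"
                )
            return ResolvedFieldRef(
                ref.name, "sample", ref.sample,
                category="sample", column=f["column"],
                value_type=f["value_type"],
            )
        if ref.namespace == "ann":
            f = self.by_category.get("annotation", {}).get(ref.name)
            if f is None:
                raise VqlValidationError(
                    f"unknown annotation field {ref.name!r}"
                )
            return ResolvedFieldRef(
                ref.name, "ann",
                category="annotation", column=f["column"],
                value_type=f["value_type"],
            )
        for category in ("core", "info", "annotation"):
            f = self.by_category.get(category, {}).get(ref.name)
            if f is not None:
                return ResolvedFieldRef(
                    ref.name, None,
                    category=category, column=f["column"],
                    value_type=f["value_type"],
                )
        raise VqlValidationError(f"unknown field {ref.name!r}")


def _check_literal(ref: ResolvedFieldRef, value, op: str) -> None:
    label = field_label(ref)
    if isinstance(value, str):
        if ref.value_type in _NUMERIC:
            raise VqlValidationError(
                f"type mismatch: {label} is {ref.value_type}, "
                f"compared with string {value!r}"
            )
    elif isinstance(value, (int, float)):
        if ref.value_type == "string":
            raise VqlValidationError(
                f"type mismatch: {label} is a string field, "
                f"compared with number {value!r}"
            )
    else:  # pragma: no cover - parser only yields str/int/float
        raise VqlValidationError(f"unsupported literal {value!r}")


def _validate_comparison(node: Comparison, schema: _Schema) -> Comparison:
    ref = schema.resolve(node.field)
    label = field_label(ref)
    if node.op in ("IS NULL", "IS NOT NULL"):
        return Comparison(ref, node.op)
    if node.op == "~":
        if ref.value_type != "string":
            raise VqlValidationError(
                f"regex operator '~' applies only to string fields, "
                f"{label} is {ref.value_type}"
            )
        return Comparison(ref, node.op, node.value)
    if node.op == "IN WORDSET":
        if ref.value_type != "string":
            raise VqlValidationError(
                f"IN WORDSET applies only to string fields, "
                f"{label} is {ref.value_type}"
            )
        if node.value not in schema.wordsets:
            raise VqlValidationError(f"unknown wordset {node.value!r}")
        return Comparison(ref, node.op, node.value)
    if node.op in ("IN", "NOT IN"):
        values = node.value
        if not values:
            raise VqlValidationError(f"empty {node.op} list for {label}")
        kinds = {isinstance(v, str) for v in values}
        if len(kinds) > 1:
            raise VqlValidationError(
                f"{node.op} list for {label} mixes strings and numbers"
            )
        for v in values:
            _check_literal(ref, v, node.op)
        return Comparison(ref, node.op, tuple(values))
    _check_literal(ref, node.value, node.op)
    return Comparison(ref, node.op, node.value)


def _validate_filter(node, schema: _Schema):
    if node is None:
        return None
    if isinstance(node, Comparison):
        return _validate_comparison(node, schema)
    if isinstance(node, Not):
        return Not(_validate_filter(node.child, schema))
    if isinstance(node, Logical):
        return Logical(
            node.op,
            tuple(_validate_filter(c, schema) for c in node.children),
        )
    raise TypeError(f"not a filter node: {node!r}")


def _check_source(source: str, schema: _Schema) -> None:
    if source not in schema.selections:
        raise VqlValidationError(f"unknown selection {source!r}")


def _check_new_name(name: str, kind: str) -> None:
    if name in KEYWORDS or name == "variants":
        raise VqlValidationError(
            f"{name!r} is reserved and cannot name a {kind}"
        )


def validate_ast(ast, store):
    """Validate a parsed statement against ``store``; returns a structurally
    identical AST whose field references are :class:`ResolvedFieldRef`.
    """
    schema = _Schema(store)
    if isinstance(ast, SelectStmt):
        _check_source(ast.source, schema)
        select_list = tuple(schema.resolve(f) for f in ast.select_list)
        filt = _validate_filter(ast.filter, schema)
        order_by = tuple(
            (schema.resolve(f), d) for f, d in ast.order_by
        )
        return SelectStmt(select_list, ast.source, filt, order_by,
                          ast.limit, ast.offset)
    if isinstance(ast, CreateSelection):
        _check_new_name(ast.name, "selection")
        _check_source(ast.source, schema)
        return CreateSelection(
            ast.name, ast.source, _validate_filter(ast.filter, schema),
            ast.bed_path,
        )
    if isinstance(ast, CreateSetOp):
        _check_new_name(ast.name, "selection")
        _check_source(ast.left, schema)
        _check_source(ast.right, schema)
        return ast
    if isinstance(ast, Drop):
        if ast.target == "selection":
            if ast.name == "variants":
                raise VqlValidationError("cannot drop the reserved selection 'variants'")
            _check_source(ast.name, schema)
        else:
            if ast.name not in schema.wordsets:
                raise VqlValidationError(f"unknown wordset {ast.name!r}")
        return ast
    if isinstance(ast, ImportWordset):
        _check_new_name(ast.name, "wordset")
        return ast
    raise TypeError(f"not a statement: {ast!r}")
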