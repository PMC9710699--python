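"""Compile validated select statements into SQL query plans over the store.

Row semantics: when the select list (or an ORDER BY key) references an
annotation field, the output has one row per (variant, matching
annotation); otherwise annotation predicates in the WHERE clause are
existential ("some annotation matches") and each variant appears at most
once.  Missing values compare as false, so every generated predicate is
strictly two-valued (``IFNULL(..., 0)``), which keeps NOT semantics
aligned with the reference evaluator.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

from .ast import (
    Comparison,
    Logical,
    Not,
    ResolvedFieldRef,
    SelectStmt,
    field_label,
    walk_filter,
)

__all__ = ["QueryPlan", "compile_select", "compile_selection_ids"]


@dataclass
class QueryPlan:
    sql: str
    params: list
    columns: list  # output labels, in select-list order
    kind: str = "select"


def _q(name: str) -> str:
    return '"' + name.replace('"', '""') + '"'


class _SqlBuilder:
    """Column expressions + genotype joins for one alias scope."""

    def __init__(self, variant_alias: str, ann_alias: str, prefix: str):
        self.v = variant_alias
        self.a = ann_alias
        self.prefix = prefix
        self.sample_aliases: dict[str, str] = {}
        self.uses_ann = False

    def expr(self, ref: ResolvedFieldRef) -> str:
        if ref.category in ("core", "info"):
            return f"{self.v}.{_q(ref.column)}"
        if ref.category == "annotation":
            self.uses_ann = True
            return f"{self.a}.{_q(ref.column)}"
        alias = self.sample_aliases.get(ref.sample)
        if alias is None:
            alias = f"{self.prefix}{len(self.sample_aliases)}"
            self.sample_aliases[ref.sample] = alias
        return f"{alias}.{_q(ref.column)}"

    def genotype_joins(self, sample_ids: dict) -> str:
        parts = []
        for sample, alias in self.sample_aliases.items():
            parts.append(
                f" LEFT JOIN genotypes {alias} ON {alias}.variant_id = "
                f"{self.v}.id AND {alias}.sample_id = {sample_ids[sample]}"
            )
        return "".join(parts)


def _filter_sql(node, b: _SqlBuilder, params: list) -> str:
    if isinstance(node, Comparison):
        col = b.expr(node.field)
        op = node.op
        if op in ("=", "!=", "<", "<=", ">", ">="):
            params.append(node.value)
            return f"IFNULL({col} {op} ?, 0)"
        if op == "~":
            params.append(node.value)
            return f"vql_regexp(?, {col})"
        if op in ("IN", "NOT IN"):
            params.extend(node.value)
            holes = ",".join("?" * len(node.value))
            return f"IFNULL({col} {op} ({holes}), 0)"
        if op == "IN WORDSET":
            params.append(node.value)
            return (f"IFNULL({col} IN (SELECT word FROM wordsets "
                    f"WHERE name = ?), 0)")
        if op == "IS NULL":
            return f"({col} IS NULL)"
        if op == "IS NOT NULL":
            return f"({col} IS NOT NULL)"
        raise ValueError(f"unknown operator {op!r}")  # pragma: no cover
    if isinstance(node, Not):
        return f"(NOT {_filter_sql(node.child, b, params)})"
    if isinstance(node, Logical):
        joined = f" {node.op} ".join(
            _filter_sql(c, b, params) for c in node.children
        )
        return f"({joined})"
    raise TypeError(f"not a filter node: {node!r}")  # pragma: no cover


def _source_clause(source: str, store, alias: str) -> tuple[str, list]:
    if source == "variants":
        return "", []
    sid = store._selection_id(source)
    return (
        f" JOIN selection_variants sv_{alias} ON sv_{alias}.variant_id ="
        f" {alias}.id AND sv_{alias}.selection_id = ?",
        [sid],
    )


def _ann_in(refs) -> bool:
    return any(r.category == "annotation" for r in refs)


def compile_select(ast: SelectStmt, store) -> QueryPlan:
    """Compile a validated SELECT into a single SQL statement.

    Output order: explicit ORDER BY keys first, then variant id (and
    annotation id in annotation-row mode) as stable tiebreakers.
    """
    sample_ids = store.sample_ids()
    order_refs = [r for r, _ in ast.order_by]
    row_mode = _ann_in(ast.select_list) or _ann_in(order_refs)
    filter_has_ann = ast.filter is not None and _ann_in(
        c.field for c in walk_filter(ast.filter)
    )

    outer = _SqlBuilder("v", "a", "g")
    where_params: list = []
    select_exprs = ", ".join(outer.expr(r) for r in ast.select_list)
    order_parts = [
        f"{outer.expr(r)} {direction}" for r, direction in ast.order_by
    ]

    where_parts: list[str] = []
    ann_join = ""
    if row_mode:
        ann_join = " LEFT JOIN annotations a ON a.variant_id = v.id"
        if ast.filter is not None:
            where_parts.append(_filter_sql(ast.filter, outer, where_params))
        order_tail = ["v.id", "a.id"]
    elif filter_has_ann:
        # existential over annotations, deduplicated per variant
        inner = _SqlBuilder("iv", "ia", "ig")
        inner_params: list = []
        inner_where = _filter_sql(ast.filter, inner, inner_params)
        inner_sql = (
            "SELECT iv.id FROM variants iv"
            " LEFT JOIN annotations ia ON ia.variant_id = iv.id"
            + inner.genotype_joins(sample_ids)
            + f" WHERE {inner_where}"
        )
        where_parts.append(f"v.id IN ({inner_sql})")
        where_params.extend(inner_params)
        order_tail = ["v.id"]
    else:
        if ast.filter is not None:
            where_parts.append(_filter_sql(ast.filter, outer, where_params))
        order_tail = ["v.id"]

    source_join, params = _source_clause(ast.source, store, "v")
    joins = source_join + ann_join + outer.genotype_joins(sample_ids)
    params.extend(where_params)

    sql = f"SELECT {select_exprs} FROM variants v{joins}"
    if where_parts:
        sql += " WHERE " + " AND ".join(where_parts)
    sql += " ORDER BY " + ", ".join(order_parts + order_tail)
    if ast.limit is not None:
        params.append(ast.limit)
        sql += " LIMIT ?"
        if ast.offset is not None:
            params.append(ast.offset)
            sql += " OFFSET ?"
    columns = [field_label(r) for r in ast.select_list]
    return QueryPlan(sql, params, columns)


def compile_selection_ids(source: str, filter_node, store) -> QueryPlan:
    """Plan yielding the distinct variant ids of ``source`` matching
    ``filter_node`` (annotation predicates existential) — the engine of
    CREATE ... FROM ... WHERE statements."""
    sample_ids = store.sample_ids()
    b = _SqlBuilder("v", "a", "g")
    where_params: list = []
    where = ""
    if filter_node is not None:
        where = " WHERE " + _filter_sql(filter_node, b, where_params)
    joins, params = _source_clause(source, store, "v")
    if b.uses_ann:
        joins += " LEFT JOIN annotations a ON a.variant_id = v.id"
    joins += b.genotype_joins(sample_ids)
    params.extend(where_params)
    sql = f"SELECT DISTINCT v.id FROM variants v{joins}{where} ORDER BY v.id"
    return QueryPlan(sql, params, ["id"], kind="ids")
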