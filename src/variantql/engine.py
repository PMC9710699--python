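"""Query execution: compiled-plan runner, an independent brute-force
reference evaluator (the test oracle), trio transmission filters, sorting
and CSV export.

The brute-force path shares no SQL with the compiled path: it walks the
store's variant/annotation/genotype rows in Python and applies
:func:`evaluate_filter` recursively, so the two can be checked against
each other.
"""

from __future__ import annotations

import csv
import os
import re
from dataclasses import dataclass, field as dc_field
from pathlib import Path

from . import datastore
from .vql import (
    Comparison,
    CreateSelection,
    CreateSetOp,
    Drop,
    FieldRef,
    ImportWordset,
    Logical,
    Not,
    SelectStmt,
    compile_select,
    compile_selection_ids,
    parse_vql,
    serialize_ast,
    validate_ast,
    walk_filter,
)

__all__ = [
    "EvalContext",
    "evaluate_filter",
    "execute_plan",
    "brute_force_select",
    "transmission_filter",
    "trio_select",
    "export_csv",
    "run_vql",
    "QueryResult",
    "TRANSMISSION_MODES",
]

TRANSMISSION_MODES = ("denovo", "autosomal_recessive", "dominant")


@dataclass
class EvalContext:
    """Everything one filter evaluation can see: one variant row (with INFO
    and aggregate columns), at most one annotation, the per-sample genotype
    map and a wordset lookup."""

    variant: dict
    annotation: dict | None = None
    genotypes: dict = dc_field(default_factory=dict)
    wordsets: object = None  # callable name -> set of words


def _field_value(ref, ctx: EvalContext):
    if ref.category in ("core", "info"):
        return ctx.variant.get(ref.column)
    if ref.category == "annotation":
        if ctx.annotation is None:
            return None
        return ctx.annotation.get(ref.name)
    return ctx.genotypes.get(ref.sample, {}).get(ref.name)


def evaluate_filter(node, ctx: EvalContext) -> bool:
    """Reference semantics for the WHERE clause: strict two-valued logic,
    with any comparison against a missing value evaluating to false."""
    if isinstance(node, Comparison):
        left = _field_value(node.field, ctx)
        op = node.op
        if op == "IS NULL":
            return left is None
        if op == "IS NOT NULL":
            return left is not None
        if left is None:
            return False
        if op == "=":
            return left == node.value
        if op == "!=":
            return left != node.value
        if op == "<":
            return left < node.value
        if op == "<=":
            return left <= node.value
        if op == ">":
            return left > node.value
        if op == ">=":
            return left >= node.value
        if op == "~":
            return re.search(node.value, str(left)) is not None
        if op == "IN":
            return left in node.value
        if op == "NOT IN":
            return left not in node.value
        if op == "IN WORDSET":
            return left in ctx.wordsets(node.value)
        raise ValueError(f"unknown operator {op!r}")  # pragma: no cover
    if isinstance(node, Not):
        return not evaluate_filter(node.child, ctx)
    if isinstance(node, Logical):
        if node.op == "AND":
            return all(evaluate_filter(c, ctx) for c in node.children)
        return any(evaluate_filter(c, ctx) for c in node.children)
    raise TypeError(f"not a filter node: {node!r}")


# ---------------------------------------------------------------------------
# execution


@dataclass
class QueryResult:
    columns: list
    rows: list  # of dicts keyed by column label
    message: str = ""


def execute_plan(plan, store) -> list:
    """Run a compiled plan; yields one dict per result row with keys in
    select-list order."""
    out = []
    for raw in store.conn.execute(plan.sql, plan.params):
        out.append({col: raw[i] for i, col in enumerate(plan.columns)})
    return out


def _sort_rows(records, order_by):
    """Stable multi-key sort matching SQLite ordering: ASC puts missing
    first, DESC puts missing last."""
    for idx in range(len(order_by) - 1, -1, -1):
        _, direction = order_by[idx]
        reverse = direction == "DESC"

        def key(rec, i=idx):
            v = rec[1][i]
            return (v is not None, v if v is not None else 0)

        records.sort(key=key, reverse=reverse)
    return records


def brute_force_select(ast: SelectStmt, store) -> list:
    """Evaluate a validated SELECT without SQL, mirroring the compiled
    plan's row semantics exactly; the central test oracle."""
    order_refs = [r for r, _ in ast.order_by]
    row_mode = any(r.category == "annotation" for r in ast.select_list)
    row_mode = row_mode or any(r.category == "annotation" for r in order_refs)
    filter_has_ann = ast.filter is not None and any(
        c.field.category == "annotation" for c in walk_filter(ast.filter)
    )
    wordsets = store.wordset

    records = []  # (row dict, sort values)
    for variant in store.variant_rows(ast.source):
        anns = store.annotations_for(variant["id"])
        gts = store.genotype_map(variant["id"])

        def emit(annotation):
            ctx = EvalContext(variant, annotation, gts, wordsets)
            row = {}
            for ref in ast.select_list:
                row.setdefault(_label(ref), _field_value(ref, ctx))
            keys = [_field_value(ref, ctx) for ref in order_refs]
            records.append((row, keys))

        if row_mode:
            for annotation in anns or [None]:
                ctx = EvalContext(variant, annotation, gts, wordsets)
                if ast.filter is None or evaluate_filter(ast.filter, ctx):
                    emit(annotation)
        elif filter_has_ann:
            if any(
                evaluate_filter(
                    ast.filter, EvalContext(variant, annotation, gts, wordsets)
                )
                for annotation in (anns or [None])
            ):
                emit(None)
        else:
            ctx = EvalContext(variant, None, gts, wordsets)
            if ast.filter is None or evaluate_filter(ast.filter, ctx):
                emit(None)

    if ast.order_by:
        _sort_rows(records, ast.order_by)
    rows = [row for row, _ in records]
    if ast.limit is not None:
        start = ast.offset or 0
        rows = rows[start:start + ast.limit]
    return rows


def _label(ref):
    from .vql import field_label

    return field_label(ref)


class StoreSnapshot:
    """In-memory copy of a store's query-relevant rows.

    Duck-types the store methods :func:`brute_force_select` uses, so large
    oracle sweeps avoid per-variant SQL round trips.
    """

    def __init__(self, store):
        self._store = store
        self._variants = {}  # selection name -> rows
        self._annotations: dict[int, list] = {}
        names = [f["name"] for f in store.field_catalogue()
                 if f["category"] == "annotation"]
        for r in store.conn.execute("SELECT * FROM annotations ORDER BY id"):
            d = {"allele": r["allele"]}
            for name in names:
                d[name] = r["ann_" + name]
            self._annotations.setdefault(r["variant_id"], []).append(d)
        fmt = [f["name"] for f in store.field_catalogue()
               if f["category"] == "sample" and f["name"] != "gt"]
        id_to_sample = {i: s for s, i in store.sample_ids().items()}
        self._genotypes: dict[int, dict] = {}
        for r in store.conn.execute("SELECT * FROM genotypes"):
            d = {"gt": r["gt"]}
            for name in fmt:
                d[name] = r["fmt_" + name]
            self._genotypes.setdefault(r["variant_id"], {})[
                id_to_sample[r["sample_id"]]
            ] = d
        self._wordsets: dict[str, frozenset] = {}

    def variant_rows(self, selection: str = "variants") -> list:
        if selection not in self._variants:
            self._variants[selection] = self._store.variant_rows(selection)
        return self._variants[selection]

    def annotations_for(self, vid: int) -> list:
        return self._annotations.get(vid, [])

    def genotype_map(self, vid: int) -> dict:
        return self._genotypes.get(vid, {})

    def wordset(self, name: str) -> frozenset:
        if name not in self._wordsets:
            self._wordsets[name] = self._store.wordset(name)
        return self._wordsets[name]


def brute_force_ids(source: str, filter_node, store) -> set:
    """Distinct variant ids of ``source`` matching ``filter_node`` with
    existential annotation semantics (oracle for CREATE ... WHERE)."""
    wordsets = store.wordset
    out = set()
    for variant in store.variant_rows(source):
        if filter_node is None:
            out.add(variant["id"])
            continue
        anns = store.annotations_for(variant["id"])
        gts = store.genotype_map(variant["id"])
        if any(
            evaluate_filter(filter_node, EvalContext(variant, a, gts, wordsets))
            for a in (anns or [None])
        ):
            out.add(variant["id"])
    return out


# ---------------------------------------------------------------------------
# trio transmission filters


def transmission_filter(mode: str, child: str, father: str, mother: str):
    """Mendelian transmission-mode filter as an ordinary filter tree.

    denovo: child carries the variant, both parents hom-ref;
    autosomal_recessive: child hom-alt, both parents het;
    dominant: child carries the variant and so does at least one parent.
    Unknown (-1) genotypes fail every clause.
    """

    def gt(sample):
        return FieldRef("gt", "sample", sample)

    if mode == "denovo":
        return Logical("AND", (
            Comparison(gt(child), "IN", (1, 2)),
            Comparison(gt(father), "=", 0),
            Comparison(gt(mother), "=", 0),
        ))
    if mode == "autosomal_recessive":
        return Logical("AND", (
            Comparison(gt(child), "=", 2),
            Comparison(gt(father), "=", 1),
            Comparison(gt(mother), "=", 1),
        ))
    if mode == "dominant":
        return Logical("AND", (
            Comparison(gt(child), "IN", (1, 2)),
            Logical("OR", (
                Comparison(gt(father), "IN", (1, 2)),
                Comparison(gt(mother), "IN", (1, 2)),
            )),
        ))
    raise ValueError(
        f"unknown transmission mode {mode!r}; expected one of "
        f"{TRANSMISSION_MODES}"
    )


def trio_select(store, mode: str, child: str, father: str, mother: str,
                source: str = "variants") -> QueryResult:
    """Run a transmission-mode filter, returning variant identity rows."""
    ast = SelectStmt(
        tuple(FieldRef(n) for n in ("chr", "pos", "ref", "alt")),
        source,
        transmission_filter(mode, child, father, mother),
    )
    checked = validate_ast(ast, store)
    plan = compile_select(checked, store)
    rows = execute_plan(plan, store)
    return QueryResult(plan.columns, rows)


# ---------------------------------------------------------------------------
# CSV export


def export_csv(rows, path, columns=None, delimiter: str = ",") -> int:
    """Write result rows as RFC 4180-style CSV (UTF-8, header line first).

    Missing values are rendered empty.  On failure the partial file is
    removed.  Returns the number of data rows written.
    """
    path = Path(path)
    count = 0
    try:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delimiter,
                                quoting=csv.QUOTE_MINIMAL)
            rows = iter(rows)
            first = next(rows, None)
            if columns is None:
                columns = list(first.keys()) if first is not None else []
            writer.writerow(columns)
            if first is not None:
                for row in _chain_one(first, rows):
                    writer.writerow(
                        ["" if row.get(c) is None else row.get(c)
                         for c in columns]
                    )
                    count += 1
    except Exception:
        if path.exists():
            os.unlink(path)
        raise
    return count


def _chain_one(first, rest):
    yield first
    yield from rest


# ---------------------------------------------------------------------------
# statement dispatch


def run_vql(store, text: str, base_dir=None) -> QueryResult:
    """Parse, validate and execute one VQL statement against ``store``.

    ``base_dir`` anchors relative file paths in INTERSECT / IMPORT WORDSET
    clauses (defaults to the current directory).
    """
    ast = parse_vql(text)
    checked = validate_ast(ast, store)
    base = Path(base_dir) if base_dir is not None else Path.cwd()

    if isinstance(checked, SelectStmt):
        plan = compile_select(checked, store)
        return QueryResult(plan.columns, execute_plan(plan, store))

    if isinstance(checked, CreateSelection):
        plan = compile_selection_ids(checked.source, checked.filter, store)
        ids = [row["id"] for row in execute_plan(plan, store)]
        if checked.bed_path is not None:
            bed_file = base / checked.bed_path
            with open(bed_file, "rt", encoding="utf-8") as fh:
                intervals = datastore.read_bed(fh)
            ids = store.filter_ids_by_bed(ids, intervals)
        selection = store.create_selection(
            checked.name, ids, provenance=serialize_ast(ast)
        )
        return QueryResult(
            [], [], f"selection {selection.name!r}: {len(selection.keys)} variants"
        )

    if isinstance(checked, CreateSetOp):
        selection = store.selection_set_op(
            checked.left, checked.right, checked.op, checked.name
        )
        return QueryResult(
            [], [], f"selection {selection.name!r}: {len(selection.keys)} variants"
        )

    if isinstance(checked, Drop):
        if checked.target == "selection":
            store.drop_selection(checked.name)
        else:
            store.drop_wordset(checked.name)
        return QueryResult([], [], f"dropped {checked.target} {checked.name!r}")

    if isinstance(checked, ImportWordset):
        with open(base / checked.path, "rt", encoding="utf-8") as fh:
            ws = store.create_wordset(checked.name, fh)
        return QueryResult(
            [], [], f"wordset {ws.name!r}: {len(ws.words)} words"
        )

    raise TypeError(f"unhandled statement {checked!r}")  # pragma: no cover
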