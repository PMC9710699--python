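import csv
import random

import pytest

from variantql import engine, fixtures
from variantql.engine import (
    EvalContext,
    StoreSnapshot,
    brute_force_select,
    evaluate_filter,
    execute_plan,
    export_csv,
    run_vql,
    transmission_filter,
    trio_select,
)
from variantql.vql import (
    Comparison,
    FieldRef,
    Not,
    ResolvedFieldRef,
    compile_select,
    parse_vql,
    serialize_ast,
    validate_ast,
)

from .conftest import build_store
from .test_model_io import MINI_HEADER


def _ann_ref(name):
    return ResolvedFieldRef(name, "ann", category="annotation",
                            column=f"ann_{name}", value_type="string")


def _core_ref(name, column=None, value_type="float"):
    return ResolvedFieldRef(name, category="core", column=column or name,
                            value_type=value_type)


class TestEvaluateFilter:
    def test_annotation_impact_match(self):
        ctx = EvalContext({"chrom": "7"}, {"impact": "HIGH"})
        node = Comparison(_ann_ref("impact"), "=", "HIGH")
        assert evaluate_filter(node, ctx) is True

    def test_qual_threshold(self):
        node = Comparison(_core_ref("qual"), ">=", 30)
        assert evaluate_filter(node, EvalContext({"qual": 29.0})) is False
        assert evaluate_filter(node, EvalContext({"qual": 30.0})) is True

    def test_regex_and_missing_rule(self):
        node = Comparison(_ann_ref("gene"), "~", "^CF")
        assert evaluate_filter(node, EvalContext({}, {"gene": "CFTR"}))
        assert not evaluate_filter(node, EvalContext({}, {"gene": None}))
        assert not evaluate_filter(node, EvalContext({}, None))

    def test_missing_comparisons_are_false_but_not_flips(self):
        leaf = Comparison(_ann_ref("gene"), "=", "CFTR")
        ctx = EvalContext({}, {"gene": None})
        assert evaluate_filter(leaf, ctx) is False
        assert evaluate_filter(Not(leaf), ctx) is True

    def test_is_null(self):
        ctx = EvalContext({"qual": None})
        assert evaluate_filter(Comparison(_core_ref("qual"), "IS NULL"), ctx)
        assert not evaluate_filter(
            Comparison(_core_ref("qual"), "IS NOT NULL"), ctx
        )

    def test_sample_gt(self):
        ref = ResolvedFieldRef("gt", "sample", "S1", category="sample",
                               column="gt", value_type="int")
        ctx = EvalContext({}, None, {"S1": {"gt": 2}})
        assert evaluate_filter(Comparison(ref, "IN", (1, 2)), ctx)
        assert not evaluate_filter(Comparison(ref, "=", 0), ctx)

    def test_wordset_membership(self):
        node = Comparison(_ann_ref("gene"), "IN WORDSET", "panel")
        ctx = EvalContext({}, {"gene": "CFTR"},
                          wordsets=lambda name: {"CFTR", "TP53"})
        assert evaluate_filter(node, ctx)


class TestExecutePlan:
    def _run(self, store, text):
        checked = validate_ast(parse_vql(text), store)
        return execute_plan(compile_select(checked, store), store)

    def test_no_filter_returns_all_of_source(self, cohort_store):
        rows = self._run(cohort_store, "SELECT chr, pos FROM variants")
        assert len(rows) == cohort_store.n_variants()

    def test_limit(self, cohort_store):
        rows = self._run(cohort_store, "SELECT chr FROM variants LIMIT 10")
        assert len(rows) == 10

    def test_order_by_pos_is_non_decreasing(self, cohort_store):
        rows = self._run(
            cohort_store, "SELECT pos FROM variants ORDER BY pos"
        )
        positions = [r["pos"] for r in rows]
        assert positions == sorted(positions)

    def test_existential_vs_row_mode_counts(self, cohort_store):
        distinct = self._run(
            cohort_store,
            "SELECT chr, pos, ref, alt FROM variants WHERE impact = 'HIGH'",
        )
        per_annotation = self._run(
            cohort_store,
            "SELECT chr, pos, ann.impact FROM variants WHERE impact = 'HIGH'",
        )
        assert len(per_annotation) >= len(distinct)
        assert all(r["ann.impact"] == "HIGH" for r in per_annotation)
        # distinct mode never repeats a variant key
        seen = [tuple(r.values()) for r in distinct]
        assert len(seen) == len(set(seen))

    def test_source_selection_restricts_rows(self, cohort_store):
        rows = self._run(cohort_store, "SELECT chr FROM oddsel")
        assert len(rows) == len(cohort_store.selection_variant_ids("oddsel"))

    def test_plan_matches_oracle_on_random_queries(self, cohort_store):
        rng = random.Random(17)
        snapshot = StoreSnapshot(cohort_store)
        for _ in range(30):
            ast = fixtures.random_select(
                rng, samples=("S01", "S02", "S03"),
                wordsets=("mygenes",), selections=("variants", "oddsel"),
            )
            checked = validate_ast(ast, cohort_store)
            plan = compile_select(checked, cohort_store)
            got = [tuple(r.values()) for r in execute_plan(plan, cohort_store)]
            want = [tuple(r.values())
                    for r in brute_force_select(checked, snapshot)]
            if ast.order_by or ast.limit is not None:
                assert got == want, serialize_ast(ast)
            else:
                assert sorted(map(repr, got)) == sorted(map(repr, want)), \
                    serialize_ast(ast)


class TestTransmissionFilter:
    @pytest.fixture()
    def trio_store(self, tmp_path):
        header = MINI_HEADER[:-1] + [
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT"
            "\tCHILD\tFATHER\tMOTHER"
        ]
        combos = [
            ("0/1", "0/0", "0/0"),  # denovo
            ("1/1", "0/1", "0/1"),  # recessive (also dominant)
            ("0/1", "0/1", "0/0"),  # dominant only
            ("0/1", "./.", "0/0"),  # unknown father
            ("0/0", "0/1", "0/1"),  # child ref
        ]
        lines = [
            f"1\t{100 + i}\t.\tA\tG\t50\tPASS\tDP=9\tGT:DP\t"
            + "\t".join(f"{gt}:5" for gt in gts)
            for i, (gts) in enumerate(combos)
        ]
        vcf = "\n".join(header + lines) + "\n"
        ped = ("F\tCHILD\tFATHER\tMOTHER\t1\t2\n"
               "F\tFATHER\t0\t0\t1\t1\nF\tMOTHER\t0\t0\t2\t1\n")
        return build_store(tmp_path, vcf, ped)[0]

    def _positions(self, store, mode):
        result = trio_select(store, mode, "CHILD", "FATHER", "MOTHER")
        return {r["pos"] for r in result.rows}

    def test_denovo(self, trio_store):
        assert self._positions(trio_store, "denovo") == {100}

    def test_recessive(self, trio_store):
        assert self._positions(trio_store, "autosomal_recessive") == {101}

    def test_dominant(self, trio_store):
        assert self._positions(trio_store, "dominant") == {101, 102}

    def test_unknown_genotype_fails_every_mode(self, trio_store):
        for mode in engine.TRANSMISSION_MODES:
            assert 103 not in self._positions(trio_store, mode)

    def test_child_ref_fails_every_mode(self, trio_store):
        for mode in engine.TRANSMISSION_MODES:
            assert 104 not in self._positions(trio_store, mode)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="unknown transmission mode"):
            transmission_filter("codominant", "a", "b", "c")

    def test_filter_is_plain_filter_node(self):
        node = transmission_filter("denovo", "C", "F", "M")
        ctx = EvalContext({}, None, {
            "C": {"gt": 1}, "F": {"gt": 0}, "M": {"gt": 0},
        })
        resolved = _resolve_gt_tree(node)
        assert evaluate_filter(resolved, ctx)


def _resolve_gt_tree(node):
    from variantql.vql import Logical

    if isinstance(node, Comparison):
        ref = node.field
        return Comparison(
            ResolvedFieldRef(ref.name, "sample", ref.sample,
                             category="sample", column="gt",
                             value_type="int"),
            node.op, node.value,
        )
    if isinstance(node, Logical):
        return Logical(node.op, tuple(_resolve_gt_tree(c)
                                      for c in node.children))
    return Not(_resolve_gt_tree(node.child))


class TestExportCsv:
    def test_header_plus_rows(self, tmp_path):
        rows = [{"a": 1, "b": "x"}, {"a": 2, "b": None}, {"a": 3, "b": "z"}]
        path = tmp_path / "out.csv"
        n = export_csv(rows, path, columns=["a", "b"])
        assert n == 3
        lines = path.read_text().splitlines()
        assert len(lines) == 4
        assert lines[0] == "a,b"
        assert lines[2] == "2,"  # missing rendered empty

    def test_delimiter_quoting(self, tmp_path):
        path = tmp_path / "out.csv"
        export_csv([{"v": "a,b"}], path, columns=["v"])
        assert path.read_text().splitlines()[1] == '"a,b"'

    def test_round_trip_with_csv_reader(self, tmp_path):
        rng = random.Random(5)
        rows = [
            {"s": rng.choice(['plain', 'with,comma', 'with"quote', 'nl\nin']),
             "n": rng.randint(-5, 5)}
            for _ in range(20)
        ]
        path = tmp_path / "rt.csv"
        export_csv(rows, path, columns=["s", "n"])
        with open(path, newline="", encoding="utf-8") as fh:
            parsed = list(csv.reader(fh))
        assert parsed[0] == ["s", "n"]
        assert parsed[1:] == [[r["s"], str(r["n"])] for r in rows]

    def test_failure_removes_partial_file(self, tmp_path):
        path = tmp_path / "fail.csv"

        def rows():
            yield {"a": 1}
            raise RuntimeError("boom")

        with pytest.raises(RuntimeError):
            export_csv(rows(), path, columns=["a"])
        assert not path.exists()


class TestRunVql:
    def test_select_returns_rows(self, cohort_store):
        result = run_vql(cohort_store, "SELECT chr, pos FROM variants LIMIT 3")
        assert result.columns == ["chr", "pos"] and len(result.rows) == 3

    def test_create_drop_cycle(self, fresh_cohort):
        store, _ = fresh_cohort
        run_vql(store, "CREATE damaging FROM variants WHERE impact = 'HIGH'")
        assert "damaging" in store.selection_names()
        ids = store.selection_variant_ids("damaging")
        assert ids == engine.brute_force_ids(
            "variants",
            validate_ast(
                parse_vql("SELECT chr FROM variants WHERE impact = 'HIGH'"),
                store,
            ).filter,
            store,
        )
        run_vql(store, "DROP SELECTION damaging")
        assert "damaging" not in store.selection_names()

    def test_create_setop(self, fresh_cohort):
        store, _ = fresh_cohort
        run_vql(store, "CREATE high FROM variants WHERE impact = 'HIGH'")
        run_vql(store, "CREATE mod FROM variants WHERE impact = 'MODERATE'")
        run_vql(store, "CREATE hm = high | mod")
        assert store.selection_variant_ids("hm") == (
            store.selection_variant_ids("high")
            | store.selection_variant_ids("mod")
        )

    def test_create_with_bed(self, fresh_cohort, tmp_path):
        store, _ = fresh_cohort
        rows = store.variant_rows()
        target = rows[0]
        bed = tmp_path / "roi.bed"
        bed.write_text(
            f"{target['chrom']}\t{target['pos'] - 1}\t{target['pos']}\n"
        )
        result = run_vql(store, f"CREATE roi FROM variants INTERSECT '{bed}'")
        assert store.selection_keys("roi") == {target["key"]}

    def test_import_wordset_statement(self, fresh_cohort, tmp_path):
        store, _ = fresh_cohort
        path = tmp_path / "panel.txt"
        path.write_text("CFTR\nTP53\n\nCFTR\n")
        result = run_vql(store, f"IMPORT WORDSET '{path}' AS panel")
        assert store.wordset("panel") == {"CFTR", "TP53"}
        run_vql(store, "DROP WORDSET panel")
        assert "panel" not in store.wordset_names()

    def test_wordset_filter_matches_python_membership(self, cohort_store):
        result = run_vql(
            cohort_store,
            "SELECT chr, pos, ann.gene FROM variants "
            "WHERE ann.gene IN WORDSET 'mygenes'",
        )
        words = cohort_store.wordset("mygenes")
        assert result.rows, "fixture should contain panel genes"
        assert all(r["ann.gene"] in words for r in result.rows)
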