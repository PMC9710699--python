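import random

import pytest
from hypothesis import given, strategies as st

from variantql import model_io
from variantql.model_io import (
    MalformedHeaderError,
    PedError,
    decompose_record,
    encode_genotype,
    parse_ped,
    parse_snpeff_ann,
    parse_vcf_header,
    parse_vep_csq,
)

from .helpers import brute_force_gt_code

MINI_HEADER = [
    "##fileformat=VCFv4.2",
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth">',
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">',
    '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations:'
    " 'Allele|Annotation|Annotation_Impact|Gene_Name'\">",
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tNA1\tNA2",
]


class TestParseVcfHeader:
    def test_info_descriptor_mapping(self):
        schema, warnings = parse_vcf_header(MINI_HEADER)
        dp = next(d for d in schema.descriptors
                  if d.name == "dp" and d.category == "info")
        assert (dp.value_type, dp.multiplicity) == ("int", "1")
        assert not warnings

    def test_ann_format_yields_normalized_descriptors(self):
        schema, _ = parse_vcf_header(MINI_HEADER)
        ann = [d.name for d in schema.descriptors if d.category == "annotation"]
        assert ann == ["allele", "consequence", "impact", "gene"]

    def test_core_fields_always_present(self):
        schema, _ = parse_vcf_header(MINI_HEADER)
        core = [d.name for d in schema.descriptors if d.category == "core"]
        assert core == ["chrom", "pos", "ref", "alt", "qual", "filter"]

    def test_samples_from_chrom_line(self):
        schema, _ = parse_vcf_header(MINI_HEADER)
        assert schema.samples == ["NA1", "NA2"]

    def test_no_ann_line_means_no_annotation_descriptors(self):
        lines = [MINI_HEADER[0], MINI_HEADER[1], MINI_HEADER[-1]]
        schema, _ = parse_vcf_header(lines)
        assert schema.annotation_descriptors() == []
        assert schema.annotation_source is None

    def test_missing_chrom_line_is_error(self):
        with pytest.raises(MalformedHeaderError):
            parse_vcf_header(MINI_HEADER[:-1])

    def test_unparseable_info_line_warns_and_skips(self):
        lines = [MINI_HEADER[0],
                 "##INFO=<ID=BROKEN,Number=1>",
                 MINI_HEADER[-1]]
        schema, warnings = parse_vcf_header(lines)
        assert warnings and "BROKEN" not in {
            d.name.upper() for d in schema.descriptors
        }

    def test_vep_csq_declaration(self):
        lines = [
            MINI_HEADER[0],
            '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence '
            'annotations from Ensembl VEP. Format: Allele|Consequence|IMPACT|'
            'SYMBOL|MOTIF">',
            MINI_HEADER[-1],
        ]
        schema, _ = parse_vcf_header(lines)
        assert schema.annotation_source == "CSQ"
        assert schema.annotation_fields == [
            "allele", "consequence", "impact", "gene", "motif"
        ]


class TestAnnotationParsers:
    FIELDS = ["allele", "consequence", "impact", "gene"]

    def test_single_snpeff_entry(self):
        records, warnings = parse_snpeff_ann(
            "G|missense_variant|MODERATE|CFTR", self.FIELDS
        )
        assert records == [{
            "allele": "G", "consequence": "missense_variant",
            "impact": "MODERATE", "gene": "CFTR",
        }]
        assert not warnings

    def test_comma_splits_entries(self):
        records, _ = parse_snpeff_ann("G|a|HIGH|X,T|b|LOW|Y", self.FIELDS)
        assert len(records) == 2
        assert records[1]["gene"] == "Y"

    def test_empty_position_is_missing(self):
        records, _ = parse_snpeff_ann("G||HIGH|X", self.FIELDS)
        assert records[0]["consequence"] is None

    def test_short_entry_padded_with_warning(self):
        records, warnings = parse_snpeff_ann("G|x", self.FIELDS)
        assert records[0]["impact"] is None and records[0]["gene"] is None
        assert warnings

    def test_vep_entry(self):
        records, _ = parse_vep_csq(
            "T|stop_gained|HIGH|CFTR", self.FIELDS
        )
        assert records == [{
            "allele": "T", "consequence": "stop_gained",
            "impact": "HIGH", "gene": "CFTR",
        }]

    def test_vep_extra_column_kept_under_normalized_name(self):
        fields = self.FIELDS + ["motif"]
        records, _ = parse_vep_csq("T|x|LOW|G1|MOT42", fields)
        assert records[0]["motif"] == "MOT42"


class TestEncodeGenotype:
    @pytest.mark.parametrize("gt,expected", [
        ("0/1", 1), ("1|1", 2), ("0/0", 0), ("./.", -1), ("./1", -1),
        ("1", 2), ("0", 0), ("1/2", 1), ("2/2", 0), ("garbage", -1),
    ])
    def test_examples(self, gt, expected):
        assert encode_genotype(gt) == expected

    def test_alt_index_two(self):
        assert encode_genotype("1/2", alt_index=2) == 1
        assert encode_genotype("2/2", alt_index=2) == 2

    def test_randomized_against_allele_count_oracle(self):
        rng = random.Random(42)
        for _ in range(1000):
            ploidy = rng.choice((1, 2, 2, 2, 3))
            alleles = [
                rng.choice([".", "0", "1", "2", "3"]) for _ in range(ploidy)
            ]
            sep = rng.choice("/|")
            gt = sep.join(alleles)
            alt_index = rng.randint(1, 3)
            assert encode_genotype(gt, alt_index) == brute_force_gt_code(
                gt, alt_index
            )

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=2),
           st.booleans())
    def test_diploid_code_is_allele_count(self, alleles, phased):
        sep = "|" if phased else "/"
        gt = sep.join(map(str, alleles))
        assert encode_genotype(gt, 1) == sum(1 for a in alleles if a == 1)


class TestDecomposeRecord:
    @pytest.fixture()
    def schema(self):
        return parse_vcf_header(MINI_HEADER)[0]

    def line(self, alt, info, gts):
        cols = ["1", "100", ".", "A", alt, "50", "PASS", info, "GT:DP"]
        cols += gts
        return "\t".join(cols)

    def test_het_for_both_alts(self, schema):
        out, _ = decompose_record(
            self.line("G,T", "DP=10", ["1/2:9", "0/0:8"]), schema
        )
        assert [d.variant.alt for d in out] == ["G", "T"]
        assert [d.genotypes[0].gt for d in out] == [1, 1]
        assert [d.genotypes[1].gt for d in out] == [0, 0]

    def test_hom_second_alt(self, schema):
        out, _ = decompose_record(
            self.line("G,T", "DP=10", ["2/2:9", "0/1:8"]), schema
        )
        assert [d.genotypes[0].gt for d in out] == [0, 2]
        assert [d.genotypes[1].gt for d in out] == [1, 0]

    def test_missing_allele_gives_unknown_everywhere(self, schema):
        out, _ = decompose_record(
            self.line("G", "DP=10", ["./1:9", "0/0:8"]), schema
        )
        assert out[0].genotypes[0].gt == -1

    def test_no_alt_skipped_with_warning(self, schema):
        out, warnings = decompose_record(
            self.line(".", "DP=10", ["0/0:9", "0/0:8"]), schema
        )
        assert out == [] and warnings

    def test_number_a_info_sliced_per_alt(self, schema):
        out, _ = decompose_record(
            self.line("G,T", "DP=10;AF=0.25,0.5", ["0/1:9", "0/0:8"]), schema
        )
        assert out[0].variant.info["af"] == 0.25
        assert out[1].variant.info["af"] == 0.5

    def test_annotation_matched_by_allele(self, schema):
        out, warnings = decompose_record(
            self.line("G,T", "DP=1;ANN=G|mis|MODERATE|X,T|stop|HIGH|Y",
                      ["0/1:9", "0/0:8"]),
            schema,
        )
        assert [a.fields["gene"] for a in out[0].annotations] == ["X"]
        assert [a.fields["gene"] for a in out[1].annotations] == ["Y"]
        assert not warnings

    def test_unmatched_allele_attaches_to_all_with_warning(self, schema):
        out, warnings = decompose_record(
            self.line("G,T", "DP=1;ANN=C|mis|MODERATE|X", ["0/1:9", "0/0:8"]),
            schema,
        )
        assert all(len(d.annotations) == 1 for d in out)
        assert warnings

    def test_format_fields_typed(self, schema):
        out, _ = decompose_record(
            self.line("G", "DP=10", ["0/1:9", "0/0:."]), schema
        )
        assert out[0].genotypes[0].fields["dp"] == 9
        assert out[0].genotypes[1].fields["dp"] is None


class TestParsePed:
    def test_founder(self):
        entries = parse_ped(["FAM1 NA1223 0 0 1 2"])
        e = entries[0]
        assert (e.family, e.individual, e.father, e.mother, e.sex,
                e.phenotype) == ("FAM1", "NA1223", None, None, 1, 2)

    def test_child_with_parents(self):
        e = parse_ped(["FAM1 KID DAD MOM 2 2"])[0]
        assert (e.father, e.mother, e.sex, e.phenotype) == ("DAD", "MOM", 2, 2)

    def test_five_columns_is_error(self):
        with pytest.raises(PedError, match="line 1"):
            parse_ped(["FAM1 X 0 0 1"])

    def test_duplicate_individual_is_error(self):
        with pytest.raises(PedError, match="duplicate"):
            parse_ped(["F A 0 0 1 1", "F A 0 0 1 2"])

    def test_phenotype_minus_nine_is_unknown(self):
        assert parse_ped(["F A 0 0 1 -9"])[0].phenotype == 0

    def test_dangling_parent_is_warning_not_error(self):
        entries = parse_ped(["F KID DAD 0 1 2"])
        warnings = model_io.pedigree_warnings(entries)
        assert warnings and "DAD" in warnings[0]


class TestImportVcf:
    VCF = "\n".join(MINI_HEADER + [
        "1\t100\t.\tA\tG\t50\tPASS\tDP=10\tGT:DP\t0/1:9\t0/0:8",
        "1\t200\t.\tC\tT\t60\tPASS\tDP=20\tGT:DP\t1/1:9\t0/1:8",
        "2\t300\t.\tG\tA,C\t70\tPASS\tDP=30\tGT:DP\t1/2:9\t0/0:8",
    ]) + "\n"

    def test_decomposition_arithmetic(self, tmp_path):
        from .conftest import build_store

        store, report = build_store(tmp_path, self.VCF)
        assert report.n_vcf_records == 3
        assert report.n_variants == 4
        assert report.n_genotypes == 8
        assert report.n_samples == 2

    def test_conservation_of_alt_counts(self, tmp_path):
        from .conftest import build_store

        store, report = build_store(tmp_path, self.VCF)
        alt_counts = [1, 1, 2]
        assert report.n_variants == sum(alt_counts)
        assert store.n_variants() == report.n_variants

    def test_ped_drives_case_aggregates(self, tmp_path):
        from .conftest import build_store

        ped = "F\tNA1\t0\t0\t1\t2\nF\tNA2\t0\t0\t2\t1\n"
        store, report = build_store(tmp_path, self.VCF, ped)
        # brute-force recount from the genotype table
        for row in store.variant_rows():
            gts = store.genotype_map(row["id"])
            assert row["case_count_hom"] == (gts["NA1"]["gt"] == 2)
            assert row["control_count_hom"] == (gts["NA2"]["gt"] == 2)
            assert row["count_var"] == sum(
                1 for g in gts.values() if g["gt"] in (1, 2)
            )

    def test_zero_sample_vcf(self, tmp_path):
        header = MINI_HEADER[:-1] + [
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        ]
        vcf = "\n".join(header + ["1\t100\t.\tA\tG\t50\tPASS\tDP=10"]) + "\n"
        from .conftest import build_store

        store, report = build_store(tmp_path, vcf)
        assert report.n_genotypes == 0 and report.n_variants == 1

    def test_annotation_referential_integrity(self, cohort_store):
        known = set(cohort_store.all_variant_ids())
        for r in cohort_store.conn.execute("SELECT variant_id FROM annotations"):
            assert r["variant_id"] in known

    def test_reimport_is_deterministic(self, tmp_path):
        from .conftest import build_store

        ped = "F\tNA1\t0\t0\t1\t2\nF\tNA2\t0\t0\t2\t1\n"
        store1, _ = build_store(tmp_path / "a", self.VCF, ped)
        store2, _ = build_store(tmp_path / "b", self.VCF, ped)
        dump1 = list(store1.conn.iterdump())
        dump2 = list(store2.conn.iterdump())
        assert dump1 == dump2

    def test_malformed_header_aborts_with_empty_store(self, tmp_path):
        bad = tmp_path / "bad.vcf"
        bad.write_text("not a vcf\n1\t100\t.\tA\tG\t.\t.\tDP=1\n")
        from variantql import datastore

        store = datastore.VariantStore(":memory:")
        with pytest.raises(MalformedHeaderError):
            model_io.import_vcf(bad, store)
        assert not store.is_initialized

    def test_ped_individual_missing_from_vcf_warns(self, tmp_path):
        from .conftest import build_store

        ped = "F\tNA1\t0\t0\t1\t2\nF\tGHOST\t0\t0\t1\t1\n"
        store, report = build_store(tmp_path, self.VCF, ped)
        assert any("GHOST" in w for w in report.warnings)
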