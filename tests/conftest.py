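import pathlib

import pytest

from variantql import datastore, fixtures, model_io


def build_store(tmp_dir, vcf_text, ped_text=None, **store_kwargs):
    """Write fixture text to disk and import it into a fresh in-memory store."""
    tmp_dir = pathlib.Path(tmp_dir)
    tmp_dir.mkdir(parents=True, exist_ok=True)
    vcf_path = tmp_dir / "input.vcf"
    vcf_path.write_text(vcf_text)
    ped_path = None
    if ped_text is not None:
        ped_path = tmp_dir / "input.ped"
        ped_path.write_text(ped_text)
    store = datastore.VariantStore(":memory:", **store_kwargs)
    report = model_io.import_vcf(vcf_path, store, ped_path=ped_path)
    return store, report


@pytest.fixture(scope="session")
def snpsift_case(tmp_path_factory):
    """(store, report, expected_key) for the 17-sample cohort example."""
    vcf, ped, key = fixtures.generate_snpsift_case()
    store, report = build_store(
        tmp_path_factory.mktemp("snpsift"), vcf, ped
    )
    return store, report, key


@pytest.fixture(scope="session")
def cohort_store(tmp_path_factory):
    """A 300-variant, 6-sample store with a wordset and a subselection."""
    spec = fixtures.CohortSpec(
        n_variants=300, n_samples=6, n_cases=2,
        multiallelic_fraction=0.25, missing_rate=0.1, seed=5,
    )
    vcf, ped = fixtures.generate_cohort(spec)
    store, report = build_store(tmp_path_factory.mktemp("cohort"), vcf, ped)
    store.create_wordset("mygenes", ["CFTR", "BRCA1", "TP53"])
    ids = store.all_variant_ids()
    store.create_selection("oddsel", ids[::3], "every third variant")
    return store


@pytest.fixture()
def fresh_cohort(tmp_path):
    spec = fixtures.CohortSpec(n_variants=60, n_samples=5, n_cases=2, seed=3)
    vcf, ped = fixtures.generate_cohort(spec)
    store, report = build_store(tmp_path, vcf, ped)
    return store, report
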