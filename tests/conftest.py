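import pytest

from cypstar.fixtures import (
    load_allele_table,
    load_assay_table,
    load_diplotype_phenotype_table,
    load_variant_annotations,
)


@pytest.fixture(scope="session")
def allele_table():
    return load_allele_table()


@pytest.fixture(scope="session")
def diplotype_rows():
    return load_diplotype_phenotype_table()


@pytest.fixture(scope="session")
def annotations():
    return load_variant_annotations()


@pytest.fixture(scope="session")
def assay_preps():
    return load_assay_table()
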