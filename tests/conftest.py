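import pytest

from fvimprint import call_snps, make_paper_fixture


@pytest.fixture(scope="session")
def fixture():
    """The packaged study fixture (fixed documented seed)."""
    return make_paper_fixture()


@pytest.fixture(scope="session")
def fixture_snps(fixture):
    """Pure SNP sites per fixture gene at default purity."""
    parent_a, parent_b = fixture.config.parents
    return {
        gene: call_snps(
            fixture.parent_reads[(gene, parent_a)],
            fixture.parent_reads[(gene, parent_b)],
        )
        for gene in fixture.gene_ids
    }
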