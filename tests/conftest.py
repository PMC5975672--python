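import pytest

from rarecnv.genome_model import CnvCall, GenomicInterval, MarkerGrid
from rarecnv.genic_impact import GeneModel
from rarecnv.io_report import load_curated_gene_sets, load_result_table


@pytest.fixture(scope="session")
def result_table():
    return load_result_table()


@pytest.fixture(scope="session")
def curated_sets():
    return load_curated_gene_sets()


@pytest.fixture
def toy_grid():
    # uniform 1 kb spacing on two chromosomes
    return MarkerGrid(
        positions={
            "1": list(range(1000, 1_000_001, 1000)),
            "2": list(range(1000, 1_000_001, 1000)),
        }
    )


@pytest.fixture
def toy_gene():
    # span 1:10_000-20_000 with three coding exons
    return GeneModel(
        symbol="TOY1",
        span=GenomicInterval("1", 10_000, 20_000),
        strand="+",
        coding_exons=(
            GenomicInterval("1", 11_000, 11_500),
            GenomicInterval("1", 14_000, 14_800),
            GenomicInterval("1", 18_000, 19_000),
        ),
    )


def make_call(chrom="1", start=100_000, end=200_000, cn=1, sample="P1", nm=100):
    return CnvCall(
        interval=GenomicInterval(chrom, start, end),
        copy_number=cn,
        sample_id=sample,
        n_markers=nm,
    )


@pytest.fixture
def call_factory():
    return make_call
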