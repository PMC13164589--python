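import numpy as np
import pytest

from karyodelim import datasets, io_tables


def make_complement(species_id: str) -> list[io_tables.ChromosomeRecord]:
    sat = datasets.SAT_PAIRS.get(species_id, ())
    return [
        io_tables.ChromosomeRecord(species_id, "mean", i, l, s, sat=i in sat)
        for i, l, s in datasets.CHROMOSOME_ARMS[species_id]
    ]


@pytest.fixture(scope="session")
def scardica_pairs():
    return make_complement(datasets.SCARDICA)


@pytest.fixture(scope="session")
def undulatifolia_pairs():
    return make_complement(datasets.UNDULATIFOLIA)


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)
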