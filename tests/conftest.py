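import numpy as np
import pytest

import denovolib as dl
from denovolib.core_io import AA_TO_CODONS, CodonUsageTable


@pytest.fixture(scope="session")
def k12_table():
    return dl.load_codon_table()


@pytest.fixture(scope="session")
def toy_table():
    """Codon table with hand-set Leu usage (CTG 0.5, CTC 0.25, TTA 0.25)
    for apportionment arithmetic; every other amino acid keeps one dominant
    codon so allocations are predictable."""
    freq = {}
    for aa, codons in AA_TO_CODONS.items():
        for i, c in enumerate(sorted(codons)):
            freq[c] = 10.0 if i == 0 else 1e-9
    freq.update({"CTG": 50.0, "CTC": 25.0, "TTA": 25.0})
    for c in AA_TO_CODONS["L"]:
        freq.setdefault(c, 1e-9)
        if c not in ("CTG", "CTC", "TTA"):
            freq[c] = 1e-9
    return CodonUsageTable(frequency=freq, taxon="toy")


@pytest.fixture(scope="session")
def candidate_pool():
    return dl.simulate_candidate_pool(120, seed=11)


@pytest.fixture(scope="session")
def small_libraries(candidate_pool):
    return dl.design_matched_library(candidate_pool, n=80, seed=11)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
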