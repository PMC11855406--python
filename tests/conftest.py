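import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # makes oracles importable

from cubkit.genetic_code import SENSE_CODONS, STOP_CODONS
from cubkit.metrics import CodonCounts
from cubkit.sequence_io import CdsRecord


def random_counts(rng: np.random.Generator, lam: float = 3.0) -> CodonCounts:
    """A random small codon-count vector (Poisson counts over sense codons,
    plus one terminal stop)."""
    counts = {c: int(rng.poisson(lam)) for c in SENSE_CODONS}
    counts[STOP_CODONS[int(rng.integers(0, 3))]] = 1
    return CodonCounts(scope_id="random", counts=counts)


def make_cds(internal_codons: list[str], gene_id: str = "g1",
             species_id: str = "sp1", stop: str = "TAA") -> CdsRecord:
    return CdsRecord(gene_id, species_id, "ATG" + "".join(internal_codons) + stop)


def valid_sequence(n_internal: int = 100, codon: str = "AAA", stop: str = "TAA") -> str:
    """A filter-passing CDS: ATG + n_internal sense codons + stop."""
    return "ATG" + codon * n_internal + stop


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20251001)


@pytest.fixture
def uniform_records():
    """A small uniform-regime synthetic gene set shared across tests."""
    from cubkit.synthetic import SyntheticSpec, generate

    records, truth = generate(SyntheticSpec(n_genes=20, length_range=(603, 903), seed=11))
    return records, truth
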