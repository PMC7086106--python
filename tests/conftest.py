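import numpy as np
import pytest

from matesys import generate_frequencies
from matesys.genotype_core import GenotypeTable, Locus


@pytest.fixture(scope="session")
def panel():
    """Default 10-locus low-polymorphism marker panel (deterministic)."""
    return generate_frequencies(rng=np.random.default_rng(12345))


@pytest.fixture
def biallelic_locus():
    return Locus("bi", ("1", "2"), np.array([0.6, 0.4]))


def make_table(loci, calls_by_individual):
    """Tiny helper: build a GenotypeTable from {id: [(a, b) | None, ...]}
    using allele *labels*."""
    ids = list(calls_by_individual)
    calls = np.full((len(ids), len(loci), 2), -1, dtype=np.int32)
    for r, ind in enumerate(ids):
        for li, g in enumerate(calls_by_individual[ind]):
            if g is None:
                continue
            loc = loci[li]
            calls[r, li] = [loc.allele_index(g[0]), loc.allele_index(g[1])]
    return GenotypeTable(ids, loci, calls)
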