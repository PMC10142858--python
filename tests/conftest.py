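import numpy as np
import pytest

from mitorec.alignment import Alignment
from mitorec.rho import build_two_locus_table, default_rho_grid

COMPLEMENT_SWAP = {"A": "C", "C": "G", "G": "T", "T": "A"}


def mutate_positions(seq: str, positions) -> str:
    """Deterministic single-base substitutions at the given positions."""
    s = list(seq)
    for p in positions:
        s[p] = COMPLEMENT_SWAP[s[p]]
    return "".join(s)


def random_sequence(length: int, seed: int) -> str:
    rng = np.random.default_rng(seed)
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


@pytest.fixture(scope="session")
def lookup_table_n15():
    """Small two-locus table shared by the rho unit tests."""
    grid = default_rho_grid(n_points=15, rho_min=0.01)
    return build_two_locus_table(n=15, rho_grid=grid, n_sims=1200, seed=11)


@pytest.fixture(scope="session")
def planted_mitotypes():
    """Four circular mitotypes: a major plus three candidates, each with a
    private divergent patch (30 substitutions spaced 30 bp)."""
    base = random_sequence(6000, seed=42)
    types = {
        "M": base,
        "C1": mutate_positions(base, range(1000, 1900, 30)),
        "C2": mutate_positions(base, range(3000, 3900, 30)),
        "C3": mutate_positions(base, range(4500, 5400, 30)),
    }
    aln = Alignment.from_sequences(list(types), list(types.values()), circular=True)
    return types, aln


@pytest.fixture(scope="session")
def planted_libraries(planted_mitotypes):
    from mitorec.heteroplasmy import build_kmer_library
    types, aln = planted_mitotypes
    libs = {}
    for x in types:
        for y in types:
            if x != y:
                libs[(x, y)] = build_kmer_library(aln, x, y, k=100, min_diff=2)
    return libs
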