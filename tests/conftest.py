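import itertools

import pytest

import enzscreen as ez
from enzscreen.mutants import MutantID, MutationLibrary


@pytest.fixture(scope="session")
def library() -> MutationLibrary:
    """The six-position combinatorial substitution library fixture."""
    return ez.load_fixture("library")


@pytest.fixture(scope="session")
def exclusions():
    return ez.load_fixture("exclusions")


@pytest.fixture(scope="session")
def set_s_records():
    """Benchmark activity records, wild-type reference row excluded."""
    return [r for r in ez.load_fixture("set_s") if r.mutant.upper() != "WT"]


@pytest.fixture(scope="session")
def set_l_top20():
    return ez.load_fixture("set_l_top20")


def brute_force_enumerate(library: MutationLibrary, max_order: int) -> list[MutantID]:
    """Independent oracle: expand every product of per-position choices."""
    out = []
    positions = library.positions
    for order in range(1, max_order + 1):
        for combo in itertools.combinations(positions, order):
            for muts in itertools.product(*(library.mutations_at(p) for p in combo)):
                out.append(MutantID(muts))
    return out
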