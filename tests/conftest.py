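import itertools

import pytest

from cooppool.assay_model import QuenchModel


def brute_force_min_cover(n: int, k: int, t: int = 2) -> int:
    """Exact minimum block count of a (n, k, t) covering design.

    Independent oracle: branch-and-bound over families of k-subsets with
    iterative deepening on the family size.  Each level covers the first
    still-uncovered t-subset with one of the blocks containing it.
    """
    universe = list(range(n))
    subsets = list(itertools.combinations(universe, t))
    blocks = [frozenset(b) for b in itertools.combinations(universe, k)]
    by_subset = {
        s: [b for b in blocks if b.issuperset(s)] for s in subsets
    }

    def covers(chosen: list, depth: int) -> bool:
        uncovered = next(
            (s for s in subsets if not any(b.issuperset(s) for b in chosen)), None
        )
        if uncovered is None:
            return True
        if depth == 0:
            return False
        for b in by_subset[uncovered]:
            if covers(chosen + [b], depth - 1):
                return True
        return False

    size = 1
    while not covers([], size):
        size += 1
    return size


@pytest.fixture
def noiseless_model() -> QuenchModel:
    return QuenchModel(readout_noise_sd=0.0)


@pytest.fixture
def membership_oracle():
    """Factory: oracle answering True iff any planted entity fits in the set."""

    def make(*entities):
        ents = [frozenset(e) for e in entities]
        return lambda s: any(s.issuperset(e) for e in ents)

    return make
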