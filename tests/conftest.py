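import numpy as np
import pytest

from esrtree.datamodel import AlleleCountMatrix, RunConfig, parse_tree

# Fixed once for the whole suite; every stochastic test derives its
# generator from this root so results are reproducible.
SUITE_SEED = 20260928


@pytest.fixture
def rng():
    return np.random.default_rng(SUITE_SEED)


@pytest.fixture(scope="session")
def three_pop_tree():
    return parse_tree("((P1,P2),P3);")


@pytest.fixture(scope="session")
def four_pop_tree():
    return parse_tree("((P1,P2),(P3,P4));")


@pytest.fixture(scope="session")
def two_pop_tree():
    return parse_tree("(P1,P2);")


def make_counts(y, n, system="A"):
    """Small AlleleCountMatrix from explicit arrays."""
    y = np.asarray(y)
    if np.isscalar(n):
        n = np.full_like(y, n)
    return AlleleCountMatrix(
        system=system,
        snp_ids=[f"s{j}" for j in range(y.shape[1])],
        y=y,
        n=np.asarray(n),
    )


def make_pair(y_a, y_x, n):
    return {"A": make_counts(y_a, n, "A"), "X": make_counts(y_x, n, "X")}


@pytest.fixture
def tiny_pair():
    """2 populations, 3 SNPs, n=10 genes: smallest non-trivial dataset."""
    y = np.array([[3, 10, 0], [5, 2, 9]])
    return make_pair(y, y[::-1], 10)


def quick_config(**kw):
    defaults = dict(
        n_pilot=2, pilot_length=25, burnin=50, chain_length=100, thin=10, seed=7
    )
    defaults.update(kw)
    return RunConfig(**defaults)
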