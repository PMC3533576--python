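"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from mitorder.gene_order import GeneOrder
from mitorder.mtio import fixture_order
from mitorder.synthetic_data import SimulationConfig, simulate_genome


@pytest.fixture(scope="session")
def gp():
    return fixture_order("ground_pattern")


@pytest.fixture(scope="session")
def gebiidea():
    return fixture_order("gebiidea")


@pytest.fixture(scope="session")
def axiidea():
    return fixture_order("axiidea")


@pytest.fixture(scope="session")
def truth_seed1():
    """One simulated genome from the ground pattern, seed 1."""
    return simulate_genome(SimulationConfig(seed=1))


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no imports from the code under
# test beyond the GeneOrder container itself)
# ---------------------------------------------------------------------------

def oracle_adjacencies(elements):
    """Normalized adjacency set of a signed circular order, by enumeration."""
    n = len(elements)
    pairs = set()
    for i in range(n):
        a, b = elements[i], elements[(i + 1) % n]
        flip = lambda s: "-" if s == "+" else "+"
        alt = ((b[0], flip(b[1])), (a[0], flip(a[1])))
        pairs.add(min((a, b), alt))
    return pairs


def oracle_breakpoints(order_elems, ref_elems):
    return len(oracle_adjacencies(order_elems) - oracle_adjacencies(ref_elems))


def oracle_circular_equal(a_elems, b_elems):
    """Equality of signed circular orders via their adjacency sets.

    For single-copy gene sets an order is uniquely reconstructed from its
    adjacency set, so set equality is order equality.
    """
    if len(a_elems) != len(b_elems):
        return False
    if len(a_elems) <= 1:
        return {g for g, _ in a_elems} == {g for g, _ in b_elems}
    return oracle_adjacencies(a_elems) == oracle_adjacencies(b_elems)


def oracle_min_deletion(order, reference, max_size=None):
    """Smallest deletion set size by exhaustive subset enumeration."""
    genes = sorted(g for g, _ in order.elements)
    limit = len(genes) if max_size is None else max_size
    for k in range(0, limit + 1):
        for combo in itertools.combinations(genes, k):
            removed = set(combo)
            kept_a = [e for e in order.elements if e[0] not in removed]
            kept_b = [e for e in reference.elements if e[0] not in removed]
            if oracle_circular_equal(kept_a, kept_b):
                return k
    raise AssertionError("no deletion set found")


def random_signed_order(rng: np.random.Generator, n: int) -> GeneOrder:
    genes = [f"g{i}" for i in range(n)]
    rng.shuffle(genes)
    return GeneOrder([(g, "+" if rng.random() < 0.5 else "-") for g in genes])


def scramble(rng: np.random.Generator, order: GeneOrder, n_moves: int) -> GeneOrder:
    """Derive a new order by a few random single-element moves/inversions."""
    elems = list(order.elements)
    n = len(elems)
    for _ in range(n_moves):
        op = rng.integers(0, 3)
        i = int(rng.integers(0, n))
        if op == 0:  # move one element
            e = elems.pop(i)
            j = int(rng.integers(0, n - 1))
            elems.insert(j, e)
        elif op == 1:  # invert one element
            g, s = elems[i]
            elems[i] = (g, "-" if s == "+" else "+")
        else:  # move + invert
            g, s = elems.pop(i)
            j = int(rng.integers(0, n - 1))
            elems.insert(j, (g, "-" if s == "+" else "+"))
    return GeneOrder(elems)
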