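"""Shared fixtures: toy sequences, energy models, random landscapes."""

from __future__ import annotations

import numpy as np
import pytest

from cotrafold import Landscape, Sequence, Structure, ToyEnergyModel, ViennaEnergyModel


@pytest.fixture
def hairpin_seq() -> Sequence:
    return Sequence("GGGAAACCC", "hairpin")


@pytest.fixture
def bistable_seq() -> Sequence:
    # two mutually exclusive helices
    return Sequence("GGGAAACCCAAAGGGAAACCC", "bistable-toy")


@pytest.fixture
def toy_model(hairpin_seq) -> ToyEnergyModel:
    return ToyEnergyModel(hairpin_seq)


@pytest.fixture
def vienna_model(hairpin_seq) -> ViennaEnergyModel:
    return ViennaEnergyModel(hairpin_seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20230413)


def random_landscape(
    rng: np.random.Generator,
    n_nodes: int,
    length: int = 30,
    occupied: bool = True,
) -> Landscape:
    """A random connected landscape with consistent saddles.

    Node identities are synthetic single-pair structures (the landscape
    algorithms only use energies, occupancies and adjacency).
    """
    nodes = [
        Structure(frozenset({(i + 1, length - i)}), length) for i in range(n_nodes)
    ]
    # continuous energies: exact ties would exercise the plateau
    # convention rather than the generic algorithm
    energies = rng.normal(0, 3, n_nodes)
    ls = Landscape(length)
    occ = rng.dirichlet(np.ones(n_nodes)) if occupied else np.zeros(n_nodes)
    if not occupied:
        occ[0] = 1.0
    for node, e, o in zip(nodes, energies, occ):
        ls.add_node(node, float(e), float(o))
    # random spanning tree keeps it connected, then extra edges
    order = rng.permutation(n_nodes)
    for idx in range(1, n_nodes):
        a, b = nodes[order[idx]], nodes[order[rng.integers(0, idx)]]
        barrier = float(rng.exponential(2.0))
        ls.add_edge(a, b, max(ls.energies[a], ls.energies[b]) + barrier)
    extra = rng.integers(0, n_nodes)
    for _ in range(extra):
        i, j = rng.integers(0, n_nodes, 2)
        if i == j:
            continue
        a, b = nodes[i], nodes[j]
        barrier = float(rng.exponential(2.0))
        ls.add_edge(a, b, max(ls.energies[a], ls.energies[b]) + barrier)
    return ls
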