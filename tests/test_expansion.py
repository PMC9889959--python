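"""Fraying constraints, guiding neighborhood, rates, and expansion steps."""

import itertools
import math

import numpy as np
import pytest

from cotrafold import (
    Sequence,
    Structure,
    ViennaEnergyModel,
    base_pair_distance,
    build_guide_graph,
    elementary_neighbors,
    enumerate_structures,
    expand,
    find_candidates,
    fraying_constraints,
    guide_edges_from_distances,
    parse_dotbracket,
    rate_from_saddle,
)
from cotrafold.energy_model import GAS_CONSTANT
from cotrafold.expansion import edge_key


class TestFrayingConstraints:
    def test_empty_parent_gives_trivial_constraint(self):
        seq = Sequence("GGGAAACCCA")
        parent = Structure(frozenset(), 10)
        assert fraying_constraints(seq, parent, mfree=6) == ["." * 10]

    def test_single_exterior_helix(self):
        seq = Sequence("GGGGGAAAACCCCCA")
        parent = parse_dotbracket("(((((....))))).")
        cs = fraying_constraints(seq, parent, mfree=6)
        # a single fraying helix: one constraint, fully opened
        assert cs == ["." * 15]

    def test_two_fraying_helices_give_three_constraints(self):
        seq = Sequence("GGGGAAAACCCCAAGGGGAAAACCCCA")
        parent = parse_dotbracket("((((....))))..((((....)))).")
        cs = fraying_constraints(seq, parent, mfree=6)
        assert len(cs) == 3  # each helix alone + both at once
        # opening helix 1 keeps helix 2 enforced with fixed loop
        assert "((((....))))" in cs[0].replace("x", ".") or "((((....))))" in cs[0]
        assert cs[0].count("(") + cs[1].count("(") == 8
        assert cs[2] == "." * 27

    def test_four_fraying_helices_give_five_constraints(self):
        seq = Sequence("GGGGAAAACCCC" * 4)
        parent = parse_dotbracket("((((....))))" * 4)
        cs = fraying_constraints(seq, parent, mfree=6)
        assert len(cs) == 5

    def test_kept_loops_are_locked(self):
        seq = Sequence("GGGGAAAACCCCAAGGGGAAAACCCCA")
        parent = parse_dotbracket("((((....))))..((((....)))).")
        cs = fraying_constraints(seq, parent, mfree=6)
        c = cs[0]
        kept_region = c[14:26]
        assert kept_region == "((((xxxx))))"

    def test_mfree_opens_enclosed_helix_too(self):
        # the exterior helix of 2 pairs liberates only 6 positions; with
        # mfree=7 the enclosed helix must fray as well
        seq = Sequence("GGAGGGGAAAACCCCACCAA")
        parent = parse_dotbracket("((.((((....)))).)).")
        cs = fraying_constraints(seq, parent.extended(20), mfree=7)
        assert cs == ["." * 20]

    def test_small_mfree_keeps_enclosed_helix(self):
        seq = Sequence("GGAGGGGAAAACCCCACCAA")
        parent = parse_dotbracket("((.((((....)))).)).")
        (c,) = fraying_constraints(seq, parent.extended(20), mfree=2)
        assert c.count("(") == 4  # inner helix kept


class TestFindCandidates:
    def test_mfe_parent_is_fixed_point(self):
        seq = Sequence("GGGGGAAAACCCCC")
        em = ViennaEnergyModel(seq)
        mfe, _ = em.mfe(14)
        cands = find_candidates(em, {mfe}, mfree=6, length=14)
        assert mfe in cands
        # no candidate is energetically worse than the trivial refolds allow
        for c in cands:
            assert em.free_energy(c) <= em.free_energy(mfe) + 0.011 or c == mfe

    def test_worse_refolds_are_discarded(self):
        seq = Sequence("GGGGGAAAACCCCCAAAA")
        em = ViennaEnergyModel(seq)
        parent, _ = em.mfe(18)
        cands = find_candidates(em, {parent}, mfree=6, length=18)
        for c in cands:
            assert em.free_energy(c) <= em.free_energy(parent) + 0.011

    def test_unconstrained_mfe_always_included(self):
        seq = Sequence("GGGAAACCCAAAGGGAAACCC")
        em = ViennaEnergyModel(seq)
        trapped = parse_dotbracket("(((...)))............")
        cands = find_candidates(em, {trapped}, mfree=6, length=21)
        mfe, _ = em.mfe(21)
        assert mfe in cands and trapped in cands


class TestGuideGraph:
    def test_two_candidates_single_edge(self):
        x = parse_dotbracket("(((...)))")
        y = parse_dotbracket(".((...)).")
        guide, shortcut = guide_edges_from_distances([x, y])
        assert len(guide) == 1 and not shortcut

    def test_worked_three_structure_example(self):
        x = parse_dotbracket("..((...))")
        y = parse_dotbracket("..(....).")
        z = parse_dotbracket("(((...)))")
        guide, shortcut = guide_edges_from_distances([x, y, z])
        gset = {frozenset((a.dot_bracket(), b.dot_bracket())) for a, b in guide}
        assert gset == {
            frozenset((x.dot_bracket(), y.dot_bracket())),
            frozenset((y.dot_bracket(), z.dot_bracket())),
        }
        sset = {frozenset((a.dot_bracket(), b.dot_bracket())) for a, b in shortcut}
        assert sset == {frozenset((x.dot_bracket(), z.dot_bracket()))}

    def test_equal_distance_does_not_suppress_edge(self):
        # strictly-less criterion: a node at max{d} == d(x,y) must not kill
        # the edge
        a = Structure(frozenset({(1, 9)}), 9)
        b = Structure(frozenset({(2, 8)}), 9)
        mid = Structure(frozenset(), 9)  # d=1 to both; max(1,1) < 2 suppresses
        guide, _ = guide_edges_from_distances([a, b, mid])
        names = {frozenset((u.dot_bracket(), v.dot_bracket())) for u, v in guide}
        assert frozenset((a.dot_bracket(), b.dot_bracket())) not in names

    def test_full_ensemble_limit_equals_elementary_moves(self):
        rng = np.random.default_rng(77)
        for _ in range(5):
            seq = Sequence("".join(rng.choice(list("ACGU"), size=9)))
            space = enumerate_structures(seq)
            if len(space) < 3:
                continue
            guide, shortcut = guide_edges_from_distances(space)
            assert not shortcut
            expected = set()
            for s in space:
                for nb in elementary_neighbors(seq, s):
                    expected.add(frozenset((s.pairs, nb.pairs)))
            got = {frozenset((a.pairs, b.pairs)) for a, b in guide}
            assert got == expected

    def test_build_guide_graph_inserts_direct_path_mfe(self):
        seq = Sequence("GGGAAACCCAAAGGGAAACCC")
        em = ViennaEnergyModel(seq)
        x = parse_dotbracket("(((...)))............")
        y = parse_dotbracket("............(((...)))")
        guide, shortcut, cands = build_guide_graph(em, {x, y})
        both = parse_dotbracket("(((...)))...(((...)))")
        assert both in cands  # union-constrained MFE of the only edge


class TestRates:
    def test_zero_barrier_gives_k0(self):
        assert rate_from_saddle(-3.0, -3.0, 1e5, 310.15) == pytest.approx(1e5)

    def test_one_kcal_barrier(self):
        k = rate_from_saddle(0.0, 1.0, 1e5, 310.15)
        assert k == pytest.approx(1e5 * math.exp(-1.0 / (GAS_CONSTANT * 310.15)))

    def test_saddle_below_state_rejected(self):
        with pytest.raises(ValueError):
            rate_from_saddle(0.0, -0.5, 1e5, 310.15)

    def test_single_move_rates_reduce_to_metropolis(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            e_x, e_y = np.round(rng.normal(0, 3, 2), 2)
            saddle = max(e_x, e_y)
            k_xy = rate_from_saddle(e_x, saddle, 1e5, 310.15)
            metropolis = 1e5 * min(1.0, math.exp(-(e_y - e_x) / (GAS_CONSTANT * 310.15)))
            assert k_xy == pytest.approx(metropolis, rel=1e-12)

    def test_detailed_balance_ratio(self):
        e_x, e_y, saddle = -2.0, -3.5, 1.2
        RT = GAS_CONSTANT * 310.15
        k_xy = rate_from_saddle(e_x, saddle, 1e5, 310.15)
        k_yx = rate_from_saddle(e_y, saddle, 1e5, 310.15)
        assert k_xy / k_yx == pytest.approx(math.exp(-(e_y - e_x) / RT), rel=1e-12)


class TestExpand:
    def test_first_nucleotide(self):
        seq = Sequence("GGGAAACCC")
        em = ViennaEnergyModel(seq)
        ls = expand(em, {}, 1, delta=1.0)
        assert len(ls.energies) == 1
        (node,) = ls.energies
        assert node.pairs == frozenset()
        assert ls.occupancies[node] == 1.0
        assert not ls.edges

    def test_single_parent_hairpin_growth(self):
        seq = Sequence("GGGGGAAAACCCCC")
        em = ViennaEnergyModel(seq)
        parent = Structure(frozenset(), 13)
        ls = expand(em, {parent: 1.0}, 14, delta=1.0)
        mfe, _ = em.mfe(14)
        assert mfe in ls.energies
        assert abs(ls.total_occupancy() - 1.0) < 1e-12
        # reversible reaction between open chain and the folded state exists
        assert len(ls.edges) >= 1

    def test_landscape_strongly_connected(self):
        rng = np.random.default_rng(11)
        for _ in range(3):
            seq = Sequence("".join(rng.choice(list("ACGU"), size=30)))
            em = ViennaEnergyModel(seq)
            parent = Structure(frozenset(), 29)
            ls = expand(em, {parent: 1.0}, 30, delta=1.0)
            assert len(ls.connected_components()) == 1

    def test_edge_saddles_dominate_endpoints(self):
        seq = Sequence("GGGAAACCCAAAGGGAAACCC")
        em = ViennaEnergyModel(seq)
        x = parse_dotbracket("(((...)))...........")
        ls = expand(em, {x: 1.0}, 21, delta=1.0)
        for (a, b), s in ls.edges.items():
            assert s >= max(ls.energies[a], ls.energies[b]) - 1e-9

    def test_expansion_deterministic(self):
        seq = Sequence("GCGCGAAAACGCGCAAGGGCC")
        em1 = ViennaEnergyModel(seq)
        em2 = ViennaEnergyModel(seq)
        x, _ = em1.mfe(20)
        ls1 = expand(em1, {x: 1.0}, 21, delta=1.0)
        ls2 = expand(em2, {x: 1.0}, 21, delta=1.0)
        assert {n.pairs for n in ls1.energies} == {n.pairs for n in ls2.energies}
        assert {
            (a.pairs, b.pairs, s) for (a, b), s in ls1.edges.items()
        } == {(a.pairs, b.pairs, s) for (a, b), s in ls2.edges.items()}

    def test_reaction_cache_reused_across_steps(self):
        seq = Sequence("GGGGGAAAACCCCCAA")
        em = ViennaEnergyModel(seq)
        cache = {}
        parent = Structure(frozenset(), 14)
        ls1 = expand(em, {parent: 1.0}, 15, delta=1.0, reaction_cache=cache)
        n_before = len(cache)
        parents = {n: o for n, o in ls1.occupancies.items()}
        expand(em, parents, 16, delta=1.0, reaction_cache=cache)
        assert n_before > 0 and len(cache) >= n_before

    def test_caged_nucleotides_stay_unpaired(self):
        seq = Sequence("GGGGGAAAACCCCC")
        em = ViennaEnergyModel(seq)
        parent = Structure(frozenset(), 13)
        ls = expand(em, {parent: 1.0}, 14, delta=1.0, caged=4)
        for node in ls.energies:
            assert all(j <= 10 for _, j in node.pairs)


    def test_edge_list_dump_format(self):
        seq = Sequence("GGGGGAAAACCCCC")
        em = ViennaEnergyModel(seq)
        parent = Structure(frozenset(), 13)
        ls = expand(em, {parent: 1.0}, 14, delta=1.0)
        text = ls.edges_as_text()
        assert len(text.splitlines()) == len(ls.edges)
        first = text.splitlines()[0].split("\t")
        assert len(first) == 5 and len(first[0]) == 14
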