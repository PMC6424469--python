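import itertools

import numpy as np
import pytest

from multimotif.attractors import PreconditionError
from multimotif.motifs import (build_atlas, classify_motifs,
                               count_motif_instances, enumerate_pfls,
                               find_minimum_topologies, interattractor_stats,
                               zscore_overlay)
from multimotif.topology import Topology

from conftest import random_topology


def brute_force_cycles(topology):
    """Independent simple-cycle enumerator by DFS over node sequences."""
    nodes = topology.nodes
    sign = {(s, t): g for s, t, g in topology.regulations}
    cycles = set()
    for length in range(1, len(nodes) + 1):
        for seq in itertools.permutations(nodes, length):
            if min(seq) != seq[0]:
                continue  # fix rotation
            closed = all(
                (seq[i], seq[(i + 1) % length]) in sign for i in range(length))
            if closed:
                cycles.add(seq)
    return cycles


def positive_cycles(topology):
    sign = {(s, t): g for s, t, g in topology.regulations}
    out = set()
    for seq in brute_force_cycles(topology):
        n_neg = sum(sign[(seq[i], seq[(i + 1) % len(seq)])] < 0
                    for i in range(len(seq)))
        if n_neg % 2 == 0:
            out.add(seq)
    return out


class TestPFLEnumeration:
    def test_self_activation_is_pfl(self):
        t = Topology.from_edges(("A",), [("A", "A", 1)])
        pfls = enumerate_pfls(t)
        assert len(pfls) == 1 and len(pfls[0]) == 1

    def test_double_negative_loop_is_pfl(self):
        t = Topology.from_edges(("A", "B"), [("A", "B", -1), ("B", "A", -1)])
        pfls = enumerate_pfls(t)
        assert len(pfls) == 1 and pfls[0].n_negative == 2

    def test_odd_negative_three_cycle_is_not_pfl(self):
        t = Topology.from_edges(("A", "B", "C"),
                                [("A", "B", 1), ("B", "C", 1), ("C", "A", -1)])
        assert enumerate_pfls(t) == []

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(80):
            t = random_topology(rng)
            got = {l.cycle for l in enumerate_pfls(t)}
            assert got == positive_cycles(t)


class TestMotifClassification:
    def test_three_loops_at_one_node_is_type_i_only(self):
        t = Topology.from_edges(("A", "B", "C"), [
            ("A", "A", 1), ("A", "B", 1), ("B", "A", 1),
            ("A", "C", 1), ("C", "A", 1)])
        rep = classify_motifs(t)
        assert rep.type_i and not rep.type_ii

    def test_bridged_disjoint_loops_is_type_ii_only(self):
        t = Topology.from_edges(("A", "B"), [
            ("A", "A", 1), ("B", "B", 1), ("A", "B", -1), ("B", "A", -1)])
        rep = classify_motifs(t)
        assert rep.type_ii and not rep.type_i

    def test_matches_triple_oracle_on_random_topologies(self):
        rng = np.random.default_rng(31)
        for _ in range(60):
            t = random_topology(rng, p_edge=0.5)
            rep = classify_motifs(t)
            loops = [frozenset(c) for c in
                     ({l.cycle for l in enumerate_pfls(t)})]
            type_i = any(a & b & c
                         for a, b, c in itertools.combinations(loops, 3))
            type_ii = False
            for a, b, c in itertools.combinations(loops, 3):
                for x, y, z in ((a, b, c), (a, c, b), (b, c, a)):
                    if not (x & y) and (x & z) and (y & z):
                        type_ii = True
            assert rep.type_i == type_i
            assert rep.type_ii == type_ii

    def test_counts(self):
        t = Topology.from_edges(("A", "B", "C"), [
            ("A", "A", 1), ("A", "B", 1), ("B", "A", 1),
            ("A", "C", 1), ("C", "A", 1)])
        counts = count_motif_instances(t)
        assert counts["n_pfls"] == 3
        assert counts["type_i"] == 1  # exactly one qualifying triple
        assert counts["type_ii"] == 0
        assert counts["shared_node_tuples"][3] == 1
        assert counts["shared_node_tuples"][4] == 0

    def test_fewer_than_three_pfls_no_instances(self):
        t = Topology.from_edges(("A", "B"), [("A", "A", 1), ("B", "B", 1)])
        counts = count_motif_instances(t)
        assert counts["type_i"] == 0 and counts["type_ii"] == 0


class TestAtlas:
    def test_single_regulation_difference_is_edge(self):
        t1 = Topology.from_edges(("A", "B"), [("A", "B", 1)])
        t2 = Topology.from_edges(("A", "B"), [("A", "B", 1), ("B", "A", 1)])
        g = build_atlas([t1, t2])
        assert g.has_edge(t1.canonical_key(), t2.canonical_key())

    def test_sign_flip_is_not_an_edge(self):
        t1 = Topology.from_edges(("A", "B"), [("A", "B", 1)])
        t2 = Topology.from_edges(("A", "B"), [("A", "B", -1)])
        g = build_atlas([t1, t2])
        assert not g.has_edge(t1.canonical_key(), t2.canonical_key())

    def test_edges_match_pairwise_symmetric_difference(self):
        rng = np.random.default_rng(5)
        tops = []
        seen = set()
        while len(tops) < 25:
            t = random_topology(rng, p_edge=0.45)
            if t.n_regulations and t.canonical_key() not in seen:
                seen.add(t.canonical_key())
                tops.append(t)
        g = build_atlas(tops)
        for t1, t2 in itertools.combinations(tops, 2):
            expected = len(t1.regulations ^ t2.regulations) == 1
            assert g.has_edge(t1.canonical_key(), t2.canonical_key()) == expected

    def test_mixed_node_sets_rejected(self):
        t1 = Topology.from_edges(("A", "B"), [("A", "B", 1)])
        t2 = Topology.from_edges(("A", "C"), [("A", "C", 1)])
        with pytest.raises(ValueError, match="common node set"):
            build_atlas([t1, t2])


class TestMinimumTopologies:
    def test_constructed_capability_oracle(self):
        """With capability = 'edge set contains {e1, e2}', exactly the
        {e1, e2} topology is minimal."""
        e1, e2 = ("A", "B", 1), ("B", "A", -1)
        extra = ("A", "A", 1)
        required = {e1, e2}

        def oracle(t):
            return required <= set(t.regulations)

        capable = [Topology.from_edges(("A", "B"), [e1, e2]),
                   Topology.from_edges(("A", "B"), [e1, e2, extra])]
        minimal, undecided = find_minimum_topologies(oracle, capable)
        assert [set(t.regulations) for t in minimal] == [required]
        assert undecided == []

    def test_unknown_child_makes_parent_undecided(self):
        t = Topology.from_edges(("A", "B"), [("A", "B", 1), ("B", "A", 1)])
        minimal, undecided = find_minimum_topologies(lambda _t: None, [t])
        assert minimal == [] and undecided == [t]


class TestAttractorGeometry:
    def test_zscore_closed_form(self):
        z = zscore_overlay(np.array([1.0, 2.0, 3.0, 4.0]))
        expected = np.array([-1.3416407865, -0.4472135955,
                             0.4472135955, 1.3416407865])
        assert np.allclose(z, expected, atol=1e-9)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std() == pytest.approx(1.0, abs=1e-12)

    def test_zscore_affine_invariance(self):
        x = np.array([0.3, 1.1, 0.9, 2.5])
        assert np.allclose(zscore_overlay(x), zscore_overlay(3.7 * x + 11.0))

    def test_zscore_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_overlay(np.ones(4))

    def test_interattractor_equal_spacing(self):
        states = [np.array([float(i), float(i)]) for i in range(4)]
        stats = interattractor_stats(states)
        assert stats["min"] == pytest.approx(stats["max"])
        assert stats["sd"] == pytest.approx(0.0, abs=1e-12)

    def test_interattractor_hand_example(self):
        states = [np.array([0.0, 0.0]), np.array([1.0, 0.1]),
                  np.array([3.0, 0.2]), np.array([6.0, 0.3])]
        d = [np.linalg.norm(states[i + 1] - states[i]) for i in range(3)]
        stats = interattractor_stats(states)
        assert stats["min"] == pytest.approx(min(d))
        assert stats["max"] == pytest.approx(max(d))
        assert stats["sd"] == pytest.approx(np.std(d))

    def test_interattractor_unordered_rejected(self):
        states = [np.array([1.0, 1.0]), np.array([2.0, 3.0]),
                  np.array([3.0, 2.0]), np.array([4.0, 4.0])]
        with pytest.raises(PreconditionError):
            interattractor_stats(states)
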