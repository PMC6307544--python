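"""Mutation sampling, the four operators, and wiring constraints."""
import numpy as np
import pytest

from holosim import (Holobiont, NichePartition, NodeRef, RegulatoryNode,
                     build_random_network)
from holosim.mutation_ops import (MutationEvent, MutationPolicy,
                                  WiringConstraint, apply_mutation,
                                  check_wiring, sample_connection_partner,
                                  sample_mutations)

from conftest import small_holobiont

CONTROL = WiringConstraint("control")
OPEN = WiringConstraint("holobiont_nonspecialized")


def _holobiont(rng, pm=1, n=20, ns=4):
    host = build_random_network(n, 2, ns, rng, "H")
    microbes = [build_random_network(n, 2, ns, rng, f"M{j+1}")
                for j in range(pm)]
    return Holobiont(host, microbes)


class TestSampling:
    def test_zero_rates_give_no_events(self, rng):
        holo = _holobiont(rng)
        for _ in range(50):
            assert sample_mutations(holo, {"mu_host": 0, "mu_microbe": 0},
                                    rng) == []

    def test_mean_hit_count_matches_binomial(self, rng):
        # mu = 0.001, N = 50: expected 0.05 selected nodes per generation
        holo = Holobiont(build_random_network(50, 2, 12, rng))
        draws = 100_000
        total = sum(len(sample_mutations(holo, {"mu_host": 0.001}, rng))
                    for _ in range(draws))
        mean = total / draws
        se = np.sqrt(0.001 * 0.999 * 50 / draws)
        assert abs(mean - 0.05) < 3 * se

    def test_operator_classes_equally_likely(self, rng):
        holo = _holobiont(rng, pm=0)
        counts = {}
        n_events = 0
        while n_events < 10_000:
            for e in sample_mutations(holo, {"mu_host": 0.5}, rng):
                key = e.kind.replace("rewire_input", "rewire") \
                            .replace("rewire_output", "rewire")
                counts[key] = counts.get(key, 0) + 1
                n_events += 1
        for kind, c in counts.items():
            assert abs(c / n_events - 0.25) < 0.02, (kind, counts)

    def test_microbial_nodes_sampled_at_microbial_rate(self, rng):
        holo = _holobiont(rng, pm=1, n=50)
        host_hits = micro_hits = 0
        for _ in range(20_000):
            for e in sample_mutations(holo, {"mu_host": 0.001,
                                             "mu_microbe": 0.01}, rng):
                if e.target.network_id == "H":
                    host_hits += 1
                else:
                    micro_hits += 1
        ratio = micro_hits / host_hits
        assert 8 < ratio < 12.5   # ten to one, loosely


class TestPartnerSampling:
    def test_host_partner_uniform_over_networks(self, rng):
        holo = _holobiont(rng, pm=1)
        draws = [sample_connection_partner(holo, "H", OPEN, rng)
                 for _ in range(10_000)]
        frac_h = draws.count("H") / len(draws)
        assert abs(frac_h - 0.5) < 0.02

    def test_specialized_microbe_never_leaves_its_niche(self, rng):
        holo = _holobiont(rng, pm=4)
        part = NichePartition(((0, 1), (2, 3)), ((0,), (1,)))
        constraint = WiringConstraint("holobiont_specialized", part)
        for _ in range(10_000):
            partner = sample_connection_partner(holo, "M4", constraint, rng)
            assert partner in ("H", "M3", "M4")

    def test_no_microbes_always_returns_host(self, rng):
        holo = _holobiont(rng, pm=0)
        assert all(sample_connection_partner(holo, "H", OPEN, rng) == "H"
                   for _ in range(100))

    def test_control_scheme_stays_within_network(self, rng):
        holo = _holobiont(rng, pm=2)
        assert all(sample_connection_partner(holo, "M1", CONTROL, rng) == "M1"
                   for _ in range(100))

    def test_specialized_single_niche_matches_nonspecialized_support(self, rng):
        """One niche holding every microbe: the specialized partner rule
        degenerates to the non-specialized one."""
        holo = _holobiont(rng, pm=3)
        part = NichePartition(((0, 1, 2),), ((0,),))
        spec = WiringConstraint("holobiont_specialized", part)
        a = {sample_connection_partner(holo, "M2", spec, rng)
             for _ in range(2000)}
        b = {sample_connection_partner(holo, "M2", OPEN, rng)
             for _ in range(2000)}
        assert a == b == {"H", "M1", "M2", "M3"}


class TestApplyMutation:
    def test_add_input_doubles_table_preserving_zero_half(self, rng):
        holo = _holobiont(rng, pm=0, n=10)
        target = NodeRef("H", 3)
        before = holo.host.nodes[3]
        event = MutationEvent("add_connection", target, direction="in")
        assert apply_mutation(holo, event, rng, CONTROL)
        after = holo.host.nodes[3]
        assert after.k == before.k + 1
        assert after.truth_table.size == 2 * before.truth_table.size
        # the new regulator is the most significant bit; its 0 half is
        # the original table
        assert np.array_equal(after.truth_table[:before.truth_table.size],
                              before.truth_table)
        assert after.regulators[1:] == before.regulators

    def test_remove_then_readd_identity_regulator_leaves_constant(self, rng):
        # k=1 node with the identity table; removing the regulator keeps
        # the regulator=0 half -> table [0]; re-adding a regulator with a
        # random new half can no longer recover the original dependence
        nodes = [RegulatoryNode((), np.array([0], dtype=np.uint8)),
                 RegulatoryNode((NodeRef("H", 0),),
                                np.array([0, 1], dtype=np.uint8))]
        from holosim import BooleanNetwork
        net = BooleanNetwork("H", nodes, [0], [0, 0])
        holo = Holobiont(net)
        event = MutationEvent("remove_connection", NodeRef("H", 1),
                              direction="in")
        assert apply_mutation(holo, event, rng, CONTROL)
        assert net.nodes[1].k == 0
        assert net.nodes[1].truth_table.tolist() == [0]
        event = MutationEvent("add_connection", NodeRef("H", 1),
                              direction="in")
        assert apply_mutation(holo, event, rng, CONTROL)
        assert net.nodes[1].k == 1
        assert net.nodes[1].truth_table[0] == 0  # old half preserved

    def test_flip_twice_restores_table(self):
        holo = small_holobiont(2)
        target = NodeRef("H", 0)
        before = holo.host.nodes[0].truth_table.copy()
        seq = np.random.default_rng(5)
        apply_mutation(holo, MutationEvent("flip_table_entry", target),
                       np.random.default_rng(77), OPEN)
        apply_mutation(holo, MutationEvent("flip_table_entry", target),
                       np.random.default_rng(77), OPEN)
        assert np.array_equal(holo.host.nodes[0].truth_table, before)

    def test_remove_from_input_free_node_is_noop(self, rng):
        from holosim import BooleanNetwork
        nodes = [RegulatoryNode((), np.array([1], dtype=np.uint8))]
        net = BooleanNetwork("H", nodes, [0], [1])
        holo = Holobiont(net)
        event = MutationEvent("remove_connection", NodeRef("H", 0),
                              direction="in")
        assert not apply_mutation(holo, event, rng, CONTROL)
        assert net.mutation_count == 0

    def test_rewire_output_without_outputs_is_noop(self, rng):
        from holosim import BooleanNetwork
        nodes = [RegulatoryNode((), np.array([1], dtype=np.uint8)),
                 RegulatoryNode((NodeRef("H", 1),),
                                np.array([0, 1], dtype=np.uint8))]
        net = BooleanNetwork("H", nodes, [0], [1, 0])   # node 0 feeds nobody
        holo = Holobiont(net)
        event = MutationEvent("rewire_output", NodeRef("H", 0),
                              direction="out")
        assert not apply_mutation(holo, event, rng, CONTROL)

    def test_in_degree_cap_blocks_and_does_not_count(self, rng):
        holo = _holobiont(rng, pm=0, n=10)
        policy = MutationPolicy(k_max=2)
        omega = holo.host.mutation_count
        event = MutationEvent("add_connection", NodeRef("H", 0),
                              direction="in")
        assert not apply_mutation(holo, event, rng, CONTROL, policy)
        assert holo.host.mutation_count == omega

    def test_malformed_event_rejected(self, rng):
        holo = _holobiont(rng, pm=0)
        with pytest.raises(ValueError):
            apply_mutation(holo, MutationEvent("shuffle", NodeRef("H", 0)),
                           rng, CONTROL)


class TestLongRunInvariants:
    def test_invariants_hold_after_ten_thousand_mutations(self):
        """Truth-table lengths, regulator distinctness, the niche wiring
        constraint and the mutation counters all survive a long random
        mutation bombardment."""
        rng = np.random.default_rng(42)
        host = build_random_network(20, 2, 5, rng, "H")
        microbes = [build_random_network(15, 2, 4, rng, f"M{j+1}")
                    for j in range(4)]
        part = NichePartition(((0, 1), (2, 3)), ((0,), (1,)))
        holo = Holobiont(host, microbes, niche_partition=part)
        constraint = WiringConstraint("holobiont_specialized", part)
        policy = MutationPolicy()
        applied = 0
        proposed = 0
        while proposed < 10_000:
            events = sample_mutations(holo, {"mu_host": 0.4,
                                             "mu_microbe": 0.4}, rng)
            proposed += len(events)
            for event in events:
                applied += apply_mutation(holo, event, rng, constraint, policy)
        for net in holo.networks():
            for node in net.nodes:
                assert node.truth_table.size == 2 ** node.k
                assert len(set(node.regulators)) == node.k
                assert node.k <= policy.k_max
        check_wiring(holo, constraint)
        assert sum(net.mutation_count for net in holo.networks()) == applied
        assert applied > 0.8 * proposed

    def test_applied_event_ratio_tracks_rate_ratio(self, rng):
        """With rates (mu, 10 mu) and equal network sizes, applied
        microbial events outnumber host events roughly tenfold."""
        holo = _holobiont(rng, pm=1, n=50, ns=12)
        counts = {"H": 0, "M1": 0}
        for _ in range(30_000):
            for e in sample_mutations(holo, {"mu_host": 0.002,
                                             "mu_microbe": 0.02}, rng):
                if apply_mutation(holo, e, rng, OPEN):
                    counts[e.target.network_id] += 1
        ratio = counts["M1"] / counts["H"]
        assert 8 <= ratio <= 12.5
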