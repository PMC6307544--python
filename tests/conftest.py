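"""Shared fixtures and an independent brute-force dynamics oracle.

The oracle (`naive_step` / `transition_table`) re-implements the
synchronous update rule directly from the node data structures —
dictionary-based, one node at a time — and never touches the packed
arrays or the compiled kernel, so it can serve as an independent
reference for the fast paths.
"""
from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from holosim import (BooleanNetwork, EvolutionConfig, Holobiont, NodeRef,
                     RegulatoryNode, build_random_network)
from holosim.mutation_ops import (MutationPolicy, WiringConstraint,
                                  apply_mutation, sample_mutations)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


# -- independent oracle ------------------------------------------------

def naive_step(holobiont: Holobiont, state: dict) -> dict:
    """One synchronous update computed node by node from first principles.

    ``state`` maps network_id -> list of 0/1.  The first-listed
    regulator is read as the most significant bit of the truth-table
    index; regulator-free nodes keep their value.
    """
    nxt = {}
    for net in holobiont.networks():
        out = []
        for node in net.nodes:
            if node.k == 0:
                out.append(state[net.network_id][len(out)])
                continue
            index = 0
            for ref in node.regulators:
                index = 2 * index + int(state[ref.network_id][ref.node_index])
            out.append(int(node.truth_table[index]))
        nxt[net.network_id] = out
    return nxt


def naive_trajectory(holobiont: Holobiont, state0: dict, t_max: int) -> list[dict]:
    states = [state0]
    for _ in range(t_max):
        states.append(naive_step(holobiont, states[-1]))
    return states


def transition_table(holobiont: Holobiont) -> dict[tuple, tuple]:
    """Exhaustive state-transition map over all 2**n global states."""
    ids = holobiont.network_ids
    sizes = [holobiont.network(i).n for i in ids]
    n = sum(sizes)
    assert n <= 14, "exhaustive oracle is for small systems"
    table = {}
    for code in range(2 ** n):
        bits = [(code >> i) & 1 for i in range(n)]
        state, pos = {}, 0
        for nid, size in zip(ids, sizes):
            state[nid] = bits[pos:pos + size]
            pos += size
        nxt = naive_step(holobiont, state)
        flat = tuple(b for nid in ids for b in nxt[nid])
        table[tuple(bits)] = flat
    return table


def flat_state(holobiont: Holobiont, state: dict) -> np.ndarray:
    return np.concatenate([np.asarray(state[i], dtype=np.uint8)
                           for i in holobiont.network_ids])


# -- builders ----------------------------------------------------------

def small_holobiont(seed: int, n_host: int = 6, n_microbe: int = 4,
                    n_microbes: int = 1, n_signal: int = 2,
                    n_mutations: int = 8) -> Holobiont:
    """Small random holobiont with some cross-network edges introduced by
    running the actual mutation operators at a high rate."""
    rng = np.random.default_rng(seed)
    host = build_random_network(n_host, 2, n_signal, rng, "H")
    microbes = [build_random_network(n_microbe, 2, min(n_signal, n_microbe),
                                     rng, f"M{j + 1}")
                for j in range(n_microbes)]
    holo = Holobiont(host, microbes)
    constraint = WiringConstraint("holobiont_nonspecialized")
    policy = MutationPolicy(k_max=4)
    applied = 0
    while applied < n_mutations:
        events = sample_mutations(holo, {"mu_host": 0.5, "mu_microbe": 0.5}, rng)
        for event in events:
            applied += apply_mutation(holo, event, rng, constraint, policy)
    return holo


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def paper_network(rng):
    """Standard-size network: N=50, K=2, Ns=12."""
    return build_random_network(50, 2, 12, rng)


@pytest.fixture
def tiny_config():
    """Small, fast configuration for loop-level unit tests."""
    return EvolutionConfig(n_nodes=16, n_signal=4, population=20,
                           n_survivors=10, copies_per_survivor=1,
                           max_generations=20)
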