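"""Mutation operators on holobiont genotypes.

Per generation, every node of every network is independently selected
for mutation with probability ``mu`` (``mu_host`` for host nodes,
``mu_microbe`` for microbial nodes; microbial populations generate
mutants roughly ten times faster).  A selected node undergoes one of
four operator classes with equal probability:

* **rewire** one input or output connection (edge count conserved),
* **add** a new input or output connection,
* **remove** one input or output connection,
* **flip** one entry of its truth table.

New connections may reach across networks: a host node may wire to any
microbe, and a microbe to the host or — depending on the interaction
scheme — to other microbes (its own niche only, in the specialized
scheme).  Truth-table bookkeeping when the in-degree changes:

* a gained regulator becomes the new most significant bit; the old
  table is preserved on its 0 half and by default the new half is
  filled with fresh random bits (``add_policy="random_half"``), so a
  single add event can change the phenotype; ``"copy_half"``
  duplicates the old table instead, making the new edge initially
  neutral;
* a removed regulator restricts the table to its 0 half by default
  (``remove_policy="zero_half"``); ``"random_half"`` picks the half at
  random.

Proposals that would duplicate an edge are redrawn a bounded number of
times and then dropped; dropped proposals, like proposals blocked by
the in-degree cap ``k_max``, are no-ops and do not count as mutations.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .network_core import BooleanNetwork, Holobiont, NodeRef, RegulatoryNode
from .tasks_errors import NichePartition

Kind = Literal["rewire_input", "rewire_output", "add_connection",
               "remove_connection", "flip_table_entry"]

__all__ = [
    "MutationEvent",
    "WiringConstraint",
    "MutationPolicy",
    "sample_mutations",
    "sample_connection_partner",
    "apply_mutation",
    "check_wiring",
]

_CLASSES = ("rewire", "add_connection", "remove_connection", "flip_table_entry")


@dataclass
class MutationEvent:
    """One proposed mutation; ``partner``/``table_index`` are filled in
    when the event is applied, ``applied`` records whether it took effect."""

    kind: Kind
    target: NodeRef
    direction: Literal["in", "out"] | None = None
    partner: NodeRef | None = None
    table_index: int | None = None
    applied: bool = False


@dataclass(frozen=True)
class WiringConstraint:
    """Which networks a mutating network may wire to.

    * ``control``: no cross-network connections (standalone evolution).
    * ``holobiont_nonspecialized``: everyone may wire to everyone.
    * ``holobiont_specialized``: microbes wire only within their own
      niche or to the host; the host may wire to any network.
    """

    scheme: Literal["control", "holobiont_nonspecialized", "holobiont_specialized"]
    niche_partition: NichePartition | None = None

    def __post_init__(self):
        if self.scheme == "holobiont_specialized" and self.niche_partition is None:
            raise ValueError("specialized scheme requires a niche partition")


@dataclass(frozen=True)
class MutationPolicy:
    """Bookkeeping conventions for the operators.

    ``add_policy`` controls the table half created for a gained
    regulator: ``copy_half`` duplicates the existing table (the new
    edge starts out dynamically neutral and acquires an effect through
    later table flips), ``random_half`` fills it with fresh random
    bits (the new edge changes the phenotype immediately).

    ``rewire_policy`` controls what "rewire one output connection of a
    node" moves.  ``move_destination`` (default) re-points the chosen
    outgoing edge at a new downstream node, applying the removal policy
    at the old destination and the addition policy at the new one.
    ``move_source`` instead redraws the *source* of the edge, exactly
    mirroring input rewiring: the downstream node keeps its in-degree
    and truth table and simply reads a different node.
    """

    k_max: int = 10
    retries: int = 5
    remove_policy: Literal["zero_half", "random_half"] = "zero_half"
    add_policy: Literal["copy_half", "random_half"] = "random_half"
    rewire_policy: Literal["move_source", "move_destination"] = "move_destination"


def sample_mutations(holobiont: Holobiont, rates: dict[str, float],
                     rng: np.random.Generator) -> list[MutationEvent]:
    """Draw this generation's mutation proposals for one holobiont.

    ``rates`` maps ``"mu_host"``/``"mu_microbe"`` to per-node
    probabilities.  Each selected node gets one event whose class is
    uniform over the four operators; the rewire/add/remove direction
    (input vs output) is uniform as well.  Events are returned in node
    order, so the sequence is reproducible from the generator state.
    """
    mu_h = float(rates["mu_host"])
    mu_m = float(rates.get("mu_microbe", mu_h))
    if mu_h < 0 or mu_m < 0:
        raise ValueError("mutation rates must be non-negative")
    events: list[MutationEvent] = []
    for net in holobiont.networks():
        mu = mu_h if net.network_id == holobiont.host.network_id else mu_m
        if mu == 0.0:
            continue
        hits = np.nonzero(rng.random(net.n) < mu)[0]
        for i in hits:
            cls = _CLASSES[rng.integers(4)]
            direction = None
            if cls != "flip_table_entry":
                direction = "in" if rng.integers(2) == 0 else "out"
            kind = cls
            if cls == "rewire":
                kind = "rewire_input" if direction == "in" else "rewire_output"
            events.append(MutationEvent(kind=kind,
                                        target=NodeRef(net.network_id, int(i)),
                                        direction=direction))
    return events


def sample_connection_partner(holobiont: Holobiont, source_network: str,
                              constraint: WiringConstraint,
                              rng: np.random.Generator) -> str:
    """Network id with which ``source_network`` may form a new connection."""
    ids = holobiont.network_ids
    host_id = ids[0]
    if constraint.scheme == "control":
        return source_network
    if len(ids) == 1:
        return ids[0]
    if source_network == host_id or constraint.scheme == "holobiont_nonspecialized":
        choices = ids
    else:  # specialized microbe: host plus its own niche
        part = constraint.niche_partition
        j = ids.index(source_network) - 1
        niche = part.niches[part.niche_of_microbe(j)]
        choices = (host_id,) + tuple(ids[1 + m] for m in niche)
    return choices[rng.integers(len(choices))]


def _random_bits(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 2, size=n, dtype=np.uint8)


def _with_added_regulator(node: RegulatoryNode, source: NodeRef,
                          policy: MutationPolicy,
                          rng: np.random.Generator) -> RegulatoryNode:
    """Prepend ``source`` as the new most significant regulator; the old
    table occupies the source=0 half, the source=1 half per policy."""
    if policy.add_policy == "copy_half":
        new_half = node.truth_table
    else:
        new_half = _random_bits(rng, node.truth_table.size)
    table = np.concatenate([node.truth_table, new_half])
    return RegulatoryNode((source,) + node.regulators, table)


def _with_removed_regulator(node: RegulatoryNode, position: int,
                            policy: MutationPolicy,
                            rng: np.random.Generator) -> RegulatoryNode:
    """Drop the regulator at ``position``, restricting the truth table to
    the half where that regulator's value is fixed (0 by default)."""
    k = node.k
    bit = k - 1 - position
    keep_value = 0
    if policy.remove_policy == "random_half":
        keep_value = int(rng.integers(2))
    idx = np.arange(2 ** k)
    mask = ((idx >> bit) & 1) == keep_value
    regs = node.regulators[:position] + node.regulators[position + 1:]
    return RegulatoryNode(regs, node.truth_table[mask])


def _draw_partner_node(holobiont: Holobiont, source_network: str,
                       constraint: WiringConstraint,
                       rng: np.random.Generator) -> NodeRef:
    nid = sample_connection_partner(holobiont, source_network, constraint, rng)
    return NodeRef(nid, int(rng.integers(holobiont.network(nid).n)))


def apply_mutation(holobiont: Holobiont, event: MutationEvent,
                   rng: np.random.Generator,
                   constraint: WiringConstraint | None = None,
                   policy: MutationPolicy = MutationPolicy()) -> bool:
    """Apply one event in place; returns True when it took effect.

    Applied events increment the mutation counter of the network owning
    the *target* node (even when the truth-table bookkeeping happens in
    a downstream network).  No-ops (duplicate edge after retries, the
    in-degree cap, removing from an input-free node, rewiring a node
    with no outputs) leave the holobiont untouched and uncounted.
    """
    if constraint is None:
        constraint = WiringConstraint("control" if not holobiont.microbes
                                      else "holobiont_nonspecialized")
    target = event.target
    net = holobiont.network(target.network_id)
    node = net.nodes[target.node_index]
    applied = False

    if event.kind == "flip_table_entry":
        ti = int(rng.integers(node.truth_table.size))
        table = node.truth_table.copy()
        table[ti] ^= 1
        net.set_node(target.node_index, RegulatoryNode(node.regulators, table))
        event.table_index = ti
        applied = True

    elif event.kind == "rewire_input":
        if node.k > 0:
            pos = int(rng.integers(node.k))
            others = set(node.regulators) - {node.regulators[pos]}
            for _ in range(policy.retries):
                cand = _draw_partner_node(holobiont, target.network_id,
                                          constraint, rng)
                if cand not in others:
                    regs = node.regulators[:pos] + (cand,) + node.regulators[pos + 1:]
                    net.set_node(target.node_index,
                                 RegulatoryNode(regs, node.truth_table))
                    event.partner = cand
                    applied = True
                    break

    elif event.kind == "rewire_output":
        edges = holobiont.outgoing_edges(target)
        if edges and policy.rewire_policy == "move_source":
            dst, pos = edges[int(rng.integers(len(edges)))]
            dst_net = holobiont.network(dst.network_id)
            dst_node = dst_net.nodes[dst.node_index]
            others = set(dst_node.regulators) - {target}
            for _ in range(policy.retries):
                cand = _draw_partner_node(holobiont, dst.network_id,
                                          constraint, rng)
                if cand not in others:
                    regs = (dst_node.regulators[:pos] + (cand,)
                            + dst_node.regulators[pos + 1:])
                    dst_net.set_node(dst.node_index,
                                     RegulatoryNode(regs, dst_node.truth_table))
                    event.partner = cand
                    applied = True
                    break
        elif edges:
            old_dst, pos = edges[int(rng.integers(len(edges)))]
            for _ in range(policy.retries):
                cand = _draw_partner_node(holobiont, target.network_id,
                                          constraint, rng)
                new_net = holobiont.network(cand.network_id)
                new_node = new_net.nodes[cand.node_index]
                moving_to_same = cand == old_dst
                if not moving_to_same and target in new_node.regulators:
                    continue  # would duplicate an existing edge
                if not moving_to_same and new_node.k >= policy.k_max:
                    continue
                old_net = holobiont.network(old_dst.network_id)
                old_net.set_node(old_dst.node_index,
                                 _with_removed_regulator(
                                     old_net.nodes[old_dst.node_index], pos,
                                     policy, rng))
                new_node = new_net.nodes[cand.node_index]  # may be the same node
                new_net.set_node(cand.node_index,
                                 _with_added_regulator(new_node, target, policy, rng))
                event.partner = cand
                applied = True
                break

    elif event.kind == "add_connection":
        direction = event.direction or ("in" if rng.integers(2) == 0 else "out")
        event.direction = direction
        if direction == "in":
            if node.k < policy.k_max:
                for _ in range(policy.retries):
                    cand = _draw_partner_node(holobiont, target.network_id,
                                              constraint, rng)
                    if cand not in node.regulators:
                        net.set_node(target.node_index,
                                     _with_added_regulator(node, cand, policy, rng))
                        event.partner = cand
                        applied = True
                        break
        else:
            for _ in range(policy.retries):
                cand = _draw_partner_node(holobiont, target.network_id,
                                          constraint, rng)
                dst_net = holobiont.network(cand.network_id)
                dst_node = dst_net.nodes[cand.node_index]
                if target in dst_node.regulators or dst_node.k >= policy.k_max:
                    continue
                dst_net.set_node(cand.node_index,
                                 _with_added_regulator(dst_node, target, policy, rng))
                event.partner = cand
                applied = True
                break

    elif event.kind == "remove_connection":
        direction = event.direction or ("in" if rng.integers(2) == 0 else "out")
        event.direction = direction
        if direction == "in":
            if node.k > 0:
                pos = int(rng.integers(node.k))
                event.partner = node.regulators[pos]
                net.set_node(target.node_index,
                             _with_removed_regulator(node, pos, policy, rng))
                applied = True
        else:
            edges = holobiont.outgoing_edges(target)
            if edges:
                dst, pos = edges[int(rng.integers(len(edges)))]
                dst_net = holobiont.network(dst.network_id)
                dst_net.set_node(dst.node_index,
                                 _with_removed_regulator(
                                     dst_net.nodes[dst.node_index], pos,
                                     policy, rng))
                event.partner = dst
                applied = True

    else:
        raise ValueError(f"malformed mutation event kind {event.kind!r}")

    if applied:
        net.mutation_count += 1
        holobiont.invalidate()
    event.applied = applied
    return applied


def check_wiring(holobiont: Holobiont, constraint: WiringConstraint) -> None:
    """Assert that no edge violates the wiring constraint (raises ValueError)."""
    ids = holobiont.network_ids
    host_id = ids[0]
    for src, dst in holobiont.edges():
        if src.network_id == dst.network_id:
            continue
        if constraint.scheme == "control":
            raise ValueError(f"cross-network edge {src} -> {dst} under control scheme")
        if constraint.scheme == "holobiont_specialized":
            if src.network_id == host_id or dst.network_id == host_id:
                continue
            part = constraint.niche_partition
            a = part.niche_of_microbe(ids.index(src.network_id) - 1)
            b = part.niche_of_microbe(ids.index(dst.network_id) - 1)
            if a != b:
                raise ValueError(
                    f"microbe-microbe edge {src} -> {dst} crosses niches")
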