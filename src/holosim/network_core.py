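"""Boolean network genotypes and deterministic synchronous dynamics.

The genotype of one organism is a :class:`BooleanNetwork`: ``N`` binary
nodes, each with an ordered list of regulators and a truth table of
length ``2**k`` (first-listed regulator read as the most significant
bit of the table index).  A :class:`Holobiont` bundles one host network
with any number of microbial networks; regulators may point across
networks, so the whole holobiont is updated as a single synchronous
dynamical system.

Conventions (documented, serialized, and relied on by the tests):

* regulator order is significant: the first regulator is the most
  significant bit of the truth-table index;
* regulator-free nodes (``k = 0``) freeze at their current value;
* self-loops are allowed, duplicate (same ordered pair) edges are not;
* the initial condition is the state at ``t = 0``; the output signal is
  read on ``t = 1 .. t_max``.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, NamedTuple, Sequence

import numpy as np

from ._kernel import PackedSystem, simulate

HOST_ID = "H"

__all__ = [
    "HOST_ID",
    "NodeRef",
    "RegulatoryNode",
    "BooleanNetwork",
    "Holobiont",
    "StateTrajectory",
    "IntegrityError",
    "build_random_network",
    "synchronous_step",
    "run_trajectory",
    "output_signal",
]


class IntegrityError(Exception):
    """A regulator reference does not resolve inside the holobiont."""


_WEIGHT_ROWS: dict[int, np.ndarray] = {}


def _weight_row(k: int) -> np.ndarray:
    """Bit weights [2**(k-1), ..., 2, 1] (first regulator = MSB)."""
    row = _WEIGHT_ROWS.get(k)
    if row is None:
        row = _WEIGHT_ROWS[k] = (1 << np.arange(k - 1, -1, -1)).astype(np.int64)
    return row


class NodeRef(NamedTuple):
    """Reference to one node of one network within a holobiont."""

    network_id: str
    node_index: int


@dataclass(frozen=True)
class RegulatoryNode:
    """One node: ordered regulators plus a truth table of length 2**k.

    Instances are immutable; mutation operators build replacement nodes.
    This makes network copies O(1) per node (structural sharing), which
    the population loop depends on.
    """

    regulators: tuple[NodeRef, ...]
    truth_table: np.ndarray  # uint8 of length 2**k, treated as read-only

    def __post_init__(self):
        object.__setattr__(self, "regulators", tuple(self.regulators))
        table = np.ascontiguousarray(self.truth_table, dtype=np.uint8)
        object.__setattr__(self, "truth_table", table)
        if len(set(self.regulators)) != len(self.regulators):
            raise ValueError(f"duplicate regulators: {self.regulators}")
        if table.shape != (2 ** self.k,):
            raise ValueError(
                f"truth table has length {table.size}, expected {2 ** self.k}")

    @property
    def k(self) -> int:
        """In-degree of the node."""
        return len(self.regulators)


class BooleanNetwork:
    """One network genotype: nodes, signal nodes, initial condition.

    ``mutation_count`` is the number of applied mutations accumulated
    along this network's lineage (copies inherit it).
    """

    __slots__ = ("network_id", "nodes", "signal_indices", "initial_condition",
                 "mutation_count", "_block")

    def __init__(self, network_id: str, nodes: Sequence[RegulatoryNode],
                 signal_indices: Sequence[int], initial_condition,
                 mutation_count: int = 0):
        self.network_id = str(network_id)
        self.nodes: list[RegulatoryNode] = list(nodes)
        self.signal_indices = tuple(int(i) for i in signal_indices)
        self.initial_condition = np.ascontiguousarray(initial_condition,
                                                      dtype=np.uint8)
        self.mutation_count = int(mutation_count)
        self._block = None
        self._validate()

    def _validate(self) -> None:
        n = len(self.nodes)
        if len(set(self.signal_indices)) != len(self.signal_indices):
            raise ValueError("signal indices must be distinct")
        if any(not 0 <= s < n for s in self.signal_indices):
            raise ValueError("signal index out of range")
        if self.initial_condition.shape != (n,):
            raise ValueError("initial condition length must equal N")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def n_signal(self) -> int:
        return len(self.signal_indices)

    def set_node(self, index: int, node: RegulatoryNode) -> None:
        """Replace one node (used by mutation operators)."""
        self.nodes[index] = node
        self._block = None

    def copy(self) -> "BooleanNetwork":
        new = BooleanNetwork.__new__(BooleanNetwork)
        new.network_id = self.network_id
        new.nodes = list(self.nodes)          # nodes are immutable: share them
        new.signal_indices = self.signal_indices
        new.initial_condition = self.initial_condition
        new.mutation_count = self.mutation_count
        new._block = self._block
        return new

    def renamed(self, new_id: str) -> "BooleanNetwork":
        """Return a copy under a new id with internal references remapped."""
        old_id = self.network_id
        nodes = []
        for node in self.nodes:
            regs = tuple(NodeRef(new_id if r.network_id == old_id else r.network_id,
                                 r.node_index) for r in node.regulators)
            nodes.append(RegulatoryNode(regs, node.truth_table))
        return BooleanNetwork(new_id, nodes, self.signal_indices,
                              self.initial_condition, self.mutation_count)

    # -- packing ------------------------------------------------------

    def _packed_block(self, offsets: Mapping[str, int], sizes: Mapping[str, int]):
        """Per-network packed arrays with regulators as global indices."""
        if self._block is not None and self._block[0] is offsets:
            return self._block[1]
        n = self.n
        ks = np.fromiter((len(node.regulators) for node in self.nodes),
                         count=n, dtype=np.int64)
        kloc = max(1, int(ks.max())) if n else 1
        regs = np.zeros((n, kloc), dtype=np.int64)
        weights = np.zeros((n, kloc), dtype=np.int64)
        tlens = np.empty(n, dtype=np.int64)
        tables = []
        for i, node in enumerate(self.nodes):
            k = int(ks[i])
            tlens[i] = node.truth_table.size
            tables.append(node.truth_table)
            if k == 0:
                continue
            for p, ref in enumerate(node.regulators):
                try:
                    off = offsets[ref.network_id]
                except KeyError:
                    raise IntegrityError(f"dangling reference {ref!r}") from None
                if not 0 <= ref.node_index < sizes[ref.network_id]:
                    raise IntegrityError(f"dangling reference {ref!r}")
                regs[i, p] = off + ref.node_index
            weights[i, :k] = _weight_row(k)
        toff_local = np.concatenate(([0], np.cumsum(tlens)[:-1]))
        block = (regs, weights, ks, toff_local, np.concatenate(tables), ks == 0)
        self._block = (offsets, block)
        return block


class Holobiont:
    """One host plus its microbiota, evaluated as one dynamical system.

    ``silenced`` is a frozenset of network ids whose cross-boundary
    regulatory links are read as 0 during the dynamics (the reversible
    "freeze_zero" disconnection used in the dysbiosis experiments).
    """

    __slots__ = ("host", "microbes", "niche_partition", "lineage_id",
                 "silenced", "_offsets", "_sizes", "_packed", "_report")

    def __init__(self, host: BooleanNetwork, microbes: Sequence[BooleanNetwork] = (),
                 niche_partition=None, lineage_id: int = 0,
                 silenced: frozenset = frozenset(), _layout=None):
        self.host = host
        self.microbes: list[BooleanNetwork] = list(microbes)
        self.niche_partition = niche_partition
        self.lineage_id = lineage_id
        self.silenced = frozenset(silenced)
        if _layout is not None:
            self._offsets, self._sizes = _layout
        else:
            ids = [host.network_id] + [m.network_id for m in self.microbes]
            if len(set(ids)) != len(ids):
                raise ValueError("network ids within a holobiont must be distinct")
            sizes = {net.network_id: net.n for net in self.networks()}
            offsets, pos = {}, 0
            for net in self.networks():
                offsets[net.network_id] = pos
                pos += net.n
            self._offsets, self._sizes = offsets, sizes
        self._packed: dict[frozenset, PackedSystem] = {}
        self._report = None

    # -- structure ----------------------------------------------------

    def networks(self) -> Iterator[BooleanNetwork]:
        yield self.host
        yield from self.microbes

    @property
    def network_ids(self) -> tuple[str, ...]:
        return (self.host.network_id,) + tuple(m.network_id for m in self.microbes)

    @property
    def n_total(self) -> int:
        return sum(net.n for net in self.networks())

    def network(self, network_id: str) -> BooleanNetwork:
        for net in self.networks():
            if net.network_id == network_id:
                return net
        raise KeyError(network_id)

    def node(self, ref: NodeRef) -> RegulatoryNode:
        return self.network(ref.network_id).nodes[ref.node_index]

    def offset(self, network_id: str) -> int:
        return self._offsets[network_id]

    def outgoing_edges(self, ref: NodeRef) -> list[tuple[NodeRef, int]]:
        """All (downstream node, regulator position) pairs fed by ``ref``."""
        out = []
        for net in self.networks():
            nid = net.network_id
            for i, node in enumerate(net.nodes):
                for p, r in enumerate(node.regulators):
                    if r == ref:
                        out.append((NodeRef(nid, i), p))
        return out

    def edges(self) -> Iterator[tuple[NodeRef, NodeRef]]:
        """All regulatory edges as (source, destination) pairs."""
        for net in self.networks():
            nid = net.network_id
            for i, node in enumerate(net.nodes):
                for r in node.regulators:
                    yield r, NodeRef(nid, i)

    def copy(self, lineage_id: int | None = None) -> "Holobiont":
        new = Holobiont.__new__(Holobiont)
        new.host = self.host.copy()
        new.microbes = [m.copy() for m in self.microbes]
        new.niche_partition = self.niche_partition
        new.lineage_id = self.lineage_id if lineage_id is None else lineage_id
        new.silenced = self.silenced
        new._offsets, new._sizes = self._offsets, self._sizes
        new._packed = dict(self._packed)
        new._report = self._report
        return new

    def invalidate(self) -> None:
        """Drop caches after a structural change (mutation/disconnection)."""
        self._packed.clear()
        self._report = None

    # -- packing ------------------------------------------------------

    def packed(self, silenced: frozenset | None = None) -> PackedSystem:
        key = self.silenced if silenced is None else frozenset(silenced)
        cached = self._packed.get(key)
        if cached is not None:
            return cached
        if key:
            # derive from the unsilenced pack: same wiring and tables, but
            # regulator readings across the silenced boundary weighted 0
            base = self.packed(frozenset())
            in_s = np.zeros(base.n_total, dtype=bool)
            for nid, start, size in zip(base.network_ids, base.starts,
                                        base.sizes):
                if nid in key:
                    in_s[start:start + size] = True
            cross = in_s[:, None] != in_s[base.regs]
            packed = PackedSystem(regs=base.regs,
                                  weights=np.where(cross, 0, base.weights),
                                  ks=base.ks, toff=base.toff,
                                  tables=base.tables, frozen=base.frozen,
                                  starts=base.starts, sizes=base.sizes,
                                  network_ids=base.network_ids,
                                  signal_idx=base.signal_idx, silenced=key)
            self._packed[key] = packed
            return packed
        blocks = [net._packed_block(self._offsets, self._sizes)
                  for net in self.networks()]
        kmax = max(b[0].shape[1] for b in blocks)
        ids = self.network_ids
        sizes = np.array([net.n for net in self.networks()], dtype=np.int64)
        starts = np.concatenate(([0], np.cumsum(sizes)[:-1]))
        n_total = int(sizes.sum())
        table_total = sum(b[4].size for b in blocks)
        regs = np.zeros((n_total, kmax), dtype=np.int64)
        weights = np.zeros((n_total, kmax), dtype=np.int64)
        ks = np.empty(n_total, dtype=np.int64)
        toff = np.empty(n_total, dtype=np.int64)
        tables = np.empty(table_total, dtype=np.uint8)
        frozen = np.empty(n_total, dtype=bool)
        pos = table_base = 0
        for b_regs, b_weights, b_ks, b_toff, b_tables, b_frozen in blocks:
            n, kloc = b_regs.shape
            regs[pos:pos + n, :kloc] = b_regs
            weights[pos:pos + n, :kloc] = b_weights
            ks[pos:pos + n] = b_ks
            toff[pos:pos + n] = b_toff + table_base
            tables[table_base:table_base + b_tables.size] = b_tables
            frozen[pos:pos + n] = b_frozen
            pos += n
            table_base += b_tables.size
        signal_idx = tuple(
            np.asarray(net.signal_indices, dtype=np.int64) + start
            for net, start in zip(self.networks(), starts))
        packed = PackedSystem(regs=regs, weights=weights, ks=ks, toff=toff,
                              tables=tables, frozen=frozen,
                              starts=starts, sizes=sizes, network_ids=ids,
                              signal_idx=signal_idx, silenced=key)
        self._packed[key] = packed
        return packed


@dataclass(frozen=True)
class StateTrajectory:
    """Synchronous trajectory of a holobiont: rows are t = 0 .. t_max."""

    states: np.ndarray                 # (t_max + 1, n_total) uint8
    network_ids: tuple[str, ...]
    starts: np.ndarray
    sizes: np.ndarray

    @property
    def t_max(self) -> int:
        return self.states.shape[0] - 1

    def network_states(self, network_id: str) -> np.ndarray:
        """Trajectory slice of one network, shape (t_max + 1, N)."""
        i = self.network_ids.index(network_id)
        start = int(self.starts[i])
        return self.states[:, start:start + int(self.sizes[i])]


def build_random_network(n_nodes: int, in_degree: int, n_signal: int,
                         rng: np.random.Generator,
                         network_id: str = HOST_ID) -> BooleanNetwork:
    """Random Kauffman network: ``in_degree`` distinct regulators per node
    (self-loops allowed), uniform random truth tables, ``n_signal``
    signal nodes drawn without replacement, uniform random initial state.
    """
    if n_signal > n_nodes:
        raise ValueError(f"n_signal={n_signal} exceeds n_nodes={n_nodes}")
    if in_degree < 0 or in_degree >= n_nodes:
        raise ValueError(
            f"in_degree={in_degree} must be in [0, n_nodes) to draw distinct regulators")
    nodes = []
    for _ in range(n_nodes):
        regs = tuple(NodeRef(network_id, int(j))
                     for j in rng.choice(n_nodes, size=in_degree, replace=False))
        table = rng.integers(0, 2, size=2 ** in_degree, dtype=np.uint8)
        nodes.append(RegulatoryNode(regs, table))
    signal = rng.choice(n_nodes, size=n_signal, replace=False)
    init = rng.integers(0, 2, size=n_nodes, dtype=np.uint8)
    return BooleanNetwork(network_id, nodes, [int(s) for s in signal], init)


def _flatten_state(holobiont: Holobiont, state) -> np.ndarray:
    if isinstance(state, Mapping):
        parts = []
        for net in holobiont.networks():
            vec = np.asarray(state[net.network_id], dtype=np.uint8)
            if vec.shape != (net.n,):
                raise ValueError(f"state for {net.network_id!r} has wrong length")
            parts.append(vec)
        return np.concatenate(parts)
    vec = np.asarray(state, dtype=np.uint8)
    if vec.size != holobiont.n_total:
        raise ValueError("global state has wrong length")
    return vec


def synchronous_step(holobiont: Holobiont, state) -> dict[str, np.ndarray]:
    """One simultaneous update of every node of every network.

    ``state`` is either a mapping ``network_id -> vector`` or a flat
    global vector; the next state is returned as a mapping.
    """
    flat = _flatten_state(holobiont, state)
    packed = holobiont.packed()
    nxt = simulate(packed, flat, 1)[1]
    out = {}
    for nid, start, size in zip(packed.network_ids, packed.starts, packed.sizes):
        out[nid] = nxt[int(start):int(start) + int(size)].copy()
    return out


def run_trajectory(holobiont: Holobiont, task_index: int = 0,
                   t_max: int = 15, initial_conditions=None) -> StateTrajectory:
    """Deterministic trajectory for one host task.

    The global initial state is the host's per-task initial condition
    ``initial_conditions[task_index]`` (or the host's own stored initial
    condition when none is given) concatenated with each microbe's own
    fixed initial condition.
    """
    if initial_conditions is None:
        host_init = holobiont.host.initial_condition
    else:
        host_states = getattr(initial_conditions, "host_states", initial_conditions)
        host_init = np.asarray(host_states, dtype=np.uint8)
        if host_init.ndim == 2:
            host_init = host_init[task_index]
    state0 = np.concatenate(
        [host_init] + [m.initial_condition for m in holobiont.microbes])
    packed = holobiont.packed()
    states = simulate(packed, state0, t_max)
    return StateTrajectory(states, packed.network_ids, packed.starts, packed.sizes)


def output_signal(network: BooleanNetwork, trajectory: StateTrajectory) -> np.ndarray:
    """Output signal R(t) = sum of signal-node states, for t = 1 .. t_max."""
    block = trajectory.network_states(network.network_id)
    sig = np.asarray(network.signal_indices, dtype=np.int64)
    return block[1:, sig].sum(axis=1)
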