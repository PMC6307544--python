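"""Low-level synchronous-update kernels on a packed (flattened) system.

A composite system (one host network plus any number of microbial
networks) is flattened into parallel arrays so that one synchronous
update is a single truth-table lookup per node:

* ``regs[i, p]``    global index of the p-th regulator of node ``i``
                    (padded with 0 beyond the node's in-degree),
* ``weights[i, p]`` bit weight ``2**(k_i - 1 - p)`` of that regulator
                    (first-listed regulator is the most significant
                    bit), 0 for padding,
* ``toff[i]``       offset of node ``i``'s truth table in ``tables``,
* ``tables``        all truth tables concatenated (uint8, 0/1),
* ``frozen[i]``     True for regulator-free nodes, which keep their
                    current value.

The same semantics are implemented twice: a numba-compiled fast path
and a pure-numpy path.  Both must agree bit for bit; the test suite
checks them against each other and against a brute-force evaluator.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly through `simulate`
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False


@dataclass(frozen=True)
class PackedSystem:
    """Flattened, read-only representation of a composite Boolean system."""

    regs: np.ndarray          # (n_total, k_max) int64
    weights: np.ndarray       # (n_total, k_max) int64
    ks: np.ndarray            # (n_total,) int64, per-node in-degree (0 for padding)
    toff: np.ndarray          # (n_total,) int64
    tables: np.ndarray        # (sum 2**k,) uint8
    frozen: np.ndarray        # (n_total,) bool
    starts: np.ndarray        # (n_networks,) int64, node offset per network
    sizes: np.ndarray         # (n_networks,) int64
    network_ids: tuple        # network id per block, host first
    signal_idx: tuple = field(default=())  # per network: global signal indices
    silenced: frozenset = field(default=frozenset())

    @property
    def n_total(self) -> int:
        return self.regs.shape[0]

    def signal_matrix(self) -> np.ndarray | None:
        """(n_networks, Ns) global signal indices, or None if Ns differs."""
        cached = getattr(self, "_sig_mat", False)
        if cached is not False:
            return cached
        mat = None
        if self.signal_idx and len({len(s) for s in self.signal_idx}) == 1:
            mat = np.asarray(self.signal_idx, dtype=np.int64)
        object.__setattr__(self, "_sig_mat", mat)
        return mat


def _simulate_np(regs, weights, toff, tables, frozen, state0, t_max):
    n = state0.size
    states = np.empty((t_max + 1, n), dtype=np.uint8)
    states[0] = state0
    cur = state0.astype(np.int64)
    any_frozen = bool(frozen.any())
    for t in range(t_max):
        idx = (cur[regs] * weights).sum(axis=1)
        nxt = tables[toff + idx].astype(np.int64)
        if any_frozen:
            nxt[frozen] = cur[frozen]
        states[t + 1] = nxt
        cur = nxt
    return states


def _simulate_multi_np(regs, weights, toff, tables, frozen, states0, t_max):
    out = np.empty((states0.shape[0], t_max + 1, states0.shape[1]),
                   dtype=np.uint8)
    for b, state0 in enumerate(states0):
        out[b] = _simulate_np(regs, weights, toff, tables, frozen,
                              state0, t_max)
    return out


if HAVE_NUMBA:

    @njit(cache=True)
    def _simulate_multi_nb(regs, weights, ks, toff, tables, frozen, states0, t_max):  # pragma: no cover
        n_batch = states0.shape[0]
        n = states0.shape[1]
        out = np.empty((n_batch, t_max + 1, n), dtype=np.uint8)
        for b in range(n_batch):
            states = out[b]
            for i in range(n):
                states[0, i] = states0[b, i]
            for t in range(t_max):
                for i in range(n):
                    if frozen[i]:
                        states[t + 1, i] = states[t, i]
                        continue
                    idx = 0
                    for p in range(ks[i]):
                        if states[t, regs[i, p]] != 0:
                            idx += weights[i, p]
                    states[t + 1, i] = tables[toff[i] + idx]
        return out

    def _simulate_nb(packed, state0, t_max):
        return _simulate_multi_nb(packed.regs, packed.weights, packed.ks,
                                  packed.toff, packed.tables, packed.frozen,
                                  state0[None, :], t_max)[0]

    @njit(cache=True)
    def _task_signals_nb(regs, wstack, ks, toff, tables, frozen,
                         niche_of_task, states0, sig_mat, t_max):  # pragma: no cover
        """Output-signal series for every task in one compiled pass.

        ``wstack`` holds one weight matrix per niche (cross-niche
        readings zeroed); ``niche_of_task[tau]`` selects the matrix used
        for task ``tau``.  Returns summed signal-node activity per
        (task, time step, network)."""
        n_tasks, n = states0.shape
        n_nets, n_sig = sig_mat.shape
        out = np.zeros((n_tasks, t_max, n_nets), dtype=np.int64)
        cur = np.empty(n, dtype=np.uint8)
        nxt = np.empty(n, dtype=np.uint8)
        for tau in range(n_tasks):
            w = wstack[niche_of_task[tau]]
            for i in range(n):
                cur[i] = states0[tau, i]
            for t in range(t_max):
                for i in range(n):
                    if frozen[i]:
                        nxt[i] = cur[i]
                        continue
                    idx = 0
                    for p in range(ks[i]):
                        if cur[regs[i, p]] != 0:
                            idx += w[i, p]
                    nxt[i] = tables[toff[i] + idx]
                for i in range(n):
                    cur[i] = nxt[i]
                for m in range(n_nets):
                    s = 0
                    for q in range(n_sig):
                        s += cur[sig_mat[m, q]]
                    out[tau, t, m] = s
        return out


def simulate(packed: PackedSystem, state0: np.ndarray, t_max: int,
             force_numpy: bool = False) -> np.ndarray:
    """Run ``t_max`` synchronous updates from ``state0``.

    Returns the full trajectory as a ``(t_max + 1, n_total)`` uint8
    array whose row 0 is the initial condition.
    """
    state0 = np.ascontiguousarray(state0, dtype=np.uint8)
    if state0.size != packed.n_total:
        raise ValueError(
            f"state has {state0.size} entries, system has {packed.n_total} nodes")
    if HAVE_NUMBA and not force_numpy:
        return _simulate_nb(packed, state0, t_max)
    return _simulate_np(packed.regs, packed.weights, packed.toff,
                        packed.tables, packed.frozen, state0, t_max)


def task_signals(packed: PackedSystem, weight_stack: np.ndarray,
                 niche_of_task: np.ndarray, states0: np.ndarray,
                 t_max: int) -> np.ndarray | None:
    """Fast path for per-task output signals: one compiled call covering
    all tasks, with per-niche weight matrices.  Returns a
    ``(n_tasks, t_max, n_networks)`` int64 array of summed signal-node
    activity, or None when the fast path does not apply (no numba, or
    networks with differing signal-node counts)."""
    if not HAVE_NUMBA:
        return None
    sig_mat = packed.signal_matrix()
    if sig_mat is None:
        return None
    states0 = np.ascontiguousarray(states0, dtype=np.uint8)
    return _task_signals_nb(packed.regs, weight_stack, packed.ks, packed.toff,
                            packed.tables, packed.frozen,
                            np.ascontiguousarray(niche_of_task, dtype=np.int64),
                            states0, sig_mat, t_max)


def simulate_batch(packed: PackedSystem, states0: np.ndarray, t_max: int,
                   force_numpy: bool = False) -> np.ndarray:
    """Run one trajectory per row of ``states0`` (shape (B, n_total));
    returns a ``(B, t_max + 1, n_total)`` uint8 array."""
    states0 = np.ascontiguousarray(states0, dtype=np.uint8)
    if states0.ndim != 2 or states0.shape[1] != packed.n_total:
        raise ValueError("states0 must be (n_batch, n_total)")
    if HAVE_NUMBA and not force_numpy:
        return _simulate_multi_nb(packed.regs, packed.weights, packed.ks,
                                  packed.toff, packed.tables, packed.frozen,
                                  states0, t_max)
    return _simulate_multi_np(packed.regs, packed.weights, packed.toff,
                              packed.tables, packed.frozen, states0, t_max)
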