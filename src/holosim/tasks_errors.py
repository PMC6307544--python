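"""Target functions (tasks), niche partitions, and every adaptation-error
functional of the model.

A task is an integer series ``F(t)``, ``t = 1 .. t_max``, with
``0 < F(t) < Ns`` strictly.  The adaptation error of a network is the
time-averaged squared deviation of its output signal from its task,

    xi = (1 / t_max) * sum_t (R(t) - F(t))**2,

and a network is *well adapted* when ``xi <= delta_A`` (inclusive).
Two aggregations of host and microbial errors into a holobiont error
are provided ("eq4": all networks weighted equally; "eq5": host and
microbiota each contribute half), plus the per-niche error used in the
specialized multitask scheme.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .network_core import Holobiont
from ._kernel import simulate_batch, task_signals

AggregationMode = Literal["eq4", "eq5"]
EvaluationScope = Literal["full", "host_plus_niche"]

__all__ = [
    "TargetFunction",
    "TaskSet",
    "InitialConditionSet",
    "NichePartition",
    "ErrorReport",
    "generate_target_function",
    "generate_task_set",
    "generate_initial_conditions",
    "adaptation_error",
    "holobiont_error",
    "niche_error",
    "is_well_adapted",
    "evaluate_holobiont",
]


@dataclass(frozen=True)
class TargetFunction:
    """Integer task series F(t) on t = 1 .. t_max with 0 < F(t) < n_signal."""

    values: tuple[int, ...]
    n_signal: int

    def __post_init__(self):
        object.__setattr__(self, "values", tuple(int(v) for v in self.values))
        if any(not 0 < v < self.n_signal for v in self.values):
            raise ValueError(
                f"target values must lie strictly between 0 and {self.n_signal}")

    @property
    def t_max(self) -> int:
        return len(self.values)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.values, dtype=np.int64)


@dataclass(frozen=True)
class TaskSet:
    """Host tasks F_1..F_T plus one task per microbial network.

    All tasks are pairwise distinct: host tasks among themselves, and
    microbial tasks from each other and from every host task.
    """

    host_tasks: tuple[TargetFunction, ...]
    microbial_tasks: tuple[TargetFunction, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "host_tasks", tuple(self.host_tasks))
        object.__setattr__(self, "microbial_tasks", tuple(self.microbial_tasks))
        seen = [t.values for t in self.host_tasks + self.microbial_tasks]
        if len(set(seen)) != len(seen):
            raise ValueError("tasks must be pairwise distinct")

    @property
    def n_host_tasks(self) -> int:
        return len(self.host_tasks)


@dataclass(frozen=True)
class InitialConditionSet:
    """One fixed host initial condition per host task (rows of host_states)."""

    host_states: np.ndarray  # (T, N) uint8

    def __post_init__(self):
        arr = np.ascontiguousarray(self.host_states, dtype=np.uint8)
        if arr.ndim != 2:
            raise ValueError("host_states must be a (T, N) array")
        object.__setattr__(self, "host_states", arr)

    @property
    def n_tasks(self) -> int:
        return self.host_states.shape[0]


@dataclass(frozen=True)
class NichePartition:
    """Disjoint microbe niches and the task subsets they assist.

    ``niches[v]`` holds microbe indices (0-based) in niche ``v``;
    ``task_assignment[v]`` holds the host-task indices assisted by that
    niche.  Niches partition the microbiota; task sets partition the
    host's tasks.
    """

    niches: tuple[tuple[int, ...], ...]
    task_assignment: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        object.__setattr__(self, "niches",
                           tuple(tuple(int(i) for i in g) for g in self.niches))
        object.__setattr__(self, "task_assignment",
                           tuple(tuple(int(i) for i in g) for g in self.task_assignment))
        if len(self.niches) != len(self.task_assignment):
            raise ValueError("one task subset per niche required")
        if any(len(g) == 0 for g in self.niches):
            raise ValueError("niches must be non-empty")
        if any(len(g) == 0 for g in self.task_assignment):
            raise ValueError("task subsets must be non-empty")
        flat = [i for g in self.niches for i in g]
        if len(set(flat)) != len(flat):
            raise ValueError("niches must be disjoint")
        flat_t = [i for g in self.task_assignment for i in g]
        if len(set(flat_t)) != len(flat_t):
            raise ValueError("task subsets must be disjoint")

    @property
    def n_niches(self) -> int:
        return len(self.niches)

    def niche_of_microbe(self, j: int) -> int:
        for v, g in enumerate(self.niches):
            if j in g:
                return v
        raise KeyError(j)

    @classmethod
    def even_split(cls, n_microbes: int, n_tasks: int,
                   n_niches: int | None = None) -> "NichePartition":
        """Deal microbes and tasks round-robin into niches as evenly as
        possible.  Defaults to ``min(n_microbes, n_tasks)`` niches (one
        task subset per niche when possible)."""
        if n_niches is None:
            n_niches = min(n_microbes, n_tasks)
        if not 1 <= n_niches <= min(n_microbes, n_tasks):
            raise ValueError("need 1 <= n_niches <= min(n_microbes, n_tasks)")
        niches = tuple(tuple(range(v, n_microbes, n_niches)) for v in range(n_niches))
        tasks = tuple(tuple(range(v, n_tasks, n_niches)) for v in range(n_niches))
        return cls(niches, tasks)


@dataclass(frozen=True)
class ErrorReport:
    """Every error functional evaluated on one holobiont.

    ``microbial_per_task[j, tau]`` is microbe ``j``'s error at its own
    task while the host ran from the initial condition of host task
    ``tau``.  In the specialized scheme microbial totals average over
    the tasks of the microbe's own niche; otherwise over all tasks.
    """

    host_per_task: np.ndarray          # (T,)
    host_total: float
    microbial_per_task: np.ndarray     # (PM, T), NaN where not evaluated
    microbial_totals: np.ndarray       # (PM,)
    holobiont_error: float
    aggregation_mode: str
    niche_errors: np.ndarray | None = None  # (PG,) in the specialized scheme


def generate_target_function(n_signal: int, t_max: int,
                             rng: np.random.Generator) -> TargetFunction:
    """Draw F(t) i.i.d. uniform on the integers {1 .. n_signal - 1}."""
    if n_signal < 2:
        raise ValueError("n_signal must be >= 2 for a non-empty target range")
    values = rng.integers(1, n_signal, size=t_max)
    return TargetFunction(tuple(int(v) for v in values), n_signal)


def generate_task_set(n_host_tasks: int, n_microbes: int, n_signal: int,
                      t_max: int, rng: np.random.Generator,
                      max_tries: int = 1000) -> TaskSet:
    """Distinct host and microbial tasks, redrawing on collision."""
    seen: set[tuple[int, ...]] = set()
    tasks: list[TargetFunction] = []
    for _ in range(n_host_tasks + n_microbes):
        for _ in range(max_tries):
            t = generate_target_function(n_signal, t_max, rng)
            if t.values not in seen:
                seen.add(t.values)
                tasks.append(t)
                break
        else:  # pragma: no cover - astronomically unlikely for Ns >= 3
            raise RuntimeError("could not draw distinct tasks")
    return TaskSet(tuple(tasks[:n_host_tasks]), tuple(tasks[n_host_tasks:]))


def generate_initial_conditions(n_tasks: int, n_nodes: int,
                                rng: np.random.Generator) -> InitialConditionSet:
    """One uniform random host initial condition per task, fixed for the run."""
    return InitialConditionSet(rng.integers(0, 2, size=(n_tasks, n_nodes),
                                            dtype=np.uint8))


def adaptation_error(signal: Sequence[int] | np.ndarray,
                     target: TargetFunction | Sequence[int]) -> float:
    """Mean squared deviation between output signal and target over
    t = 1 .. t_max; zero iff they coincide."""
    r = np.asarray(signal, dtype=np.int64)
    f = target.as_array() if isinstance(target, TargetFunction) \
        else np.asarray(target, dtype=np.int64)
    if r.shape != f.shape:
        raise ValueError(f"signal length {r.shape} != target length {f.shape}")
    return float(np.mean((r - f) ** 2))


def holobiont_error(host_error: float, microbial_errors: Sequence[float],
                    mode: AggregationMode = "eq5") -> float:
    """Aggregate host and microbial errors into one holobiont error.

    ``eq4`` weights every network equally:  (xi_H + sum_j xi_M_j) / (1 + PM).
    ``eq5`` weights host and microbiota equally:  (xi_H + mean_j xi_M_j) / 2.
    With an empty microbiota both reduce to the host error.
    """
    micro = np.asarray(microbial_errors, dtype=float)
    if micro.size == 0:
        return float(host_error)
    if mode == "eq4":
        return float((host_error + micro.sum()) / (1 + micro.size))
    if mode == "eq5":
        return float(0.5 * (host_error + micro.mean()))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def niche_error(host_per_task_errors: Sequence[float] | np.ndarray,
                niche: Sequence[int], tasks: Sequence[int],
                microbial_per_task_errors: np.ndarray) -> float:
    """Adaptation error of one niche.

    ``niche`` holds the microbe indices of the niche, ``tasks`` the host
    task indices it assists.  The host term is the host's mean error
    over those tasks; each niche microbe contributes its mean error over
    the same tasks; the total is divided by (1 + niche size).
    """
    niche = tuple(niche)
    tasks = tuple(tasks)
    if not niche or not tasks:
        raise ValueError("niche and task set must be non-empty")
    host_pt = np.asarray(host_per_task_errors, dtype=float)
    micro_pt = np.asarray(microbial_per_task_errors, dtype=float)
    host_term = host_pt[list(tasks)].mean()
    micro_term = sum(micro_pt[i, list(tasks)].mean() for i in niche)
    return float((host_term + micro_term) / (1 + len(niche)))


def is_well_adapted(error: float, threshold: float) -> bool:
    """Inclusive comparison against the adaptation threshold delta_A."""
    return error <= threshold


def evaluate_holobiont(holobiont: Holobiont, task_set: TaskSet,
                       initial_conditions: InitialConditionSet,
                       niche_partition: NichePartition | None = None,
                       mode: AggregationMode = "eq5",
                       scope: EvaluationScope = "host_plus_niche") -> ErrorReport:
    """Run one trajectory per host task and fill every error functional.

    In the default ``host_plus_niche`` scope the evaluation of a task
    silences the microbes outside the niche assigned to that task, so
    each niche assists only its own tasks; the alternative ``full``
    scope simulates the whole holobiont for every task (all microbes'
    nodes update and may influence the host on every task).  Without a
    niche partition both scopes coincide.
    """
    part = niche_partition if niche_partition is not None else holobiont.niche_partition
    tasks = task_set.host_tasks
    T = len(tasks)
    PM = len(holobiont.microbes)
    if initial_conditions.n_tasks != T:
        raise ValueError("one initial condition per host task required")
    if PM != len(task_set.microbial_tasks):
        raise ValueError("one microbial task per microbe required")
    if scope not in ("full", "host_plus_niche"):
        raise ValueError(f"unknown evaluation scope {scope!r}")
    t_max = tasks[0].t_max
    micro_inits = [m.initial_condition for m in holobiont.microbes]
    f_host = np.stack([t.as_array() for t in tasks])
    f_micro = np.stack([t.as_array() for t in task_set.microbial_tasks]) \
        if PM else np.empty((0, t_max), dtype=np.int64)

    host_pt = np.empty(T)
    micro_pt = np.full((PM, T), np.nan)
    niche_scoped = scope == "host_plus_niche" and part is not None

    if micro_inits:
        micro_flat = np.concatenate(micro_inits)
        states0 = np.concatenate(
            [initial_conditions.host_states,
             np.broadcast_to(micro_flat, (T, micro_flat.size))], axis=1)
    else:
        states0 = initial_conditions.host_states
    ids = holobiont.network_ids
    base = holobiont.packed()
    if niche_scoped:
        packs = []
        for g in part.niches:
            outside = frozenset(ids[1 + j] for j in range(PM) if j not in g)
            packs.append(holobiont.packed(holobiont.silenced | outside))
        niche_of_task = np.empty(T, dtype=np.int64)
        for v, ts in enumerate(part.task_assignment):
            niche_of_task[list(ts)] = v
    else:
        packs = [base]
        niche_of_task = np.zeros(T, dtype=np.int64)

    signals = task_signals(base, np.stack([p.weights for p in packs]),
                           niche_of_task, states0, t_max)
    if signals is None:
        # per-pack fallback: simulate each niche's tasks and sum signals
        signals = np.empty((T, t_max, 1 + PM), dtype=np.int64)
        for v, pack in enumerate(packs):
            ts = np.nonzero(niche_of_task == v)[0]
            states = simulate_batch(pack, states0[ts], t_max)
            sig_mat = pack.signal_matrix()
            if sig_mat is not None:
                signals[ts] = states[:, 1:, sig_mat].sum(axis=3)
            else:
                signals[ts] = np.stack(
                    [states[:, 1:, s].sum(axis=2) for s in pack.signal_idx],
                    axis=2)

    host_pt[:] = np.mean((signals[:, :, 0] - f_host) ** 2, axis=1)
    if PM:
        if niche_scoped:
            for v, (g, ts) in enumerate(zip(part.niches, part.task_assignment)):
                ts = list(ts)
                for j in g:
                    micro_pt[j, ts] = np.mean(
                        (signals[ts, :, 1 + j] - f_micro[j]) ** 2, axis=1)
        else:
            diffs = signals[:, :, 1:] - f_micro.T[None, :, :]
            micro_pt[:, :] = np.mean(diffs ** 2, axis=1).T

    host_total = float(host_pt.mean())
    niche_errors = None
    if part is not None:
        totals = np.empty(PM)
        for j in range(PM):
            ts = list(part.task_assignment[part.niche_of_microbe(j)])
            totals[j] = micro_pt[j, ts].mean()
        niche_errors = np.array([
            niche_error(host_pt, g, ts, micro_pt)
            for g, ts in zip(part.niches, part.task_assignment)])
        xi_l = float(niche_errors.mean())
    else:
        totals = micro_pt.mean(axis=1) if PM else np.empty(0)
        xi_l = holobiont_error(host_total, totals, mode)

    return ErrorReport(host_per_task=host_pt, host_total=host_total,
                       microbial_per_task=micro_pt, microbial_totals=totals,
                       holobiont_error=xi_l, aggregation_mode=mode,
                       niche_errors=niche_errors)
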