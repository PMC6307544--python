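"""Scenario runners: control vs holobiont evolution, multitask
specialization scans, dysbiosis (disconnection) and diversity-loss
sweeps, and one-parameter sweeps.

Every experiment is a set of independently seeded replicates of
:func:`holosim.evolution_engine.evolve`; summaries (first threshold
crossing, adaptation probability at a fixed generation, final errors,
post-disconnection errors) are recomputed from the per-generation
records so that nothing depends on hidden state.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .network_core import BooleanNetwork, Holobiont, NodeRef, RegulatoryNode
from .tasks_errors import (ErrorReport, InitialConditionSet, NichePartition,
                           TaskSet, evaluate_holobiont,
                           generate_initial_conditions, generate_task_set)
from .evolution_engine import (EvolutionConfig, GenerationRecord,
                               PretrainError, evolve,
                               pretrain_microbial_network)

__all__ = [
    "ExperimentSpec",
    "ExperimentResult",
    "ReplicateInputs",
    "derive_rng",
    "prepare_replicate",
    "run_replicate",
    "run_experiment",
    "records_frame",
    "first_crossing",
    "disconnect_networks",
    "diversity_loss_sweep",
    "multitask_adaptation_scan",
]


def derive_rng(master_seed: int, *labels) -> np.random.Generator:
    """Named child random stream: the master seed plus a CRC of each
    label feeds one SeedSequence, so adding a stream never shifts the
    draws of another."""
    entropy = [int(master_seed) & 0x7FFFFFFF]
    entropy += [zlib.crc32(str(l).encode()) for l in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))


@dataclass(frozen=True)
class ReplicateInputs:
    """Frozen inputs of one replicate: tasks, initial conditions and the
    pretrained microbiota."""

    task_set: TaskSet
    initial_conditions: InitialConditionSet
    microbes: tuple[BooleanNetwork, ...]


@dataclass(frozen=True)
class ExperimentSpec:
    """One experiment: a base configuration, replicate seeds, and an
    optional one-parameter sweep."""

    name: str
    config: EvolutionConfig
    seeds: tuple[int, ...]
    sweep_param: str | None = None
    sweep_values: tuple = ()

    def __post_init__(self):
        if len(set(self.seeds)) != len(self.seeds):
            raise ValueError("replicate seeds must be distinct")
        if self.sweep_param is not None and not self.sweep_values:
            raise ValueError("sweep_values required with sweep_param")

    def configs(self) -> list[tuple[object, EvolutionConfig]]:
        if self.sweep_param is None:
            return [(None, self.config)]
        return [(v, replace(self.config, **{self.sweep_param: v}))
                for v in self.sweep_values]


@dataclass
class ExperimentResult:
    """Per-generation tables plus derived summaries."""

    spec: ExperimentSpec
    records: pd.DataFrame    # one row per (sweep value, seed, generation)
    summary: pd.DataFrame    # one row per (sweep value, seed)
    populations: dict = field(default_factory=dict)  # (value, seed) -> final pop
    inputs: dict = field(default_factory=dict)       # (value, seed) -> ReplicateInputs


def prepare_replicate(config: EvolutionConfig, seed: int) -> ReplicateInputs:
    """Draw the tasks and initial conditions and pretrain the microbiota
    for one replicate, all from named child streams of ``seed``."""
    task_rng = derive_rng(seed, "tasks")
    task_set = generate_task_set(config.n_tasks, config.n_microbes,
                                 config.n_signal, config.t_max, task_rng)
    ics = generate_initial_conditions(config.n_tasks, config.n_nodes,
                                      derive_rng(seed, "host-ics"))
    microbes = []
    for j, task in enumerate(task_set.microbial_tasks):
        for attempt in range(5):
            try:
                microbes.append(pretrain_microbial_network(
                    task, config, derive_rng(seed, "pretrain", j, attempt),
                    network_id=f"M{j + 1}"))
                break
            except PretrainError:
                if attempt == 4:
                    raise
    return ReplicateInputs(task_set, ics, tuple(microbes))


def run_replicate(config: EvolutionConfig, seed: int,
                  inputs: ReplicateInputs | None = None,
                  stop=None) -> tuple[list[GenerationRecord], list[Holobiont],
                                      ReplicateInputs]:
    """One fully seeded replicate: prepare inputs, evolve, return records,
    final population and the inputs used."""
    if inputs is None:
        inputs = prepare_replicate(config, seed)
    records, population = evolve(config, inputs.task_set,
                                 inputs.initial_conditions, inputs.microbes,
                                 derive_rng(seed, "evolve"), stop=stop)
    return records, population, inputs


def records_frame(records: Sequence[GenerationRecord], **labels) -> pd.DataFrame:
    frame = pd.DataFrame([vars(r) for r in records])
    for key, value in labels.items():
        frame[key] = value
    return frame


def first_crossing(records: Sequence[GenerationRecord] | pd.DataFrame,
                   threshold: float) -> int | None:
    """First generation whose mean host error is at or below ``threshold``."""
    if isinstance(records, pd.DataFrame):
        hit = records.loc[records["mean_host_error"] <= threshold, "generation"]
        return int(hit.iloc[0]) if len(hit) else None
    for rec in records:
        if rec.mean_host_error <= threshold:
            return rec.generation
    return None


def _summarize(records: list[GenerationRecord], config: EvolutionConfig) -> dict:
    last = records[-1]
    pa = [r.adaptation_probability for r in records]
    return {
        "first_crossing": first_crossing(records, config.delta_a),
        "final_mean_host_error": last.mean_host_error,
        "final_mean_microbial_error": last.mean_microbial_error,
        "final_adaptation_probability": last.adaptation_probability,
        "max_adaptation_probability": max(pa),
        "final_mean_host_mutations": last.mean_host_mutations,
        "final_generation": last.generation,
    }


def run_experiment(spec: ExperimentSpec, keep_populations: bool = False,
                   stop=None) -> ExperimentResult:
    """Run every (sweep value, seed) replicate of ``spec``."""
    record_frames, summary_rows = [], []
    populations, inputs_map = {}, {}
    for value, config in spec.configs():
        for seed in spec.seeds:
            records, population, inputs = run_replicate(config, seed, stop=stop)
            record_frames.append(
                records_frame(records, sweep_value=value, seed=seed))
            row = {"sweep_value": value, "seed": seed}
            row.update(_summarize(records, config))
            summary_rows.append(row)
            if keep_populations:
                populations[(value, seed)] = population
                inputs_map[(value, seed)] = inputs
    return ExperimentResult(spec=spec,
                            records=pd.concat(record_frames, ignore_index=True),
                            summary=pd.DataFrame(summary_rows),
                            populations=populations, inputs=inputs_map)


def disconnect_networks(holobiont: Holobiont, microbe_subset: Iterable[str],
                        mode: Literal["freeze_zero", "excise"] = "freeze_zero",
                        ) -> Holobiont:
    """Sever every regulatory connection crossing the boundary between
    ``microbe_subset`` and the rest of the holobiont.

    ``freeze_zero`` (default, reversible): severed regulator values are
    read as 0 during the dynamics, truth tables untouched.  ``excise``
    (irreversible): crossing edges are structurally removed, each
    downstream truth table restricted to the removed regulator's 0 half.
    """
    subset = frozenset(microbe_subset)
    known = set(holobiont.network_ids[1:])
    unknown = subset - known
    if unknown:
        raise ValueError(f"not microbial networks of this holobiont: {sorted(unknown)}")
    if mode == "freeze_zero":
        out = holobiont.copy()
        out.silenced = holobiont.silenced | subset
        out.invalidate()
        return out
    if mode != "excise":
        raise ValueError(f"unknown disconnection mode {mode!r}")
    out = holobiont.copy()
    out.silenced = holobiont.silenced
    for net in out.networks():
        inside = net.network_id in subset
        for i, node in enumerate(net.nodes):
            regs, table = node.regulators, node.truth_table
            pos = 0
            while pos < len(regs):
                crossing = (regs[pos].network_id in subset) != inside
                if crossing:
                    k = len(regs)
                    bit = k - 1 - pos
                    idx = np.arange(2 ** k)
                    table = table[((idx >> bit) & 1) == 0]
                    regs = regs[:pos] + regs[pos + 1:]
                else:
                    pos += 1
            if regs is not node.regulators:
                net.set_node(i, RegulatoryNode(regs, table))
    out.invalidate()
    return out


def diversity_loss_sweep(holobiont: Holobiont, task_set: TaskSet,
                         initial_conditions: InitialConditionSet,
                         delta_n_values: Sequence[int], reps: int,
                         rng: np.random.Generator,
                         mode: str = "freeze_zero",
                         scope: str = "host_plus_niche") -> pd.DataFrame:
    """Mean post-disconnection host error as a function of the number
    ``delta_n`` of microbial networks disconnected.

    For each ``delta_n``, ``reps`` uniformly random subsets of that size
    are disconnected and the host error (averaged over tasks) recorded;
    ``delta_n = 0`` is the adapted baseline.
    """
    microbe_ids = holobiont.network_ids[1:]
    pm = len(microbe_ids)
    rows = []
    for dn in delta_n_values:
        dn = int(dn)
        if not 0 <= dn <= pm:
            raise ValueError(f"delta_n={dn} outside [0, {pm}]")
        n_draws = 1 if dn in (0, pm) else reps
        for rep in range(n_draws):
            subset = [microbe_ids[i]
                      for i in rng.choice(pm, size=dn, replace=False)]
            cut = disconnect_networks(holobiont, subset, mode=mode)
            report = evaluate_holobiont(cut, task_set, initial_conditions,
                                        cut.niche_partition, scope=scope)
            rows.append({"delta_n": dn, "rep": rep,
                         "host_error": report.host_total})
    frame = pd.DataFrame(rows)
    curve = frame.groupby("delta_n", as_index=False)["host_error"].mean()
    curve = curve.rename(columns={"host_error": "mean_host_error"})
    return curve.merge(frame.groupby("delta_n", as_index=False).size(), on="delta_n")


def multitask_adaptation_scan(config: EvolutionConfig, pm_values: Sequence[int],
                              scheme: Literal["nonspecialized", "specialized"],
                              seeds: Sequence[int],
                              at_generation: int = 500) -> pd.DataFrame:
    """Adaptation probability at a fixed generation as a function of the
    number of microbial networks, for one interaction scheme.

    ``pm_values`` containing 0 reproduces the multitask control baseline
    (both schemes coincide without microbes).
    """
    rows = []
    for pm in pm_values:
        pm = int(pm)
        if pm == 0:
            cfg = replace(config, scheme="control", n_microbes=0, n_niches=None)
        else:
            n_niches = min(pm, config.n_tasks) if scheme == "specialized" else None
            cfg = replace(config, scheme=scheme, n_microbes=pm,
                          n_niches=n_niches)
        cfg = replace(cfg, max_generations=at_generation)
        for seed in seeds:
            records, _, _ = run_replicate(cfg, seed)
            rows.append({"n_microbes": pm, "seed": seed,
                         "adaptation_probability":
                             records[at_generation].adaptation_probability,
                         "mean_host_error": records[at_generation].mean_host_error})
    return pd.DataFrame(rows)
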