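"""Population-level evolutionary loop.

A generation is one full round of mutation, evaluation and elitist
selection: every network of every holobiont is mutated at its rate,
every holobiont is evaluated on the host's task(s), per-generation
population statistics are recorded, and the ``n_survivors`` holobionts
with the smallest holobiont error are kept and replicated
(``copies_per_survivor`` deep copies each) to restore the population
size.  Survivors are re-mutated in the next generation — there is no
frozen elite.

The population starts as ``P`` identical replicas of one randomly
constructed host, each paired with deep copies of the same pretrained
microbial networks.  Microbes are pretrained standalone with the same
algorithm until their best individual is strictly below the adaptation
threshold, so at generation 0 the microbiota is well adapted while the
host is not.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Literal, Sequence

import numpy as np

from .network_core import (HOST_ID, BooleanNetwork, Holobiont,
                           build_random_network)
from .tasks_errors import (ErrorReport, InitialConditionSet, NichePartition,
                           TargetFunction, TaskSet, evaluate_holobiont,
                           generate_initial_conditions, is_well_adapted)
from .mutation_ops import (MutationPolicy, WiringConstraint, apply_mutation,
                           sample_mutations)

Scheme = Literal["control", "nonspecialized", "specialized"]

__all__ = [
    "EvolutionConfig",
    "GenerationRecord",
    "PretrainError",
    "pretrain_microbial_network",
    "select_and_replicate",
    "evolve",
    "compute_generation_record",
]

_SCHEME_TO_WIRING = {
    "control": "control",
    "nonspecialized": "holobiont_nonspecialized",
    "specialized": "holobiont_specialized",
}


class PretrainError(RuntimeError):
    """Pretraining did not reach the adaptation threshold in time."""


@dataclass(frozen=True)
class EvolutionConfig:
    """All simulation parameters.

    Defaults are the standard study conditions: networks of ``n_nodes``
    = 50 with in-degree 2 (critical Kauffman regime) and 12 signal
    nodes, tasks evaluated over 15 time steps, populations of 100 with
    the 10 best individuals kept and copied 9 times each, host mutation
    rate 0.001 per node per generation and microbial rate 10x that,
    adaptation threshold 1.
    """

    n_nodes: int = 50
    in_degree: int = 2
    n_signal: int = 12
    t_max: int = 15
    population: int = 100
    n_microbes: int = 0
    n_tasks: int = 1
    n_niches: int | None = None
    mu_host: float = 0.001
    mu_microbe: float = 0.01
    delta_a: float = 1.0
    n_survivors: int = 10
    copies_per_survivor: int = 9
    aggregation_mode: Literal["eq4", "eq5"] = "eq5"
    scheme: Scheme = "control"
    evaluation_scope: Literal["full", "host_plus_niche"] = "host_plus_niche"
    max_generations: int = 500
    k_max: int = 10
    remove_policy: Literal["zero_half", "random_half"] = "zero_half"
    add_policy: Literal["copy_half", "random_half"] = "random_half"
    rewire_policy: Literal["move_source", "move_destination"] = "move_destination"
    pretrain_max_generations: int = 5000

    def __post_init__(self):
        if self.n_survivors * (1 + self.copies_per_survivor) != self.population:
            raise ValueError(
                f"n_survivors * (1 + copies_per_survivor) = "
                f"{self.n_survivors * (1 + self.copies_per_survivor)} "
                f"must equal population = {self.population}")
        if self.mu_host < 0 or self.mu_microbe < 0:
            raise ValueError("mutation rates must be non-negative")
        if self.scheme == "specialized":
            pg = self.n_niches if self.n_niches is not None \
                else min(self.n_microbes, self.n_tasks)
            if pg > self.n_tasks:
                raise ValueError("cannot have more niches than tasks")
        if self.scheme == "control" and self.n_microbes:
            raise ValueError("the control scheme has no microbial networks")

    @property
    def gamma(self) -> float:
        """Ratio of microbial to host mutation rates (inf when mu_host = 0)."""
        if self.mu_host == 0:
            return math.inf
        return self.mu_microbe / self.mu_host

    def with_gamma(self, gamma: float) -> "EvolutionConfig":
        """Derive rates from a ratio; ``gamma = inf`` means ``mu_host = 0``
        with the microbial rate kept at its current value."""
        if math.isinf(gamma):
            return replace(self, mu_host=0.0)
        return replace(self, mu_microbe=gamma * self.mu_host)

    def wiring_constraint(self, partition: NichePartition | None) -> WiringConstraint:
        return WiringConstraint(_SCHEME_TO_WIRING[self.scheme], partition)

    def mutation_policy(self) -> MutationPolicy:
        return MutationPolicy(k_max=self.k_max, remove_policy=self.remove_policy,
                              add_policy=self.add_policy,
                              rewire_policy=self.rewire_policy)

    def niche_partition(self) -> NichePartition | None:
        if self.scheme != "specialized":
            return None
        return NichePartition.even_split(self.n_microbes, self.n_tasks,
                                         self.n_niches)


@dataclass(frozen=True)
class GenerationRecord:
    """Population statistics of one generation, measured on the
    population as it stands after the generation's full round of
    mutation, selection and replication."""

    generation: int
    mean_host_error: float
    mean_microbial_error: float   # NaN when there are no microbes
    mean_holobiont_error: float
    adaptation_probability: float  # fraction of hosts with error <= delta_A
    mean_host_mutations: float
    best_error: float


def _evaluate_cached(holo: Holobiont, task_set: TaskSet,
                     ics: InitialConditionSet, config: EvolutionConfig) -> ErrorReport:
    if holo._report is None:
        holo._report = evaluate_holobiont(
            holo, task_set, ics, holo.niche_partition,
            mode=config.aggregation_mode, scope=config.evaluation_scope)
    return holo._report


def compute_generation_record(population: Sequence[Holobiont],
                              reports: Sequence[ErrorReport],
                              config: EvolutionConfig,
                              generation: int) -> GenerationRecord:
    host_errors = np.array([r.host_total for r in reports])
    xi_l = np.array([r.holobiont_error for r in reports])
    if config.n_microbes:
        micro = float(np.mean([r.microbial_totals.mean() for r in reports]))
    else:
        micro = float("nan")
    pa = float(np.mean([is_well_adapted(e, config.delta_a) for e in host_errors]))
    omega = float(np.mean([h.host.mutation_count for h in population]))
    return GenerationRecord(generation=generation,
                            mean_host_error=float(host_errors.mean()),
                            mean_microbial_error=micro,
                            mean_holobiont_error=float(xi_l.mean()),
                            adaptation_probability=pa,
                            mean_host_mutations=omega,
                            best_error=float(xi_l.min()))


def select_and_replicate(population: Sequence[tuple[Holobiont, float]],
                         config: EvolutionConfig,
                         rng: np.random.Generator | None = None) -> list[Holobiont]:
    """Keep the ``n_survivors`` lowest-error holobionts (stable ties) and
    restore the population with ``copies_per_survivor`` deep copies each."""
    if len(population) != config.population:
        raise ValueError(
            f"expected population of {config.population}, got {len(population)}")
    errors = np.array([e for _, e in population])
    order = np.argsort(errors, kind="stable")[:config.n_survivors]
    out: list[Holobiont] = []
    for rank in order:
        survivor = population[int(rank)][0]
        out.append(survivor)
        out.extend(survivor.copy() for _ in range(config.copies_per_survivor))
    return out


def evolve(config: EvolutionConfig, task_set: TaskSet,
           initial_conditions: InitialConditionSet,
           pretrained_microbes: Sequence[BooleanNetwork],
           rng: np.random.Generator,
           founder_host: BooleanNetwork | None = None,
           stop: Callable[[GenerationRecord], bool] | None = None,
           ) -> tuple[list[GenerationRecord], list[Holobiont]]:
    """Run the evolutionary loop and return the per-generation records
    plus the final population.

    Records cover generations ``0 .. max_generations`` (generation 0 is
    the unmutated founder population).  The record of generation ``g``
    describes the population as it stands after the full round of
    mutation, selection and replication of that generation — the
    survivors and their copies, not the transient pool of fresh mutants
    that selection has just filtered.  ``stop`` may end the run early,
    checked after each generation's record.
    """
    if len(pretrained_microbes) != config.n_microbes:
        raise ValueError("one pretrained microbe per n_microbes required")
    partition = config.niche_partition()
    constraint = config.wiring_constraint(partition)
    policy = config.mutation_policy()
    rates = {"mu_host": config.mu_host, "mu_microbe": config.mu_microbe}

    if founder_host is None:
        founder_host = build_random_network(config.n_nodes, config.in_degree,
                                            config.n_signal, rng, HOST_ID)
    founder = Holobiont(founder_host,
                        [m.copy() for m in pretrained_microbes],
                        niche_partition=partition)
    population = [founder.copy(lineage_id=i) for i in range(config.population)]

    records: list[GenerationRecord] = []
    reports = [_evaluate_cached(h, task_set, initial_conditions, config)
               for h in population]
    rec = compute_generation_record(population, reports, config, 0)
    records.append(rec)
    if stop is not None and stop(rec):
        return records, population

    for g in range(1, config.max_generations + 1):
        for holo in population:
            for event in sample_mutations(holo, rates, rng):
                apply_mutation(holo, event, rng, constraint, policy)
        reports = [_evaluate_cached(h, task_set, initial_conditions, config)
                   for h in population]
        scored = list(zip(population, (r.holobiont_error for r in reports)))
        population = select_and_replicate(scored, config)
        # survivors and their copies carry cached reports, so this re-read
        # of the post-round population costs nothing
        reports = [_evaluate_cached(h, task_set, initial_conditions, config)
                   for h in population]
        rec = compute_generation_record(population, reports, config, g)
        records.append(rec)
        if stop is not None and stop(rec):
            break
    return records, population


def pretrain_microbial_network(task: TargetFunction, config: EvolutionConfig,
                               rng: np.random.Generator,
                               network_id: str = HOST_ID) -> BooleanNetwork:
    """Evolve a standalone network until its best individual is strictly
    below the adaptation threshold on ``task``; return that individual
    with its mutation counter reset.

    Uses the plain single-network algorithm (control wiring, host
    mutation rate) regardless of ``config.scheme``.
    """
    # standalone pretraining always mutates at a positive host-type rate,
    # even for gamma = inf runs where the coevolving host itself has mu = 0
    mu = config.mu_host if config.mu_host > 0 else 0.001
    solo = replace(config, scheme="control", n_microbes=0, n_tasks=1,
                   n_niches=None, mu_host=mu,
                   max_generations=config.pretrain_max_generations)
    task_set = TaskSet((task,))
    ics = generate_initial_conditions(1, solo.n_nodes, rng)
    records, population = evolve(
        solo, task_set, ics, (), rng,
        stop=lambda rec: rec.best_error < solo.delta_a)
    if not records[-1].best_error < solo.delta_a:
        raise PretrainError(
            f"no individual below delta_A={solo.delta_a} within "
            f"{solo.pretrain_max_generations} generations")
    reports = [_evaluate_cached(h, task_set, ics, solo) for h in population]
    best = population[int(np.argmin([r.holobiont_error for r in reports]))]
    microbe = best.host.copy()
    # the per-task initial condition used during pretraining becomes the
    # microbe's own fixed initial condition inside a holobiont
    microbe.initial_condition = ics.host_states[0].copy()
    microbe.mutation_count = 0
    return microbe if network_id == HOST_ID else microbe.renamed(network_id)
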