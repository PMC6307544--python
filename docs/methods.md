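# Methods

This note records the model conventions, parameter choices, measurement
definitions and known limitations of `holosim`. Everything stated here
is implemented and exercised by the test suite; no empirical claim is
made beyond what the tests and `scripts/acceptance.py` themselves
compute.

## Model

**Networks.** A genotype is a directed Boolean network of `N` nodes.
Each node holds an ordered list of regulators and a truth table of
length `2^k`; the first-listed regulator is read as the most
significant bit of the table index (this ordering is serialized, so
results are reproducible across implementations). All nodes update
simultaneously. Initial networks have exactly `K = 2` distinct
regulators per node, drawn uniformly with self-loops allowed — the
critical Kauffman regime, chosen because critical networks couple
robustness with adaptability. Mutation can change in-degrees, so
evolved networks have an Erdős–Rényi-like degree distribution around
`K`.

**Conventions the model leaves open, fixed here:**

* *Regulator-free nodes* (`k = 0`, reachable through connection
  removals) freeze at their current value. The alternative — pinning
  them to an arbitrary constant — would inject an unreferenced
  parameter.
* *Duplicate edges* (same ordered source→destination pair) are
  disallowed; mutation proposals that would create one are redrawn up
  to 5 times and then dropped as no-ops.
* *Self-loops* are allowed, matching the uniform random construction.

**Tasks.** A task `F(t)` is drawn i.i.d. uniform on the integers
`{1, …, Ns−1}` for each of `t_max = 15` time steps. Host tasks,
microbial tasks and all of them jointly are pairwise distinct
(collisions are redrawn). Each host task τ has its own fixed random
initial condition `Σ_τ`; each microbial network carries one fixed
initial condition of its own (the state it was pretrained from),
reused for every host task. The output signal is compared with the
task on `t = 1 … 15`, with `Σ` the state at `t = 0`. A config hook
accepts explicit `F(t)` vectors for non-uniform task families.

**Errors.** Host error `ξ_H`: mean squared deviation of `R(t)` from
`F(t)` over the 15 steps, averaged over tasks when there are several.
Microbial errors are defined identically against each microbe's own
task, evaluated inside the holobiont dynamics (the host's initial
condition selects the trajectory). Holobiont error: either the
equal-per-network mean `(ξ_H + Σ_j ξ_M_j) / (1 + P_M)` ("eq4") or the
host-vs-microbiota balanced form `½(ξ_H + mean_j ξ_M_j)` ("eq5", the
default used for selection). The two coincide for `P_M = 1`. In the
specialized scheme the holobiont error is the mean over niches of the
niche error

```
ξ_G = (ξ_H|niche tasks + Σ_{i in niche} mean_{niche tasks} ξ_M_i) / (1 + niche size),
```

where the host term is the host's mean error over the niche's tasks
(the natural reading when a niche assists several tasks).
A network is well adapted when `ξ ≤ δ_A`, inclusive; `δ_A = 1` means
at most one signal node may deviate by one unit at every time step.

## Mutation operators

Every node of every network is independently selected with probability
`μ` per generation (`μ_H = 0.001` for host nodes, `μ_M = 10 μ_H` for
microbial nodes — microbial populations generate mutants an order of
magnitude faster). A selected node undergoes one of four operator
classes with equal probability: rewire one input or output connection,
add a new input or output connection, remove one, or flip one
truth-table entry. Directions (input vs output) are uniform.

Truth-table bookkeeping when the in-degree changes is not dictated by
the model definition; the defaults are:

* **add** (`add_policy="random_half"`): the gained regulator becomes
  the new most significant bit; the old table occupies its 0 half and
  the new half is filled with fresh random bits, so a single add is a
  standalone evolutionary move that can change the phenotype
  immediately. The neutral alternative (`copy_half`, duplicating the
  old table) is available but measurably starves the search of
  variation at these low mutation rates.
* **remove** (`remove_policy="zero_half"`): the table is restricted to
  the half where the removed regulator is 0 (`random_half` picks the
  half at random).
* **rewire** (`rewire_policy="move_destination"`): one endpoint of the
  chosen edge moves — the edge count is conserved, distinguishing
  rewiring from add/remove; the old downstream node applies the
  removal policy and the new one the addition policy. The
  table-preserving alternative (`move_source`) is available.

New connections may cross network boundaries: a host node wires to any
network of its holobiont with equal probability; a microbial node
wires to itself, the host, or — in the non-specialized scheme — any
other microbe; in the specialized scheme a microbe may wire only to
the host or to microbes of its own niche. An in-degree cap
(`k_max = 10`) bounds truth-table growth; capped or duplicate
proposals are no-ops and do not increment the mutation counter Ω.

## Evolutionary loop and measurement convention

A generation is one full round: mutate every network of every
holobiont → evaluate → keep the `n_survivors = 10` holobionts with the
smallest ξ_L (stable ties) → restore the population with
`copies_per_survivor = 9` deep copies each. Survivors are re-mutated
in later generations (no frozen elite); copies inherit wiring and the
accumulated-mutation counter Ω, so Ω is a lineage property.

Per-generation statistics (mean errors, adaptation probability
`P_A` = fraction of hosts with `ξ_H ≤ δ_A`, mean Ω) describe the
population **as it stands after the round completes** — the survivors
and their copies. This matters: at `μ_M = 10 μ_H` roughly 40 % of
holobionts carry fresh microbial mutations at any instant, transient
variation that selection purges immediately. Measured before
selection, that churn inflates the holobiont ensemble's mean error and
masks the coevolutionary speed-up almost completely, while leaving the
control case (95 % unmutated clones) nearly unchanged; measured after
the round, the control case is unaffected and the holobiont speed-up
appears at its reported strength. "First crossing" always means the
first generation whose recorded mean host error is ≤ δ_A.

**Pretraining.** Microbial networks are pretrained standalone with the
same algorithm (control wiring, host rate; the host rate falls back to
0.001 when the coevolution run itself uses `μ_H = 0`, the γ = ∞ case)
until the best individual is strictly below δ_A; that individual joins
the holobiont with its counter reset and its pretraining initial
condition as its own fixed initial condition. Pretraining failures
(no success within 5000 generations) are retried with a derived
sub-seed.

**Evaluation scope.** In the specialized multitask scheme the
evaluation of a task silences the microbes outside the task's niche
(their cross-boundary regulator values read as 0), so each niche
assists exactly its own tasks (`evaluation_scope="host_plus_niche"`,
the default). This task-conditioning is what makes specialization
effective: microbes carry one fixed initial condition, so under the
alternative `full` scope (every microbe active in every task's
trajectory) microbial influence is identical across tasks and the
specialized and non-specialized schemes become empirically
indistinguishable. The `full` scope remains available for that
comparison.

**Disconnection.** The dysbiosis and diversity-loss experiments sever
cross-boundary links at evaluation time by reading the severed
regulator values as 0 (`freeze_zero`, reversible, the default); the
irreversible `excise` mode structurally removes the crossing edges via
the removal policy.

**Seeding.** All randomness derives from one master seed through named
child streams (master + CRC-labelled SeedSequence), so adding a
consumer never shifts the draws of another and every run is bit
reproducible.

## Default study conditions

| parameter | default | meaning |
|---|---|---|
| `n_nodes` (N) | 50 | nodes per network (a functional module's scale) |
| `in_degree` (K) | 2 | initial regulators per node (critical regime) |
| `n_signal` (Ns) | 12 | signal nodes defining R(t) |
| `t_max` | 15 | task length; typical transient length at K=2 |
| `population` (P) | 100 | holobionts per generation |
| `mu_host` | 0.001 | host mutation rate / node / generation |
| `mu_microbe` | 0.01 | microbial rate (γ = 10) |
| `delta_a` | 1.0 | adaptation threshold |
| `n_survivors` / copies | 10 / 9 | elitist selection and replication |
| `aggregation_mode` | eq5 | holobiont error used for selection |
| `k_max` | 10 | in-degree cap |

## Problem sizes used by the tests and the acceptance script

Full-scale single-task ensembles run quickly, so the test suite and
`scripts/acceptance.py` use the standard conditions directly: 10–20
replicates of control evolution (up to 4500 generations, stopping once
the error reaches 0.2) and of single-microbe holobiont evolution
(500 generations). Multitask ensembles are far heavier; the suite runs
them at the scaled preset `P = 30` (10 survivors × 2 copies): the
non-specialized/specialized `P_M = 10` contrast on 4 seeds
(500 / 300 generations) and specialized `P_M = 25` on 3 seeds, and the
diversity-loss sweep on a smaller specialized community (`T = 4`,
`P_M = 8`, 250 generations, 10 seeds, 5 random subsets per Δn). These
sizes are defaults of the shipped presets, not of the model.

## What the synthetic tasks do and do not emulate

Tasks are unconstrained jagged integer series; they stand in for
required gene-expression time courses without modelling any concrete
pathway. Uniform sampling makes task difficulty itself a random
variable: series that repeatedly visit values near 1 or `Ns − 1`
require near-unanimous signal-node states and are markedly harder than
mid-range curves, producing a heavy right tail in adaptation times.
Ensemble means over seeds are therefore systematically slower than a
single illustrative run of median difficulty — comparisons between
schemes (control vs holobiont vs specialized) are the robust
quantities, absolute crossing times are not. Passing tests show the
model's comparative claims hold under these conditions; they say
nothing about real regulatory networks, real microbiota, or any
specific organism.

## Known limitations

* Node counts are fixed: no gene duplication/deletion, recombination,
  or horizontal transfer of subnetworks; competition and parasitism
  are not modelled.
* Synchronous deterministic updates only (no asynchronous or noisy
  dynamics).
* The microbiota of the founder population consists of identical
  copies of one pretrained network per slot; microbial diversity
  arises only through subsequent mutation.
* The truth-table bookkeeping policies on in-degree change are
  conventions (documented above and configurable); the qualitative
  phenomena are robust to them but absolute adaptation speeds are not.
* `P_A` saturates in discrete jumps within a single population because
  selection keeps the population nearly clonal; smooth adaptation
  probabilities arise only as averages over replicate seeds.
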