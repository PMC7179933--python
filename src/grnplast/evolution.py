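"""Mutation-selection hill climbing of genomes toward target reaction norms.

The evolutionary engine is deliberately minimal: a single resident
lineage, one mutant per generation, and deterministic fixation when the
mutant's (optionally cost-regularised) fitness is at least the
resident's.  Unstable mutants are lethal and replaced by a fresh
mutation of the resident without consuming a generation.  Fitness is
the fraction of truth-table rows where the expressed phenotype matches
the target; with connection costs the selected quantity is

    W_t = W - lambda * CC,    CC in {mean |B|, mean B^2}  (L1 / L2).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np

from .dynamics import (
    DynamicsParams,
    Genome,
    TensorGenome,
    develop_batch,
    draw_initial_state,
)
from .logic import TruthTable, enumerate_environments

__all__ = [
    "EvolutionConfig",
    "TrainingTask",
    "EvolutionTrace",
    "fitness",
    "connection_cost",
    "total_fitness",
    "mutate",
    "evolve",
]


@dataclass(frozen=True)
class EvolutionConfig:
    """Knobs of the hill-climbing protocol.

    mutation_halfwidth   each mutated entry is perturbed by U(-h, +h)
    entry_mutation_prob  per-entry mutation probability; default 1/ng for
                         matrices and 1/ng^2 for tensors, so the expected
                         number of mutated entries is ng in both cases
    max_generations      generation cap of one run
    fitness_target       stop once raw W on the training rows reaches this
    drift_generations    extra generations of (neutral-drift-permitting)
                         selection after the fitness target is first hit;
                         lets the lineage settle into the bulk of the
                         equal-fitness region of genome space
    reg_mode             none / L1 / L2 connection cost
    lam                  weight of the connection cost in W_t
    unstable_redraw_cap  lethal-mutant redraws allowed per generation
    """

    mutation_halfwidth: float = 0.1
    entry_mutation_prob: Optional[float] = None
    max_generations: int = 10_000
    fitness_target: float = 1.0
    drift_generations: int = 0
    reg_mode: str = "none"
    lam: float = 0.0
    unstable_redraw_cap: int = 100

    def __post_init__(self) -> None:
        if self.entry_mutation_prob is not None and not (
            0.0 < self.entry_mutation_prob <= 1.0
        ):
            raise ValueError("entry_mutation_prob must be in (0, 1]")
        if self.lam < 0:
            raise ValueError("lambda must be non-negative")
        if self.reg_mode not in ("none", "L1", "L2"):
            raise ValueError(f"unknown reg_mode {self.reg_mode!r}")
        if not 0.0 <= self.fitness_target <= 1.0:
            raise ValueError("fitness_target must lie in [0, 1]")
        if self.drift_generations < 0:
            raise ValueError("drift_generations must be non-negative")

    def mutation_prob_for(self, genome: Genome) -> float:
        if self.entry_mutation_prob is not None:
            return self.entry_mutation_prob
        if isinstance(genome, TensorGenome):
            return 1.0 / genome.ng**2
        return 1.0 / genome.ng


@dataclass(frozen=True)
class TrainingTask:
    """A target reaction norm and the truth-table rows exposed to selection."""

    target: TruthTable
    training_rows: Optional[np.ndarray] = None  # default: every row

    def __post_init__(self) -> None:
        rows = self.training_rows
        if rows is None:
            rows = np.arange(self.target.n_rows, dtype=np.int64)
        else:
            rows = np.asarray(rows, dtype=np.int64)
            if rows.size == 0:
                raise ValueError("training_rows must be non-empty")
            if np.unique(rows).size != rows.size:
                raise ValueError("training_rows must not contain duplicates")
            if rows.min() < 0 or rows.max() >= self.target.n_rows:
                raise ValueError("training row index out of range")
        object.__setattr__(self, "training_rows", rows)

    @property
    def ts_size(self) -> int:
        return int(self.training_rows.size)


def fitness(
    phenotype: Union[TruthTable, np.ndarray],
    target: TruthTable,
    rows: Optional[Sequence[int]] = None,
) -> float:
    """Match fraction between a phenotype vector and the target.

    ``phenotype`` is either a full :class:`TruthTable` (then ``rows``
    selects the scored subset) or an output vector already restricted to
    ``rows`` (in the same order).
    """
    if rows is None:
        rows = np.arange(target.n_rows)
    else:
        rows = np.asarray(rows, dtype=np.int64)
    want = target.outputs[rows]
    if isinstance(phenotype, TruthTable):
        if phenotype.ne != target.ne:
            raise ValueError("phenotype and target must share ne")
        got = phenotype.outputs[rows]
    else:
        got = np.asarray(phenotype)
        if got.size != rows.size:
            raise ValueError("phenotype vector length must equal the row subset size")
    return float((got == want).sum()) / rows.size


def connection_cost(genome: Genome, mode: str) -> float:
    """Mean absolute (L1) or mean squared (L2) interaction strength."""
    w = genome.weights
    if mode == "L1":
        return float(np.abs(w).mean())
    if mode == "L2":
        return float((w**2).mean())
    raise ValueError(f"unknown connection-cost mode {mode!r}")


def total_fitness(wp: float, genome: Genome, config: EvolutionConfig) -> float:
    """W_t = W - lambda * CC; equals raw W when regularisation is off."""
    if config.reg_mode == "none" or config.lam == 0.0:
        return wp
    return wp - config.lam * connection_cost(genome, config.reg_mode)


def mutate(genome: Genome, config: EvolutionConfig, rng: np.random.Generator) -> Genome:
    """Perturb each entry independently with the per-entry probability.

    Perturbations are U(-h, +h) added to the entry, clamped to [-1, 1].
    A fixed number of RNG draws is consumed regardless of the mask, so
    mutant streams are reproducible from the seed alone.
    """
    p = config.mutation_prob_for(genome)
    w = genome.weights
    mask = rng.random(w.shape) < p
    nu = rng.uniform(-config.mutation_halfwidth, config.mutation_halfwidth, size=w.shape)
    new_w = np.clip(w + np.where(mask, nu, 0.0), -1.0, 1.0)
    out = genome.copy()
    if isinstance(out, TensorGenome):
        out.B3 = new_w
    else:
        out.B = new_w
    return out


@dataclass
class EvolutionTrace:
    """Per-generation record of one hill-climbing run."""

    fitness_history: list  # (generation, W, W_t, CC) of the resident
    generations_to_target: Optional[int]  # None when the target was not reached
    final_genome: Genome
    final_fitness: float
    reached: bool
    total_redraws: int
    init_g: Optional[np.ndarray] = None  # the run's frozen initial state
    aborted: bool = False  # redraw cap exhausted in some generation

    def generations_to_fitness(self, threshold: float) -> Optional[int]:
        """First generation at which resident W reached ``threshold``."""
        for gen, w, _, _ in self.fitness_history:
            if w >= threshold:
                return gen
        return None


def _training_phenotype(
    genome: Genome,
    train_envs: np.ndarray,
    params: DynamicsParams,
    rng: np.random.Generator,
    init_g: np.ndarray,
):
    results = develop_batch(genome, train_envs, params, rng, init_g=init_g)
    if not all(r.stable for r in results):
        return None
    return np.array([r.phenotype for r in results], dtype=np.int8)


def evolve(
    initial_genome: Genome,
    task: TrainingTask,
    params: DynamicsParams,
    config: EvolutionConfig,
    rng: np.random.Generator,
) -> EvolutionTrace:
    """Hill-climb from ``initial_genome`` toward the task's target.

    Per generation one mutant is proposed; mutants that are unstable in
    any training environment are lethal and redrawn (up to the redraw
    cap) without advancing the generation counter.  The mutant fixes iff
    its W_t is at least the resident's (ties accepted, allowing neutral
    drift).  The run stops ``config.drift_generations`` generations after
    raw W on the training rows first reaches ``config.fitness_target``
    (immediately when that is 0), or at ``config.max_generations``.

    Initial concentrations are drawn once per run and held constant
    across generations and environments (genomes are the only heritable,
    varying state); the frozen vector is returned as ``trace.init_g`` so
    post-training expression can reuse it.
    """
    if initial_genome.ne != task.target.ne:
        raise ValueError("genome and target disagree on the number of factors")
    envs = enumerate_environments(task.target.ne)
    train_envs = envs[task.training_rows]
    init_g = draw_initial_state(initial_genome, params, rng)

    resident = initial_genome.copy()
    pheno = _training_phenotype(resident, train_envs, params, rng, init_g)
    if pheno is None:
        raise ValueError("initial genome must develop stably in all training environments")
    w = fitness(pheno, task.target, task.training_rows)
    cc = connection_cost(resident, config.reg_mode) if config.reg_mode != "none" else 0.0
    wt = total_fitness(w, resident, config)

    history = [(0, w, wt, cc)]
    reached = w >= config.fitness_target
    gens_to_target = 0 if reached else None
    total_redraws = 0

    gen = 0
    while gen < config.max_generations:
        if reached and gen >= gens_to_target + config.drift_generations:
            break
        gen += 1
        mutant = None
        mut_pheno = None
        for _ in range(config.unstable_redraw_cap):
            candidate = mutate(resident, config, rng)
            cand_pheno = _training_phenotype(candidate, train_envs, params, rng, init_g)
            if cand_pheno is not None:
                mutant, mut_pheno = candidate, cand_pheno
                break
            total_redraws += 1
        if mutant is None:
            return EvolutionTrace(
                fitness_history=history,
                generations_to_target=None,
                final_genome=resident,
                final_fitness=w,
                reached=False,
                total_redraws=total_redraws,
                init_g=init_g,
                aborted=True,
            )
        wm = fitness(mut_pheno, task.target, task.training_rows)
        ccm = (
            connection_cost(mutant, config.reg_mode)
            if config.reg_mode != "none"
            else 0.0
        )
        wtm = total_fitness(wm, mutant, config)
        if wtm >= wt:
            resident, w, wt, cc = mutant, wm, wtm, ccm
        history.append((gen, w, wt, cc))
        if not reached and w >= config.fitness_target:
            reached = True
            gens_to_target = gen

    return EvolutionTrace(
        fitness_history=history,
        generations_to_target=gens_to_target,
        final_genome=resident,
        final_fitness=w,
        reached=reached,
        total_redraws=total_redraws,
        init_g=init_g,
    )
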