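"""Drivers for the five in-silico experiments.

1a/1b  evolvability of reaction norms versus the number of environmental
       factors, network size, target complexity, and genome kind
       (classical matrix vs second-order tensor);
2      unbiased scanning of random GRN space: how often each plasticity
       family arises and where in the (density, strength, size) space;
3      transition assays between complexity classes and the long-term
       class distribution implied by the transition likelihoods;
4a     generalisation from partial truth tables, with optional L1/L2
       connection costs;
4b     (see :mod:`grnplast.morphogen`) 2D morphogen-patterning
       demonstration.

Every driver derives all replicate randomness from a single master seed
via ``SeedSequence((master_seed, *key))`` and returns tidy DataFrames.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dynamics import (
    ClassicalGenome,
    DynamicsParams,
    TensorGenome,
    express_function,
    random_genome,
)
from .evolution import EvolutionConfig, TrainingTask, evolve, fitness
from .logic import (
    FunctionClass,
    OmegaConstraint,
    TruthTable,
    classify_function,
    complexity_omega,
    random_function,
)
from .seeds import rng_from

__all__ = [
    "ScanRecord",
    "TransitionMatrix",
    "exp1_evolvability",
    "exp2_scan",
    "exp3_transitions",
    "steady_state",
    "exp4a_generalise",
    "random_completion_matches",
]

#: Complexity classes used in the three-state transition analysis:
#: Omega = 0 (single-input), 0 < Omega < 1 (other linearly separable),
#: Omega = 1 (non-linearly separable).
DEFAULT_TRANSITION_CLASSES = (
    FunctionClass.SINGLE_INPUT,
    FunctionClass.LINEAR_OTHER,
    FunctionClass.NON_LINEAR,
)


def _empty_genome(kind: str, ng: int, ne: int):
    if kind == "classical":
        return ClassicalGenome.empty(ng, ne)
    if kind == "tensor":
        return TensorGenome.empty(ng, ne)
    raise ValueError(f"unknown genome kind {kind!r}")


# ---------------------------------------------------------------------------
# Experiment 1: evolvability curves
# ---------------------------------------------------------------------------


def exp1_evolvability(
    ne_values: Sequence[int],
    ng_values: Sequence[int],
    omega_constraints: Sequence[OmegaConstraint],
    replicates: int,
    params: Optional[DynamicsParams] = None,
    config: Optional[EvolutionConfig] = None,
    genome_kind: str = "classical",
    master_seed: int = 0,
    near_threshold: float = 0.9,
) -> pd.DataFrame:
    """Generations-to-target for every (ne, ng, constraint) cell.

    Each replicate starts from the empty network, draws a fresh target
    with the requested complexity constraint, and hill-climbs until the
    fitness target or the generation cap.  Returns one row per
    replicate with the generations needed to first reach
    ``near_threshold`` and the full fitness target.
    """
    params = params or DynamicsParams()
    config = config or EvolutionConfig()
    rows = []
    for ne in ne_values:
        for ng in ng_values:
            for ci, constraint in enumerate(omega_constraints):
                for rep in range(replicates):
                    rng = rng_from(master_seed, ne, ng, ci, rep)
                    target = random_function(ne, constraint, rng)
                    trace = evolve(
                        _empty_genome(genome_kind, ng, ne),
                        TrainingTask(target),
                        params,
                        config,
                        rng,
                    )
                    rows.append(
                        {
                            "ne": ne,
                            "ng": ng,
                            "constraint": str(constraint),
                            "genome_kind": genome_kind,
                            "replicate": rep,
                            "target_omega": complexity_omega(target).omega,
                            "generations_to_near": trace.generations_to_fitness(
                                near_threshold
                            ),
                            "generations_to_target": trace.generations_to_target,
                            "reached": trace.reached,
                            "final_fitness": trace.final_fitness,
                        }
                    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Experiment 2: random scanning of GRN space
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScanRecord:
    """One stable random GRN and the reaction norm it expresses."""

    ng: int
    density: float  # realised fraction of non-zero entries
    mean_abs_strength: float  # mean |B_ij| over the non-zero entries
    function_class: FunctionClass
    omega: float  # NaN for non-plastic networks


def exp2_scan(
    n_samples: int,
    master_seed: int = 0,
    ne: int = 2,
    ng_range: tuple = (4, 23),
    params: Optional[DynamicsParams] = None,
    max_resample: int = 1000,
) -> tuple:
    """Sample random GRNs and tally the plasticity families they express.

    Unstable genomes are resampled (and counted) so that the summary is
    over ``n_samples`` stable networks, mirroring viability selection.
    Returns ``(records DataFrame, summary dict)`` where the summary maps
    each :class:`FunctionClass` to its relative frequency and carries
    the unstable count.
    """
    params = params or DynamicsParams()
    lo, hi = ng_range
    records = []
    n_unstable = 0
    for i in range(n_samples):
        rng = rng_from(master_seed, i)
        for _ in range(max_resample):
            ng = int(rng.integers(lo, hi + 1))
            genome = random_genome(ng, rng, ne=ne)
            expressed = express_function(genome, params, rng)
            if expressed.stable:
                break
            n_unstable += 1
        else:
            raise RuntimeError("could not draw a stable genome within the cap")
        table = expressed.table
        nz = genome.B != 0
        records.append(
            ScanRecord(
                ng=ng,
                density=float(nz.mean()),
                mean_abs_strength=float(np.abs(genome.B[nz]).mean()) if nz.any() else 0.0,
                function_class=classify_function(table),
                omega=complexity_omega(table).omega,
            )
        )
    df = pd.DataFrame(
        {
            "ng": [r.ng for r in records],
            "density": [r.density for r in records],
            "mean_abs_strength": [r.mean_abs_strength for r in records],
            "function_class": [r.function_class.value for r in records],
            "omega": [r.omega for r in records],
        }
    )
    counts = df["function_class"].value_counts()
    summary = {
        fc: float(counts.get(fc.value, 0)) / n_samples for fc in FunctionClass
    }
    summary["n_unstable"] = n_unstable
    summary["n_samples"] = n_samples
    return df, summary


# ---------------------------------------------------------------------------
# Experiment 3: transition assays and the implied steady state
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionMatrix:
    """Estimated transition likelihoods between complexity classes.

    ``p[a, b]`` is the mean of 1/generations needed to re-evolve from a
    network trained on a class-``a`` target to a class-``b`` target
    (0 contributed by replicates that failed within the cap).
    """

    classes: tuple
    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=np.float64)
        if p.shape != (len(self.classes), len(self.classes)):
            raise ValueError("p must be square over the class list")
        if (p < 0).any():
            raise ValueError("transition likelihoods must be non-negative")
        object.__setattr__(self, "p", p)


def exp3_transitions(
    replicates: int,
    classes: Sequence[FunctionClass] = DEFAULT_TRANSITION_CLASSES,
    ne: int = 2,
    ng: int = 8,
    params: Optional[DynamicsParams] = None,
    config: Optional[EvolutionConfig] = None,
    master_seed: int = 0,
) -> tuple:
    """Estimate p(a -> b) for every ordered pair of complexity classes.

    Per class ``a`` and replicate, one network is trained from the empty
    genome until it expresses a random class-``a`` target perfectly;
    clones of that same trained network are then re-evolved toward a
    random target of every class ``b``, and the inverse of the number of
    generations the second phase needs (1/max(gens, 1)) estimates the
    ``a -> b`` transition likelihood.  Phases that fail within the
    generation cap contribute 0.  Returns ``(TransitionMatrix, detail
    DataFrame)``.
    """
    params = params or DynamicsParams()
    config = config or EvolutionConfig()
    classes = tuple(classes)
    k = len(classes)
    p = np.zeros((k, k))
    rows = []
    for ai, ca in enumerate(classes):
        vals = [[] for _ in range(k)]
        for rep in range(replicates):
            rng = rng_from(master_seed, ai, rep)
            target_a = random_function(ne, ca, rng)
            trained = evolve(
                _empty_genome("classical", ng, ne),
                TrainingTask(target_a),
                params,
                config,
                rng,
            )
            if not trained.reached:
                for bi, cb in enumerate(classes):
                    vals[bi].append(0.0)
                    rows.append(
                        {"from": ca.value, "to": cb.value, "replicate": rep,
                         "phase": "train", "generations": None, "likelihood": 0.0}
                    )
                continue
            for bi, cb in enumerate(classes):
                rng_b = rng_from(master_seed, ai, rep, bi)
                target_b = random_function(ne, cb, rng_b)
                if ca == cb:
                    # within-class transitions are between *different*
                    # functions of that class
                    for _ in range(100):
                        if target_b != target_a:
                            break
                        target_b = random_function(ne, cb, rng_b)
                retrace = evolve(
                    trained.final_genome.copy(),
                    TrainingTask(target_b),
                    params,
                    config,
                    rng_b,
                )
                if retrace.reached:
                    gens = retrace.generations_to_target
                    lik = 1.0 / max(gens, 1)
                else:
                    gens, lik = None, 0.0
                vals[bi].append(lik)
                rows.append(
                    {"from": ca.value, "to": cb.value, "replicate": rep,
                     "phase": "transition", "generations": gens, "likelihood": lik}
                )
        for bi in range(k):
            p[ai, bi] = float(np.mean(vals[bi]))
    return TransitionMatrix(classes, p), pd.DataFrame(rows)


def steady_state(
    tm: TransitionMatrix,
    init: Optional[np.ndarray] = None,
    dt: float = 0.1,
    tol: float = 1e-9,
    max_iter: int = 1_000_000,
) -> np.ndarray:
    """Long-term class-frequency distribution implied by the transitions.

    Iterates the flow  x_i <- x_i + dt * sum_j p(j -> i) x_j  followed
    by renormalisation of the frequency vector each step, until the
    largest change is below ``tol``.  The fixed point is the dominant
    eigenvector of the transition matrix, so the result is invariant to
    uniform rescaling of the matrix.
    """
    k = len(tm.classes)
    x = np.full(k, 1.0 / k) if init is None else np.asarray(init, dtype=np.float64)
    if x.shape != (k,) or (x < 0).any() or x.sum() == 0:
        raise ValueError("init must be a non-negative frequency vector over the classes")
    x = x / x.sum()
    if not tm.p.any():
        warnings.warn("zero transition matrix: returning the initial frequencies")
        return x
    flow = tm.p.T  # flow[i, j] = p(class_j -> class_i)
    for _ in range(max_iter):
        x_new = x + dt * (flow @ x)
        x_new /= x_new.sum()
        if np.abs(x_new - x).max() < tol:
            return x_new
        x = x_new
    return x


# ---------------------------------------------------------------------------
# Experiment 4a: generalisation from partial truth tables
# ---------------------------------------------------------------------------


def exp4a_generalise(
    omega_constraint: OmegaConstraint,
    ts_size: int,
    replicates: int,
    ne: int = 3,
    ng: int = 12,
    lam: float = 0.0,
    reg_mode: str = "none",
    params: Optional[DynamicsParams] = None,
    config: Optional[EvolutionConfig] = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Train on ``ts_size`` random rows, then score the full reaction norm.

    Per replicate: draw a target with the requested complexity, train
    from the empty network on a random row subset until the maximum
    training fitness (or the generation cap), then express the full
    function and count matches over all ``2**ne`` rows.  The random-
    completion expectation for the unseen rows is ``(2**ne - TS)/2``
    total matches beyond the training rows.
    """
    params = params or DynamicsParams()
    base = config or EvolutionConfig()
    if not 1 <= ts_size <= 2**ne:
        raise ValueError(f"ts_size must be in [1, {2**ne}]")
    config = EvolutionConfig(
        mutation_halfwidth=base.mutation_halfwidth,
        entry_mutation_prob=base.entry_mutation_prob,
        max_generations=base.max_generations,
        fitness_target=base.fitness_target,
        drift_generations=base.drift_generations,
        reg_mode=reg_mode,
        lam=lam,
        unstable_redraw_cap=base.unstable_redraw_cap,
    )
    n_rows = 2**ne
    rows = []
    for rep in range(replicates):
        rng = rng_from(master_seed, rep)
        target = random_function(ne, omega_constraint, rng)
        train_rows = rng.choice(n_rows, size=ts_size, replace=False)
        task = TrainingTask(target, train_rows)
        trace = evolve(_empty_genome("classical", ng, ne), task, params, config, rng)
        expressed = express_function(
            trace.final_genome, params, rng, init_g=trace.init_g
        )
        if expressed.stable:
            total = fitness(expressed.table, target) * n_rows
            train = fitness(expressed.table, target, train_rows) * ts_size
        else:
            # unstable in a novel environment: score only the stable rows
            match = expressed.outputs == target.outputs
            total = float(match.sum())
            train = float(match[train_rows].sum())
        rows.append(
            {
                "replicate": rep,
                "ts_size": ts_size,
                "lambda": lam,
                "reg_mode": reg_mode,
                "target_omega": complexity_omega(target).omega,
                "train_matches": train,
                "total_matches": total,
                "unseen_matches": total - train,
                "train_reached": trace.reached,
                "random_unseen_expectation": (n_rows - ts_size) / 2.0,
            }
        )
    return pd.DataFrame(rows)


def random_completion_matches(
    target: TruthTable,
    ts_size: int,
    replicates: int,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Unbiased control: complete unseen rows uniformly at random.

    The training rows are reproduced exactly; every unseen row is +1 or
    -1 with equal probability.  The mean unseen-row matches converge to
    the ``(2**ne - TS)/2`` chance baseline.
    """
    n_rows = target.n_rows
    if not 0 <= ts_size <= n_rows:
        raise ValueError(f"ts_size must be in [0, {n_rows}]")
    rows = []
    for rep in range(replicates):
        rng = rng_from(master_seed, rep)
        train_rows = rng.choice(n_rows, size=ts_size, replace=False)
        outputs = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_rows)
        outputs[train_rows] = target.outputs[train_rows]
        match = outputs == target.outputs
        rows.append(
            {
                "replicate": rep,
                "ts_size": ts_size,
                "total_matches": float(match.sum()),
                "unseen_matches": float(match.sum()) - ts_size,
                "random_unseen_expectation": (n_rows - ts_size) / 2.0,
            }
        )
    return pd.DataFrame(rows)
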