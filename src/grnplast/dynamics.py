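"""Continuous GRN development and binary phenotype readout.

A genome is a signed interaction matrix ``B`` (classical model) or a
third-order tensor ``B3`` (second-order model, where gene products and
environmental factors modulate interaction strengths).  Development
integrates

    dg_i/dt = R(h_i) / (K_M + R(h_i)) - mu * g_i,

with the Ramp function R keeping concentrations non-negative, from
noisy initial conditions (g_i = 0.1 + xi, xi ~ U(-1e-2, 1e-2)) until a
steady state or a step cap.  The binary cell phenotype is +1 when the
final concentration of the gene of interest reaches the readout
threshold, and -1 otherwise.

The regulatory input of gene i is

    classical:  h_i = sum_j B_ij g_j + EF_i          (only for i < ne)
    tensor:     h_i = sum_j g_j sum_k B3_ijk (g_k + EF_k [k < ne])

i.e. each environmental factor targets exactly one gene (classical) or
modulates interaction strengths (second-order).  Gene indices are
0-based: genes 0..ne-1 are environmentally sensitive, and ``goi`` must
be one of the remaining genes.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from . import _kernels
from .logic import TruthTable, enumerate_environments

__all__ = [
    "ClassicalGenome",
    "TensorGenome",
    "Genome",
    "DynamicsParams",
    "DevelopmentResult",
    "ExpressedFunction",
    "regulatory_input",
    "regulatory_input_tensor",
    "develop",
    "develop_batch",
    "draw_initial_state",
    "express_function",
    "random_genome",
]


def _check_indices(ng: int, ne: int, goi: int) -> None:
    if ng < 1:
        raise ValueError("ng must be positive")
    if not 0 <= ne <= ng:
        raise ValueError(f"need 0 <= ne <= ng, got ne={ne}, ng={ng}")
    if not 0 <= goi < ng:
        raise ValueError(f"goi must be a gene index in [0, {ng - 1}]")
    if goi < ne:
        raise ValueError("the gene of interest cannot be environmentally sensitive")


@dataclass
class ClassicalGenome:
    """Heritable regulatory matrix: B[i, j] = effect of gene j on gene i."""

    ng: int
    ne: int
    goi: int
    B: np.ndarray

    def __post_init__(self) -> None:
        _check_indices(self.ng, self.ne, self.goi)
        B = np.asarray(self.B, dtype=np.float64)
        if B.shape != (self.ng, self.ng):
            raise ValueError(f"B must be ({self.ng}, {self.ng}), got {B.shape}")
        if np.abs(B).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("interaction strengths must lie in [-1, 1]")
        self.B = B

    @classmethod
    def empty(cls, ng: int, ne: int = 2, goi: Optional[int] = None) -> "ClassicalGenome":
        """The ancestral 'empty network' with no regulatory interactions."""
        if goi is None:
            goi = ne
        return cls(ng, ne, goi, np.zeros((ng, ng)))

    def copy(self) -> "ClassicalGenome":
        return replace(self, B=self.B.copy())

    @property
    def weights(self) -> np.ndarray:
        return self.B


@dataclass
class TensorGenome:
    """Second-order genome: B3[i, j, k] = gene k's contribution to j -> i."""

    ng: int
    ne: int
    goi: int
    B3: np.ndarray

    def __post_init__(self) -> None:
        _check_indices(self.ng, self.ne, self.goi)
        B3 = np.asarray(self.B3, dtype=np.float64)
        if B3.shape != (self.ng, self.ng, self.ng):
            raise ValueError(
                f"B3 must be ({self.ng}, {self.ng}, {self.ng}), got {B3.shape}"
            )
        if np.abs(B3).max(initial=0.0) > 1.0 + 1e-12:
            raise ValueError("interaction strengths must lie in [-1, 1]")
        self.B3 = B3

    @classmethod
    def empty(cls, ng: int, ne: int = 2, goi: Optional[int] = None) -> "TensorGenome":
        if goi is None:
            goi = ne
        return cls(ng, ne, goi, np.zeros((ng, ng, ng)))

    def copy(self) -> "TensorGenome":
        return replace(self, B3=self.B3.copy())

    @property
    def weights(self) -> np.ndarray:
        return self.B3


Genome = Union[ClassicalGenome, TensorGenome]


@dataclass(frozen=True)
class DynamicsParams:
    """Parameters of the developmental integration.

    mu               decay rate of every gene product (per time unit)
    km               Michaelis-Menten saturation coefficient
    dt               Euler step
    max_steps        integration cap in Euler steps; hitting it without
                     a steady state flags the genome unstable (lethal)
    stability_window steps between compared concentration snapshots
    stability_tol    steady state when, for every gene, |delta g_i| over
                     one window is <= tol * max(g_i, stability_floor)
    stability_floor  scale floor of the per-gene stability test; set at
                     the phenotype threshold so a gene still drifting
                     through the readout region is never frozen early
    init_base        initial concentration of every gene
    init_noise       half-width of the uniform initial-condition noise
    pheno_threshold  g_goi at or above this reads out as phenotype +1
    """

    mu: float = 0.1
    km: float = 1.0
    dt: float = 1e-2
    max_steps: int = 1_000_000
    stability_window: int = 1000
    stability_tol: float = 0.01
    stability_floor: float = 1e-2
    init_base: float = 0.1
    init_noise: float = 1e-2
    pheno_threshold: float = 1e-2

    def __post_init__(self) -> None:
        for name in ("mu", "km", "dt", "max_steps", "stability_window",
                     "stability_tol", "stability_floor", "init_base", "init_noise",
                     "pheno_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.stability_tol >= 1:
            raise ValueError("stability_tol must be < 1")
        if self.init_noise >= self.init_base:
            raise ValueError("init_noise must be smaller than init_base")


@dataclass(frozen=True)
class DevelopmentResult:
    """Outcome of one developmental integration in one environment."""

    stable: bool
    steps_used: int
    g_final: np.ndarray
    phenotype: int  # +1 / -1; 0 marks an invalid (unstable) readout
    g_min: float  # smallest concentration seen during integration


def _validate_env(env: Sequence[int], ne: int) -> np.ndarray:
    env = np.asarray(env, dtype=np.float64).ravel()
    if env.size != ne:
        raise ValueError(f"environment must have length ne={ne}, got {env.size}")
    if env.size and not np.isin(env, (-1.0, 1.0)).all():
        raise ValueError("environment entries must be -1 or +1")
    return env


def regulatory_input(
    genome: ClassicalGenome, g: Sequence[float], env: Sequence[int], gene_index: int
) -> float:
    """h_i for the classical model at concentrations ``g`` (0-based gene)."""
    if not 0 <= gene_index < genome.ng:
        raise ValueError(f"gene_index must be in [0, {genome.ng - 1}]")
    g = np.asarray(g, dtype=np.float64)
    env = _validate_env(env, genome.ne)
    h = float(genome.B[gene_index] @ g)
    if gene_index < genome.ne:
        h += float(env[gene_index])
    return h


def regulatory_input_tensor(
    genome: TensorGenome, g: Sequence[float], env: Sequence[int], gene_index: int
) -> float:
    """h_i for the second-order model: EFs modulate interaction strengths."""
    if not 0 <= gene_index < genome.ng:
        raise ValueError(f"gene_index must be in [0, {genome.ng - 1}]")
    g = np.asarray(g, dtype=np.float64)
    env = _validate_env(env, genome.ne)
    u = g.copy()
    u[: genome.ne] += env
    return float(g @ (genome.B3[gene_index] @ u))


def _env_matrix(genome: Genome, envs: np.ndarray) -> np.ndarray:
    """Per-gene environmental terms, zero beyond the sensitive genes."""
    n_env = envs.shape[0]
    padded = np.zeros((n_env, genome.ng))
    if genome.ne:
        padded[:, : genome.ne] = envs
    return padded


def draw_initial_state(
    genome: Genome, params: DynamicsParams, rng: np.random.Generator
) -> np.ndarray:
    """One noisy initial concentration vector, g_i = base + U(-noise, noise)."""
    return params.init_base + rng.uniform(
        -params.init_noise, params.init_noise, size=genome.ng
    )


def develop_batch(
    genome: Genome,
    envs: np.ndarray,
    params: DynamicsParams,
    rng: np.random.Generator,
    init_g: Optional[np.ndarray] = None,
) -> list[DevelopmentResult]:
    """Develop the genome once in each environment.

    By default every development draws fresh initial noise; passing
    ``init_g`` (an ``(ng,)`` vector) starts every environment from that
    exact state instead, as the evolutionary engine does to keep the
    initial conditions constant within a run.
    """
    envs = np.atleast_2d(np.asarray(envs, dtype=np.float64))
    if envs.shape[1] != genome.ne:
        raise ValueError(
            f"environments must have {genome.ne} columns, got {envs.shape[1]}"
        )
    n_env = envs.shape[0]
    if init_g is not None:
        init_g = np.asarray(init_g, dtype=np.float64)
        if init_g.shape != (genome.ng,):
            raise ValueError(f"init_g must have shape ({genome.ng},)")
        g0 = np.tile(init_g, (n_env, 1))
    else:
        g0 = params.init_base + rng.uniform(
            -params.init_noise, params.init_noise, size=(n_env, genome.ng)
        )
    ef = _env_matrix(genome, envs)
    if isinstance(genome, ClassicalGenome):
        stable, steps, g_min = _kernels.integrate_classical(
            genome.B, ef, g0, params.mu, params.km, params.dt,
            params.max_steps, params.stability_window, params.stability_tol,
            params.stability_floor,
        )
    else:
        stable, steps, g_min = _kernels.integrate_tensor(
            genome.B3, ef, g0, params.mu, params.km, params.dt,
            params.max_steps, params.stability_window, params.stability_tol,
            params.stability_floor,
        )
    results = []
    for e in range(n_env):
        if stable[e]:
            pheno = 1 if g0[e, genome.goi] >= params.pheno_threshold else -1
        else:
            pheno = 0
        results.append(
            DevelopmentResult(bool(stable[e]), int(steps[e]), g0[e].copy(),
                              pheno, float(g_min[e]))
        )
    return results


def develop(
    genome: Genome,
    env: Sequence[int],
    params: DynamicsParams,
    rng: np.random.Generator,
    init_g: Optional[np.ndarray] = None,
) -> DevelopmentResult:
    """Run one development in one environment."""
    env = _validate_env(env, genome.ne)
    return develop_batch(genome, env.reshape(1, -1), params, rng, init_g=init_g)[0]


@dataclass(frozen=True)
class ExpressedFunction:
    """The reaction norm a genome expresses over a set of table rows."""

    ne: int
    rows: np.ndarray  # row indices of the full truth table
    outputs: np.ndarray  # +1/-1 per row; 0 where development was unstable
    stable: bool  # every requested environment stabilised

    @property
    def table(self) -> Optional[TruthTable]:
        """The full truth table, or None if partial or unstable."""
        if not self.stable or self.rows.size != 2**self.ne:
            return None
        return TruthTable(self.ne, self.outputs.astype(np.int8))


def express_function(
    genome: Genome,
    params: DynamicsParams,
    rng: np.random.Generator,
    rows: Optional[Sequence[int]] = None,
    init_g: Optional[np.ndarray] = None,
) -> ExpressedFunction:
    """Develop the genome in each requested environment and collect outputs.

    ``rows`` selects truth-table rows (default: all ``2**ne``).  Each
    development draws fresh initial noise unless ``init_g`` pins the
    initial state.  If any environment fails to stabilise the result is
    flagged unstable.
    """
    if genome.ne < 1:
        raise ValueError("express_function requires at least one environmental factor")
    envs = enumerate_environments(genome.ne)
    if rows is None:
        rows = np.arange(envs.shape[0])
    else:
        rows = np.asarray(rows, dtype=np.int64)
        if rows.size == 0 or np.unique(rows).size != rows.size:
            raise ValueError("rows must be non-empty and free of duplicates")
        if rows.min() < 0 or rows.max() >= envs.shape[0]:
            raise ValueError("row index out of range")
    results = develop_batch(genome, envs[rows], params, rng, init_g=init_g)
    outputs = np.array([r.phenotype for r in results], dtype=np.int8)
    return ExpressedFunction(
        ne=genome.ne,
        rows=rows,
        outputs=outputs,
        stable=all(r.stable for r in results),
    )


def random_genome(
    ng: int,
    rng: np.random.Generator,
    ne: int = 2,
    goi: Optional[int] = None,
    sigma: float = 0.1,
) -> ClassicalGenome:
    """Draw a random classical genome for unbiased GRN-space scanning.

    One connection density p ~ U(0,1) and one mean m ~ U(-1,1) are drawn
    per genome; each entry is non-zero with probability p, with value
    Normal(m, sigma) clamped to [-1, 1].  Drawing the mean per genome
    (rather than per entry) keeps the realised mean strengths from
    collapsing to a narrow band and spreads genomes across the whole
    (density, strength) plane.
    """
    if ng < ne + 1:
        raise ValueError(f"need ng >= ne + 1 = {ne + 1} (env genes plus goi)")
    density = rng.uniform(0.0, 1.0)
    mean = rng.uniform(-1.0, 1.0)
    mask = rng.random((ng, ng)) < density
    values = rng.normal(mean, sigma, size=(ng, ng))
    B = np.where(mask, np.clip(values, -1.0, 1.0), 0.0)
    if goi is None:
        goi = ne
    return ClassicalGenome(ng=ng, ne=ne, goi=goi, B=B)
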