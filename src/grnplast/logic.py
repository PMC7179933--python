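"""Boolean reaction norms and their information-theoretic complexity.

A multi-dimensional reaction norm maps combinations of ``ne`` binary
environmental factors (EF_i = +1 present, -1 absent) to a binary cell
phenotype.  Each such map is a Boolean function, summarised by a truth
table of ``2**ne`` rows.  This module represents those tables, measures
their complexity Omega,

    Omega = 1 - max_i I(P, EF_i) / H(P),

where ``P`` is the output column under the uniform environment
distribution and ``I`` is mutual information in bits, and classifies
functions into non-plastic / single-input / other linearly separable /
non-linearly separable families.

Row-ordering convention (fixed package-wide): row index ``r`` encodes
the environment where EF_i = +1 iff bit ``i`` of ``r`` is set, with the
least-significant bit corresponding to EF_1 (input index 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Callable, Iterable, Sequence, Union

import numpy as np

__all__ = [
    "MAX_NE",
    "FunctionClass",
    "TruthTable",
    "OmegaReport",
    "enumerate_environments",
    "mutual_information",
    "complexity_omega",
    "is_linearly_separable",
    "classify_function",
    "class_distribution",
    "random_function",
]

#: Largest supported number of environmental factors (2**16-row tables).
MAX_NE = 16

#: Largest ``ne`` for which exhaustive function enumeration is feasible.
MAX_NE_EXHAUSTIVE = 4

# Muroga's bound on minimal integer weights of threshold functions,
# ceil((n+1)^((n+1)/2) / 2^n): enough to enumerate every linearly
# separable function of n <= 4 inputs on an integer weight grid.
_WEIGHT_BOUND = {1: 1, 2: 2, 3: 2, 4: 4}


class FunctionClass(str, Enum):
    """Four-way classification of a Boolean plasticity function."""

    NON_PLASTIC = "non_plastic"  # constant output: no plasticity at all
    SINGLE_INPUT = "single_input"  # output equals EF_i or NOT EF_i
    LINEAR_OTHER = "linear_other"  # linearly separable, multi-input
    NON_LINEAR = "non_linear"  # not linearly separable (XOR-like)


def enumerate_environments(ne: int) -> np.ndarray:
    """All ``2**ne`` environments in the package's fixed row order.

    Returns an ``(2**ne, ne)`` int8 array with entries in {-1, +1};
    row ``r`` has EF_i = +1 iff bit ``i`` of ``r`` is set (LSB = EF_1).
    """
    if not 1 <= ne <= MAX_NE:
        raise ValueError(f"ne must be in [1, {MAX_NE}], got {ne}")
    rows = np.arange(2**ne, dtype=np.int64)
    bits = (rows[:, None] >> np.arange(ne)) & 1
    return (2 * bits - 1).astype(np.int8)


def _as_pm1(values: Iterable[int]) -> np.ndarray:
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values)
    arr = arr.astype(np.int8)
    if arr.ndim != 1 or not np.isin(arr, (-1, 1)).all():
        raise ValueError("outputs must be a 1-D vector with entries in {-1, +1}")
    return arr


@dataclass(frozen=True)
class TruthTable:
    """A complete multi-dimensional reaction norm over ``2**ne`` environments."""

    ne: int
    outputs: np.ndarray = field(hash=False)

    def __post_init__(self) -> None:
        if not 1 <= self.ne <= MAX_NE:
            raise ValueError(f"ne must be in [1, {MAX_NE}], got {self.ne}")
        out = _as_pm1(self.outputs)
        if out.size != 2**self.ne:
            raise ValueError(
                f"outputs must have length 2**ne = {2**self.ne}, got {out.size}"
            )
        out.setflags(write=False)
        object.__setattr__(self, "outputs", out)

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_callable(cls, ne: int, fn: Callable[..., int]) -> "TruthTable":
        """Build a table by evaluating ``fn(*env)`` on every environment.

        ``fn`` receives ``ne`` arguments in {-1, +1} and must return a
        truthy value (mapped to +1) or a falsy/-1 value (mapped to -1).
        """
        envs = enumerate_environments(ne)
        outs = []
        for env in envs:
            val = fn(*(int(v) for v in env))
            outs.append(1 if (val is True or val == 1) else -1)
        return cls(ne, np.array(outs, dtype=np.int8))

    @classmethod
    def constant(cls, ne: int, value: int) -> "TruthTable":
        return cls(ne, np.full(2**ne, value, dtype=np.int8))

    @classmethod
    def single_input(cls, ne: int, input_index: int, negated: bool = False) -> "TruthTable":
        """The identity (or negated identity) function on one input."""
        envs = enumerate_environments(ne)
        col = envs[:, input_index].astype(np.int8)
        return cls(ne, -col if negated else col)

    # -- views -------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return 2**self.ne

    def environments(self) -> np.ndarray:
        return enumerate_environments(self.ne)

    def row_index(self, env: Sequence[int]) -> int:
        """Row of this table corresponding to an environment vector."""
        env = _as_pm1(env)
        if env.size != self.ne:
            raise ValueError(f"environment must have length {self.ne}")
        bits = (env > 0).astype(np.int64)
        return int((bits << np.arange(self.ne)).sum())

    def negate(self) -> "TruthTable":
        return TruthTable(self.ne, -self.outputs)

    def permute_inputs(self, perm: Sequence[int]) -> "TruthTable":
        """Relabel the inputs: new input ``i`` is old input ``perm[i]``."""
        envs = enumerate_environments(self.ne)
        new_out = np.empty_like(self.outputs)
        for r, env in enumerate(envs):
            old_env = np.empty(self.ne, dtype=np.int8)
            for i, p in enumerate(perm):
                old_env[p] = env[i]
            new_out[r] = self.outputs[self.row_index(old_env)]
        return TruthTable(self.ne, new_out)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TruthTable):
            return NotImplemented
        return self.ne == other.ne and np.array_equal(self.outputs, other.outputs)


# Common named two-input tables, mostly for interactive use and docs.
def named_table(name: str, ne: int = 2) -> TruthTable:
    """Standard logic gates (AND/OR/XOR/XNOR/NAND/NOR) as truth tables."""
    gates = {
        "AND": lambda *e: all(v > 0 for v in e),
        "OR": lambda *e: any(v > 0 for v in e),
        "XOR": lambda *e: (sum(v > 0 for v in e) % 2) == 1,
        "XNOR": lambda *e: (sum(v > 0 for v in e) % 2) == 0,
        "NAND": lambda *e: not all(v > 0 for v in e),
        "NOR": lambda *e: not any(v > 0 for v in e),
    }
    try:
        fn = gates[name.upper()]
    except KeyError as exc:
        raise ValueError(f"unknown gate {name!r}; choose from {sorted(gates)}") from exc
    return TruthTable.from_callable(ne, fn)


# ---------------------------------------------------------------------------
# Entropies and Omega
# ---------------------------------------------------------------------------


def _entropy_from_counts(counts: np.ndarray) -> float:
    """Shannon entropy in bits of a discrete distribution given by counts."""
    total = counts.sum()
    h = 0.0
    for c in counts.ravel():
        if c > 0:
            p = c / total
            h -= p * math.log2(p)
    return h


def output_entropy(table: TruthTable) -> float:
    """H(P) in bits, with P uniform over the table's rows."""
    n_pos = int((table.outputs == 1).sum())
    return _entropy_from_counts(np.array([n_pos, table.n_rows - n_pos]))


def mutual_information(table: TruthTable, input_index: int) -> float:
    """I(P, EF_i) in bits under the uniform distribution over rows.

    ``input_index`` is 0-based (input 0 is EF_1).  Computed as
    H(P) + H(EF_i) - H(P, EF_i); by construction H(EF_i) = 1 bit.
    """
    if not 0 <= input_index < table.ne:
        raise ValueError(
            f"input_index must be in [0, {table.ne - 1}], got {input_index}"
        )
    envs = enumerate_environments(table.ne)
    ef = envs[:, input_index]
    out = table.outputs
    joint = np.array(
        [
            [int(((out == o) & (ef == e)).sum()) for e in (-1, 1)]
            for o in (-1, 1)
        ]
    )
    h_p = _entropy_from_counts(joint.sum(axis=1))
    h_e = _entropy_from_counts(joint.sum(axis=0))
    h_pe = _entropy_from_counts(joint)
    mi = h_p + h_e - h_pe
    return max(mi, 0.0)  # clip tiny negative round-off


@dataclass(frozen=True)
class OmegaReport:
    """Complexity of a reaction norm and the quantities behind it."""

    output_entropy: float
    per_input_mi: np.ndarray
    omega: float  # NaN when not defined
    defined: bool


def complexity_omega(
    table: TruthTable, constant_policy: str = "undefined"
) -> OmegaReport:
    """Complexity Omega = 1 - max_i I(P, EF_i) / H(P).

    Constant (non-plastic) tables have H(P) = 0 and Omega is not
    determined; ``constant_policy`` selects the reported value:
    ``"undefined"`` (default; ``omega`` is NaN, ``defined`` False) or
    ``"zero"`` (Omega = 0, the convention used when non-plastic
    functions are pooled with Omega = 0 functions).
    """
    if constant_policy not in ("undefined", "zero"):
        raise ValueError(f"unknown constant_policy {constant_policy!r}")
    h_p = output_entropy(table)
    mi = np.array([mutual_information(table, i) for i in range(table.ne)])
    if h_p == 0.0:
        omega = 0.0 if constant_policy == "zero" else math.nan
        return OmegaReport(0.0, mi, omega, defined=False)
    omega = 1.0 - mi.max() / h_p
    omega = min(max(omega, 0.0), 1.0)  # clip round-off at the boundaries
    return OmegaReport(h_p, mi, omega, defined=True)


# ---------------------------------------------------------------------------
# Linear separability and function classes
# ---------------------------------------------------------------------------


def is_linearly_separable(
    table: TruthTable, max_updates: int = 10_000, method: str = "auto"
) -> bool:
    """Whether the table is a threshold function of its +-1 inputs.

    ``method="enumeration"`` checks membership in the exhaustively
    enumerated set of threshold functions (exact, ne <= 4).
    ``method="perceptron"`` runs the perceptron rule with a hard update
    cap: convergence is guaranteed iff the function is separable, so
    exhausting the cap is read as non-separable.  ``"auto"`` picks
    enumeration when available.
    """
    if method == "auto":
        method = "enumeration" if table.ne <= MAX_NE_EXHAUSTIVE else "perceptron"
    if method == "enumeration":
        if table.ne > MAX_NE_EXHAUSTIVE:
            raise ValueError("enumeration method requires ne <= 4")
        sig = _outputs_signature(table.outputs)
        return sig in _separable_signatures(table.ne)
    if method != "perceptron":
        raise ValueError(f"unknown method {method!r}")
    envs = enumerate_environments(table.ne).astype(np.float64)
    x = np.hstack([envs, np.ones((envs.shape[0], 1))])  # bias column
    y = table.outputs.astype(np.float64)
    w = np.zeros(table.ne + 1)
    updates = 0
    while updates < max_updates:
        scores = y * (x @ w)
        wrong = np.nonzero(scores <= 0)[0]
        if wrong.size == 0:
            return True
        r = int(wrong[0])
        w += y[r] * x[r]
        updates += 1
    return False


def _outputs_signature(outputs: np.ndarray) -> bytes:
    return (outputs > 0).astype(np.uint8).tobytes()


@lru_cache(maxsize=None)
def _separable_signatures(ne: int) -> frozenset:
    """Signatures of every threshold function of ``ne`` inputs (ne <= 4).

    Enumerates sign(w . x + b) over the integer weight grid given by
    Muroga's bound, with half-integer biases so no row ever sits on the
    boundary.
    """
    bound = _WEIGHT_BOUND[ne]
    envs = enumerate_environments(ne).astype(np.float64)
    axes = [np.arange(-bound, bound + 1, dtype=np.float64)] * ne
    weights = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, ne)
    max_dot = ne * bound
    biases = np.arange(-max_dot - 0.5, max_dot + 1.0, 1.0)
    scores = weights @ envs.T  # (n_weights, 2**ne)
    sigs = set()
    for b in biases:
        outs = scores + b > 0
        for row in outs.astype(np.uint8):
            sigs.add(row.tobytes())
    return frozenset(sigs)


def _single_input_signatures(ne: int) -> set:
    sigs = set()
    for i in range(ne):
        for neg in (False, True):
            sigs.add(_outputs_signature(TruthTable.single_input(ne, i, neg).outputs))
    return sigs


def classify_function(table: TruthTable, method: str = "auto") -> FunctionClass:
    """Classify a table into the four plasticity families."""
    out = table.outputs
    if (out == out[0]).all():
        return FunctionClass.NON_PLASTIC
    if _outputs_signature(out) in _single_input_signatures(table.ne):
        return FunctionClass.SINGLE_INPUT
    if is_linearly_separable(table, method=method):
        return FunctionClass.LINEAR_OTHER
    return FunctionClass.NON_LINEAR


# ---------------------------------------------------------------------------
# Exhaustive enumeration and sampling
# ---------------------------------------------------------------------------


@lru_cache(maxsize=None)
def _function_space(ne: int):
    """All ``2**2**ne`` tables with their class label and Omega (NaN if undefined)."""
    if not 1 <= ne <= MAX_NE_EXHAUSTIVE:
        raise ValueError(f"exhaustive enumeration requires ne <= {MAX_NE_EXHAUSTIVE}")
    n_rows = 2**ne
    n_fn = 2**n_rows
    codes = np.arange(n_fn, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n_rows)) & 1
    outputs = (2 * bits - 1).astype(np.int8)  # (n_fn, n_rows)
    classes = np.empty(n_fn, dtype="U16")
    omegas = np.empty(n_fn, dtype=np.float64)
    for idx in range(n_fn):
        t = TruthTable(ne, outputs[idx])
        classes[idx] = classify_function(t).value
        omegas[idx] = complexity_omega(t).omega
    return outputs, classes, omegas


def class_distribution(ne: int) -> dict:
    """Relative frequency of each function class in the mathematical space.

    Exhaustive over all ``2**2**ne`` Boolean functions; requires ne <= 4.
    """
    _, classes, _ = _function_space(ne)
    n = classes.size
    return {
        fc: float((classes == fc.value).sum()) / n for fc in FunctionClass
    }


OmegaConstraint = Union[FunctionClass, float, "tuple[float, float]"]


def _constraint_mask(
    classes: np.ndarray, omegas: np.ndarray, constraint: OmegaConstraint, tol: float
) -> np.ndarray:
    if isinstance(constraint, FunctionClass):
        return classes == constraint.value
    if isinstance(constraint, tuple):
        lo, hi = constraint
        with np.errstate(invalid="ignore"):
            return np.isfinite(omegas) & (omegas >= lo) & (omegas <= hi)
    value = float(constraint)
    with np.errstate(invalid="ignore"):
        return np.isfinite(omegas) & (np.abs(omegas - value) <= tol)


def random_function(
    ne: int,
    constraint: OmegaConstraint,
    rng: np.random.Generator,
    tol: float = 1e-9,
    max_tries: int = 1_000_000,
) -> TruthTable:
    """Uniformly sample a truth table satisfying an Omega/class constraint.

    ``constraint`` is a :class:`FunctionClass`, an exact Omega value
    (matched within ``tol``), or an inclusive ``(lo, hi)`` Omega range.
    For ne <= 4 the pool is enumerated exhaustively; above that,
    rejection sampling over random output vectors is used.
    """
    if ne <= MAX_NE_EXHAUSTIVE:
        outputs, classes, omegas = _function_space(ne)
        mask = _constraint_mask(classes, omegas, constraint, tol)
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError(f"no ne={ne} function satisfies constraint {constraint!r}")
        choice = int(rng.choice(idx))
        return TruthTable(ne, outputs[choice])
    for _ in range(max_tries):
        outs = rng.choice(np.array([-1, 1], dtype=np.int8), size=2**ne)
        t = TruthTable(ne, outs)
        cls = classify_function(t)
        omg = complexity_omega(t).omega
        if _constraint_mask(
            np.array([cls.value], dtype="U16"), np.array([omg]), constraint, tol
        )[0]:
            return t
    raise ValueError(
        f"rejection sampling failed for constraint {constraint!r} at ne={ne}"
    )
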