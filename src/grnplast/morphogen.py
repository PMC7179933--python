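"""2D morphogen-field patterning: generalisation in a multicellular context.

A rectangular embryonic field of 50 x 25 = 1250 cells reads positional
information from three continuous morphogen gradients:

* a Turing-like striped pattern  EF1(x, y) = sin(x * k),
* a radial gradient from an anterior corner  EF2(x, y) = sqrt(x^2 + y^2),
* lateral diffusion from the antero-posterior midline
  EF3(x, y) = sqrt(|y - midline|).

The gradients are thresholded into five binary inputs (1 bit from EF1,
2 from EF2, 2 from EF3 by default; thresholds sit at field-wise
quantiles so every bit is informative), giving each cell a 5-factor
environment and a 32-row plasticity table.  The target pattern applies
the composite function  AND(OR(AND(EF1, EF2), AND(EF2, EF3)), EF1)  to
one designated bit per morphogen.

Cells are independent (no cell-cell signalling): the pattern isolates
the morphogen-interpretation problem, so a genome evolved on a subset
of table rows can be scored on how much of the spatial pattern it
rescues.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .dynamics import ClassicalGenome, DynamicsParams, express_function
from .evolution import EvolutionConfig, TrainingTask, evolve
from .logic import TruthTable, enumerate_environments
from .seeds import rng_from

__all__ = [
    "FieldConfig",
    "MorphogenField",
    "build_morphogen_field",
    "exp4b_pattern",
]


class FieldConfigError(ValueError):
    """A threshold choice left some binary input constant across the field."""


@dataclass(frozen=True)
class FieldConfig:
    """Geometry, gradients and discretisation of the embryonic field."""

    width: int = 50
    height: int = 25
    stripe_wavenumber: float = 2.0 * np.pi / 10.0  # 10-cell stripe period
    radial_centre: tuple = (0.0, 0.0)  # anterior-left corner
    midline_row: Optional[float] = None  # default: the central row
    #: quantiles of each gradient at which the binary inputs switch on;
    #: one entry per bit, gradients in order (EF1, EF2, EF2, EF3, EF3)
    bit_quantiles: tuple = (0.5, 1.0 / 3.0, 2.0 / 3.0, 1.0 / 3.0, 2.0 / 3.0)
    #: gradient index (0..2) feeding each of the five bits
    bit_sources: tuple = (0, 1, 1, 2, 2)
    #: bit designated as the logical EF1/EF2/EF3 of the composite target
    designated_bits: tuple = (0, 1, 3)

    def __post_init__(self) -> None:
        if len(self.bit_quantiles) != len(self.bit_sources):
            raise ValueError("bit_quantiles and bit_sources must align")
        if len(self.designated_bits) != 3:
            raise ValueError("exactly one designated bit per morphogen")


def _composite_target(e1: np.ndarray, e2: np.ndarray, e3: np.ndarray) -> np.ndarray:
    """AND(OR(AND(EF1, EF2), AND(EF2, EF3)), EF1) on +-1 inputs, as +-1."""
    b1, b2, b3 = e1 > 0, e2 > 0, e3 > 0
    out = ((b1 & b2) | (b2 & b3)) & b1
    return np.where(out, 1, -1).astype(np.int8)


@dataclass(frozen=True)
class MorphogenField:
    """A discretised embryonic field and its target pattern."""

    config: FieldConfig
    env_matrix: np.ndarray  # (n_cells, 5) of +-1
    target_pattern: np.ndarray  # (n_cells,) of +-1
    gradients: np.ndarray = field(repr=False)  # (n_cells, 3) continuous values
    thresholds: np.ndarray = field(repr=False)  # realised threshold per bit

    @property
    def n_cells(self) -> int:
        return self.env_matrix.shape[0]

    @property
    def ne(self) -> int:
        return self.env_matrix.shape[1]

    @property
    def shape(self) -> tuple:
        return (self.config.height, self.config.width)

    def cell_rows(self) -> np.ndarray:
        """Truth-table row index of each cell's environment."""
        bits = (self.env_matrix > 0).astype(np.int64)
        return (bits << np.arange(self.ne)).sum(axis=1)

    @property
    def target_table(self) -> TruthTable:
        """The full 32-row plasticity table behind the pattern."""
        envs = enumerate_environments(self.ne)
        d = self.config.designated_bits
        outs = _composite_target(envs[:, d[0]], envs[:, d[1]], envs[:, d[2]])
        return TruthTable(self.ne, outs)

    def pattern_grid(self, values: Optional[np.ndarray] = None) -> np.ndarray:
        """Reshape a per-cell vector (default the target) to (height, width)."""
        v = self.target_pattern if values is None else np.asarray(values)
        return v.reshape(self.shape)


def build_morphogen_field(config: Optional[FieldConfig] = None) -> MorphogenField:
    """Evaluate the gradients, threshold them into bits, set the target."""
    config = config or FieldConfig()
    h, w = config.height, config.width
    y, x = np.mgrid[0:h, 0:w].astype(np.float64)
    x, y = x.ravel(), y.ravel()
    cx, cy = config.radial_centre
    midline = (h - 1) / 2.0 if config.midline_row is None else config.midline_row
    gradients = np.column_stack(
        [
            np.sin(x * config.stripe_wavenumber),
            np.sqrt((x - cx) ** 2 + (y - cy) ** 2),
            np.sqrt(np.abs(y - midline)),
        ]
    )
    n_bits = len(config.bit_sources)
    env = np.empty((x.size, n_bits), dtype=np.int8)
    thresholds = np.empty(n_bits)
    for b, (src, q) in enumerate(zip(config.bit_sources, config.bit_quantiles)):
        thr = np.quantile(gradients[:, src], q)
        thresholds[b] = thr
        bit = gradients[:, src] > thr
        if bit.all() or not bit.any():
            raise FieldConfigError(
                f"bit {b} (gradient {src}, quantile {q}) is constant across the field"
            )
        env[:, b] = np.where(bit, 1, -1)
    d = config.designated_bits
    target = _composite_target(env[:, d[0]], env[:, d[1]], env[:, d[2]])
    return MorphogenField(config, env, target, gradients, thresholds)


def exp4b_pattern(
    field_: MorphogenField,
    ts_size: int,
    mode: str,
    replicates: int,
    ng: int = 16,
    params: Optional[DynamicsParams] = None,
    config: Optional[EvolutionConfig] = None,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Pattern-rescue accuracy after selection on a partial table.

    ``mode="biased"``: evolve a genome on ``ts_size`` random rows of the
    32-row table, then develop every cell under its own 5-bit
    environment (one development per distinct environment) and score
    the fraction of cells matching the target pattern.
    ``mode="unbiased_control"``: keep the training rows exact and fill
    every unseen row uniformly at random - the inductive-bias-free
    baseline.  ``ts_size = 0`` gives the zero-information control.
    """
    if mode not in ("biased", "unbiased_control"):
        raise ValueError(f"unknown mode {mode!r}")
    table = field_.target_table
    n_rows = table.n_rows
    if not 0 <= ts_size <= n_rows:
        raise ValueError(f"ts_size must be in [0, {n_rows}]")
    if mode == "biased" and ts_size == 0:
        raise ValueError("biased mode needs at least one training row")
    params = params or DynamicsParams()
    config = config or EvolutionConfig()
    cell_rows = field_.cell_rows()
    records = []
    for rep in range(replicates):
        rng = rng_from(master_seed, rep)
        train_rows = rng.choice(n_rows, size=ts_size, replace=False) if ts_size else np.array([], dtype=np.int64)
        if mode == "biased":
            task = TrainingTask(table, train_rows)
            trace = evolve(
                ClassicalGenome.empty(ng, field_.ne), task, params, config, rng
            )
            expressed = express_function(
                trace.final_genome, params, rng, init_g=trace.init_g
            )
            outputs = expressed.outputs  # 0 marks unstable rows -> mismatch
            reached = trace.reached
        else:
            outputs = rng.choice(np.array([-1, 1], dtype=np.int8), size=n_rows)
            if ts_size:
                outputs[train_rows] = table.outputs[train_rows]
            reached = True
        cell_pheno = outputs[cell_rows]
        accuracy = float((cell_pheno == field_.target_pattern).mean())
        row_match = outputs == table.outputs
        unseen = np.setdiff1d(np.arange(n_rows), train_rows)
        records.append(
            {
                "replicate": rep,
                "mode": mode,
                "ts_size": ts_size,
                "pattern_accuracy": accuracy,
                "table_matches": float(row_match.sum()),
                "unseen_matches": float(row_match[unseen].sum()),
                "random_unseen_expectation": (n_rows - ts_size) / 2.0,
                "train_reached": reached,
            }
        )
    return pd.DataFrame(records)
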