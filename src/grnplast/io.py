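"""Serialization of tables, genomes, traces and run manifests.

Formats are deliberately plain: truth tables and matrices are CSV with
headers, genome metadata travels in a JSON sidecar next to the matrix
CSV, experiment configs are YAML or JSON, and every experiment run can
write a JSON manifest (master seed, config snapshot, package version)
sufficient to reproduce it exactly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .dynamics import ClassicalGenome, Genome, TensorGenome
from .evolution import EvolutionTrace
from .logic import TruthTable, enumerate_environments

__all__ = [
    "FormatError",
    "read_truth_table",
    "write_truth_table",
    "read_genome",
    "write_genome",
    "write_trace",
    "load_config",
    "RunManifest",
    "write_manifest",
]


class FormatError(ValueError):
    """A file failed to parse; the message names the offending field."""


def write_truth_table(table: TruthTable, path: Union[str, Path]) -> Path:
    """CSV with one row per environment: EF_1..EF_ne columns plus output."""
    path = Path(path)
    envs = enumerate_environments(table.ne)
    df = pd.DataFrame(envs, columns=[f"EF_{i + 1}" for i in range(table.ne)])
    df["output"] = table.outputs
    df.to_csv(path, index=False)
    return path


def read_truth_table(path: Union[str, Path]) -> TruthTable:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable CSV ({exc})") from exc
    ef_cols = [c for c in df.columns if c.startswith("EF_")]
    if not ef_cols or "output" not in df.columns:
        raise FormatError(
            f"{path}: expected EF_1..EF_ne columns and an 'output' column, "
            f"got {list(df.columns)}"
        )
    ne = len(ef_cols)
    ef_cols = [f"EF_{i + 1}" for i in range(ne)]
    missing = [c for c in ef_cols if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing environment columns {missing}")
    if len(df) != 2**ne:
        raise FormatError(
            f"{path}: a table over {ne} factors needs {2**ne} rows, got {len(df)}"
        )
    envs = df[ef_cols].to_numpy()
    if not np.isin(envs, (-1, 1)).all():
        raise FormatError(f"{path}: environment entries must be -1 or +1")
    outputs = np.empty(2**ne, dtype=np.int8)
    seen = np.zeros(2**ne, dtype=bool)
    for line, (env, out) in enumerate(zip(envs, df["output"]), start=2):
        bits = (np.asarray(env) > 0).astype(np.int64)
        r = int((bits << np.arange(ne)).sum())
        if seen[r]:
            raise FormatError(f"{path}: line {line}: duplicate environment {env.tolist()}")
        if out not in (-1, 1):
            raise FormatError(f"{path}: line {line}: output must be -1 or +1, got {out}")
        seen[r] = True
        outputs[r] = out
    return TruthTable(ne, outputs)


def write_genome(genome: Genome, path: Union[str, Path]) -> Path:
    """Matrix rows as CSV plus a JSON sidecar with ng/ne/goi/kind.

    Tensors are flattened to ``ng**2`` rows of ``ng`` columns in C order
    (row index = i * ng + j, column = k); the sidecar records this.
    """
    path = Path(path)
    is_tensor = isinstance(genome, TensorGenome)
    w = genome.weights.reshape(-1, genome.ng)
    pd.DataFrame(w, columns=[f"c{k}" for k in range(genome.ng)]).to_csv(
        path, index=False
    )
    meta = {
        "ng": genome.ng,
        "ne": genome.ne,
        "goi": genome.goi,
        "kind": "tensor" if is_tensor else "classical",
        "tensor_layout": "row (i*ng + j), column k, C order" if is_tensor else None,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return path


def read_genome(path: Union[str, Path]) -> Genome:
    path = Path(path)
    sidecar = path.with_suffix(".json")
    if not sidecar.exists():
        raise FormatError(f"{sidecar}: genome sidecar not found")
    try:
        meta = json.loads(sidecar.read_text())
        ng, ne, goi, kind = meta["ng"], meta["ne"], meta["goi"], meta["kind"]
    except (json.JSONDecodeError, KeyError) as exc:
        raise FormatError(f"{sidecar}: malformed sidecar ({exc})") from exc
    try:
        w = pd.read_csv(path).to_numpy(dtype=np.float64)
    except Exception as exc:
        raise FormatError(f"{path}: not a readable matrix CSV ({exc})") from exc
    if kind == "tensor":
        if w.shape != (ng * ng, ng):
            raise FormatError(
                f"{path}: tensor genome needs shape ({ng * ng}, {ng}), got {w.shape}"
            )
        return TensorGenome(ng, ne, goi, w.reshape(ng, ng, ng))
    if w.shape != (ng, ng):
        raise FormatError(f"{path}: genome needs shape ({ng}, {ng}), got {w.shape}")
    return ClassicalGenome(ng, ne, goi, w)


def write_trace(trace: EvolutionTrace, path: Union[str, Path]) -> Path:
    """Per-generation resident fitness as CSV (generation, W, W_t, CC)."""
    path = Path(path)
    df = pd.DataFrame(trace.fitness_history, columns=["generation", "W", "W_t", "CC"])
    df.to_csv(path, index=False)
    return path


def load_config(path: Union[str, Path]) -> dict:
    """Read an experiment configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".json",):
            data = json.loads(text)
        else:
            data = yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(f"{path}: malformed config ({exc})") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: config must be a mapping, got {type(data).__name__}")
    return data


@dataclass
class RunManifest:
    """Everything needed to re-run an experiment bit-for-bit."""

    command: str
    master_seed: int
    config: dict
    package_version: str = ""
    derived_seed_scheme: str = "SeedSequence((master_seed, *key))"
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )

    def __post_init__(self) -> None:
        if not self.package_version:
            from . import __version__

            self.package_version = __version__


def write_manifest(manifest: RunManifest, path: Union[str, Path]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(manifest), indent=2, default=str))
    return path
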