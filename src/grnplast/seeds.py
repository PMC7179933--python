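"""Deterministic seed derivation for replicate-level reproducibility.

Every source of randomness in the package descends from a single master
seed through ``SeedSequence((master_seed, *key))``, so any replicate can
be re-run in isolation from the manifest alone.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rng_from", "derived_seed"]


def rng_from(master_seed: int, *key: int) -> np.random.Generator:
    """A generator deterministically derived from the master seed and a key."""
    return np.random.default_rng(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)))


def derived_seed(master_seed: int, *key: int) -> int:
    """A 32-bit integer seed derived from the master seed and a key."""
    return int(np.random.SeedSequence((int(master_seed),) + tuple(int(k) for k in key)).generate_state(1)[0])
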