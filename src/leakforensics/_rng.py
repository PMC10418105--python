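"""Deterministic seed fan-out.

One top-level integer seed drives every stage; each stage derives its own
child seed by stable hashing of the stage name, so adding a stage never
perturbs the streams of existing ones and no global RNG state is touched.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["stage_seed", "stage_rng"]


def stage_seed(seed: int, stage: str) -> int:
    """Derive a child seed (< 2**31) from a master seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """A named, reproducible generator for one pipeline stage."""
    return np.random.default_rng(stage_seed(seed, stage))
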