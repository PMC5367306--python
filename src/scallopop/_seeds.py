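"""Deterministic per-stage random streams.

A single integer seed drives every stochastic stage of the package. Child
streams are derived from (seed, stage-name) so that adding or reordering
stages never perturbs the draws of another stage.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(seed: int, stage: str) -> int:
    """Derive a stable 31-bit child seed from a master seed and a stage name."""
    digest = hashlib.sha256(f"{int(seed)}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(seed: int, stage: str) -> np.random.Generator:
    """A numpy Generator seeded deterministically by ``(seed, stage)``."""
    return np.random.default_rng(child_seed(seed, stage))
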