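"""Deterministic seed derivation.

A single master seed drives every stochastic stage of a run.  Each stage
derives its own child seed from ``(master, stage-tag)`` so that adding or
re-ordering stages never perturbs the randomness of the others, and so that
re-running one stage from saved intermediates reproduces the full-run output.
Tags are hashed with CRC-32 (stable across platforms and Python versions,
unlike ``hash``).
"""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, tag: str) -> int:
    """A 31-bit seed derived deterministically from master seed and stage tag."""
    ss = np.random.SeedSequence(int(master_seed), spawn_key=(zlib.crc32(tag.encode("utf8")),))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def child_rng(master_seed: int, tag: str) -> np.random.Generator:
    return np.random.default_rng(child_seed(master_seed, tag))
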