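"""Seed management.

A single root seed fans out into named sub-streams (``input``, ``weights``,
``noise``, ``encoder`` ...) so that, e.g., frozen background noise and input
randomisation can be controlled independently while staying reproducible.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["substream_seed", "rng_for"]


def _stable_hash(name: str) -> int:
    """Deterministic 32-bit integer hash of a stream name (process-independent)."""
    digest = hashlib.sha256(name.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "little")


def substream_seed(root_seed: int, name: str) -> np.random.SeedSequence:
    """SeedSequence for the named sub-stream of ``root_seed``."""
    return np.random.SeedSequence(entropy=int(root_seed), spawn_key=(_stable_hash(name),))


def rng_for(root_seed: int, name: str) -> np.random.Generator:
    """Generator for the named sub-stream of ``root_seed``.

    Identical (seed, name) pairs always yield identical streams; different
    names yield statistically independent streams.
    """
    return np.random.default_rng(substream_seed(root_seed, name))
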