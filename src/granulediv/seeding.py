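"""Deterministic child-seed derivation.

Every stochastic operation in the package derives its generator from a
master seed plus a string context (operation name, sample/pair ids), so
results do not depend on the order in which operations run.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed_sequence", "child_rng"]


def child_seed_sequence(master_seed: int, *tokens) -> np.random.SeedSequence:
    """Build a SeedSequence from ``master_seed`` and a context key.

    The tokens are hashed so that (master, "rarefy", "S1") and
    (master, "rarefy", "S2") give statistically independent streams
    regardless of call order.
    """
    key = "\x1f".join(str(t) for t in tokens).encode("utf-8")
    digest = hashlib.blake2b(key, digest_size=8).digest()
    return np.random.SeedSequence(
        [int(master_seed) % (2**63), int.from_bytes(digest, "little")]
    )


def child_rng(master_seed: int, *tokens) -> np.random.Generator:
    """Generator seeded from ``master_seed`` and a context key."""
    return np.random.default_rng(child_seed_sequence(master_seed, *tokens))
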