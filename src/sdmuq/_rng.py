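"""Deterministic seed derivation.

One master seed per experiment; every stochastic component receives a child
seed derived from the master seed plus a string label, so that adding or
removing one component (an ESM, an archetype, an ensemble member) never
perturbs the random stream of any other.
"""

from __future__ import annotations

import hashlib

import numpy as np

__all__ = ["child_seed", "child_rng"]


def child_seed(master_seed: int, *labels: object) -> int:
    """Derive a 31-bit child seed from a master seed and a label path.

    The derivation is a SHA-256 hash of the master seed and the labels,
    so it is stable across platforms and Python versions (unlike ``hash``).
    """
    key = ":".join([str(int(master_seed))] + [str(lab) for lab in labels])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


def child_rng(master_seed: int, *labels: object) -> np.random.Generator:
    """A ``numpy`` Generator seeded by :func:`child_seed`."""
    return np.random.default_rng(child_seed(master_seed, *labels))
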