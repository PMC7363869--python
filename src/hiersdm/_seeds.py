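"""Deterministic seed derivation.

One master seed per run; every stochastic stage draws from a child seed
obtained by hashing the master seed together with stage labels (species,
stage name, pseudo-absence set, cross-validation run).  The rule is stable
across platforms and Python processes so results are citable.
"""

from __future__ import annotations

import hashlib

import numpy as np


def child_seed(master: int, *labels: object) -> int:
    """Derive a 31-bit child seed from a master seed and labels."""
    key = ":".join([str(int(master))] + [str(l) for l in labels])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def child_rng(master: int, *labels: object) -> np.random.Generator:
    return np.random.default_rng(child_seed(master, *labels))
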