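"""Deterministic seed derivation.

A single master seed fixes every random stream in a run. Stage- and
sample-specific generators are derived by hashing the master seed together
with string tokens (stage name, sample index, genome id, ...), so that
changing one token changes only that stream: re-simulating sample 3 does
not perturb the community design, and vice versa.
"""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(master: int, *tokens: object) -> int:
    """Derive a 31-bit seed from a master seed and a token path.

    The derivation is a SHA-256 over the decimal master seed and the
    string forms of the tokens, so it is stable across platforms and
    Python hash randomization.
    """
    h = hashlib.sha256()
    h.update(str(int(master)).encode())
    for tok in tokens:
        h.update(b"\x1f")
        h.update(str(tok).encode())
    return int.from_bytes(h.digest()[:4], "big") & 0x7FFFFFFF


def derive_rng(master: int, *tokens: object) -> np.random.Generator:
    """A numpy Generator seeded from ``derive_seed(master, *tokens)``."""
    return np.random.default_rng(derive_seed(master, *tokens))
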