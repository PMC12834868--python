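"""Deterministic, counter-style seed derivation.

A single master seed spawns an independent stream for every labelled
consumer (subset evaluation iterations, selector runs, tuning folds, ...)
by hashing the master seed together with string tokens naming the consumer.
Adding a classifier or selector therefore never perturbs the streams of the
others, and re-running with the same master seed reproduces every draw.
"""

from __future__ import annotations

import hashlib

__all__ = ["derive_seed"]

_MODULUS = 2**31 - 1  # keep derived seeds int32-safe for every RNG backend


def derive_seed(master_seed: int, *tokens: object) -> int:
    """Derive a reproducible sub-seed from ``master_seed`` and tokens.

    Tokens are stringified and hashed with SHA-256; the result is reduced
    modulo 2**31 - 1 so it is accepted by both numpy and scikit-learn.
    """
    payload = "|".join([str(int(master_seed))] + [str(t) for t in tokens])
    digest = hashlib.sha256(payload.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") % _MODULUS
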