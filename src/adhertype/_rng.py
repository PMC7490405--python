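"""Deterministic seed derivation.

All randomness in the pipeline flows from one master seed.  Each stage
(generation, k-means, bootstrap, partitioning, CV folds) draws from a
named substream so that stages can be re-run in isolation and still
reproduce the end-to-end run bit for bit.
"""

import hashlib

import numpy as np

# scikit-learn's random_state must fit in a signed 32-bit int
_SEED_MOD = 2**31


def derive_seed(master_seed: int, stream: str) -> int:
    """Derive a stable per-stage seed from the master seed and a stream name.

    Uses SHA-256 so the mapping is identical across platforms and Python
    processes (unlike ``hash``, which is salted).
    """
    digest = hashlib.sha256(f"{master_seed}:{stream}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % _SEED_MOD


def derive_rng(master_seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(master_seed, stream))
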