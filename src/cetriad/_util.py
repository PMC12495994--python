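"""Small shared helpers: seed derivation and validation."""

from __future__ import annotations

import hashlib

import numpy as np


def derive_seed(global_seed: int, name: str) -> int:
    """Derive a stable per-operation seed from a global seed.

    Keeps every module independently reproducible: two runs with the same
    global seed see the same stream regardless of call order elsewhere.
    The result is always < 2**31.
    """
    digest = hashlib.sha256(f"{int(global_seed)}:{name}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def rng_for(global_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(derive_seed(global_seed, name))


def check_symmetric(a: np.ndarray, tol: float = 1e-9, what: str = "matrix") -> None:
    if a.shape[0] != a.shape[1]:
        raise ValueError(f"{what} is not square: {a.shape}")
    if not np.allclose(a, a.T, atol=tol):
        raise ValueError(f"{what} is not symmetric within {tol}")
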