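"""Shared numerical helpers: seeded substreams and positive-definite repair."""

from __future__ import annotations

import zlib

import numpy as np

__all__ = ["substream", "child_seed", "nearest_pd", "pearson"]


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, reproducible random substream derived from a root seed.

    Every stochastic stage draws from ``substream(root_seed, stage_name)`` so
    that stages are independently reproducible and re-entrant regardless of
    execution order.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(key,)))


def child_seed(seed: int, name: str) -> int:
    """A plain integer seed (< 2**31) derived from a root seed and a label."""
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(zlib.crc32(name.encode("utf-8")),))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def nearest_pd(mat: np.ndarray, floor: float = 1e-6) -> np.ndarray:
    """Repair a symmetric matrix to positive definite by eigenvalue clipping.

    Eigenvalues below ``floor`` are raised to ``floor``; the matrix is
    re-symmetrised. Leaves already-PD matrices essentially untouched.
    """
    sym = 0.5 * (mat + mat.T)
    vals, vecs = np.linalg.eigh(sym)
    if vals[0] >= floor:
        return sym
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    return 0.5 * (out + out.T)


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of two 1-D arrays (0.0 if either is constant)."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    xs = x - x.mean()
    ys = y - y.mean()
    denom = np.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        return 0.0
    return float((xs @ ys) / denom)
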