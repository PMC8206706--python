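"""Canonical ordering of trait pairs.

Pairwise trait correlations are stored as flat vectors indexed by a fixed
canonical pair order: all pairs (i, j) with i < j, sorted by (i, j).  For
K = 4 this is 1v2, 1v3, 1v4, 2v3, 2v4, 3v4.
"""

from __future__ import annotations

import numpy as np

__all__ = ["n_pairs", "canonical_pairs", "pair_labels", "pair_index_matrix"]


def n_pairs(k: int) -> int:
    """Number of unordered trait pairs for ``k`` traits."""
    return k * (k - 1) // 2


def canonical_pairs(k: int) -> list[tuple[int, int]]:
    """Zero-based (i, j) pairs with i < j in canonical order."""
    return [(i, j) for i in range(k) for j in range(i + 1, k)]


def pair_labels(k: int) -> list[str]:
    """Human-readable one-based labels, e.g. ``'1v2'``."""
    return [f"{i + 1}v{j + 1}" for i, j in canonical_pairs(k)]


def pair_index_matrix(k: int) -> np.ndarray:
    """K x K symmetric matrix mapping (i, j) to the flat pair index.

    The diagonal is set to -1 (no self pair).
    """
    m = np.full((k, k), -1, dtype=np.int64)
    for p, (i, j) in enumerate(canonical_pairs(k)):
        m[i, j] = p
        m[j, i] = p
    return m
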