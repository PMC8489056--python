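"""Small shared helpers for the stability modules."""

from __future__ import annotations

import numpy as np


def ranks_ascending(scores: np.ndarray) -> np.ndarray:
    """1-based ranks, ascending by score, ties broken by input order."""
    order = np.argsort(scores, kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def ranks_descending(scores: np.ndarray) -> np.ndarray:
    """1-based ranks, descending by score, ties broken by input order."""
    order = np.argsort(-np.asarray(scores), kind="stable")
    ranks = np.empty(len(scores), dtype=int)
    ranks[order] = np.arange(1, len(scores) + 1)
    return ranks


def sample_sd(x: np.ndarray, axis=None) -> np.ndarray:
    """Standard deviation with the n-1 denominator (package-wide convention)."""
    return np.std(np.asarray(x, dtype=float), axis=axis, ddof=1)
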