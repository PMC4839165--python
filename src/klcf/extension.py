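"""Character-level extension primitives.

Extensions are computed by direct character comparison (no suffix-tree /
LCA machinery): the exact longest common extension ``lcp0``, its
k-mismatch generalization ``lcp_k`` (at most k+1 chained jump-extensions),
and the full sweep of one suffix against every position of ``y``.

Positions are 0-based; one-past-the-end starts are allowed and yield 0.
End-of-string is not a mismatch -- extension simply stops there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .sequences import EncodedSequence


@dataclass(frozen=True)
class SweepResult:
    """Best k-mismatch extension of one suffix over y, with all tie positions."""

    best: int
    ties: np.ndarray  # ascending y-positions attaining best


def _check_pos(seq: EncodedSequence, pos: int, name: str) -> None:
    if not 0 <= pos <= seq.n:
        raise ValueError(f"{name}={pos} out of range for sequence of length {seq.n}")


def lcp0(x: EncodedSequence, i: int, y: EncodedSequence, j: int) -> int:
    """Length of the longest exact common prefix of ``x[i:]`` and ``y[j:]``.

    The sentinel code never matches anything, itself included.
    """
    _check_pos(x, i, "i")
    _check_pos(y, j, "j")
    return int(_kernels.lcp0_kernel(x.codes, i, y.codes, j))


def lcp_k(x: EncodedSequence, i: int, y: EncodedSequence, j: int, k: int) -> int:
    """Longest common prefix of ``x[i:]`` and ``y[j:]`` with at most ``k`` mismatches."""
    _check_pos(x, i, "i")
    _check_pos(y, j, "j")
    if k < 0:
        raise ValueError("mismatch budget k must be non-negative")
    return int(_kernels.lcp_k_kernel(x.codes, i, y.codes, j, k))


def full_sweep(x: EncodedSequence, i: int, y: EncodedSequence, k: int) -> SweepResult:
    """Best ``lcp_k`` of suffix ``i`` over every y-position, with all ties."""
    _check_pos(x, i, "i")
    if k < 0:
        raise ValueError("mismatch budget k must be non-negative")
    vbuf = np.empty(y.n, dtype=np.int64)
    best = int(_kernels.sweep_kernel(x.codes, i, y.codes, k, vbuf))
    return SweepResult(best=best, ties=np.flatnonzero(vbuf == best).astype(np.int64))
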