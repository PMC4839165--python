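"""Reference computations: the naive quadratic oracle and a greedy heuristic.

``naive_lcf_vector`` sweeps every (suffix, position) pair and is the ground
truth that the exact stepping algorithm is required to reproduce.

``greedy_lcf_vector`` re-implements the kmacs idea at the statistic level:
for each suffix, find the longest *exact* match, then extend with k
mismatches only from the positions tied at that exact maximum.  It is a
lower bound on the true per-suffix k-LCF and systematically undershoots
when the best k-mismatch match is not seeded by the best exact match.
"""

from __future__ import annotations

from . import _kernels
from .core import FilterStats, SuffixLCFVector, _check_pair
from .sequences import EncodedSequence


def naive_lcf_vector(x: EncodedSequence, y: EncodedSequence, k: int) -> SuffixLCFVector:
    """Ground-truth per-suffix k-LCF values by full quadratic sweeping."""
    _check_pair(x, y, k)
    values, bestj = _kernels.naive_kernel(x.codes, y.codes, k)
    return SuffixLCFVector(values=values, k=k, mode="naive", best_j=bestj)


def greedy_lcf_vector(x: EncodedSequence, y: EncodedSequence, k: int) -> SuffixLCFVector:
    """kmacs-style heuristic lower bound on the per-suffix k-LCF values."""
    _check_pair(x, y, k)
    values, bestj = _kernels.greedy_kernel(x.codes, y.codes, k)
    return SuffixLCFVector(values=values, k=k, mode="greedy", best_j=bestj)


def naive_stats(x: EncodedSequence, y: EncodedSequence) -> FilterStats:
    """FilterStats of the naive algorithm: every pair is examined."""
    total = x.n * y.n
    return FilterStats(pairs_total=total, pairs_examined=total)
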