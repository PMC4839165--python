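"""Per-suffix k-mismatch longest-common-factor vectors by carry/filter/verify.

For every suffix ``x[i:]`` the algorithm computes the length of its longest
common prefix with at most ``k`` mismatches against *any* position of ``y``
(the per-suffix k-LCF).  Rather than sweeping all ``n * m`` position pairs,
each step carries the previous suffix's optimum forward, filters candidate
y-positions with two per-symbol mask conditions, and verifies the survivors
with extensions:

* carry-over: every position tied at the step-``i`` optimum ``L`` yields a
  candidate for step ``i+1`` -- ``L - 1`` when the first aligned characters
  matched, else ``L`` plus one exact extension past the old final mismatch;
* filter a: a candidate preceded by a character matching ``x[i]`` cannot
  beat ``L - 1`` and is dropped;
* filter b: a strictly longer match must align ``x[i+L]`` with a matching
  character (the first symbol of the last jump);
* verification: the guessed length ``c = L + lcp0(...)`` is confirmed by a
  full jump-extension; survivors become the new best or join the tie list.

``exact`` mode adds a tie-completion pass when the step ends at ``L - 1``
(filter b is unsound exactly there); ``relaxed`` mode skips that pass,
trading guaranteed exactness for speed while remaining a lower bound.

Two interchangeable engines exist: a compiled kernel (default) and the
step-by-step Python implementation below, which doubles as the readable
reference of the algorithm.  Both are cross-checked against the naive
quadratic oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .extension import full_sweep, lcp0, lcp_k
from .sequences import EncodedSequence, SymbolPositionIndex, build_symbol_index


@dataclass
class FilterStats:
    """Counters of (suffix, y-position) pairs reaching an extension.

    ``pairs_examined`` counts every pair on which a jump-extension or direct
    k-mismatch extension is evaluated: full-sweep positions, carry-over
    extensions, verified scan survivors, tie-pass evaluations and the
    per-step direct check of the first y-position.  Pairs rejected on the
    cheap exact-extension guess alone are not counted.
    """

    pairs_total: int = 0
    pairs_examined: int = 0
    verifications_accepted: int = 0

    @property
    def percentage(self) -> float:
        """Share of the quadratic maximum actually considered, in percent."""
        if self.pairs_total == 0:
            return 0.0
        return 100.0 * self.pairs_examined / self.pairs_total


@dataclass
class StepState:
    """Optimum of one suffix: index ``i``, value ``L`` and its tie list."""

    i: int
    L: int
    ties: np.ndarray  # ascending y-positions attaining L


@dataclass
class SuffixLCFVector:
    """The n per-suffix k-LCF values, with the smallest attaining y-position."""

    values: np.ndarray
    k: int
    mode: str
    best_j: np.ndarray | None = None

    @property
    def n(self) -> int:
        return int(self.values.shape[0])


def _ext0(x: EncodedSequence, i: int, y: EncodedSequence, j: int) -> int:
    """lcp0 with start positions past either end contributing 0."""
    if i >= x.n or j >= y.n:
        return 0
    return int(_kernels.lcp0_kernel(x.codes, i, y.codes, j))


def _check_pair(x: EncodedSequence, y: EncodedSequence, k: int) -> None:
    if x.n < 1 or y.n < 1:
        raise ValueError("sequences entering comparison must be non-empty")
    if k < 0:
        raise ValueError("mismatch budget k must be non-negative")


def carry_over(
    state: StepState,
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    stats: FilterStats | None = None,
) -> tuple[int | None, list[int]]:
    """Advance the step-``i`` optimum to candidates for step ``i+1``.

    Returns ``(L_max, ties)`` over the carried positions, or ``(None, [])``
    when no tie survives (all sat at the last position of y) and the caller
    must fall back to a full sweep.
    """
    xc, yc = x.codes, y.codes
    n, m = x.n, y.n
    i, L = state.i, state.L
    best: int | None = None
    ties: list[int] = []
    for j0 in state.ties:
        j0 = int(j0)
        if j0 + 1 >= m:
            continue
        if i + L >= n or j0 + L >= m:
            # Step-i alignment touched a sequence end: no (k+1)-th mismatch
            # to reason from, evaluate directly.
            cand = lcp_k(x, i + 1, y, j0 + 1, k)
            if stats is not None:
                stats.pairs_examined += 1
        elif xc[i] >= 0 and xc[i] == yc[j0]:
            cand = L - 1
        else:
            cand = L + _ext0(x, i + L + 1, y, j0 + L + 1)
            if stats is not None:
                stats.pairs_examined += 1
        if best is None or cand > best:
            best = cand
            ties = [j0 + 1]
        elif cand == best:
            ties.append(j0 + 1)
    return best, ties


def candidate_mask(
    x: EncodedSequence,
    i: int,
    L: int,
    index_y: SymbolPositionIndex,
) -> np.ndarray:
    """Positions ``r`` of y surviving both per-symbol filters at step ``i``.

    Each surviving ``r`` denotes the candidate pair ``(i + 1, r + 1)``.
    Filter a keeps ``r`` with ``y[r]`` not matching ``x[i]`` (a sentinel
    ``x[i]`` keeps everything); filter b demands ``y[r + L]`` match
    ``x[i + L]`` and is skipped when that anchor lies past the end of x.
    """
    m = index_y.m
    xc = x.codes
    keep = np.ones(m, dtype=bool)
    if xc[i] >= 0:
        keep &= ~index_y.masks[xc[i]]
    if i + L < x.n:
        anchor = xc[i + L]
        shifted = np.zeros(m, dtype=bool)
        if anchor >= 0 and L < m:
            shifted[: m - L] = index_y.masks[anchor][L:]
        keep &= shifted
    if m > 0:
        keep[m - 1] = False  # r + 1 must be a valid start in y
    return np.flatnonzero(keep)


def verify_candidate(
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    i: int,
    r: int,
    L: int,
    L_max: int,
    stats: FilterStats,
) -> tuple[str, int]:
    """Verify candidate pair ``(i + 1, r + 1)`` against the current best.

    The guessed length ``c`` assumes the (k+1)-th mismatch falls right after
    the filter-b anchor; candidates that cannot reach ``L_max`` are rejected
    on that guess alone, the rest get a full jump-extension and are accepted
    only when it confirms the guess.  Returns one of ``("new_best", c)``,
    ``("tie", c)`` or ``("reject", c)``.
    """
    c = L + _ext0(x, i + L + 1, y, r + L + 1)
    if c < L_max:
        return "reject", c
    l_true = lcp_k(x, i + 1, y, r + 1, k)
    stats.pairs_examined += 1
    if l_true != c:
        return "reject", c
    stats.verifications_accepted += 1
    if c > L_max:
        return "new_best", c
    return "tie", c


def _step(
    state: StepState,
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    index_y: SymbolPositionIndex,
    stats: FilterStats,
    exact: bool,
) -> StepState:
    n, m = x.n, y.n
    i, L = state.i, state.L
    xc, yc = x.codes, y.codes

    L_max, ties = carry_over(state, x, y, k, stats)
    if L_max is None:
        sweep = full_sweep(x, i + 1, y, k)
        stats.pairs_examined += m
        return StepState(i + 1, sweep.best, sweep.ties)

    processed = {int(j0) + 1 for j0 in state.ties if int(j0) + 1 < m}

    # The first y-position has no predecessor pair, hence is unreachable by
    # carry or filters: evaluate it directly to preserve exactness.
    v0 = lcp_k(x, i + 1, y, 0, k)
    stats.pairs_examined += 1
    processed.add(0)
    if v0 > L_max:
        L_max, ties = v0, [0]
    elif v0 == L_max:
        ties.append(0)

    for r in candidate_mask(x, i, L, index_y):
        r = int(r)
        if r + 1 in processed:
            continue
        verdict, c = verify_candidate(x, y, k, i, r, L, L_max, stats)
        if verdict == "new_best":
            L_max, ties = c, [r + 1]
            processed.add(r + 1)
        elif verdict == "tie":
            ties.append(r + 1)
            processed.add(r + 1)

    if exact and L_max == L - 1:
        # Filter b is unsound at exactly L-1: recover the discarded ties.
        for r in range(m - 1):
            p = r + 1
            if p in processed:
                continue
            if xc[i] >= 0 and yc[r] == xc[i]:
                continue
            l_true = lcp_k(x, i + 1, y, p, k)
            stats.pairs_examined += 1
            if l_true == L_max:
                stats.verifications_accepted += 1
                ties.append(p)

    return StepState(i + 1, L_max, np.array(sorted(ties), dtype=np.int64))


def step_exact(
    state: StepState,
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    index_y: SymbolPositionIndex,
    stats: FilterStats,
) -> StepState:
    """One exact step: the returned optimum and tie list are complete."""
    return _step(state, x, y, k, index_y, stats, exact=True)


def step_relaxed(
    state: StepState,
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    index_y: SymbolPositionIndex,
    stats: FilterStats,
) -> StepState:
    """One relaxed step: the L-1 tie pass is skipped, ties may be missed."""
    return _step(state, x, y, k, index_y, stats, exact=False)


def lcf_vector(
    x: EncodedSequence,
    y: EncodedSequence,
    k: int,
    mode: str = "exact",
    engine: str = "compiled",
) -> tuple[SuffixLCFVector, FilterStats]:
    """Compute all per-suffix k-LCF values of ``x`` against ``y``.

    Parameters
    ----------
    mode : "exact" or "relaxed"
        Exact mode provably equals the naive quadratic computation; relaxed
        mode is a lower bound that skips the expensive tie-completion pass.
    engine : "compiled" or "python"
        Same algorithm; the compiled kernel is the default, the Python
        engine drives the step functions above one call at a time.
    """
    _check_pair(x, y, k)
    if mode not in ("exact", "relaxed"):
        raise ValueError(f"unknown mode {mode!r}")
    exact = mode == "exact"
    stats = FilterStats(pairs_total=x.n * y.n)
    if engine == "compiled":
        values, bestj, examined, accepted = _kernels.stepping_kernel(
            x.codes, y.codes, k, exact
        )
        stats.pairs_examined = int(examined)
        stats.verifications_accepted = int(accepted)
        return SuffixLCFVector(values, k, mode, bestj), stats
    if engine != "python":
        raise ValueError(f"unknown engine {engine!r}")

    index_y = build_symbol_index(y)
    sweep = full_sweep(x, 0, y, k)
    stats.pairs_examined += y.n
    state = StepState(0, sweep.best, sweep.ties)
    values = np.zeros(x.n, dtype=np.int64)
    bestj = np.zeros(x.n, dtype=np.int64)
    values[0] = state.L
    bestj[0] = state.ties[0]
    step = step_exact if exact else step_relaxed
    for _ in range(x.n - 1):
        state = step(state, x, y, k, index_y, stats)
        values[state.i] = state.L
        bestj[state.i] = state.ties[0]
    return SuffixLCFVector(values, k, mode, bestj), stats
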