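"""Numba-compiled inner loops.

All kernels work on int8 code arrays, 0-based, with the never-matching
sentinel encoded as a negative value: two codes match iff they are equal
and non-negative.  The algorithmic contract is the naive character-level
semantics; compilation is purely an implementation detail.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=False)
def lcp0_kernel(x, i, y, j):
    """Exact longest common extension of x[i:] vs y[j:]."""
    n = x.shape[0]
    m = y.shape[0]
    l = 0
    while i + l < n and j + l < m and x[i + l] >= 0 and x[i + l] == y[j + l]:
        l += 1
    return l


@njit(cache=False)
def lcp_k_kernel(x, i, y, j, k):
    """k-mismatch longest common extension via k+1 chained jump-extensions."""
    n = x.shape[0]
    m = y.shape[0]
    l = 0
    mism = 0
    while i + l < n and j + l < m:
        if x[i + l] >= 0 and x[i + l] == y[j + l]:
            l += 1
        else:
            if mism == k:
                break
            mism += 1
            l += 1
    return l


@njit(cache=False)
def sweep_kernel(x, i, y, k, vbuf):
    """Evaluate suffix i of x against every y-position; fill vbuf, return best."""
    m = y.shape[0]
    best = -1
    for j in range(m):
        v = lcp_k_kernel(x, i, y, j, k)
        vbuf[j] = v
        if v > best:
            best = v
    return best


@njit(cache=False)
def naive_kernel(x, y, k):
    """Ground-truth per-suffix maxima by full quadratic sweeping."""
    n = x.shape[0]
    m = y.shape[0]
    values = np.zeros(n, np.int64)
    bestj = np.zeros(n, np.int64)
    for i in range(n):
        best = -1
        arg = 0
        for j in range(m):
            v = lcp_k_kernel(x, i, y, j, k)
            if v > best:
                best = v
                arg = j
        values[i] = best
        bestj[i] = arg
    return values, bestj


@njit(cache=False)
def greedy_kernel(x, y, k):
    """kmacs-style heuristic: extend with k mismatches only from the
    positions attaining the longest *exact* match of each suffix."""
    n = x.shape[0]
    m = y.shape[0]
    values = np.zeros(n, np.int64)
    bestj = np.zeros(n, np.int64)
    l0 = np.zeros(m, np.int64)
    for i in range(n):
        ex = -1
        for j in range(m):
            v = lcp0_kernel(x, i, y, j)
            l0[j] = v
            if v > ex:
                ex = v
        best = -1
        arg = 0
        for j in range(m):
            if l0[j] == ex:
                v = lcp_k_kernel(x, i, y, j, k)
                if v > best:
                    best = v
                    arg = j
        values[i] = best
        bestj[i] = arg
    return values, bestj


@njit(cache=False)
def stepping_kernel(x, y, k, exact):
    """Carry / filter / verify stepping over all suffixes of x.

    Returns (values, bestj, pairs_examined, verifications_accepted).
    ``exact`` toggles the L-1 tie-completion pass; without it the tie lists
    may be incomplete and later values may undershoot (relaxed mode).
    """
    n = x.shape[0]
    m = y.shape[0]
    values = np.zeros(n, np.int64)
    bestj = np.zeros(n, np.int64)
    ties = np.empty(m, np.int64)
    tmp = np.empty(m, np.int64)
    vbuf = np.empty(m, np.int64)
    stamp = np.full(m, -1, np.int64)
    examined = 0
    accepted = 0

    # Initial full sweep for the first suffix.
    best = sweep_kernel(x, 0, y, k, vbuf)
    examined += m
    nt = 0
    for j in range(m):
        if vbuf[j] == best:
            ties[nt] = j
            nt += 1
    values[0] = best
    bestj[0] = ties[0]

    for i in range(n - 1):
        L = values[i]
        Lmax = -1
        nnew = 0

        # Carry the previous optimum (and all its ties) one position ahead.
        for t in range(nt):
            j0 = ties[t]
            if j0 + 1 >= m:
                continue
            if i + L >= n or j0 + L >= m:
                # The step-i alignment ran into a sequence end: the (k+1)-th
                # mismatch the carry formulas presuppose does not exist.
                cand = lcp_k_kernel(x, i + 1, y, j0 + 1, k)
                examined += 1
            elif x[i] >= 0 and x[i] == y[j0]:
                cand = L - 1
            else:
                cand = L + lcp0_kernel(x, i + L + 1, y, j0 + L + 1)
                examined += 1
            if cand > Lmax:
                Lmax = cand
                tmp[0] = j0 + 1
                nnew = 1
            elif cand == Lmax:
                tmp[nnew] = j0 + 1
                nnew += 1

        if nnew == 0:
            # Degenerate carry: every tie sat at the last position of y.
            best = sweep_kernel(x, i + 1, y, k, vbuf)
            examined += m
            nt = 0
            for j in range(m):
                if vbuf[j] == best:
                    ties[nt] = j
                    nt += 1
            values[i + 1] = best
            bestj[i + 1] = ties[0]
            continue

        # Mark carried images so the scan and tie pass skip them.
        for t in range(nt):
            j0 = ties[t]
            if j0 + 1 < m:
                stamp[j0 + 1] = i

        # The first y-position has no predecessor pair (no position 0 of the
        # previous step maps onto it), so no filter can reach it: evaluate
        # it directly each step to keep the exact mode exact.
        v0 = lcp_k_kernel(x, i + 1, y, 0, k)
        examined += 1
        stamp[0] = i
        if v0 > Lmax:
            Lmax = v0
            tmp[0] = 0
            nnew = 1
        elif v0 == Lmax:
            tmp[nnew] = 0
            nnew += 1

        # Filtered candidate scan.  Filter a: previous character must NOT
        # match x[i].  Filter b: the character L past the candidate must
        # match x[i+L] (the first symbol of the last jump), applicable only
        # while that anchor exists.
        a = x[i]
        anchor_ok = i + L < n
        b = np.int8(-1)
        if anchor_ok:
            b = x[i + L]
        if not (anchor_ok and b < 0):
            # (a sentinel anchor matches nothing: the scan would be empty)
            for r0 in range(m - 1):
                p = r0 + 1
                if stamp[p] == i:
                    continue
                if a >= 0 and y[r0] == a:
                    continue
                if anchor_ok:
                    if r0 + L >= m:
                        continue
                    if y[r0 + L] != b:
                        continue
                c = L + lcp0_kernel(x, i + L + 1, y, r0 + L + 1)
                if c < Lmax:
                    continue
                lt = lcp_k_kernel(x, i + 1, y, p, k)
                examined += 1
                if lt == c:
                    accepted += 1
                    stamp[p] = i
                    if c > Lmax:
                        Lmax = c
                        tmp[0] = p
                        nnew = 1
                    else:
                        tmp[nnew] = p
                        nnew += 1

        # L-1 tie completion: when no strictly longer match was found the
        # second filter may have discarded genuine length-(L-1) ties, so
        # they are recovered with direct evaluations (exact mode only).
        if exact and Lmax == L - 1:
            for r0 in range(m - 1):
                p = r0 + 1
                if stamp[p] == i:
                    continue
                if a >= 0 and y[r0] == a:
                    continue
                lt = lcp_k_kernel(x, i + 1, y, p, k)
                examined += 1
                if lt == Lmax:
                    accepted += 1
                    tmp[nnew] = p
                    nnew += 1

        sub = tmp[:nnew]
        sub.sort()
        for t in range(nnew):
            ties[t] = tmp[t]
        nt = nnew
        values[i + 1] = Lmax
        bestj[i + 1] = ties[0]

    return values, bestj, examined, accepted
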