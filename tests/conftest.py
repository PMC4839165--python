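"""Shared fixtures and independent brute-force oracles.

The oracles here deliberately use a different formulation from the package
(cumulative Hamming counting over growing prefixes, pure Python) so that
agreement is meaningful.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import klcf

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


def oracle_lcp_k(xc, i, yc, j, k) -> int:
    """Largest l with at most k Hamming mismatches between the length-l
    prefixes of x[i:] and y[j:], by scanning growing prefixes."""
    cap = min(len(xc) - i, len(yc) - j)
    best = 0
    mism = 0
    for l in range(1, cap + 1):
        a, b = xc[i + l - 1], yc[j + l - 1]
        if not (a == b and a >= 0):
            mism += 1
        if mism <= k:
            best = l
        else:
            break
    return best


def oracle_vector(x: klcf.EncodedSequence, y: klcf.EncodedSequence, k: int) -> list[int]:
    """Per-suffix maxima by exhaustive enumeration."""
    xc, yc = list(x.codes), list(y.codes)
    return [
        max(oracle_lcp_k(xc, i, yc, j, k) for j in range(len(yc)))
        for i in range(len(xc))
    ]


def random_pair(seed: int, n: int, m: int | None = None, sigma: int = 4, sentinel_frac: float = 0.0):
    """Deterministic random code-array pair for fuzz tests."""
    rng = np.random.default_rng(seed)
    m = n if m is None else m
    xc = rng.integers(0, sigma, n).astype(np.int8)
    yc = rng.integers(0, sigma, m).astype(np.int8)
    if sentinel_frac > 0:
        for c in (xc, yc):
            c[rng.random(len(c)) < sentinel_frac] = klcf.SENTINEL
    alpha = klcf.DNA if sigma == 4 else klcf.BINARY
    return (
        klcf.EncodedSequence("x", xc, alpha),
        klcf.EncodedSequence("y", yc, alpha),
    )


@pytest.fixture
def toy_pair():
    """The 4-bp worked example: per-suffix values [3, 2, 1, 1] at k=0."""
    return klcf.encode_sequence("ACGT", "x"), klcf.encode_sequence("TACG", "y")
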