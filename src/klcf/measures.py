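"""Similarity measures and distance matrices built on per-suffix k-LCF vectors.

From one vector two statistics follow at no extra cost: its maximum, the
length of the longest common substring with k mismatches (k-LCF), and its
mean, the k-mismatch average common substring statistic (kACS).  The kACS
values feed the ACS-style distance

    d'(x -> y) = ln(m) / kACS(x -> y) - 2 ln(n) / n,
    d(x, y)    = (d'(x -> y) + d'(y -> x)) / 2,

the log-corrected, self-term-subtracted, symmetrized normalization of the
ACS/kmacs lineage.  Small negative values on near-identical sequences are
clamped to 0.  Raw kACS and k-LCF are always reported alongside the
normalized distance.
"""

from __future__ import annotations

import math
import warnings
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .core import FilterStats, SuffixLCFVector, lcf_vector
from .sequences import EncodedSequence


@dataclass(frozen=True)
class ComparisonSummary:
    """Scalar summary of one directed comparison x -> y."""

    lcf: int  # longest common substring with k mismatches
    acs: float  # mean per-suffix value (kACS statistic, residues)
    filter_percentage: float
    mode: str
    k: int


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        object.__setattr__(self, "values", v)


def summarize(vector: SuffixLCFVector, stats: FilterStats) -> ComparisonSummary:
    """Collapse a per-suffix vector into its k-LCF / kACS summary."""
    if vector.n == 0:
        raise ValueError("cannot summarize an empty vector")
    return ComparisonSummary(
        lcf=int(vector.values.max()),
        acs=float(vector.values.mean()),
        filter_percentage=stats.percentage,
        mode=vector.mode,
        k=vector.k,
    )


def _directed_acs(x: EncodedSequence, y: EncodedSequence, k: int, mode: str) -> float:
    from .baselines import greedy_lcf_vector, naive_lcf_vector

    if mode in ("exact", "relaxed"):
        vec, _ = lcf_vector(x, y, k, mode=mode)
    elif mode == "naive":
        vec = naive_lcf_vector(x, y, k)
    elif mode == "greedy":
        vec = greedy_lcf_vector(x, y, k)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return float(vec.values.mean())


def _directed_distance(acs: float, n: int, m: int) -> float:
    if acs == 0.0:
        warnings.warn(
            "kACS is 0 (no shared in-alphabet residue); distance capped",
            RuntimeWarning,
            stacklevel=2,
        )
        return n * math.log(m)
    return math.log(m) / acs - 2.0 * math.log(n) / n


def acs_distance(x: EncodedSequence, y: EncodedSequence, k: int, mode: str = "exact") -> float:
    """Symmetrized ACS-style distance between two sequences (clamped at 0)."""
    if x.n < 2 or y.n < 2:
        raise ValueError("sequences must have length >= 2 for the ACS distance")
    d_xy = _directed_distance(_directed_acs(x, y, k, mode), x.n, y.n)
    d_yx = _directed_distance(_directed_acs(y, x, k, mode), y.n, x.n)
    return max(0.0, 0.5 * (d_xy + d_yx))


def distance_matrix(
    seqs: list[EncodedSequence],
    k: int,
    mode: str = "exact",
    threads: int = 1,
) -> DistanceMatrix:
    """All-pairs ACS-style distance matrix (symmetric, zero diagonal).

    Pairs are independent, so the worker count never changes the values.
    """
    if len(seqs) < 2:
        raise ValueError("need at least two sequences")
    labels = [s.id for s in seqs]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate sequence labels")
    pairs = [(a, b) for a in range(len(seqs)) for b in range(a + 1, len(seqs))]

    def work(pair: tuple[int, int]) -> float:
        a, b = pair
        return acs_distance(seqs[a], seqs[b], k, mode)

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            dists = list(pool.map(work, pairs))
    else:
        dists = [work(p) for p in pairs]

    values = np.zeros((len(seqs), len(seqs)))
    for (a, b), d in zip(pairs, dists):
        values[a, b] = values[b, a] = d
    return DistanceMatrix(labels=labels, values=values)


def write_phylip(matrix: DistanceMatrix, path: str | Path) -> None:
    """Write a square PHYLIP distance matrix (relaxed label width)."""
    with open(path, "w") as fh:
        fh.write(f"{len(matrix.labels)}\n")
        for label, row in zip(matrix.labels, matrix.values):
            cells = " ".join(f"{v:.6f}" for v in row)
            fh.write(f"{label:<12s} {cells}\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix written by :func:`write_phylip`."""
    with open(path) as fh:
        tokens = fh.read().split()
    count = int(tokens[0])
    labels, rows = [], []
    idx = 1
    for _ in range(count):
        labels.append(tokens[idx])
        rows.append([float(t) for t in tokens[idx + 1 : idx + 1 + count]])
        idx += 1 + count
    return DistanceMatrix(labels=labels, values=np.array(rows))


def nj_tree(matrix: DistanceMatrix) -> str:
    """Neighbor-joining tree of a distance matrix, serialized as Newick."""
    import io

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj

    if len(matrix.labels) == 2:
        # Degenerate case below what NJ is defined for: split the distance.
        a, b = matrix.labels
        half = matrix.values[0, 1] / 2.0
        return f"({a}:{half:.6f},{b}:{half:.6f});"
    tree = nj(SkbioDM(matrix.values, ids=matrix.labels))
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()
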