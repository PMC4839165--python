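# klcf

Alignment-free sequence comparison through longest common substrings with
mismatches: an exact filtering algorithm for the per-suffix k-mismatch
longest-common-factor statistic, a faster relaxed variant, naive and greedy
baselines, and the ACS-style distances built on top for distance-matrix
phylogenetics.

## The problem

Composition-based (alignment-free) sequence comparison is attractive for
whole-genome phylogenetics — e.g. on mitochondrial genomes of 16–17 kbp —
because it avoids the cost of full alignments. Exact-match statistics such
as the Average Common Substring (ACS) are fast but brittle; allowing a
bounded number *k* of mismatches captures biological variability much
better but is expensive to compute exactly.

For sequences `x` (length *n*) and `y` (length *m*), let `LCP_k(X_i, Y_j)`
be the length of the longest common prefix of the suffixes starting at `i`
in `x` and `j` in `y` when up to *k* Hamming mismatches are allowed. The
central statistic is the per-suffix vector

    V_k(i) = max_j LCP_k(X_i, Y_j),        i = 1 … n

from which two similarity measures follow at no extra cost:

* **k-LCF** = `max_i V_k(i)` — the longest common substring with *k*
  mismatches;
* **kACS** = `(1/n) Σ_i V_k(i)` — the *k*-mismatch generalization of the
  ACS statistic, which feeds the log-corrected, symmetrized ACS distance
  `d(x,y) = ½ [ ln m / kACS(x→y) + ln n / kACS(y→x) ] − ln n / n − ln m / m`
  used for tree reconstruction.

Computing `V_k` naively costs `O(k·n·m)`. The algorithm here walks the
suffixes of `x` left to right, carrying each suffix's optimum to the next
one, filtering candidate `y`-positions with two per-symbol mask conditions,
and verifying the few survivors with jump-extensions. The **exact** mode
provably reproduces the naive computation; the **relaxed** mode skips an
expensive tie-recovery pass, runs roughly twice as fast, and in practice
stays within a fraction of a percent of the exact kACS value.

## Worked example

```python
>>> import klcf
>>> x = klcf.encode_sequence("ACGT", "x")
>>> y = klcf.encode_sequence("TACG", "y")
>>> vec, stats = klcf.lcf_vector(x, y, k=0)
>>> list(vec.values)
[3, 2, 1, 1]
>>> summary = klcf.summarize(vec, stats)
>>> summary.lcf, summary.acs
(3, 1.75)
```

The vector says: the suffix `ACGT` shares a 3-residue prefix with some
position of `y` (`ACG` at position 2), suffix `CGT` shares 2 (`CG`), and so
on. Its maximum (3) is the longest common substring with 0 mismatches, its
mean (1.75) the ACS statistic.

The same workflow from the shell, including distance matrices and
neighbor-joining trees over a multi-FASTA file:

```bash
klcf compare x.fasta y.fasta --k 5 --mode exact --out results/
# prints: LCF_5 = 27    kACS = 17.472848    filter% = 43.0673    mode = exact
klcf matrix genomes.fasta --k 5 --mode relaxed --out results/ --tree
klcf bench-random --count 5 --length 16500 --k 5 --mode exact --mode relaxed
```

(The `compare` line above shows the output for a pair of uniform random
16,500 bp sequences at `k = 5`: the longest 5-mismatch common substring is
27 bp and the mean over suffixes 17.47 bp; `filter%` is the share of the
`n·m` position pairs on which an extension was actually evaluated.)

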