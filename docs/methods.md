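# Methods

## Statistic and definitions

For sequences `x = x_1…x_n` and `y = y_1…y_m` over an alphabet Σ (DNA by
default), `LCP_k(X_i, Y_j)` is the largest ℓ such that the length-ℓ
prefixes of the suffixes `X_i` and `Y_j` differ in at most `k` positions
(Hamming mismatches). The package computes the per-suffix vector
`V_k(i) = max_j LCP_k(X_i, Y_j)` for all `i`, from which the k-LCF (its
maximum: the longest common substring with k mismatches) and kACS (its
mean: the k-mismatch average common substring statistic) follow directly.

Characters outside the alphabet (N regions, IUPAC ambiguity codes, gaps)
are encoded as a sentinel that matches nothing, itself included, so
undefined regions always count as mismatches. This prevents both spurious
similarity and the pathological behaviour that exact-match heuristics show
when an undefined region makes the best exact match length 0 and the tie
set explode. Lower-case input is upper-cased; there is no soft-masking
concept in the statistic.

All extensions are computed by direct character comparison ("jump
extensions": at most k+1 chained exact extensions, each skipping one
mismatch). Index structures (suffix trees, LCA preprocessing) are
deliberately absent: at the problem sizes this statistic is used for,
naive extensions are faster in practice than constant-time LCA queries
with their preprocessing and constant factors.

## The stepping algorithm

`V_k(1)` is computed by a full sweep of suffix 1 against every position of
`y` (O(km) with jump extensions). Each subsequent value is derived from
the previous one:

1. **Carry-over.** Let `L = V_k(i)` with tie list T (all `j` attaining
   `L`). For `j ∈ T`: if `x_i = y_j`, the pair `(i+1, j+1)` attains exactly
   `L − 1`; otherwise it attains `L + lcp0(i+L+1, j+L+1)` (one exact
   extension past the old final mismatch). If the step-i alignment ran
   into a sequence end, the formulas do not apply (there is no (k+1)-th
   mismatch) and the pair is evaluated directly with a jump extension.
   The maximum of these candidates, `L_max ≥ L − 1`, is the floor for
   step i+1. If every tie sat at the last position of `y`, the step falls
   back to a full sweep.
2. **Filtering.** Any other position `r+1` of `y` can only beat `L_max`
   if (a) `y_r` does *not* match `x_i` (otherwise the pair is bounded by
   `L − 2` inherited from a non-tie), and (b) `y_{r+L}` matches `x_{i+L}`
   — a match longer than `L − 1` must align that anchor inside an exact
   run. Both conditions are evaluated with per-symbol boolean occurrence
   masks over `y`: the complement of the mask of `x_i`, AND the mask of
   `x_{i+L}` shifted by `L`. The anchor is the single symbol at offset
   `L` fixed from step i, even as `L_max` grows during the scan (the
   stronger whole-segment filter would prune more but is unnecessary for
   correctness and is not enabled).
3. **Verification.** Each surviving candidate gets a guessed length
   `c = L + lcp0(i+L+1, r+L+1)` (terms past either end contribute 0).
   If `c < L_max` the candidate is discarded with no further work.
   Otherwise a full jump extension computes the true value, and the
   candidate is accepted — as a new best or as a tie — only if the true
   value equals `c`. Ties are verified exactly like new bests: accepting
   unverified ties would poison the carry of later steps and break
   exactness.
4. **Tie completion (exact mode only).** Filter (b) is unsound precisely
   when the step's final value is `L − 1`: a tie of that length has its
   (k+1)-th mismatch exactly on the anchor. When a step ends at `L − 1`,
   all positions passing filter (a) that were not already processed are
   evaluated directly and equal values join the tie list. The **relaxed**
   mode skips this pass; its tie lists may be incomplete, so later values
   can undershoot — it is always a lower bound, empirically within a
   fraction of a percent on kACS.
5. **First column.** The pair `(i+1, 1)` has no predecessor pair and is
   unreachable by carry or filters; it is evaluated directly once per
   step. Without this the "exact" mode would not actually be exact —
   rare on random data, but real.

The worst case remains `O(k·n·m)`; the filters make the practical cost a
small fraction of that. The scan runs in ascending position order; exact
results are order-independent, and the fixed order makes the instrumented
counters reproducible.

### Instrumentation

`FilterStats.pairs_examined` counts every (suffix, position) pair on which
a jump-extension or direct k-mismatch extension is evaluated: full-sweep
positions, carry-over extensions (the `x_i = y_j` carry computes `L − 1`
arithmetically and is not counted), verified scan survivors, tie-pass
evaluations and the per-step first-column check. Cheap `lcp0`-only
rejections are not counted. This convention is one reasonable reading of
"pairs considered"; other readings (e.g. counting only strict-improvement
verifications) produce materially smaller percentages, so the filtering
percentage should be compared across modes and budgets within this
package, not across tools.

## Baselines

* `naive_lcf_vector` — the quadratic ground truth: every suffix swept
  against every position. The exact mode is required (and tested) to equal
  it element-wise.
* `greedy_lcf_vector` — the kmacs-style heuristic at the statistic level:
  for each suffix, find the longest *exact* match, then run the k-mismatch
  extension only from the positions tied at that exact maximum. It is a
  lower bound and systematically undershoots when the best k-mismatch
  match is not seeded by the best exact match; on uniform random DNA at
  n = 2,000 its mean kACS error is ~18–19%, versus ~0.8% for the relaxed
  mode (both computed by the test-suite and the acceptance script).

## Distances and trees

The ACS-style distance is `d'(x→y) = ln(m)/kACS(x→y) − 2·ln(n)/n`,
symmetrized by averaging both directions and clamped at 0 (the formula has
a known small-negative pathology on near-identical short sequences; the
self-distance is 0 by the clamp). If kACS is exactly 0 (no shared
in-alphabet residue at k = 0) the directed distance is capped at
`n·ln(m)` — the value the formula would give at the smallest positive
kACS — with a runtime warning. Raw kACS and k-LCF are always reported
next to the normalized distance, because precision statements about the
heuristics are made on the raw statistic, not the transform. Distance
matrices are written as square PHYLIP; neighbor-joining trees are
delegated to scikit-bio and serialized as Newick.

## Synthetic study conditions

The generator produces i.i.d. uniform sequences over the alphabet —
deterministic given (count, length, seed). The synthetic panels emulate
the scale of the real use case (mitochondrial genomes, 16,000–17,000 bp;
the benchmarks use 16,500 bp and 5 sequences) but none of its structure:
no base-composition skew, no repeats, no homology between sequences, no
undefined regions (sentinel behaviour is exercised separately with
contaminated fuzz instances). Passing tests therefore demonstrate
algorithmic correctness and the relative behaviour of the variants, not
phylogenetic accuracy on real genomes; uniform sequences are if anything
the *hardest* case for the filters (maximal candidate-set entropy) and a
mild case for the greedy heuristic.

Problem sizes in the default test run and acceptance script are chosen to
keep a full run in minutes on one CPU: oracle-equivalence panels at
n = 50/200/500 with 100 instances per configuration and k ∈ {0,1,2,5,10}
over DNA and binary alphabets; precision panels at n = 2,000 with 20
seeds; filtering-power panels at full 16,500 bp (all ordered pairs of 5
sequences in the tests, 3 in the acceptance script).

## Numerical and design choices

* 0-based positions in the Python API, 1-based in user-facing output.
* Tie lists are kept in ascending position order; `best_j` reports the
  smallest attaining position.
* Two engines implement the same stepping algorithm — a compiled kernel
  (numba) and a pure-Python step-by-step reference — and are tested to
  agree on values *and* instrumentation counters; both are tested against
  the naive oracle and an independent cumulative-Hamming enumeration.
* The distance cap, the 0-clamp, and PHYLIP output at 6 decimals are the
  only places floating point enters; the statistic itself is integral.

## Known limitations

* Exact mode's tie-completion pass scans most of `y` whenever a step ends
  at `L − 1`; on uniform random DNA that is frequent, so exact mode's
  advantage over the naive oracle is smaller there than on real,
  repeat-bearing genomes. Relaxed mode is the practical default at scale.
* The per-symbol mask filters assume a small alphabet; a large (e.g.
  protein) alphabet works but dilutes filter (a)'s power.
* The greedy baseline reproduces the kmacs *idea* at the statistic level,
  not the kmacs implementation; runtime comparisons with it are out of
  scope.
* No attempt is made to bundle or reproduce analyses of specific real
  genome sets; the CLI supports that workflow (`matrix --tree`) on
  user-provided FASTA.
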