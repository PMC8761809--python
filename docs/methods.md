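# Methods

## Problem and model

Overlap–layout–consensus (OLC) assembly begins by finding, for every
sequencing read, the other reads whose **suffix equals its prefix** — the
dovetail adjacencies that become edges of the assembly graph. `sufpref`
computes these all-pairs suffix–prefix overlaps in a single pass over a
generalized suffix array, in two variants:

* **exact** — for high-accuracy long reads (PacBio HiFi class), where the
  overlap must match base-for-base;
* **end-tolerant** — for reads whose errors cluster at the two ends, where
  up to `K` bases may be cut from the source read's tail and from the
  target read's head before the remaining flanks must match exactly.

Both variants are forward-strand only: reads are treated as strings over
`{A,C,G,T,N}` and reverse-complement overlaps are out of scope (the
simulator samples a single strand, and real pipelines can pre-orient or
duplicate reads).

## Data structures

All reads are stitched into one *original string*: each read followed by a
separator, the whole text ended by a terminator. Internally every symbol is
remapped to an integer so that

    terminator < sep_1 < sep_2 < … < sep_n < A < C < G < T < N,

i.e. each separator occurrence is its own symbol, ranked by position. This
single choice makes an ordinary suffix sort of the integer text a correct
*generalized* suffix sort: the first `n+1` ranks are exactly the sentinel
positions, no common prefix ever crosses a sentinel, and the longest common
prefix (LCP) array automatically counts base symbols only. `N` is kept as a
fifth base (above `T`) so read coordinates are preserved.

Three arrays are built over the text of length `L`:

* `SA(i)` — start position of the rank-`i` suffix;
* `LCP(i)` — longest common prefix of the suffixes ranked `i-1` and `i`;
* `DA(i)` — the read owning position `SA(i)` (separators belong to the read
  they follow; the terminator to pseudo-read `n+1`).

Read intervals `Fi/Se/LEN` are derived from the **sorted positions** of the
`n+1` sentinel entries rather than from their ranks, which makes the
derivation independent of any backend's sentinel-ordering convention. `Se`
points at the last *base* of a read, so `LEN` counts bases and every
downstream length formula is consistent; the length of the suffix starting
at position `p` of read `x` is `Se(x) − p + 1`.

### Suffix-array backend

The default backend is a vectorized prefix-doubling (Manber–Myers) sort in
numpy. Doubling stops as soon as all ranks are distinct, which for
sentinel-separated reads happens once the window exceeds the longest
repeated prefix — bounded by the read length — so a 10-Mb text of 5-kb
reads needs ~14 rounds (≈1 minute on one core). A naive
explicit-comparison construction is shipped alongside as the conformance
oracle; the test suite checks the two agree exhaustively on tiny alphabets
and on randomized instances. Any linear-time generalized-SA construction
could be dropped in; conformance is defined by the invariants, not the
algorithm.

## Exact traversal

The keystone identity is that for ranks `X < Y`,
`lcp(SA(X), SA(Y)) = min(LCP[X+1..Y])`. A monotonic stack maintains, at
every rank `i`, the set of earlier suffixes that are still *entire
prefixes* of the current suffix: each element stores a suffix length
(`first`, strictly increasing bottom to top) and a fixed-capacity rolling
queue of the reads owning suffixes of that length. Per rank:

1. **pop** every element with `first > LCP(i)` — those suffixes can no
   longer fully match anything later;
2. if `SA(i)` is the *start of a read* (a complete-read suffix), **harvest**:
   walk from the top downward emitting `(source, first)` pairs, queue
   members newest-first, skipping the target's own suffixes, until `k`
   results (default 10). Deeper elements are valid shorter candidates; a
   `top_only` flag restricts the walk to the top element for strict
   stream-of-top behaviour;
3. **push or merge** the current suffix: join the top's queue if the
   lengths are equal, else push a fresh element.

Every emitted pair is a true overlap by the stack invariant (soundness),
and the rank-1 answer per target is the global maximum (completeness) with
one structural exception: when a candidate suffix equals the **entire
target read**, its rank relative to the target is decided by separator
order, i.e. input order, and a later-input source is missed. This is
inherent to any single forward pass; at realistic read lengths a
whole-read coincidence between distinct reads does not occur, and the test
suite pins down that this is the only divergence from a brute-force
oracle.

Records are streamed in target-encounter order; `head_cut = tail_cut = 0`;
`containment` flags overlaps that consume the whole source read.

## Tolerant traversal

With cut budget `K`, a read's prefix may start anywhere in its first `K+1`
positions, and a candidate suffix may sacrifice up to `K` tail bases. Two
changes to the stack discipline:

* **merge-on-pop** — when `LCP(i)` falls below the top, *all* elements with
  `first ≥ LCP(i)` are popped and the best one is re-pushed truncated to
  `first = LCP(i)`. "Best" minimizes the implied tail cut
  `full_suffix_length − LCP(i)`; representatives whose cut would exceed `K`
  are not eligible (their cut can only grow later, so they are dead weight
  that would mask valid deeper candidates). Ties keep the most recent
  representative, consistent with the replace-on-equal push rule.
* **harvest near read heads** — at every suffix whose head offset
  `h = SA(i) − Fi(DA(i))` is at most `K`, the stack top is offered to read
  `DA(i)` as a candidate with `head_cut = h`: the per-read best is kept in
  the `ANS`/`LEN` arrays, and every candidate also goes into the read's
  min-heap of the `k` best answers (heap top = worst kept answer;
  replace-and-sift when full).

Stack elements hold a single representative SA rank plus a *shadow*: the
previously displaced equal-length representative with a different owner.
The shadow, together with a harvest that walks past self-owned tops,
preserves exactly the information the exact version's rolling queue keeps,
and makes the `K = 0` run reproduce the exact version's rank-1 records —
a property the suite verifies on hundreds of random instances.

The tolerant pass is *greedy*: a single representative survives each merge,
and matches whose source suffix sorts lexicographically **after** every
harvestable target suffix are unreachable in one pass (the package
documents this as an upper bound against the brute-force cut oracle rather
than claiming equality). Output is deferred until the pass completes,
deduplicated per (target, source) keeping the longest match, ranked by
descending matched length, and emitted in input-read order. A multi-`K`
sweep helper reruns the pass for several budgets and keeps the per-pair
maximum.

## Simulator and accuracy protocol

The generator reproduces the validation protocol the method is judged by:

* reference: uniform i.i.d. `A/C/G/T`, default 500 kb;
* reads: substrings at uniform random starts, default 2,000 × 5,000 bp
  (20× coverage), true intervals recorded in a check file;
* end errors (tolerant protocol): each read is split into three parts —
  two flanks of `⌊(1−core_fraction)/2·len⌋` bases around an untouched core
  of at least half the read (`core_fraction = 0.5`); each flank base is
  substituted independently with probability `1 − flank_accuracy`
  (default 0.2) by a uniformly chosen different base. Substitutions only:
  lengths, and hence check intervals, stay exact.

Evaluation: records shorter than 100 bp are invalid data and discarded;
a surviving record is *correct* when the source and target reads' true
reference intervals (0-based, half-open) share at least one position.
Accuracy = correct/evaluable; an empty evaluable set raises instead of
returning a vacuous 1.0.

What the simulator does **not** model: indels and homopolymer errors,
chimeric reads, coverage bias, reverse strands, diploidy. Passing the
protocol therefore demonstrates the algorithmic correctness of the overlap
machinery under the stated error model, not robustness to full real-world
long-read noise; reads with random internal errors should be corrected
first (exact version) or have their centers corrected (tolerant version).

## Defaults and numerical choices

| parameter | default | meaning |
|---|---|---|
| `k` / `k_top` | 10 | candidates kept per read (both versions) |
| `queue_size` | = k | rolling-queue capacity per stack element (exact) |
| `min_overlap` | 1 (library), 100 (evaluation) | shortest reported/evaluable overlap |
| `K` | required input | max head/tail cut (tolerant); set to the flank length when known |
| `flank_accuracy` | 0.8 | per-base flank accuracy in the simulator |
| `core_fraction` | 0.5 | error-free central fraction of each simulated read |

Tie-breaking is deterministic everywhere: equal-length exact candidates
emit newest-first (rolling-queue order); tolerant emission sorts by
(length desc, tail cut, head cut, source index); merge ties keep the most
recent representative. Duplicate read identifiers get `_dupJ` suffixes.
Degenerate inputs: a single read yields no records; empty files, empty
sequences and non-`ACGTN` symbols raise immediately.

The desk-scale study size used throughout the tests and the reproduction
script — 500 kb reference, 2,000 × 5 kb reads — keeps 20× coverage, the
read:reference length ratio, and the ≥100 bp evaluation filter of the
protocol while indexing ~10 Mb of text, the package's own choice of a
size that exercises every code path at full fidelity.

## Known limitations

* Whole-read-identical candidates are reported one-directionally (input
  order decides), see above.
* The tolerant pass is greedy and one-directional; its reported best can
  fall short of the brute-force cut oracle on adversarial toys, though on
  end-error data at coverage every true adjacency offers many harvest
  opportunities (one per head offset ≤ K) and the protocol accuracy is
  unaffected.
* No reverse-complement handling, no `.gz` transparency beyond what the
  caller does, no contig construction: the output graph is the hand-off
  point to downstream layout tools.
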