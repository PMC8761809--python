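# sufpref

All-pairs **suffix–prefix overlap** detection for long sequencing reads,
built on a generalized suffix array and a monotonic stack.

Overlap–layout–consensus assembly needs, for every read, the other reads
whose suffix matches its prefix — the dovetail adjacencies that become the
edges of the assembly graph. `sufpref` finds them in a single linear pass
over the suffix array of the sentinel-concatenated read set, instead of
aligning all read pairs:

* **exact mode** — base-perfect overlaps, for high-accuracy long reads
  (PacBio HiFi class) or pre-corrected data;
* **tolerant mode** — overlaps allowing up to `K` bases to be cut from the
  source read's tail and the target read's head, for reads whose
  sequencing errors cluster at the two ends.

## Method in brief

The reads `r_1 … r_n` are concatenated as `r_1·$_1·r_2·$_2·…·r_n·$_n·#`
with per-position separator ranks, and three arrays are built: the suffix
array `SA`, the LCP array, and the document array `DA` (which read owns
each suffix). The identity
`lcp(SA(X), SA(Y)) = min(LCP[X+1..Y])` lets a monotonic stack maintain, at
every rank, exactly the earlier suffixes that are still full prefixes of
the current suffix. When the traversal reaches a complete read (exact
mode), the stack holds all reads whose suffix equals that read's prefix,
longest on top — harvesting the top `k` gives the read's best candidate
partners with no further comparison. Tolerant mode generalizes both sides:
elements popped by a falling LCP are merged back truncated (a tail cut
within budget `K`), and every suffix starting at most `K` bases into its
read harvests candidates for that read's cut prefix, maintained per read
in a min-heap of the `k` best. Results become a TSV edge list and,
optionally, a GFA-1 or PAF file for downstream tools.

See `docs/methods.md` for the full model, invariants, tie-breaking rules
and limitations.

## Worked example

Simulate 300 error-free reads of 1 kb from a random 50 kb reference
(ground-truth coordinates go to the check file), find exact overlaps, and
score them against the truth:

```sh
sufpref simulate --out-reads reads.fa --out-check check.tsv \
        --ref-len 50000 --n-reads 300 --read-len 1000 --seed 42
sufpref exact --in reads.fa --out overlaps.tsv --min-overlap 100 --gfa graph.gfa
sufpref evaluate --overlaps overlaps.tsv --check check.tsv
```

```
$ head -4 overlaps.tsv
target_id	source_id	overlap_len	head_cut	tail_cut	containment	rank
read229	read57	983	0	0	0	1
read229	read29	927	0	0	0	2
read229	read295	906	0	0	0	3

$ sufpref evaluate --overlaps overlaps.tsv --check check.tsv
accuracy	100.0000%	(1684 evaluable records)
```

Reading the output: `read57`'s final 983 bases equal `read229`'s first 983
bases exactly (`head_cut`/`tail_cut` are 0 in exact mode), making it the
best assembly predecessor of `read229`; the next-ranked candidates overlap
by 927 and 906 bases. The evaluation line says that all 1,684 reported
overlaps of ≥ 100 bp connect reads whose true reference intervals
intersect — every reported adjacency is genomically real.

For end-noisy reads, add `--errors` to `simulate` (two 80%-accurate flanks
around an error-free core of at least half the read) and run
`sufpref tolerant --K <flank length>` instead; `head_cut`/`tail_cut` then
report how many bases were trimmed from the target's start and the
source's end before the exact match.

The same functionality is available as a library:

```python
from sufpref import (read_sequences, concatenate, build_index,
                     derive_boundaries, find_overlaps_exact)

rs = read_sequences("reads.fa")
ct = concatenate(rs)
si = build_index(ct)
b = derive_boundaries(si, ct)
records = find_overlaps_exact(si, b, k=10, min_overlap=100)
```

Short narrative scripts for each capability live in `examples/`.

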