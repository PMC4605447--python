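# Methods

## Model

The package implements text-based compound similarity over SMILES strings.
No chemistry is parsed: a compound is a printable-ASCII string, and its
feature set is the multiset of overlapping q-character substrings (Lingos)
produced by a sliding window of offset 1. A string of length *l* yields
max(0, *l* − *q* + 1) Lingos. The per-compound **LINGO profile** stores:

| field     | meaning                                   |
|-----------|-------------------------------------------|
| scores    | distinct Lingos packed into integers, sorted ascending |
| numbers   | multiplicity of each distinct Lingo        |
| length    | *l*, the character count                   |
| magnitude | the distinct-Lingo count                   |

Packing is big-endian per-character ASCII (first character in the most
significant byte), so integer comparison of scores coincides with
lexicographic comparison of substrings and a score fits 32 bits for q ≤ 4
(64 bits up to q = 8; larger q is rejected). The byte order is a free choice
— any injective packing yields identical similarities — but order
preservation makes "sorted scores" equal "sorted substrings", which is
convenient for reasoning and testing.

The Tanimoto coefficient of two profiles is intersection-over-union of the
Lingo collections, computed by one linear merge of the two ascending score
lists (cost ≤ magnitude_a + magnitude_b merge steps, instrumented and
tested):

* **multiset** (default): I = Σ_shared min(n_a, n_b), U = Σn_a + Σn_b − I.
* **set**: I = number of shared distinct Lingos, U = mag_a + mag_b − I.

The multiset form counts repeats, so `CCCCC` vs `CCCC` scores 1/2 in
multiset mode but 1 in set mode (one distinct Lingo each, shared). The
multiset interpretation is the default because it is the standard multiset
Jaccard over q-gram bags and the stricter of the two; the set mode is kept
as an engine/CLI option. Intersections and unions are accumulated in exact
integer arithmetic and divided once in double precision, so coefficients
carry no accumulation-order sensitivity.

**Degenerate inputs.** A string shorter than q has an empty profile. Any
comparison involving an empty profile — including empty vs empty — is
defined as 0: a molecule too short to produce a Lingo matches nothing, not
everything. This is a deliberate convention (the alternatives, 1 or NaN,
both poison thresholded screening).

**Ring-digit zeroing** (off by default): optionally every digit outside a
bracket atom — a ring-closure label whose numeric value is arbitrary — is
replaced by '0' before profiling, making profiles invariant to ring
numbering (`C1CCCCC1` ≡ `C2CCCCC2`). It is off by default so the profile
reflects the string exactly as written.

## Engine

An A2A run has three phases. *Preprocessing* builds every profile once and
packs them into flat CSR-style arrays. The *comparison phase* fills the
k × r coefficient matrix: the **query** library is partitioned across an
abstract worker pool, each worker computes its own rows with a batched merge
kernel (numba-JIT when available, releasing the GIL so threads overlap;
otherwise a pure-Python kernel with identical semantics), and rows merge
back in original query order. The *output phase* reports entries **strictly
greater** than the threshold, ordered by query, then descending coefficient,
then database id. Strictness has a documented edge: at threshold 1.0 nothing
is reported, not even identical compounds.

Workers abstract both levels of a hierarchical parallel machine (threads
within a block, devices of unequal capability); relative capability enters
as per-worker weights. Database profiles are shared by all workers; only the
query is split. Because partitioning decides *who* computes a row and never
*what* is computed, the matrix is bit-identical across worker counts,
strategies and policies — a tested invariant, and the reason correctness
does not ride on the scheduler.

For memory-bounded operation, `screen()` tiles the database in chunks
(`--chunk-size`), filters each k × chunk block at the threshold, and merges
the partial hit lists; its output equals the materialize-then-filter route
exactly. The CLI uses the streaming route unless `--matrix-out` asks for the
full matrix.

## Scheduling

Four workload measures estimate a compound's comparison cost from its
profile: **S** = sum of unique scores, **N** = sum of numbers, **L** =
length, **M** = magnitude. S is read literally as the *unweighted* sum over
unique scores (a multiplicity-weighted variant is out of scope). N and L
satisfy N = L − (q − 1) for every compound with length ≥ q, so they order
compounds identically — a structural explanation for why strategy choice
matters little, which the test suite asserts. An empty profile costs 0 under
S, N, M; L stays the raw character count.

Two deterministic assignment policies map sorted-descending workloads to
workers (ties: lower compound index, then lower worker number):

* **greedy LPT** (default): assign the next compound to the worker
  minimizing projected weighted load (load + w)/weight. On equal weights it
  carries the classical (4/3 − 1/(3m))·OPT makespan guarantee, checked
  against a branch-and-bound exhaustive optimum on small random instances.
* **sorted round-robin**: deal the sorted list cyclically, ignoring weights
  — the analogue of mapping a sorted library onto the threads of a block.

Descending sort order is required for LPT's guarantee. The `imbalance`
diagnostic — max weighted worker load over the weighted mean load, 1.0 at
perfect balance, 0 for zero total load — is how strategies are compared at
desk scale; wall-clock speedups are hardware statements this package does
not attempt.

## Synthetic libraries

`synth` generates deterministic random text over a SMILES-like alphabet
(organic-subset atoms, aromatics, bonds, branches, brackets, digits, stereo
and charge marks), with uniform or truncated-normal length distributions.
Defaults — 20–80 characters, uniform — model the short-string regime of
drug-like SMILES libraries at desk scale. Generated strings are **not**
chemically valid molecules, and deliberately so: every stage of the method
treats SMILES as text, so length distribution, alphabet and repeat structure
are the features that matter. Consequently, passing tests demonstrate the
text-processing pipeline, not chemical retrieval quality on real libraries;
character frequencies are uniform rather than empirical, which slightly
understates the Lingo collision rate of real SMILES. One generated
constraint exists purely for format round-tripping: a string never starts
with '#', which the `.smi` reader would take for a comment.

`mutate_pair` plants controllably similar pairs: exactly *s* seeded random
positions are replaced by different characters. One substitution destroys at
most q overlapping Lingos, so the multiset intersection of a mutant with its
parent is at least (L − q + 1) − q and mean similarity decays monotonically
with *s* — both tested properties, and the mechanism behind the planted hits
used in end-to-end determinism checks.

## Numerical and design choices

* q defaults to 4 — the established sweet spot for q-gram similarity of
  SMILES; it is configurable, with packing widened to 64 bits for 4 < q ≤ 8.
* Threshold defaults to 0.85, comparison strict (>); coefficients are exact
  integer ratios evaluated once in double precision, so a constructed pair
  with coefficient exactly 17/20 sits exactly at 0.85 and is excluded.
* Profiles are rebuilt per run rather than cached to a sidecar file;
  construction is tens of microseconds per compound, far below comparison
  cost at any library size where caching would matter.
* Test and acceptance problem sizes (up to 1,000 × 1,000 compounds, ~10⁶
  pairwise comparisons) are the package's desk-scale reference conditions;
  the engine itself is size-agnostic and streams hits to keep memory at
  O(k × chunk).

## Known limitations

* No chemical normalization: two SMILES spellings of the same molecule
  (beyond ring-digit zeroing) have different profiles. Canonicalize upstream
  if that matters.
* The set/multiset choice changes coefficients for repeat-heavy strings;
  results from the two modes are not comparable.
* Worker pools are OS threads; with the pure-Python kernel they serialize on
  the GIL (results unchanged, speed only).
* Workload strategies balance *estimated* cost. The strategy is applied to
  the axis being partitioned (the query); the database contributes the same
  additive merge cost to every query row, so a query-side measure is the
  right discriminator between rows, but the estimate is still a proxy, not a
  measurement.
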