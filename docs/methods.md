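# Methods

## Problem and approach

Overlap detection between noisy long reads (SMRT-class data: 10–15%
per-base error, predominantly insertions and deletions) is the first and
most expensive stage of overlap–layout–consensus assembly.  This package
detects all-vs-all pairwise overlaps and reports **boundary coordinates
only** — no base-level alignment or CIGAR is ever produced by the
detector; full dynamic programming is reserved for the evaluation
harness, where optimality matters and cost is accepted.

The detector is a hierarchical seed method:

1. **Indexing.**  Reads are stored 2 bits per base (A=0, C=1, G=2, T=3;
   complement = 3 − code) with the reverse-complement strand materialized
   alongside.  Every k-mer (default k = 16) of both strands of every
   reference read is recorded in an occurrence index.  k-mers occurring
   more than `max_kmer_count` times (default 10 000) are dropped as
   repeat-induced; k-mers occurring fewer than `min_kmer_count` times
   (default 2) are dropped as unusable.  The low-count floor is applied
   only in self-overlap mode: when reference and query sets coincide, a
   k-mer supporting a true overlap necessarily occurs at least twice in
   the indexed set, so the floor is safe there and is forced to 1 in
   two-set mode where it is not.  The floor is summed over strands.
2. **Matching.**  Query reads are scanned on the forward strand only;
   reverse-orientation overlaps surface through the indexed reverse
   strands.  For each (query, reference) pair the strand with the larger
   raw match count is kept (tie → forward); matches are deduplicated on
   (qpos, rpos) and sorted.
3. **Clustering.**  A single greedy pass over the (qpos, rpos)-sorted
   matches breaks a new cluster at the first match inconsistent with its
   predecessor.  Consistency of adjacent matches is the diagonal-drift
   bound |Δq − Δr| ≤ `max_shift` · max(Δq, Δr) with both gaps
   non-negative.  The prose definition ("equidistant within a threshold
   governed by maxShift") fixes no formula; relative drift against the
   larger gap is the natural formalization of a 20% indel tolerance and
   is pinned here as the package's defining predicate, checked per
   adjacent pair (not cumulatively).  If no cluster survives selection
   plus the binomial filter, the pass is retried with the sort order
   reversed ((rpos, qpos)), which separates interleaved chains.
4. **Selection and filtering.**  The cluster with the most matched query
   bases wins (ties → more hits, then leftmost on the query).  Seed hits
   in an alignment of length L are modelled as Binomial(L, p) with
   p = (1 − e)^(2k) — a seed survives only if all k bases are error-free
   on both reads — and a cluster is rejected when its hit count falls
   below μ − 3σ = Lp − 3√(Lp(1−p)).
5. **Extension.**  The winning cluster's region is pushed outward with
   k′-mer matches (default k′ = 12) confined to the maximum alignment
   window obtained by projecting the seed bounds with the indel allowance
   (1 + max_shift).  Candidates are consumed in order of proximity to the
   current boundary; a candidate violating the drift bound is skipped
   (not terminal), and extension stops when the accumulated k′ hit set
   falls below the μ − 3σ floor computed with p = (1 − e)^(2k′) and L the
   currently extended span.  k′-mers are matched locally within the
   bounded windows rather than through a global k′ index, which would
   dwarf the k index for no benefit.
6. **Validation and output.**  All k′-mer matches across the final region
   (deduplicated by position pair) face the μ − 3σ floor once more, with
   L the longer region span; at least one supporting hit is always
   required.  Survivors are written in a 12-column M4-style dialect with
   forward-strand coordinates (reverse-strand positions flipped via
   pos_fwd = len − pos_rev, half-open).

### Alignment length estimate

The alignment length that parameterizes the binomial filter is computed
configuration-generally: L = max(seed spans) + min(q_L, r_L) +
min(querySize − q_R, refSize − r_R), i.e. the seed region plus the
largest extension each side can support before one read ends.  In the
configuration where the query overhangs left and the reference right,
this reduces exactly to the projected form r_R + querySize − q_R; the
general form keeps the filter symmetric under swapping the overhang
orientation, which a one-sided formula is not — applied verbatim to the
mirror configuration it would inflate L by both non-overlapping tails
and reject roughly half of all true dovetail overlaps.

### Numerical and policy choices

* Non-ACGT input: lowercase is uppercased; any other character becomes
  'A' deterministically and is counted in a per-read warning.  A 2-bit
  alphabet has no fifth symbol, and a deterministic replacement keeps
  every run reproducible.
* Strand-count tie → forward; best-cluster ties → larger hit count, then
  leftmost on the query.  All tie-breaks are deterministic.
* Extension-time and validation-time μ − 3σ use k′ in p, the only choice
  consistent with counting k′-mer hits; the original k-mer hits are not
  folded into the final count (a k-mer hit implies overlapping k′ hits
  and would be double counting).
* The reported identity is an estimate inverted from the k′ hit density
  through the p-formula (identity ≈ (hits/positions)^(1/(2k′))), not a
  DP identity — the detector never computes one.
* Overlaps shorter than `min_olap_len` (default 100 bp) are suppressed
  from output; the evaluation applies its own 2000 bp analysis floor
  separately, so detector output stays complete.
* `threads` is accepted for interface compatibility.  Per-pair work is a
  pure function of (query, reference, configuration) and records are
  sorted by (query_id, ref_id) before writing, so any parallel schedule
  is required to reproduce the serial output byte for byte; the
  implementation runs serially.

## Evaluation harness

Reported overlaps are judged against the *optimal* local alignment
(Smith–Waterman, linear gap penalty, default +2/−3/−5) rather than a
third-party mapper.  For each assessed pair, the optimal alignment is
computed in both orientations of the target (higher score wins, tie →
forward) by a numba-compiled linear-memory kernel: one pass for score
and end cell, one pass over reversed prefixes for the start cell, with
ties broken toward the smallest end coordinates.  The optimal alignment
must be *good* — length ≥ `min_align_len` (default 2000 bp) and identity
≥ 0.6 over its interval, measured by edlib global alignment of the two
interval substrings — before a verdict is issued.  Three nested
correctness modes compare the report with the optimum: **presence** (the
pair was reported), **length** (reported length and direction within
`bound_tolerance` (default 0.2) of the optimal length), **bounds**
(additionally all four endpoints within the same tolerance).  By
construction bounds ⊆ length ⊆ presence, so the three sensitivities are
monotone.

Sensitivity samples true-overlap pairs from ground truth; a sampled pair
whose optimal alignment fails the goodness floor is excluded from the
denominator (it admits no reference answer), while in precision — which
is truth-free and samples reported pairs — such a report counts as
incorrect.  Specificity samples pairs with no placement intersection and
measures the fraction not reported.  All sampling is uniform without
replacement from a seeded generator, so estimates are bit-for-bit
reproducible.

## Read simulator

The simulator emulates SMRT-style data: an i.i.d. uniform genome; read
lengths lognormal with mean 8000 bp truncated to [1000, 40000] by
redraw; placements and strands uniform, reads drawn until the target
coverage is met; and an i.i.d. per-base error process at 12% total error
split 50/35/15 insertion/deletion/substitution — indel-dominant, with
errors treated as random, which is the minimal model matching the
technology's error character.  It does **not** model homopolymer bias,
chimeras, or quality values, and the ground-truth overlap bounds are
projected under the error-free approximation: indels drift read
coordinates by O(error_rate · overlap length), which the 20% evaluation
tolerance absorbs.  Passing tests on this generator therefore
demonstrate correct behaviour under random indel-dominant noise, not
under sequence-context-correlated error structure.

## Study scales

The bundled studies run on a 200 kb repeat-free genome: 20x error-free
(every true overlap ≥ 2000 bp must be recovered with exact bounds —
complete k-mer coverage makes the seed region coincide with the true
overlap) and 30x at 12% error (bounds-mode sensitivity and DP-validated
precision).  DP validation is quadratic in read length, so the
estimators sample 150 pairs per estimate in the acceptance script (100
in the test suite, 500 for specificity); at the observed margins the
binomial sampling error of these sizes is far smaller than the distance
to the pass thresholds.  Smaller fixtures (30–40 kb) back the unit and
property tests.

## Known limitations

* Only the winning strand's matches are clustered; pairs with genuinely
  ambiguous orientation (palindromic repeats) resolve by tie-break.
* One overlap per read pair is reported — by design, as assembly
  consumes the single best overlap.
* The binomial model assumes independent per-position seed survival;
  clustered errors violate this mildly in real data.
* The index is in-memory only; desk-scale read sets are the target, not
  multi-Gbp production runs.
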