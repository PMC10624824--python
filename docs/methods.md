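# Methods

This note documents the models, algorithms and numerical choices behind
`gapweld`, what the synthetic-data generator does and does not emulate,
and the limitations a user should know before applying the pipeline to
real assemblies.

## Coordinates, strands and case

All in-memory coordinates are 0-based half-open; AGP, coordinate tables
and human-readable reports use 1-based inclusive coordinates and are
converted at the I/O boundary.  Minus-strand MAF rows are normalized to
forward-strand intervals at parse time, so no downstream code handles
reverse-strand offsets.  Base case is preserved everywhere (lowercase =
soft-masked repeat, which the repeat-ratio windows rely on); all base
*comparisons* are case-insensitive.

## Gap model

A gap is a maximal run of N/n bases.  The discovery threshold
`min_len` defaults to 10 bp: isolated Ns are usually ambiguity calls
rather than assembly gaps, and published gap sets typically come from
an assembly's official annotation, so a discovery cutoff has to be
chosen when scanning sequence directly.  An explicit gap BED can be
supplied instead to reproduce a specific gap universe.  Gaps touching a
sequence end are flagged *terminal*: one flank is missing, so the
closure criteria cannot be met and they are reported as unevaluable.

## Flank alignment

Each gap contributes up to `F = 10,000` bp of flanking sequence per
side (truncated at sequence ends and at neighbouring gap edges).  The
built-in aligner is a deterministic seed-and-chain design:

1. **Anchors.** Exact k-mer matches (`k = 15`) between flank and donor,
   both strands.  The donor is indexed once as a sorted array of 2-bit
   k-mer codes (numpy); k-mers containing non-ACGT characters never
   anchor, and donor k-mers occurring more than `max_hits = 100` times
   are skipped as hyper-repetitive.
2. **Chaining.** Anchors on one donor sequence and strand are grouped
   into tight diagonal bands (drift ≤ 30 bp, the small-indel budget).
   The tight band matters: with a permissive band, anchors from a
   nearby repeat copy (offset by less than the band width) can be
   absorbed into a chain and split it.  Bands are split wherever
   consecutive anchors are more than `max_anchor_gap = 500` bp apart on
   either axis, then strictly colinear chains are re-merged across
   larger indels.
3. **Filtering.** Chains whose anchored query span is below
   `min_cluster = 25` bp are dropped.  The defaults k = 15 /
   min_cluster = 25 mirror the minimum-match and minimum-cluster
   lengths conventionally used when placing flanks with a genome
   aligner.
4. **Refinement.** Each kept chain's spanned query/donor substrings are
   globally aligned with edlib (Needleman–Wunsch mode), and matches /
   aligned columns are counted by walking the returned path against the
   actual sequences.  A column is a match only when both bases agree
   case-insensitively and neither is N; indel columns stay in the
   denominator, so `pct_identity = 100·matches/aligned_columns` follows
   the common coordinate-table convention.  Edit-distance-optimal paths
   coincide with match/mismatch/gap-scored paths on the
   point-substitution divergences this pipeline targets, and the C
   implementation keeps a 200-gap run in tens of seconds; the identity
   semantics above are independent of the path engine.

Multiple alignments per flank are reduced by a fully specified ordering
(longest query coverage, then highest identity, then donor coordinate),
so results are deterministic across platforms and donor record order.
Flanks aligning to both strands yield separate records, never merged.

The built-in aligner is a stand-in, not a clone of any external genome
aligner.  For bit-compatibility with an external run, alignments can be
ingested as a tab-separated coordinate table (1-based inclusive, query
named `<gap_id>|L` / `<gap_id>|R`); reversed target coordinates denote
minus-strand hits.

## Closure criteria

A gap closes only when all four criteria hold for the two chosen (best)
flank alignments:

| criterion | rule | default |
|---|---|---|
| c1 | each alignment's flank coverage **strictly greater than** `min_aln_len` | 5,000 bp |
| c2 | mean of the two identities **strictly greater than** `min_mean_identity` | 90.0 % |
| c3 | same donor sequence, same strand, donor order consistent with target order | — |
| c4 | no N under either donor placement | — |

Both thresholds are strict inequalities, following the criteria's
"larger than"/"higher than" phrasing: 5,000 bp exactly fails c1 and a
mean of 90.0 exactly fails c2.  c2 averages the two *chosen*
alignments, not all candidate records.  c3 additionally requires the
same donor sequence even though order/orientation alone are the named
conditions: cross-sequence placements cannot define a fill, so the
requirement is forced by well-definedness.  c4 checks only donor bases
under the two placements; `require_fill_n_free` optionally extends the
check to the fill itself.

**Fill projection.**  How fill coordinates derive from flank alignments
is a design choice here: the gap-proximal alignment ends are projected
onto the donor and extended by any unaligned gap-proximal flank tail —
tail bases are target sequence and must not appear both in the retained
flank and in the fill.  On '−' the fill is the reverse complement of
the spanned donor interval.  If the two projections cross, the fill is
empty and the overlap is tolerated up to `max_overlap` (default 0: any
crossing rejects, with the distinct reason code `overlap-too-large` so
the policy is auditable).  Projections escaping the donor sequence
reject with `fill-out-of-bounds`.

Closures on one sequence are applied in descending coordinate order, so
earlier coordinates remain valid; all bases outside closed gaps are
byte-identical in the output.

## Concordance statistics

Match/mismatch counting skips columns where either row has a gap
character — the reported total is match + mismatch only, which is the
convention that makes per-chromosome `Match/Total` ratios reproducible
from the published count tables this package's fixtures carry.  N
against anything counts as mismatch by default (conservative);
`skip_n` excludes those columns.  Overlapping blocks are counted as
given with a warning (`dedup` merges by first-genome coordinates
first).  Synteny coverage is the merged-union length of one side's
block intervals divided by the genome size.

## QV

`QV = −10·log₁₀(error_bases / callable_bases)`, capped (default 60) for
zero-error sequences to avoid −∞; the cap is configurable and the raw
counts are always emitted so users can re-derive under other
conventions.  Error bases per variant = reference-allele length (SNP 1,
deletion len(REF), insertion 1 anchor base); variant-calling
conventions differ between studies, and carrying the counts keeps the
choice transparent.

## Windows and the Mann-Whitney engine

Repeat ratios use non-overlapping windows (default 50 kb) tiled from
position 0; the denominator is non-N bases.  Terminal windows shorter
than half the window size are dropped (too noisy), as are windows with
no non-N bases.  A window belongs to the closed-gap group if it
overlaps any closed-gap interval by ≥ 1 bp.

The Mann-Whitney U test uses exact enumeration over all C(n+m, n)
labelings (midranks for ties) when both groups have ≤ 8 observations,
and scipy's tie- and continuity-corrected normal approximation
otherwise.  For tie-free 8/8 data the worst-case absolute difference
between the two engines over the whole U support is 0.0109 (at
U = 24/40), a property of the normal approximation itself — without
continuity correction it would be 0.046.  The unit tests assert this
analytic bound by enumerating it directly.

## Scaffolding benchmark

A contig counts as *connected* iff its scaffold holds at least two
contig components.  Physical coverage at a position is the number of
mate-pair outer spans containing it, computed per sequence by a
difference array and prefix sum, which makes the genome-wide mean equal
Σ span-length / Σ sequence-length exactly.  The per-gap statistic is
the mean depth over the gap interval; `midpoint` and `span-whole-gap`
modes exist for sensitivity analysis, since published descriptions of
"physical coverage at gaps" do not always distinguish the three.  The
pair loader's insert window (5–25 kb) brackets a 10–15 kb long-insert
library and is recorded in the output metadata because it conditions
every number.  Orientation filtering defaults to on for SAM/BAM input
and off for TSV input (TSV producers are assumed pre-filtered).

## Synthetic data

The generator's defaults are the *paper-scale-mini* study conditions: a
5 Mbp donor in five 1 Mbp sequences, two soft-masked repeat families
(40 × 300 bp and 20 × 600 bp copies per sequence), 200 planted gaps
with N-runs and deleted donor segments drawn uniformly from
100–2,000 bp, flanks of 10 kb with inter-gap spacing ≥ 2F + margin so
flanks never overlap, no point mutations unless requested, 10 % of gaps
with an inverted target right flank (a planted c3 failure), 10 % with a
200 bp N-island written into the donor image of the left flank (a
planted c4 failure; 200 bp is below `max_anchor_gap`, so the island
sits *under* a single flank alignment rather than splitting it, which
is what makes c4 — not c1 — the failing rule), and a 10–15 kb mate-pair
library modelled as Normal(12.5 kb, 1.25 kb) fragments at depth 5.
These sizes keep a full pipeline run in tens of seconds while leaving
each flank long enough for the 5 kb criterion to bind.

Truth statuses are computed **analytically from the edit plan**, never
by running the pipeline, so a generator bug and a pipeline bug cannot
cancel: inversion → rejected(c3); N-island → rejected(c4); otherwise
closed/rejected(c2) by the expected identity 100·(1−µ) with a 2-point
margin around the 90 % threshold (outside the margin, the ~0.3-point
sampling error of per-flank identity at 10 kb cannot flip the
outcome).  Mutation rates inside the margin get status `uncertain` and
are not used by the shipped configurations.  N-islands are planted into
the donor *after* the target is copied, so they exist only in the donor
— the object the closure stage aligns against — while the target's gap
set stays exactly the planned one.

What the generator does **not** emulate: sequencing errors at the read
level, heterozygosity/diploidy, large-scale translocations between
sequences, GC or repeat-landscape realism beyond planted tandem-free
repeat families, and gap-length distributions of real assemblies (real
reference gaps are often tens of kb; the mini scale uses 0.1–2 kb so
hundreds of gaps fit in 5 Mbp).  Passing the planted-gap recovery tests
therefore demonstrates the correctness of the coordinate arithmetic,
criteria logic and fill extraction — not that a particular real donor
will close a particular real gap set.

## Numerical and degenerate-input choices

- `merge_intervals` coalesces touching intervals; empty input → empty
  output.
- Ratio fields are reported to 3 decimals by default (matching the
  published tables the fixtures reproduce); raw counts accompany them.
- An empty variant table yields the QV cap, not an error; a variant on
  an unknown sequence is an error (likely a naming mismatch).
- Gaps with a zero-length flank (terminal) or no flank alignment are
  `unevaluable`, distinct from `rejected`.
- All randomness flows through `numpy.random.default_rng` seeded from a
  single integer; identical config + seed reproduces every output
  byte-for-byte.

## Known limitations

- The built-in aligner refines whole chained spans with edit-distance
  alignment; for divergences dominated by long indels the reported
  identity can differ slightly from an affine-gap aligner's.  The
  coordinate-ingestion path sidesteps this entirely.
- Closure is single-donor and single-pass; iterative multi-donor
  closing and polishing of fill sequence are out of scope.
- The concordance module consumes alignment blocks; it does not build
  synteny blocks from raw genomes.
- Scaffold AGP parsing requires tiling components; partially specified
  AGPs are rejected rather than repaired.
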