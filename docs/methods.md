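# Methods

This note records the models and procedures `pirnakit` implements, the
parameters that matter, the design choices made where the design was genuinely
open, and what the synthetic-data generator does and does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open. RepeatMasker `.out` rows
(1-based inclusive; `C` orientation rows carry consensus coordinates as
"(left) end begin") and SAM positions are converted at ingestion and back at
writing, so a single convention holds everywhere between the readers and
writers. Consensus coordinates remain 1-based inclusive, as repeat annotation
tools report them, and are always stored with `cons_begin <= cons_end`
regardless of strand.

Small-RNA alignments are accepted as SAM (via pysam; a minimal column parser
handles headerless SAM, which pysam cannot open without `@SQ` lines) or as a
7-column tabular dialect (`read_id contig five_prime_pos strand length
sequence n_hits`) so that simulations and tests never need binary alignment
files. The 5′-end coordinate is the leftmost aligned base for + reads and the
rightmost for − reads; first/tenth bases are reported in read orientation
(minus-strand SAM stores the reverse complement, which is undone). The
multimapper count `n_hits` is taken from an NH-style tag when present, else
from the number of records sharing a read id, else 1 — the faithful fallback
when the aligner emitted all placements. The read-length window defaults to
[23, 29] nt and both bounds are configurable; piRNA populations are variously
described as ~24–32 nt, and neither window is asserted as correct.

## TE copy merging and structural classification

RepeatMasker reports fragments; insertions are reconstructed by chaining.
Two adjacent hits join one copy iff they share contig, mapped family and
strand, their genomic gap is ≤ `max_gap` (default 5000 nt), and their
consensus intervals advance consistently with the strand (non-decreasing along
the genome for +, non-increasing for −, with up to `max_overlap_cons` = 30 nt
of tolerated overlap). Chaining is greedy in genomic order with one open copy
per (contig, family, strand); every input hit lands in exactly one copy, and
re-merging emitted fragments reproduces the copies (idempotence), both of
which are property-tested.

LTR elements are annotated against separate LTR and internal consensi
(`FAM_LTR`, `FAM_I`, with `-LTR`/`-int` variants and a user-extensible alias
table). Sub-consensus coordinates are lifted onto the full consensus
(length `L`, terminal repeats of `ltr_len`): internal hits shift by one LTR
length; an LTR hit can sit at either terminal repeat, so both placements are
tried and the one consistent with the chain is kept — a lone LTR defaults to
the strand's leading terminal. Completeness is the union of lifted consensus
intervals divided by `L`, capped at 1.

Classification: non-LTR copies are full-length iff completeness ≥
`full_len_threshold` (default 0.70, boundary inclusive). LTR copies must
additionally cover ≥ 50% (`ltr_region_cov_min`) of each terminal repeat and of
the interior. A copy whose interior coverage is ≤ `max_overlap_cons` but which
covers LTR sequence is a solo LTR (the recombination product that deletes the
interior); everything else is a fragment. The 50% sub-region requirement is a
lenient, configurable choice; no principled tolerance exists for partially
masked terminal repeats.

Locus summaries: antisense is defined relative to a caller-supplied cluster
transcription strand. Windowed family enrichment assigns each element to the
tiling window containing its start (simplest reproducible rule; window size is
a parameter, default 100 kb). The transposon-trap report lists families with
≥ 2 full-length antisense copies, and families with ≥ 1 full-length copy plus
an antisense fragment < 10% diverged from the consensus (boundary exclusive) —
the signatures of a locus actively trapping mobile elements.

## Cluster calling

Weighted 5′-end counts (weight 1/n_hits per placement; a `unique` mode keeps
only single-placement reads) are computed in sliding windows (default 1 kb
window, 500 nt step). A window with weighted count k seeds a cluster when the
Poisson upper tail P(X ≥ ⌈k⌉ | λ = N·w/L_total) — N total weighted reads,
L_total summed contig length — multiplied by the number of scanned windows is
≤ `density_p` (default 0.07). The multiplication is the deliberate choice
here: a raw per-window test at p ≤ 0.07 marks ~5% of null windows significant
by construction (thousands per scanned megabase at 500-nt steps), so the
p-value is instead interpreted as a budget on the *expected number* of false
seed windows per scan, which is what makes a sub-0.1/Mb false-cluster rate
achievable at all. The literal per-window rule remains available
(`multiple_testing="none"`).

Overlapping significant windows are merged, and each merged locus is screened
by four criteria, each reported as a separate flag so failures are
attributable: length ≥ `min_size` (1 kb); weighted fraction of reads with
first base T/U or tenth base A ≥ `u10a_min` (0.33); the top ⌈0.01·D⌉ of D
distinct read sequences carry ≤ `top1_max_share` (0.90) of the locus weight
(distinct-sequence basis makes the concentration rule scale-free; read id is
the fallback identity when sequences are absent); and main-strand fraction ≥
`mainstrand_min` (0.25). Loci with main-strand fraction ≥ `uni_strand_cutoff`
(0.75, this package's addition, configurable) are classified uni-strand, the
rest dual-strand. Candidates that fail are returned with `passed=False`
rather than dropped.

Promoter anchoring scans a contig and its reverse complement exhaustively for
ungapped matches of a ≥ 20 nt promoter sequence with ≤ `max_mismatch`
mismatches (vectorised sliding-window comparison). From an anchor, the locus
is delimited along the transcription direction through the family-enrichment
profile, tolerating `max_gap_windows` consecutive windows below
`min_window_count`; the stopping reason (below threshold vs contig end) is
reported, since a locus truncated by a contig break is not a biological
boundary.

## Ping-pong scoring

For each + strand 5′-end stack at p, the − strand 5′-end count c_o is taken
at p + o − 1 for offsets o = 1..20; o = 10 means the two 5′ ends overlap by
exactly 10 nt, the ping-pong signature. The score is the mid-rank of c_10
among the 19 other offsets: (#{c_o < c_10} + 0.5·#{c_o = c_10}) / 19, clamped
to [0, 1] — 1.0 when the partner stack exceeds every neighbouring offset, 0.5
under a flat (null) profile. The statistic is local (same-position background),
scale-free (invariant under uniform scaling of stack heights, hence under
weighted vs raw counting of the same data), and needs no genome-wide
calibration. Sites are emitted only when both the + stack and the offset-10
partner are non-empty. Anchoring on + stacks counts each pair once; the
mirror analysis is recovered by reflecting coordinates and swapping strands,
which is tested. The 10th-base adenine bias of partner reads is reported as a
separate fraction, not folded into the score, keeping the score auditable.

A known property of this construction: a solitary offset-10 partner over an
(almost) empty local background scores near 1.0, so isolated coincidental
read pairs in very sparse data can reach high scores. Specificity should be
judged — as the acceptance measurements do — against the actual background
read density of the library, not position-by-position in near-empty regions.

## Cross-genotype comparison and horizontal transfer

Insertion homology across genotypes is established by synteny: ordered
annotation-token lists are globally aligned by dynamic programming maximizing
match − mismatch − gap with scores +0.2 / 0.1 / 0.09 ("match score",
"mismatch penalty", "gap penalty" in a maximization). Tokens match when their
family groups (after an explicit, user-supplied equivalence table for
near-identical families) and, by default, strands agree. Ties in the traceback
prefer match > mismatch > gap, making output deterministic. The DP is verified
against exhaustive enumeration of monotone pairings on small inputs.

Panels are star-progressive around a reference genotype (full multiple
alignment of annotations is not attempted): DP-matched same-group pairs join
the reference token's column; unmatched tokens form new columns keyed by
their left flanking matched reference token, family group and ordinal, so
same-family private insertions between the same anchors merge across
genotypes in order of appearance. Every input copy lands in exactly one
column. Sharing spectra report the proportion of columns present in exactly k
genotypes; in full-length-only mode a column needs at least one full-length
carrier, but degraded carriers still count toward k (fragmented copies of a
once-full-length insertion are shared, not private).

Percent identity is computed from a global alignment with unit
match/mismatch/gap scores; identity = matches / aligned (both-base) columns,
gap columns excluded from the denominator — a stated choice, configurable in
spirit by computing on the alignment directly. Arguments are canonically
ordered before alignment so the function is exactly symmetric under
tie-broken optima. Horizontal transfer is called when identity strictly
exceeds `ht_threshold` (default 0.98, sitting above the 0.93–0.97 identity
band expected under vertical descent, for which a strictly vertically
transmitted element is the reference baseline); a warning is emitted if the
threshold overlaps the baseline band. Direction of transfer is never
inferred. The restriction-digest utility matches IUPAC-degenerate motifs
(overlapping matches included, case-insensitive, forward strand) and places
cuts `cut_offset` bases into each match; fragment lengths always sum to the
input length.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are the study conditions the rest of the package is
validated against: 79% antisense insertions of which 85% are LTR-class
(uni-strand trap composition); a 7-genotype panel with a private-dominant
sharing spectrum (54% singletons, 21% fixed, the remainder spread);
full-length probability 0.30 and solo-LTR probability 0.10; per-base
divergence 0.05; reads of modal length 26 nt in [23, 29] with 1U and 10A
probabilities 0.75; 1/n multimapping up to 50 placements, with copy-number
n_hits for reads landing in planted repeats; a planted 5-kb cluster holding a
third of a 15,000-read library over a megabase background; and 20 planted
ping-pong pair positions when pair emission is switched on.

The TE library defaults to 30 families, 60% LTR-class, consensus lengths
3–7 kb with 300 nt terminal repeats — a diversity chosen to reflect real
somatic trap loci, which carry tens of distinct full-length families plus
many more fragment families. Library diversity matters for the panel
analyses: synteny alignment cannot distinguish two unrelated private
insertions of the *same* family between the same flanking anchors, so a
library much smaller than realistic inflates sharing by homoplasy.

Deliberate simplifications: background sequence is i.i.d. uniform A/C/G/T (no
heterochromatin composition, no nesting of insertions — planted copies are
spaced at least `min_insertion_spacing` = 5100 nt apart so they remain
separable by the default merge gap); truncation of fragments is a uniform
20–65% contiguous slice of the consensus (kept below the full-length
threshold and overlapping internal sequence, so truth categories are exact by
construction); no sequencing error, quality scores or long reads; multimapper
placements are represented by a single emitted record carrying `n_hits`. Tests
passing on these simulations therefore validate bookkeeping, thresholds and
statistical behaviour of the methods — not robustness to nested insertions,
annotation noise or library misspecification, which real data exhibit.

Determinism: every generator draws from `default_rng(SeedSequence([seed,
stream]))` with fixed stream ids, so identical configurations produce
byte-identical outputs across runs.

## Measurement choices in the acceptance script

Recovery of the generator dials (antisense fraction, private fraction) is
averaged over three independent n = 200 replicates: a single binomial draw at
n = 200 has a standard deviation of ~0.035 on these fractions, so a ±0.05
check on one draw would fail a substantial share of seeds from sampling noise
alone; averaging three replicates makes the check about the estimator rather
than one draw, while keeping each replicate at the stated size. Cluster and
ping-pong performance use 50 seeded megabase simulations each; the DP oracle
uses 200 random list pairs of length ≤ 8 (where exhaustive enumeration is
cheap). These sizes keep the full script around a minute on one CPU.

## Known limitations

- Greedy chaining keeps one open copy per (contig, family, strand): deeply
  interleaved copies of the same family and strand can trade fragments; with
  spaced, non-nested insertions (and in the simulations) the partition is
  exact.
- The mid-rank ping-pong score saturates for isolated pairs in sparse data
  (see above); it orders sites well but is not a calibrated p-value.
- Star-progressive panels inherit the reference's resolution: insertions
  absent from the reference are merged by flank + family + ordinal, which can
  conflate distinct same-family events between the same anchors.
- `percent_identity` runs full global alignment; it is meant for consensus- or
  copy-length sequences (kilobases), not chromosomes.
- The QC quantile flags assume benchmark windows are representative of
  well-assembled sequence; with fewer than 20 benchmark windows the quantile
  is refused rather than estimated.
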