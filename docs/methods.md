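# Methods

`switchjoint` analyzes the junctions created when class switch recombination
(CSR) joins a DNA double-strand break in the donor switch region (Sµ) of the
immunoglobulin heavy-chain locus to a break in a downstream acceptor switch
region (Sγ1, Sα, ...).  The package covers four assays — LR-PCR long-read
sequencing of the recombined interval, HTGTS junction capture, Sanger-sequenced
V(D)J coding joints, and metaphase-spread aberration counts — plus a simulator
that generates all of their inputs with known ground truth.  This note records
the models, conventions and parameter choices, and what the synthetic tests do
and do not demonstrate.

## Coordinate model

All internal coordinates are 0-based, half-open, on the *canonical*
(transcriptional) strand of the locus, with 0 at the canonical 5' edge.  Genome
coordinates in either convention (0-based half-open or 1-based inclusive,
declared explicitly in the config) are converted once at I/O boundaries.  The
Igh locus lies on the genome minus strand while joins are described in
transcriptional orientation; a single internal frame avoids strand/sign errors.
Break coordinates are between-base positions: a donor break `d` means the donor
side retained `ref[:d]`; an acceptor break `a` means the acceptor side retained
`ref[a:]` (deletional) or the reverse complement of `ref[:a]` (inversional).

A `LocusMap` bundles the assay geometry: primer footprints, donor/acceptor S
regions, ROI windows (S region ± `roi_pad`, default 5 kb) for the both-ends
read filter, the HTGTS bait site and acceptor assignment window (±
`junction_pad`, default 10 kb), the productive-amplicon length window for the
isotype (e.g. 4.9–17.3 kb for Sµ–Sγ1), the prey strand that denotes a
deletional join, and an optional junction blocklist (e.g. the rearranged
non-productive allele of the CH12F3 line).  Validation is total: every
structural violation is reported, none silently repaired.

## Microhomology definition

Microhomology (MH) at a junction is implemented as the *junction-placement
ambiguity*: the number of alternative break-pair placements that produce the
same joined molecule, i.e. the length of the tract over which the junction
cannot be localized.  For a deletional join this is the sum of the maximal
leftward run with `ref[d-1-i] == ref[a-1-i]` and the maximal rightward run with
`ref[d+i] == ref[a+i]`; inversional joins use the complementary comparisons
with shifts `(d+t, a-t)`.  This count is invariant under moving the junction
within its tract, which makes MH values comparable across callers that use
different placement conventions, and it is exactly what a brute-force
enumeration of placements measures (the oracle used in the tests).  Exact-match
MH only; mismatch-tolerant ("imperfect") MH is not called, mirroring
HTGTS-style practice.

Per junction, MH and untemplated insertion are mutually exclusive by
convention: any untemplated base sets MH to 0.  A *direct joint* has neither.
The MH landscape caps reported lengths at 20 bp (configurable); biologically
meaningful TMEJ signal lives at 4–8 bp.

## Built-in aligner

The synthetic test path uses a deliberately narrow seed-and-extend aligner so
no external mapper binary is needed: unique 21-mers of both reference strands
are indexed; read anchors are chained by diagonal (band 16 bp, enough for
1-bp-indel drift between adjacent anchors while rejecting spurious
junction-spanning k-mer hits); each block end is extended base-by-base.
Extension crosses an isolated mismatch (next mismatch ≥ 20 bp away — a
sequencing error) but stops at the first mismatch followed by another within
20 bp (the density jump where the read switches template).  On error-free
reads this places each junction-facing block end exactly at the boundary of
the MH-ambiguity tract.  Blocks shorter than 100 bp are discarded; chains with
more than 4 blocks are flagged complex and excluded.  Real data enters through
standard SAM/BAM from any long-read mapper; junction coordinates from external
mappers can shift within MH tracts, which the placement-invariant MH
definition absorbs.

## LR-PCR pipeline

Reads must align to both ends of the region of interest (one block overlapping
each ROI window) or they are filtered out.  The primary breakpoint of a read
is the junction between the last donor-side (ROI5) block and the acceptor-side
(ROI3) block holding the read's 3' end; earlier block-to-block junctions (e.g.
intra-Sµ deletions) are kept as secondary junctions.  When MH lets both blocks
claim junction bases, the blocks overlap in read coordinates by m bases;
placement is resolved *leftmost-in-read* (ambiguous bases to the donor side,
acceptor block advanced by m), so one physical junction always yields one key,
and m is the per-read MH observation.

Calls are deduplicated by key `(donor_break, acceptor_break, orientation)`;
depth is the read count of the group and groups below `min_depth` (default 10,
counted after ROI filtering, no quality weighting) are dropped to counter
PCR amplification bias.  Blocklist matching is exact by default with a
configurable tolerance for mapper jitter.  Consensus insertion and MH lengths
are majority votes (ties toward the smaller value); single-read junctions are
flagged.

Classification is recomputable from coordinates alone: a joint is *resected*
when either break lies outside its S region; the *productive-length* flag
compares the coordinate-derived amplicon length, `(d - primer5.start) +
insertion + (primer3.end - a)`, with the isotype's productive minimum.
Summaries report both views the assay offers: observed read lengths (median,
% at or below the productive minimum) and coordinate-based junction
classifications, with 250 bp binned junction histograms over each S region ±
pad.  Empty inputs yield absent (null) percentages, never 0.

## HTGTS pipeline

TLX-like junction tables are consumed as produced by HTGTS pipelines (a
column-name dialect maps headers; rows missing mandatory fields are dropped
with a logged count).  Off-chromosome prey is classed "translocation_other"
and excluded from CSR summaries.  On-locus prey is assigned to Sµ-intra
(donor_S ± roi_pad), Sµ-acceptor (acceptor_S ± junction_pad), a named extra S
region, or "outside"; orientation is deletional iff the prey strand equals the
configured `del_strand`.  Within the Sµ-acceptor window, prey outside the
unpadded acceptor S region carries the resected flag — the same junctions are
counted in the assignment window and flagged resected, mirroring the
"within and outside" split of zoomed acceptor-region distributions.  The
INV/DEL ratio and resected percentage are computed over Sµ-acceptor joints
(a config switch restricts to the unpadded region); histograms use 1 kb bins
genome-wide and 250 bp bins in the acceptor zoom.  When a junction-context
column and reference are available, per-junction signatures feed the direct /
MH ≥ 4 bp / >1 bp-insertion summaries and the MH landscape.

## V(D)J junction decomposition

A Sanger-sequenced coding joint is decomposed against germline V and J
references by maximal anchored matching: the longest prefix of the sequence
matching the V prefix and the longest suffix matching the J suffix (each
allowing `max_mismatch` mismatches, default 0).  Resections are the germline
bases missing at those maximal extents; an overlap of the matched spans is the
junction MH (ambiguous bases counted as present on both sides); a gap is an
untemplated insertion.  The simulator's truth table records the same canonical
decomposition recomputed by explicit placement enumeration, because a junction
with shared flanks genuinely cannot be attributed further — exact recovery is
then a well-defined target, which the tests verify field-for-field.

## Fisher's exact test and metaphase reports

Metaphase tables count, per genotype, total spreads, spreads with a locus
break and spreads with a locus translocation (disjoint classes enforced at
input).  Contrasts against a reference genotype use the two-sided Fisher's
exact test in three tabulations: normal vs aberrant (aberrant = breaks +
translocations), break vs others, translocation vs others.  The p-value is
the probability-mass definition — the sum of hypergeometric probabilities of
all tables at most as probable as the observed one (relative tie tolerance
1e-12) — computed with exact integer binomial coefficients and rounded once
at the end, so an exhaustive sweep of every table with total ≤ 40 agrees with
full rational-arithmetic enumeration to better than 1e-12.  Per-experiment
rows, when provided, are pooled for the tests and additionally summarized as
mean ± SEM of per-experiment percentages.  Raw p-values are reported without
multiple-testing correction, matching how such panels are typically presented.

## Synthetic data generator

The simulator is the package's ground-truth instrument, not a fixture: a
60 kb locus (configurable, ≥ 20 kb) with primer sites at ~1.7% and ~92% of the
locus, a 4 kb donor S region at 10% and a 4 kb acceptor S region at 77%, each
built from tandem G-rich repeat units with 8% per-base degeneracy.  The unit
lengths are coprime (25 vs 23 bp) and share only short motifs, so donor and
acceptor arrays never phase-align over long stretches: junction MH stays in
the realistic short range and break placement remains decidable — a property
real Sµ/Sγ1 pairs share, since their repeat units differ.  The germline
primer-to-primer span (~54 kb) exceeds the productive window, as on the real
locus where the primers are >100 kb apart, so only recombined molecules
amplify.  Thresholds are scaled so the productive window brackets exactly the
within-S (S_S) amplicon range.

Events are sampled at the break-coordinate level (no AID chemistry):
inversional with probability `p_inversion` (default 0.12), resected with
probability `p_resected` (default 0.13) — the donor break moving upstream of
Sµ and/or the acceptor break downstream of the acceptor region by a geometric
tract (mean 800 bp, capped to leave ≥ 300 bp of primer-proximal template,
without which neither a primer nor any aligner has substrate) — otherwise
uniform within the S regions.  Untemplated insertions (probability 0.10,
1–6 bp) have boundary bases constrained to differ from the adjacent template
base; otherwise the boundary base would be templated and no analysis could
recover the planted insertion length.  The defaults emulate an NHEJ-deficient
(Xrcc4-null-like) sample, the condition under which resected and inversional
joints are abundant enough to exercise every code path; per-event depth is
uniform on 10–20 reads.  Two rejection rules keep ground truth well-defined:
an event is redrawn if its MH tract straddles an S border (its label would
depend on placement convention) or if its placement-equivalence class collides
with an already-planted event (two such events render identical molecules and
are physically one junction).

LR-PCR rendering emits `depth` copies of the amplicon per *deletional* event
(two convergent primers cannot amplify an inversion; those events are returned
unamplified), from either strand, with independent substitutions (0.2%) and
1-bp indels (0.02%) emulating CCS-like fidelity.  HTGTS rendering emits one
row per event with bait = donor break, prey = acceptor break, prey strand by
orientation, and a `donor|insertion|prey` context window.  V(D)J rendering
applies geometric resections (mean 3 bp) to a random 300 bp V and 200 bp J
segment with the same insertion model.

What the simulator does *not* emulate: AID deamination and transcription-
coupled break formation (break positions are uniform, real ones cluster at
AGCT hotspots), intra-Sµ joins, chromosomal translocations to other loci,
PCR length bias (depth is independent of amplicon size), and CCS quality
scores.  Passing tests therefore demonstrate the correctness of the calling,
classification and counting machinery under realistic junction structure —
not performance on real-read artifacts such as chimeras or reference
divergence, which the SAM/BAM path delegates to an external mapper.

## Numerical and convention choices

- Ties in consensus votes break toward the smaller value; junction tables are
  sorted by key, so all outputs are byte-deterministic for a given seed.
- `microhomology_length` truncates at sequence ends (computed over the
  available overlap) and caps at `mh_max`.
- The aligner retries with a denser anchor stride (8 bp) if the default
  (32 bp) yields no blocks.
- Percentages are plain ratios × 100 rendered by `json` at full double
  precision; no rounding is applied before comparison in tests.
- Problem sizes used in the shipped verification runs: 10,000 junctions for
  the MH oracle sweep, every 2×2 table with total ≤ 40 for Fisher, 2,000
  events (≈26,000 reads) for the error-free end-to-end run, 600 events for
  the noisy run, 500 V(D)J junctions — sizes at which every stochastic check
  is stable across seeds.

## Known limitations

- Exact-key deduplication splits reads whose sequencing error falls within
  ~20 bp of the junction into orphan keys; at 0.2% error and depth 10–20 this
  loses a depth-dependent fraction of events (the surviving unique junctions
  are the exact ones — verified ≥ 99% within the MH tract of a planted event).
  A clustering consensus would recover them at the cost of the crisp
  unique-breakpoint definition.
- `productive_length` uses coordinate-derived amplicon length; with nonzero
  error rates the observed read length can differ by a few bases.
- The INV/DEL ratio definition covers the acceptor assignment window; real
  analyses differing on window choice will differ correspondingly (the window
  is configuration).
- No genome-build liftover: configs must match the build of the alignments or
  junction tables they describe.
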