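# Methods

## Model and assumptions

`repeatgate` genotypes a tandem-repeat locus from circular-consensus (CCS)
reads produced by amplification-free Cas9 target capture.  It assumes each
on-target read spans the whole captured fragment: an upstream arm ending at
the repeat, the repeat tract, and a downstream arm to the Cas9 cut site.
Because the tract length is the unknown of interest, no reference alignment
is used anywhere; the only locus knowledge is the *target design* — two
short recognition sites flanking the repeat, the expected arm lengths, and
the repeat unit(s).

Read-level error is assumed to be sparse and dominated by single-base
insertions/deletions, the residual error mode of CCS consensus building.
Reads may represent either strand; both strands are searched and the
qualifying one is kept (with the orientation reported), so no assumption is
made about library asymmetry.

## Arm-length convention

`l1` is measured from the oriented read's 5' end **through the last base of
the upstream recognition site**; `l2` from the **first base of the
downstream site** through the 3' end.  The anchors count toward the arms
and the tract is exactly the inter-anchor substring.  Expected values in
the shipped designs are calibrated to the same convention, which is all
that matters — the filter compares like with like.  `l1_expected` is a
list: at the *HTT* locus a common SNP (rs2857935) destroys the proximal
BamHI fragmentation site and the next site lies 1736 bp further upstream,
so heterozygous samples legitimately produce two upstream arm lengths
(913 and 2649 bp); the classifier accepts a read whose arm matches *any*
configured value within the tolerance (default 10%).

The design-level `capture_span(design, n)` helper implements the
fragmentation-site-to-Cas9-site arithmetic `l1 + n*len(unit) + l2` (the
*HTT* design gives 1125 bp at the 19-repeat reference allele).  For loci
with a flanking secondary repeat (HTT's CCG) the inter-anchor tract also
contains the fixed junction sequence and the secondary tract, so the
zero-error read length equals `capture_span(n)` plus those; for single-unit
loci the two coincide exactly.

## Anchor search

Approximate site occurrence is minimum unit-cost Levenshtein distance over
all read substrings, with budget `max_site_edits` (default 2).
Substitutions are allowed alongside indels: the platform's errors are
mostly indels, but the operative constraint is the budget, and excluding
substitutions from the edit alphabet would be arbitrary.  Determinism: ties
are broken by smallest start, then shortest span.  `N` bases mismatch
everything (cost 1).  Implementation: a leftmost-exact fast path; then an
edlib cost-only prefilter; then the package's own semi-global DP
(vectorised over read offsets) that yields the exact cost-by-start profile
and the tie-broken span.  Coordinates are 0-based half-open throughout.

When both strands carry both anchors in order, the strand whose anchors
cost strictly fewer total edits wins; only an exact tie is rejected as
ambiguous.  A genuine capture is always cheaper than a spurious
opposite-strand hit that only enters at a higher budget, so acceptance is
monotone in `max_site_edits` and in `length_tolerance` (loosening a
threshold never turns an accepted read into a rejection), while true
palindromic pathology is still rejected.  Rejections carry the first
failing check, evaluated in a fixed order: upstream site, downstream site,
anchor order, arm lengths.

## Indel correction (optional)

A defective inter-run window holding one indel — `len(unit)-1` bp (one
deletion), `len(unit)+1` bp (one insertion), or a single base at a unit
boundary (a boundary insertion) — is restored to one exact unit copy (or
removed, in the boundary case) when at least two consecutive exact unit
copies flank it on **each** side.  The window must additionally be
derivable from the unit by that single indel; anything else, including any
substitution and any multi-error window, is left untouched.  Scanning is
left-to-right, one correction per gap per pass, iterated to a fixed point
(a correction can merge runs and enable a neighbouring one).  Clean tracts
are fixed points.  Correction is optional (`--no-correct`): modifying reads
is not always advisable, and all downstream steps run identically without
it.

By construction the rule cannot repair errors in the first/last two units
of a run, in the junction sequence, or in clustered pairs; those remain
visible as interruptions.  This is deliberate — the rule only rewrites
sequence when a single-indel explanation is unambiguous.

## Decomposition and counting

The tract is decomposed into unit-length windows labelled by exact match
against the primary unit, then the secondary units in declared order, else
`other`.  The frame is anchored at the first exact primary-unit occurrence
(modulo unit length) and **re-synchronises** after every defective window
at the next exact unit occurrence; the skipped gap contributes
`max(1, round(gap/unit))` `other` windows.  Re-synchronisation is what
keeps a lone indel an isolated interruption instead of cascading
frame-shifted labels through the rest of the tract; it is the property
that makes uncorrected histograms still peak at the true alleles, keeps
repeat-content plots readable, and makes the number of `other` windows
monotone under correction.  The price is that the window count is no
longer a pure function of tract length; instead `sum(counts) ==
len(unit_track)` holds by construction.

Two counting modes cover the shipped loci:

* `longest_run` (*HTT*): each unit's count is its longest run of
  consecutive exact windows — the pure CAG tract and pure CCG tract,
  excluding the fixed CAACAGCCGCCA junction between them.
* `tract_total` (*FMR1*, *ATXN10*, *C9orf72*): the reported count is the
  total number of windows of any label, with each interrupting unit's
  count alongside.  An *FMR1* CGG count therefore includes AGG positions,
  which are simultaneously reported as interruptions with their window
  indices.  Whether interruption positions should count toward the total
  is genuinely undecidable from published descriptions; both readings are
  available by switching `counting_mode`, and the shipped default treats
  the printed CGG totals as tract totals.

## Allele calling

Per-read counts per unit form a histogram.  Allele A is the modal bin
(ties to the smaller count); allele B is the best-supported remaining bin;
the call is heterozygous iff `support(B) >= max(min_support,
het_fraction*support(A))` with defaults 10 and 0.2.  The relative term lets
adjacent genuine alleles (17/18) survive while the absolute floor stops
noise bins at low depth; a fixed masking window around A cannot do both.
Raising `min_support` can only turn calls homozygous, never the reverse,
and calling is order-invariant in the reads.

For *HTT* the per-read (CAG, CCG) pairs are phased: reads are assigned to
the nearer CAG allele and the CCG allele reported with CAG allele *i* is
the modal CCG among its reads.  Phased CCG calls are ordered by CAG phase
(allele 1 pairs with the shorter CAG allele), so the observation that the
longer CCG tends to flank the shorter CAG is an output, not an assumption.
Size-ranked calls (everything except phased flanking repeats) keep
`allele1 <= allele2`.

Mosaicism summaries: histogram bins with support ≥ `noise_floor` (default
2) are assigned to the nearer called allele; each allele reports its bins'
min–max range and off-modal read fraction.  Wider ranges for larger
alleles are the somatic-instability signal.

Cohort summaries count called alleles over 2N haplotypes and report
one-decimal percentage shares plus zygosity and genotype counts.  A
reference 11-sample HD-cohort genotype table ships with the package as
input for these summaries.

## Simulator

The generator emulates exactly the structure the classifier assumes:
uniform-random arms (GC 0.5) ending/starting in the recognition sites with
total lengths drawn from the design's expected values, tracts assembled
from seeded per-allele counts (junction sequence included for *HTT*;
optional AGG placements for *FMR1*), i.i.d. per-base
substitution/insertion/deletion errors (defaults 0.002/0.005/0.005 — an
indel-dominated CCS-like profile), a reverse-complemented fraction
(default 0.5), and an off-target fraction of random sequence.  Mosaicism
is a rounded symmetric zero-mean normal spread of the primary count with a
per-allele sd; no directional expansion bias is asserted, because the
spread's shape is not established — consequently simulated expanded-allele
ranges are symmetric about the mode where real ones may skew upward.

The truth table records per-read seeded counts, class, orientation,
per-region error counts, and the number of *correctable defects*: units
(or unit boundaries) carrying exactly one indel whose two flanking units
on each side — and the intervening boundaries — are error-free.  This is
precisely the correction rule's premise, marked independently at injection
time, and is the denominator on which correction efficacy is measured:
conditioning on reads with at least one such defect, correction strictly
reduces interruption windows in ~100% of reads, while over *all* reads the
count never increases.  An unconditioned "fraction of reads with any tract
error improved" would instead measure how often errors happen to fall in
the rule's domain (~60–70% at 1% indel error), which conflates placement
with efficacy.

What the simulator does **not** model: subread-level error correlation,
polymerase kinetics, capture chemistry, base modifications, real genomic
arm sequence (user-supplied arms are accepted via custom designs).
Passing tests therefore demonstrate the pipeline's correctness on reads
with the assumed structure and error profile, not capture performance on
real libraries.

## Numerical and operational choices

* Problem sizes: validation runs use 100 seeded replicates of 200-read
  samples for genotype recovery, 500-read samples for correction efficacy,
  1000 random pairs for the anchor-search oracle, and study-style
  reproductions at the published per-sample on-target depths (186/75/117
  reads).  Genotype recovery at 1% indel error with correction enabled is
  ~100% across the tested genotype grid, including the adjacent 17/18
  heterozygote and the 17/17 homozygote.
* Zygosity at low depth: with ~75 reads and substantial mosaic spread the
  expanded allele's modal bin can approach the absolute `min_support`
  floor, and the call can degrade to homozygous-normal — allelic-dropout
  behaviour an analyst should watch for; deeper sampling or a lower
  `min_support` resolves it.  Study-style reproductions aggregate a few
  replicates for stable reporting.
* Degenerate inputs: empty FASTA yields an empty read list with a warning;
  an empty inter-anchor span is an empty tract with zero counts; histograms
  below `min_support` raise a coverage error that the pipeline converts to
  a null call with a warning.
* Plots are SVG by default with a TSV twin written next to every image;
  nothing downstream depends on pixels.
* All randomness flows through numpy `default_rng` seeds; identical seeds
  give byte-identical simulated FASTA and identical analysis outputs.

## Known limitations

Anchors for *FMR1*, *ATXN10* and *C9orf72* ship as clearly-marked
synthetic placeholders (the real flanks belong in a user config); repeat
counts are per-read exact-window counts, so systematic miscounting below
the error model's assumptions (e.g. long homopolymer slips spanning
several units) is out of scope; no clinical interpretation beyond an
annotation of the standard HD CAG bands is produced; and very large
expansions that fail CCS consensus generation upstream never reach this
pipeline at all.
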