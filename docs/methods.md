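# Methods

## The discovery model

A transcribed 5′UTR leaves a contiguous plateau of strand-specific RNA-seq
coverage immediately upstream of an annotated translation start, at a depth
comparable to the coding sequence it feeds. The caller walks outward from
the base 5′ of each gene's translation start on the gene's strand
("upstream" means decreasing coordinates for plus-strand genes, increasing
for minus-strand), extending while per-base depth ≥ `min_depth` and
tolerating runs of sub-threshold bases up to `max_gap` nt. The walk stops at
the first longer gap, after `max_scan` nt, or at the boundary of the nearest
annotated gene on the same strand — opposite-strand genes do not stop it,
because coverage is strand-resolved and an antisense neighbour contributes
nothing to the scanned track. The TSS estimate is the most distal retained
covered base; a gene whose upstream window starts with a longer-than-
tolerated gap, or whose window has zero length because a same-strand
neighbour abuts it, simply yields no candidate.

Parameters, defaults, and rationale:

| parameter | default | meaning |
|---|---|---|
| `min_depth` | 5 reads | per-base depth that counts as "covered"; low enough to follow a UTR expressed at a quarter of its CDS at moderate sequencing depth |
| `max_gap` | 10 nt | longest sub-threshold run bridged; absorbs local mappability dropouts without fusing separate transcripts |
| `max_scan` | 600 nt | upstream search limit; bacterial 5′UTRs above a few hundred nt are rare |
| `min_ratio` | 0.25 | comparable-expression floor: mean UTR depth / mean CDS depth, inclusive |
| `min_length` | 35 nt | shortest known UTR regulatory element (aptamer domains start near this size) |
| CDS window | first 300 nt | CDS depth is averaged over min(CDS length, 300) nt from the translation start, avoiding 3′-decay artifacts in long genes |

"Comparable expression with the adjacent gene" has no canonical numeric
definition; it is operationalized here as the depth ratio above, on the
reasoning that a UTR transcribed as part of the mRNA should carry a
substantial fraction of that mRNA's signal, and the threshold is exposed
rather than hard-coded. All thresholds are inclusive (≥), so boundary
lengths of exactly 35 nt are retained and RACE-refined lengths of exactly
30 nt survive the exclusion rules, matching the "<35" / "<30" phrasing of
the filters being modeled.

Post-validation exclusion removes candidates whose interval overlaps a
same-strand neighbour's annotated extent (transcription running through
from the upstream gene rather than an independent 5′ end), whose
RACE-refined length falls below 30 nt, or which lack RT-PCR confirmation;
all three checks always run so an excluded candidate carries every
applicable flag.

## TSS refinement from 5′RACE

5′RACE ligates a known 45-nt adapter to mRNA 5′ ends; in a sequenced
product, the base immediately following the adapter is the TSS. Per read,
the adapter (with U read as T) is located allowing at most one substitution
— the kit-printed sequence is known, but sequencing errors in it should not
discard a read. The first 10 transcript bases after the adapter anchor the
read on the genome by exact search in a window from `max_scan` nt upstream
of the translation start to 50 nt inside the CDS (so reads that actually
start within the CDS are seen and rejected rather than silently unmapped).
A read is rejected when the anchor has zero hits (unmappable), two or more
hits (ambiguous placement), or maps at/inside the CDS start — the last rule
guarantees refinement never moves a TSS into the coding region. The call is
the modal mapped position over surviving reads, with ties broken toward the
most distal (longest-UTR) position, and requires `min_support` (default 2)
supporting reads; anything less is an explicit no-call with a reason.

## RT-PCR confirmation logic

Primer set A amplifies from inside the putative UTR into the CDS (contiguity
evidence); set B amplifies within the CDS only (expression control); a
no-reverse-transcriptase control detects genomic DNA contamination.
Classification is a total function over the 8 boolean combinations:
contamination dominates everything; otherwise a missing B band is an assay
failure; with B present, A present means confirmed and A absent means the
UTR was not detected.

## Reporter screen statistics

Per sample the summary statistic is the median fluorescence over the event
population (≥ 50,000 events in the emulated protocol) — robust to the heavy
right tail of per-cell expression. Per strain × condition, replicate medians
are paired against the same strain's unstressed RMG control replicates:
ratio = mean(treated medians) / mean(control medians), with dispersion
reported as the standard deviation of per-replicate ratios (the quantity
shown as error bars on fold-change plots). A strain × condition is called
responsive when a two-sided one-sample t-test of the log₂ per-replicate
ratios against 0 gives p < α (default 0.05) **and** |mean log₂ ratio| ≥
`min_effect` (default 0.5, ≈1.4-fold) — the effect floor keeps
statistically significant but biologically trivial shifts out of the hit
list. "Significant fluorescence change" has no published numeric
definition; this rule is the package's codification, with both knobs
exposed. Benjamini–Hochberg correction across conditions within a screen is
available behind a flag and off by default to match per-candidate
reporting.

ΔΔC_T quantification: ΔC_T = Ct(target) − Ct(reference) per replicate;
ΔΔC_T = mean ΔC_T(treated) − mean ΔC_T(control); fold = 2^(−ΔΔC_T). The
statistic is invariant to any constant shift of all Ct values, and the
reference gene is a named input column rather than an assumption.
Per-replicate folds (each treated ΔC_T against the mean control ΔC_T)
provide the reported spread.

Western quantification divides the target band by the internal-control band
per lane (RecA, or total protein when loading was mass-normalized) and
reports per-condition means and standard deviations over replicates.

Reporter inserts for the GFP fusion are UTR + the first 90 nt of the native
CDS (a multiple of 3, keeping the downstream reporter in frame while
preserving RNA structure around the start codon), flanked by
outward-cutting BsmBI recognition contexts for Golden Gate assembly; any
internal BsmBI site on either strand is a hard error reporting its offset.

## The synthetic-data generator

The generator emulates the study's data-generating process, not its
sequences: a uniform-random genome with 10 genes in 50 kb (≥ 300 nt
intergenic gaps), planted UTRs abutting each CDS start with lengths 35–150
nt and UTR/CDS expression ratios 0.3–1.0 unless specified, Poisson coverage
(negative binomial with configurable dispersion available, since real
RNA-seq is overdispersed; exact plateaus available for oracle tests) at
mean depth 100 over CDS and depth × ratio over UTRs, RACE reads of
adapter + 60 nt with substitution errors only outside the first 10
transcript bases, log-normal fluorescence parameterized by the true median
and a per-event CV of 0.4 with 5% log-normal replicate jitter (triplicates;
no replicate-variance model was published, so a modest biological jitter is
assumed), and Ct tables built from Ct = base − log₂(fold) + noise with a
condition-constant reference gene. One global seed fans out to independent
per-stage child streams, so any stage can be regenerated alone and every
artifact is byte-reproducible.

What the generator does *not* emulate — and therefore what passing tests do
not establish about real data: mappability and GC biases, operon read-through
at levels between background and CDS, misannotated start codons, partial
adapter degradation in RACE products, flow-cytometry gating artifacts, and
amplification-efficiency differences between qPCR primer pairs.

## Numerical and design choices

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive) is
  converted at the I/O boundary, BEDGraph taken as-is.
- A zero mean CDS depth cannot produce a finite ratio; such candidates get
  ratio 0 with a logged warning and fail the comparability filter rather
  than raising.
- Degenerate t-tests (zero variance across replicate ratios) are resolved
  without NaNs: a zero mean shift is non-responsive, a nonzero identical
  shift is treated as unambiguous.
- Error-rate simulations (type-I and power of the responsiveness call) run
  1000 strains at 1000 events per replicate rather than the full 50,000:
  the test statistic is driven by replicate-level jitter, next to which the
  median's sampling noise at 1000 events is already negligible, and the
  generator's event-count default is untouched.
- The per-base oracle used in tests is an independent single-base walk
  (pure Python, sets for blocked intervals) sharing no code with the
  vectorized caller.

## Known limitations

- The discovery engine calls at most one UTR per gene and no internal or
  antisense TSS; operon structure is only respected through the same-strand
  boundary rule.
- Discovery counts from the original genome-wide screen (hundreds of initial
  candidates) depend on unpublished depth thresholds and undeposited
  transcriptomic data and are not reproduction targets; the engine is
  validated by planted-truth recovery instead.
- RACE refinement assumes substitution-only errors; indels in the anchor
  region defeat the exact search and the read is dropped (a no-call, never
  a wrong call).
- Conservation labels ("Highly conserved", "Somewhat conserved") are
  free-text annotations with no numeric cutoffs; they are joined and
  counted, never computed.
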