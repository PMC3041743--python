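# Methods

This note records the models, parameter choices and numerical
conventions behind `agsnp`, and what the synthetic-data experiments do
and do not demonstrate.

## Coordinate and data conventions

All internal coordinates are 0-based half-open. Conversion happens only
at boundaries: VCF positions are written 1-based; BLAST-tabular query
coordinates are read as 1-based inclusive. Alignments are stored in
reference orientation (the SAM convention), so pileup code is
strand-agnostic. `N` bases count toward depth but never toward allele
counts. A variant call's depth is the number of reads contributing a
base at the position; deletion-spanning reads are excluded, consistent
with indel evidence never being scored as a variant.

## Replicate removal

cd-hit-454-style clustering is emulated greedily: reads sorted longest
first seed clusters; a read joins a cluster when its 20-mer prefix
matches the representative within 3 bases of the representative's start,
ungapped identity over the shorter read is ≥ 0.98, and the shorter read
covers ≥ 0.90 of the longer. Identity is computed over the shorter read
(the stated thresholds do not specify the denominator). The longest
member represents the cluster, ties broken by smallest identifier, which
makes the kept set invariant under input permutation. Ungapped anchored
comparison is adequate because artificial replicates are clonal
re-reads of one template and share its systematic indels.

## Annotation

Category precedence is REPEAT > characterized gene > uncharacterized,
reflecting the sequential removal order of the annotation pipeline; a
read with any repeat hit at E ≤ 1e-10 is a repeat regardless of gene
homology, and gene-database subjects that are themselves
transposon-related (marked with a `TE|` prefix) never confer gene
status. cDNA promotion of uncharacterized reads requires ≥ 2 mapped cDNA
reads — one mapping is too easily spurious; the threshold is this
package's default, not a published value.

Repeat junctions are recomputed from hit geometry rather than an
external primer-design tool (a documented simplification): overlapping
hits of the same element are merged; a junction is emitted where two
distinct elements abut (midpoint of any overlap, a deterministic and
symmetric choice) and where a repeat hit ends ≥ 30 bp inside the read
(repeat/unknown junction). The 30 bp minimum flank keeps downstream
SNPs and primers anchorable and matches the scale of the 3'-end filter.
Reads with at least one junction are re-categorized as repeat-junction
reads; junctionless repeats are never used as mapping references.

## Single-copy depth model

Per-reference depth is the median of per-position coverage (all
positions counted once the reference has one aligned read). The median
is robust to the coverage ramps at reference-read ends, where only fully
contained short reads can align. The depth histogram over characterized
gene reads is fitted by maximum likelihood with a Gumbel law after
discarding zeros and trimming above the empirical 99th percentile — the
raw histogram mixes in the repeat-inflated tail, which would otherwise
dominate the scale parameter. A Weibull option (`family="weibull"`)
suits the left-skewed histograms seen at very low coverage. X̄ and s are
the mean and standard deviation of the *fitted* law (the convention
when moments are quoted from a fitted distribution), and the cutoff is
the integer part of X̄ + 2s — truncation, so 10.7 + 2·21.3 = 53.3 prints
as 53. Equality is single-copy (depth ≤ cutoff), keeping a printed
cutoff usable as "≤ cutoff". A degenerate histogram (one depth value)
yields s = 0 with a warning. Per-platform models are fitted
independently; the pipeline classifies copy number with the
highest-coverage genomic platform. Copy classes apply to gene,
repeat-junction and uncharacterized reads; plain repeats stay UNKNOWN
because they are never mapped.

## Calling, merging, filtering

Candidate calling is deliberately permissive (any non-reference
majority base, `min_alt = 1`); all stringency lives in the filter stack
so filter combinations can be studied on one candidate set. Sites are
biallelic: platforms disagreeing on the alternate allele drop the site
(ALT_CONFLICT). After merging, the consensus base ratio is recomputed
from the summed counts — whether the original pipeline recomputed or
required each platform to pass separately is not stated; recomputation
is the reading consistent with merging alignment data to raise depth.
Per-platform depth ceilings are enforced per contributing platform on
merged calls, since the maxima are platform-specific. The mapping-
quality rule requires every alternate-supporting observation to map at
quality ≥ 20. The rejection ledger records the first failing criterion
in the fixed filter order; the passing set itself is order-independent
(each criterion is evaluated on the original candidate geometry — in
particular, proximity is measured on pre-filter candidate positions).
"Reads with only one SNP are retained" for uncharacterized references
is read as: the reference must carry exactly one otherwise-passing SNP;
if several pass, all are rejected. The uncharacterized depth ceilings
(5 for 454 and Solexa, 25 for SOLiD genomic) follow the stricter
published override; for the Solexa maximum the filter uses the tabled
value 10 rather than the narrative cutoff 8 — the source is internally
inconsistent there, and the table is taken as authoritative. The NQS
window truncates at reference ends rather than auto-failing; the 3'-end
rule already guards the decaying right edge.

## Error models

Single-read rates count I/D/X events from the alignment walk with total
aligned read bases as denominator. Consensus is a majority vote with
ties resolved to the trusted base — the transparent desk-scale
equivalent of consensus calling. Variant-calling error mode is consensus
mode with a long-read-derived reference standing in for truth, so both
sides contribute errors; the random half-split of reads used for that
design takes an explicit seed.

## The synthetic-data generator

The generator's defaults encode the study conditions: a 5 Mb genome
with 59% characterized repeats (24 TE families, 25% of copies nested
inside other copies, creating junction breakpoints), ~10% genes (22%
of them absent from the gene database, 5% duplicated, 80% expressed),
two uncharacterized 10-copy repeat families, and single-copy intergenic
DNA; organellar contamination at 1.64% of long reads and artificial
replicates at 11.33%; long reads at 1.35× coverage, mean length
380.5 bp, with error rates 1.2e-3 substitutions and 6.2e-3 indels per
base, 85% of indels homopolymer-adjacent, error probability rising ~4×
from 5' to 3', and 80% of erroneous bases drawn with sub-threshold
qualities (so the Q30/NQS-20 filter removes the published "over 70%" of
substitution errors); short-read platforms at desk-scale analogues of
the study's mapped coverages (SOLiD genomic 8×/50 bp, Solexa 2×/84 bp,
SOLiD cDNA 3×/50 bp) with the platform consensus-scale substitution
rates (1.8e-4, 3.5e-4). SNPs are planted at 1/876 bp in genes and
1/612 bp near junctions; uncharacterized single-copy DNA uses the genic
rate, since accession divergence does not depend on annotation class
(the lower published density there is a consequence of the stricter
filters, not of lower divergence). Both accessions are treated as
homozygous inbreds (heterozygosity 0 by default; a nonzero value
exercises the CBR < 0.9 rejection path).

Read placement emulates a mapper in report-all mode: a read sampled
from inside an element copy is aligned at every homologous reference
location (copies are identical in the simulator), which makes mapped
depth proportional to genomic copy number — the signal the depth model
consumes. Junction-spanning reads place uniquely. Short platforms are
simulated substitution-only; their published indel rates are 1–2 orders
below the long-read platform's and indels are never variants. Fragment
positions are uniform (no GC bias), and truth alignments replace a real
mapper — mapping is not the contribution, and an external SAM can be
substituted where realism matters.

What passing tests therefore show: the pipeline's logic — annotation
precedence, depth calibration, filter stack, merging, error accounting —
behaves correctly and recovers planted truth at the expected operating
point. What they do not show: robustness to mapper-specific placement
artifacts, diverged repeat copies, GC-biased coverage, or chimeric
reads, none of which the generator emulates.

## Observed operating point

On the default genome the end-to-end run passes ~1,400–1,500 SNPs at
precision 0.83–0.86, with recall ~0.46–0.48 of planted SNPs covered by
a usable reference read (about one third of all planted SNPs, the 1.35×
reference sampling being the largest single loss — consistent with the
published observation that roughly half of expected genic SNPs are
discoverable at these coverages). Recall rises monotonically with
short-read coverage over 2–8×. The filters that remove most true SNPs
are, in order, the homopolymer rule (~a quarter of candidate true
sites sit in or would create a ≥ 3 bp run), the single-SNP rule on
uncharacterized references, and minimum depth at low coverage; about
40% of junction-bearing reads classify multi-copy because their
repeat flanks accumulate multi-mapped reads, matching the scale of the
published single-copy fraction for junction reads (58%).

## Problem sizes

The test suite exercises 400 kb genomes for module tests and the 5 Mb
default for the end-to-end acceptance checks; `scripts/acceptance.py`
runs the 5 Mb genome once at default platforms, four times for the
coverage sweep, plus a 1 Mb copy-number experiment and a 120 kb
error-model experiment. These sizes were chosen so a complete from-
scratch reproduction stays within a few minutes on one CPU while every
rate being tested still has hundreds-to-thousands of events behind it.
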