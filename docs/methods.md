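# Methods

This note documents the models, rules and numerical choices behind
`mztscope`, what the synthetic-data generator does and does not emulate,
and the design decisions taken where more than one reasonable reading of
the procedures existed.

## Coordinates and formats

All internal coordinates are 0-based half-open. GFF3/GTF (1-based
inclusive) are converted at the I/O boundary; BED/bedGraph pass through
unchanged. A single convention internally prevents off-by-one drift, and
the round-trip (write → parse) is an identity on valid inputs. H3K4me3
peaks are treated as strandless; "non-redundant exons" always means
deduplication by the exact (chrom, start, end, strand) tuple. Positions
absent from an RNAPII bedGraph contribute **zero** to region means —
absence of ChIP coverage is absence of signal, so the mean over a region
is signal mass divided by region length. Conservation tracks are the one
exception: there, uncovered bases are *missing* (excluded from numerator
and denominator), matching how per-base conservation scores with alignment
gaps are averaged.

## Expression quantification and classification

RPKM is computed per exon and averaged over the gene's deduplicated exon
set across isoforms. When two isoforms carry an identical exon with
separately tabulated counts, the lexicographically first carrier's count is
used; on real data the counts are identical by construction (they come
from the same genomic interval), so this rule only pins down the synthetic
case deterministically.

All log-ratios and fold changes use a pseudocount of 0.01 RPKM (two
orders of magnitude below the RPKM ≥ 1 working range, and configurable).
Consequences worth knowing: a gene at exactly 10.0-fold induction measures
(10x + c)/(x + c) < 10 for any c > 0, so boundary-exact checks are done in
the c → 0 limit; and with c → 0 a gene with zero oocyte signal has
infinite fold and is embryonic by definition.

* **maternal** — oocyte RPKM ≥ 1 in PA *or* RZ.
* **embryonic** — ≥ 10-fold rise over oocyte at any later stage. The call
  is made on the PA library (the embryonic transcriptome is described over
  polyadenylated data); the library is selectable.
* **RZ-enriched** — log2(PA/RZ) ≤ −0.5 at the queried stage. A maternal
  call is additionally required (configurable off): without it, silent
  genes would enter the set through pseudocount artifacts.

K-means clustering (scikit-learn, Euclidean, `n_init=10`, seeded) operates
on either log2(RPKM + c) or on rows rescaled to sum 1. Defaults are k = 7
for PA/RZ-ratio clustering and k = 6 for embryonic profiles; the analysis
that motivated these displays used clusters in those ranges without fixing
k, so both are configuration values, not conclusions. Row scaling keeps
all-zero rows as zeros with a flag instead of dropping them (shape
preservation; the caller decides). Peak-stage assignment breaks ties by
the earliest stage — deterministic and biologically conservative.
RT-qPCR fold changes use 2^−ΔΔCt with a normalizer gene (odc1 in the
motivating assays) and a reference stage; the reference stage folds to
exactly 1.

## The annotation pipeline

Five steps: collect models → update with evidence → expression validation
→ TSS validation → representative selection; then new-gene-model
discovery. The load-bearing thresholds (all configurable, defaults are the
procedure's published values):

| parameter | default | role |
|---|---|---|
| min junction reads | 5 | a splice junction is credible |
| expressed exon reads | 3 | an exon counts as expressed (pooled reads) |
| expressed exon fraction | 1/3 | model is expressed (exact rational compare) |
| RNAPII body ratio | 0.5 | upstream-rescue bridge threshold |
| upstream search | 50 kb | rescue-peak search cap |
| peak/exon overlap | 1 bp | minimal reading of "overlaps" |

Decisions taken where the procedure was underdetermined:

* **"Sharing at least 1 exon" = exact exon identity**, not overlap.
  Overlap-based grouping would merge unrelated overlapping genes;
  identity is unambiguous and testable (a reciprocal-overlap mode would be
  a straightforward extension). Gene ids are the lexicographically
  smallest member model id, so grouping is deterministic.
* **Evidence linkage for model updating requires ≥ 1 exact shared splice
  junction on the same strand**, and evidence transcripts qualify only
  when all their introns are supported (filtered junctions or annotated
  introns). Junction sharing is the standard assembly-merge criterion and
  avoids chimeric fusions. Contributed exons are unioned with the
  originals — originals are extended, never removed.
* **Rescue geometry**: the RNAPII test region runs from the peak's
  gene-side edge to the 5′ exon start, exclusive of both; a zero-length
  gap passes trivially. The gene body is first-exon start to last-exon end,
  introns included ("gene body" conventionally includes introns). The
  "no different gene models in between" blocker set is the annotated
  working set (reference plus exon-sharing alternates), **not**
  yet-unclassified evidence transcripts — otherwise a stray 5′-UTR
  fragment assembled upstream of a truncated gene would always block its
  own parent's rescue, which is exactly backwards.
* **NGM overlap is strand-blind** exonic overlap ≥ 1 bp against the
  reference (conservative for claiming novelty; same-strand-only mode
  available). Unspliced single-exon candidates are excluded outright.
* **NGM-vv support is RNA-seq OR EST** (the weaker reading; a flag
  requires both). Representative-selection ties fall to longest genomic
  span, then smallest model id.
* Per-model TSS codes V/U/X are mutually exclusive; the gene-level status
  is V if any member validates, U if the gene was upstream-rescued, X
  otherwise. Curation consumes the gene-level status.

The pipeline records every status transition with its triggering rule in a
machine-readable run log.

## Coding potential

Conditional likelihoods are renormalized within each amino-acid class
(stop codons form their own class — their relative usage is informative,
and conditioning keeps single-codon classes at LLR exactly 0). Raw table
weights are rescaled to a total of 1000 (per-mil convention); classes
containing a zero weight get +0.5 pseudo-counts on every member before
normalization, keeping all LLRs finite while leaving zero-free classes
bit-exact.

ORF counting: Met through the last sense codon, stop excluded; runs
reaching the sequence end without a stop count in full. Both choices
matter at the 100-aa curation cutoff and are configurable in spirit (the
counting convention is documented here and frozen in the oracle tests).
N-containing codons are neutral: LLR 0, never a start, never a stop.

Windows slide by one codon (3 bp) within each frame — 1-bp sliding would
just re-enumerate the other frames. For sequences shorter than one window
the frame's full codon run is scored; frames without a complete window in
longer sequences contribute nothing. Window sums use compensated
summation (`math.fsum`), making scores independent of summation order and
exactly equal to independent per-window enumeration.

## The synthetic-data generator

The generator emulates a six-stage design (oocyte, stage 6, 9, 12, 16, 30)
with PA and RZ libraries, on one synthetic chromosome with ≥ 12 kb between
gene loci (so curation's 10-kb downstream search never crosses loci except
where a planted fragment/parent pair intends it to).

**Planted classes and their study conditions.** Maternal genes draw oocyte
RZ from U[8, 50] (comfortably above the RPKM ≥ 1 filter, so recovery
failures measure counting noise, not planting ambiguity); deadenylated
profiles plant log2(PA/RZ) in [−2.5, −1.0] at oocyte/st6/st9 (the filter
boundary is −0.5; no quantitative ratio is established for fully
deadenylated transcripts, so the range is a documented choice inside the
configurable [−3, −0.5] band); maternal-embryonic genes rise 1.5–3× (well
under the 10-fold filter); embryonic-only genes sit at 0.02 RPKM before a
random onset stage (st9 or later) and U[5, 30] after; lncRNAs draw U[2, 8]
so their median expression is about a third of the coding classes'.
Sequencing depth defaults to 20 M mapped reads per library.

**Counts** are Poisson per exon with mean RPKM × exon_kb × depth — the
exact inverse of the RPKM formula. This is the simplest count model;
biological overdispersion, positional bias, multi-mapping and library-size
variation are *not* emulated, so passing recovery tests demonstrates
correctness of the rules under idealized counting noise, not performance
on real libraries.

**Sequences.** Coding exons are sampled codon-wise from the bundled coding
table (ATG start, in-frame terminal stop); lncRNA exons and all
intergenic/intronic background are sampled triplet-wise from the noncoding
table, with lncRNA transcripts rejection-sampled to a maximal ORF ≤ 100 aa.
The bundled tables are synthetic: a vertebrate-like amino-acid composition
whose synonymous preferences are deliberately concentrated (dominant codon
85–95% per class) and set against an AT-rich (40% GC) independent-base
background. The concentration bounds the positive tail of the per-codon
LLR under the noncoding model, which is what keeps the *maximum* over many
90-bp windows negative for noncoding sequences; real codon bias is weaker,
and separation of real transcripts by this score is correspondingly
weaker. The tables are inputs, not constants — any 64-triplet TSV can be
substituted.

**Chromatin.** Each expressed gene's true TSS gets an H3K4me3 peak
(±200 bp) with probability 1 − dropout; RNAPII covers gene bodies at a
level tied to expression. Three artifact constructions exercise the
curation traps: (i) *UTR fragments* — a configurable number of genes are
annotated with truncated 5′ ends (their two leading UTR exons missing
from the reference model); the evidence set carries those UTR exons as a
spliced fragment, the true-TSS peak sits over the fragment, and bridging
RNAPII at 0.8× body level connects peak to annotated gene. The fragment
therefore reaches NGM-vv (it is expressed and peak-validated) and is
removed precisely by the downstream-gene X/U filter, because its parent is
upstream-rescued (U). These genes' peaks are exempt from dropout so the
construction holds at any dropout level. (ii) *Broken genes* — two
evidence halves each share exact exons with an intact reference gene and
are regrouped with it; the intact model wins representative selection.
(iii) *Unspliced single-exon models*, excluded early by design.

Everything is deterministic given the seed (sub-streams seed+1, +2, +3 for
sequences, counts and chromatin).

## Problem sizes

The default configuration plants 50 genes (10 per class) plus 9 artifact
models on a ~1.5 Mb chromosome; the test suite and the acceptance script
use this size, plus a 420-gene run for the codon-frequency calibration
check and 200 sequences per class for the coding/noncoding separation
measurement. These sizes give binomial/Poisson error bars tight enough for
the 3-sigma checks the suite applies while keeping the whole suite around
a few seconds of runtime.

## Known limitations

* Counting noise only (Poisson); no overdispersion or mapping artifacts.
* The grouping rule (exact exon identity) will not merge isoforms that
  share no identical exon; real annotations occasionally need the
  overlap-based mode this package does not yet expose.
* The curation homology screen is an exclusion-list hook, not an automated
  BLAST step; results depend on the list the user supplies.
* Single-chromosome synthetic genomes; multi-chromosome inputs are
  supported by all parsers and operations but not exercised by the
  generator.
* Expression matrices are dense pandas frames — appropriate for
  annotation-scale gene counts, not for single-cell-scale matrices.
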