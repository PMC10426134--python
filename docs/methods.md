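# Methods

## Model and procedure

`mapquant` treats the RNA expression of an MHC-I-associated peptide (MAP) as
the number of sequenced reads that could have encoded it, anywhere in the
genome. This is deliberately annotation-independent: the unit of measurement
is the 24–33-nt MAP-coding sequence (MCS), not a transcript model. The
procedure is: expand the peptide to its complete MCS set under the standard
genetic code; find every perfect genomic placement of every MCS; count the
primary reads that exactly span a placement; normalize; and attribute
biotypes to the expressed placements.

### Coordinates

All internal coordinates are 0-based half-open. GTF (1-based closed) and VCF
(1-based) are converted at the parser boundary; BED passes through.
Soft-masked reference bases are uppercased on load — repeat-derived peptides
are a central use case, so masking must not suppress matches — and `N` never
matches any query base.

### Localization

The reference is indexed by fixed-length seeds (default `seed_length = 12`,
both strands served from a plus-strand index). For a query MCS, candidate
starts are generated from **every sliding seed** of the query and each
candidate is verified base by base. A mismatch is licensed only when the
catalogued SNV set contains that exact position with the read base among its
alternate alleles; at most `max_mismatch` (default 3) licensed mismatches
are accepted per placement — unbounded mismatch tolerance on a 24-mer
against a dense variant catalog degenerates into spurious placements.

Sensitivity guarantee: since the sliding seeds include
$\lfloor |MCS|/\text{seed\_length} \rfloor$ disjoint seeds, any placement
with at most $\lfloor |MCS|/\text{seed\_length} \rfloor - 1$ mismatches is
found (pigeonhole); with the defaults that covers every single-mismatch
placement of any MCS length, and placements with more mismatches are found
whenever one clean seed-length window survives. Exhaustive-scan equivalence
is enforced in the test suite against a brute-force sliding-window oracle.

Spliced placements are searched only across **annotated** exon–exon
junctions: each multi-exon transcript's exons are concatenated and scanned
at every offset with the same SNV rule; matches crossing a junction become
multi-block locations (exported as BED12 blocks). De-novo junction discovery
is out of scope; the restriction is recorded in output metadata by
construction (spliced locations exist only where the GTF has junctions).
Manual-mode queries are verified at their stated location with the same
perfect-alignment rule and rejected with a diagnostic otherwise.

### Counting

Only primary alignment records (flag 0x100 unset) are examined, so records
correspond one-to-one to sequenced reads; $R_t$, the normalization
denominator, counts the same population over the whole file (supplementary
and duplicate-marked records included — they exist in the original fastq;
duplicate counting can be disabled). A read counts for a location iff the
location's positions map to consecutive read bases (which excludes indels,
clips, and unannotated skips inside the span) and every base equals the
expected plus-strand base (reference, or licensed alternate). Each record
counts at most once per location; both mates of a pair spanning the MCS
count twice by default, with an optional fragment-collapsed mode, because
the per-read rule is the primitive the counting model defines.

Stranded libraries filter reads through the eight-case table keyed by
(layout, chemistry, location strand); for paired data the required flag-bit
masks are 0x50/0xA0 or 0x60/0x90 for the R1/R2 mates, for single-end data
the read orientation must equal (forward chemistry) or oppose (reverse) the
location strand. Unstranded counting takes every primary read and equals
the union of the two stranded selections for properly oriented pairs.

Normalization: $\mathrm{RPHM} = tr_{MAP} / R_t \times 10^8$ and
$\log_{10}(\mathrm{RPHM} + 1)$. $R_t \le 0$ is a hard error. Single-cell
BAMs can be counted per cell-barcode tag (`CB`); per-cell size-factor
normalization is delegated downstream.

### Biotypes

Each expressed location is intersected with transcript features (CDS with
frame checking, 5'/3' UTR, non-coding and pseudogene exons, introns derived
as inter-exon gaps) and repeat annotations (grouped by repeat class into
ERE_LINE / ERE_SINE / ERE_LTR / ERE_other). A location overlapping both
exonic and intronic parts of one transcript is an exon–intron junction; no
overlap at all is intergenic. In-frame status requires all blocks inside
the CDS of a same-strand transcript, splice-consistent block boundaries, and
a codon-boundary offset in transcription order. Features are matched
regardless of strand by default (annotation intersection mirrors unstranded
cohort processing); a strict-strand option exists.

Reads are apportioned over classes by EM. With $\varnothing_j$ the per-class
coefficient (initialized at 0.1 for every observed class; unobserved classes
stay at 0), the E-step distributes each peptide's reads:

$$Z_i(j) = \frac{1}{R_i} \sum_k r_k \,
  \frac{\varnothing_j}{\sum_{b \in B_k} \varnothing_b}$$

over its locations $k$ (reads $r_k$, class sets $B_k$), and the M-step
averages: $\varnothing_j \leftarrow \frac{1}{N}\sum_i Z_i(j)$. The M-step is
implemented as the average of the E-step distributions — the reading under
which the update actually uses the E-step; a read-weighted pooled summary
($\sum_i R_i Z_i / \sum_i R_i$) is also exposed. "Unchanged parameter
vector" convergence is implemented as max absolute change < 1e-8 with a
10,000-iteration cap, since exact float equality is fragile.

Percentages are reported at three scopes — per location (normalized
coefficients over the classes present), per cohort, and global (location
reads distributed by per-location shares, normalized by scope total) — and
a scope with zero reads is *undefined*, not zero. Best guess: any in-frame
origin forces `in_frame` with certainty equal to its percentage (a peptide
that can come from a canonical protein most likely does); otherwise the
argmax class; exact ties are all reported.

### Prioritization

The tumor-specific-antigen cascade runs in order: (1) drop peptides with no
genomic location; (2) tolerance filter — discard at mean RPHM ≥ 8.55 in any
mTEC/DC group (8.55 RPHM is the minimum expression conferring > 5%
probability of generating a MAP, and mTEC+DC expression is treated as a
union because both compartments shape central tolerance); (3) normal-tissue
filter at the same threshold, with testis exempt when the cancer–testis
exemption is on (high testis expression flags a CTA instead); (4) tumor
versus normal fold change ≥ 5 on group means with a 0.5 pseudocount in the
denominator, exempt (testis) groups excluded from the reference so a CTA's
testis signal cannot mask tumor upregulation; (5) when ribosome-profiling
counts are supplied, translation evidence requires > 0 reads. Every peptide
records exactly one discard stage or none. The threshold applies to group
means by default; a per-sample-max variant is available through
`build_matrix` inputs.

The immunogenicity model is an L2 logistic regression (liblinear solver) on
per-peptide mean RPHM in mTEC and DC groups, evaluated by stratified shuffle
splits (10 repeats, 20% held out) reporting mean ROC-AUC, then refitted on
all data for prediction.

## Synthetic data

The `fixtures` module generates the entire input bundle with ground truth:
a seeded random genome with peptide MCS planted at chosen loci (contiguous,
spliced across an annotated intron, minus-strand, or carrying catalogued SNV
alternates, in which case the reference holds the reference allele and the
reads the alternate), GTF transcripts engineered to put plants in or out of
frame, repeat BED entries, a VCF, and sorted indexed BAMs containing the
requested spanning reads plus mandatory decoys (one-base-short coverage,
one internal mismatch, a clip inside the span, antisense reads, secondary
copies) and background reads. The background is rejection-screened by direct
substring scan so no planted peptide's MCS occurs anywhere unplanned, on
either strand, in reference or haplotype; background reads never overlap
planted spans. Regeneration from the same seed is byte-identical.

What the generator does **not** emulate: sequencing errors and quality
variation, fragment-length distributions, coverage biases, real repeat
structure (each ERE plant is a single annotated copy, not a family of
thousands), population-scale variant density, or cohort-scale sample counts.
Passing tests therefore demonstrate the correctness of the counting and
attribution machinery under clean conditions, not robustness to noisy real
data. Problem sizes were chosen so the whole suite runs in minutes on one
CPU: fixture genomes of kilobases to tens of kilobases, panels of 50–60
nonamers drawn from low-degeneracy residues (MCS sets ≤ 512, so exhaustive
enumeration stays cheap), and a few hundred reads per sample.

## Numerical and design choices

- Peptides outside 8–11 residues, selenocysteine/pyrrolysine, and ambiguous
  residues are rejected, not expanded.
- MCS expansion order is lexicographic; location order is
  (chrom, start, strand, blocks); reports are written in sorted order, so
  reruns are byte-identical and thread counts cannot change results
  (ordered reduction over samples).
- Seed lengths below 8 are refused, below 12 warned (candidate lists grow);
  seeds containing `N` are not indexed.
- Zero-read locations contribute nothing to any biotype percentage; adding
  one never changes a profile.
- "No genomic location" and "located but zero reads" are distinct states in
  every report.
- Arbitrary GTF/VCF paths replace fixed annotation-release switches, making
  the engine version-agnostic.

## Limitations

- Biotype attributions are expression-based predictions; they do not
  incorporate translation evidence.
- Mismatches are licensed only by single-nucleotide variants; indel-bearing
  placements are not searched.
- Placements needing more licensed mismatches than disjoint clean seeds
  exist (> 1 with the defaults) can in principle be missed; raise
  `max_mismatch` only together with a shorter seed if that matters.
- The EM fit runs on whatever samples are supplied; coefficients from small
  cohorts are correspondingly noisy.
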