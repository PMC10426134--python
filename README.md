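# mapquant

Annotation-independent RNA expression and probabilistic biotypes for
MHC-I-associated peptides (MAPs), computed directly from alignment files.

## The problem

MHC-I-associated peptides are 8–11-residue fragments displayed at the cell
surface; immunopeptidomics identifies them by mass spectrometry, and their
RNA-level expression in tumors versus normal tissues drives the selection of
actionable tumor antigens. Conventional quantifiers (Kallisto, HTSeq) measure
the *parental transcript*, which fails for peptides from unannotated regions
(introns, endogenous retroelements, intergenic DNA) and ignores that the
degeneracy of the genetic code lets one peptide arise from many genomic loci.

`mapquant` instead measures each peptide directly:

1. **Reverse translation** — a peptide of residues $a_1 \dots a_k$ expands to
   all $\prod_i d(a_i)$ MAP-coding sequences (MCS, 24–33 nt), where $d$ is
   codon degeneracy (up to 6 for R/L/S).
2. **Localization** — every MCS is matched exhaustively against the reference
   genome on both strands. A placement is *perfect* when each base equals the
   reference or is a catalogued dbSNP single-nucleotide alternate at that
   position; annotated exon–exon junctions are searched for spliced
   placements.
3. **Counting** — per sample, only primary alignment records (SAM flag 0x100
   unset) that *exactly span* an MCS — consecutive read bases, no indel or
   clip, every base matching — are counted; stranded libraries are filtered
   through the eight-way (layout × chemistry × location strand) SAM-flag
   table. Counts sum over all locations of a peptide: $tr_{MAP}$.
4. **Normalization** —
   $\mathrm{RPHM} = \dfrac{tr_{MAP}}{R_t} \times 10^8$ (reads per hundred
   million, $R_t$ = total primary reads), log-scaled as
   $\log_{10}(\mathrm{RPHM}+1)$ for cross-sample averaging.
5. **Biotypes** — expressed locations are intersected with GENCODE-style and
   RepeatMasker-style annotations; reads are apportioned across biotype
   classes by an expectation–maximization fit (coefficients initialized at
   0.1, iterated to a fixed point), reported per location, per cohort, and
   globally, with a *best guess* (any in-frame origin wins; otherwise the
   top-share class; exact ties all reported).
6. **Prioritization** — a filter cascade for tumor-specific antigens
   (mTEC/DC tolerance filter at 8.55 RPHM, normal-tissue filter, fivefold
   tumor/normal upregulation, Ribo-seq translation evidence; high testis-only
   expression flags a cancer–testis antigen), plus a logistic-regression
   immunogenicity score on mTEC and DC expression.

## Worked example

All inputs can be generated synthetically — the `fixtures` subcommand plants
peptide-coding sequences in a random genome and emits matching reads with a
known truth table:

```bash
mapquant fixtures --out fix --seed 4 --n-peptides 10
# peps.txt: one "name peptide" line per planted peptide
# manifest.tsv: s1 <tab> fix/sample.bam <tab> single_end <tab> forward <tab> unstranded
mapquant query --genome fix/genome.fa --gtf fix/annotations.gtf \
    --ere-bed fix/eres.bed --vcf fix/snvs.vcf \
    --peptides peps.txt --manifest manifest.tsv --out out
head -5 out/expression.tsv
```

```
peptide	sample	tr_map	rphm	log_rphm	status
p000	s1	25	5617977.5281	6.7496	ok
p001	s1	5	1123595.5056	6.0506	ok
p002	s1	25	5617977.5281	6.7496	ok
p003	s1	6	1348314.6067	6.1298	ok
```

`tr_map` is the summed exact-spanning read count over every genomic location
of the peptide (here each planted locus received the number of reads recorded
in `fix/sample.bam.truth.json`); `rphm` normalizes by the sample's 445
primary reads ($25/445 \times 10^8 \approx 5.6\times10^6$), and `log_rphm`
is its log transform. Peptides with no perfect genomic placement are reported
with `status=no_location` rather than silently dropped. The run also writes
`out/per_location.tsv` (per-location counts), `out/locations.bed` (BED12,
spliced placements as blocks), and `out/biotypes.tsv` (per-scope biotype
percentages and the best guess).

The library surface mirrors the pipeline: `mapquant.reverse_translate`,
`mapquant.locate.locate` / `locate_spliced` / `resolve_manual`,
`mapquant.counting.count_mcs_reads` / `rphm`, `mapquant.biotype.em_fit`,
`mapquant.prioritize.tsa_cascade` / `fit_immunogenicity`, and
`mapquant.run` for the orchestrated whole.

## Scope notes

Read alignment itself is out of scope: `mapquant` consumes coordinate-sorted
indexed BAM/CRAM. Spliced placements are restricted to annotated junctions.
Single-cell data are supported at the counting level (per-cell-barcode
splits); per-cell normalization is left to dedicated downstream tools. See
`docs/methods.md` for the model, parameter defaults, and limitations.
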