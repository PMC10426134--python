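"""Synthetic, self-consistent test inputs with known ground truth.

Generates a random reference genome with peptide-coding sequences planted at
chosen locations (contiguous, spliced across an annotated intron, on either
strand, optionally differing from the reference at catalogued SNV
positions), the matching GTF / ERE BED / VCF annotations, and sorted indexed
BAMs whose spanning reads, decoys, and background reads realize a known
per-peptide truth table.  Everything is deterministic given the seed.

The background is rejection-screened so that no MCS of any planted peptide
occurs anywhere except at its planted locations, on either strand, in
either the reference or the variant-bearing haplotype; the screen is a
direct sliding-window substring scan, independent of the locator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .counting import LibraryConfig
from .genome import (
    AnnotationIndex,
    ReferenceGenome,
    SNVCatalog,
    load_annotations,
    load_snvs,
    reverse_complement,
)
from .locate import GenomicLocation
from .revtrans import n_mcs, reverse_translate

_BASES = "ACGT"

# residues encoded by at most two codons, keeping MCS sets small enough to
# enumerate exhaustively in tests
LOW_DEGENERACY_AA = "CDEFHKMNQWY"


@dataclass
class Plant:
    """One peptide-coding sequence to embed in the synthetic reference."""

    name: str
    peptide: str
    chrom: str = "chr1"
    start: int = 100
    strand: str = "+"
    mcs: str | None = None  # default: lexicographically first MCS
    reads: int = 10  # sense spanning reads
    antisense_reads: int = 0  # counted unstranded, not stranded
    snv_offsets: tuple[int, ...] = ()  # offsets in the forward-oriented span
    intron: tuple[int, int] | None = None  # (nt before junction, intron length)
    annotation: str | None = None  # coding_in|coding_out|ncRNA|pseudogene|intron|ERE:<class>/<family>
    decoys: bool = False

    def resolved_mcs(self) -> str:
        return self.mcs if self.mcs else min(reverse_translate(self.peptide))


@dataclass
class FixtureSpec:
    seed: int = 0
    chromosomes: dict[str, int] = field(default_factory=lambda: {"chr1": 20000})
    plants: list[Plant] = field(default_factory=list)
    background_reads: int = 200
    read_length: int = 60
    library: LibraryConfig = field(
        default_factory=lambda: LibraryConfig("single_end", "forward", "unstranded")
    )
    n_random_snvs: int = 0
    secondary_copies: int = 0  # extra 0x100 copies of spanning reads
    screen_mcs_limit: int = 4096  # enumerate full MCS sets up to this size


@dataclass
class FixtureReference:
    spec: FixtureSpec
    fasta: str
    gtf: str
    ere_bed: str
    vcf: str
    genome: ReferenceGenome
    haplotype: dict[str, str]  # reference with plant SNV alternates applied
    snv_catalog: SNVCatalog
    annotations: AnnotationIndex
    plant_locations: dict[str, GenomicLocation]  # plant name -> planted location


@dataclass
class FixtureBam:
    path: str
    truth: dict  # see make_bam


def _plant_geometry(plant: Plant) -> tuple[tuple[tuple[int, int], ...], str]:
    """Blocks and forward-oriented expected sequence of one plant."""
    mcs = plant.resolved_mcs()
    q = mcs if plant.strand == "+" else reverse_complement(mcs)
    if plant.intron:
        e1, ilen = plant.intron
        if not (0 < e1 < len(q)) or ilen < 20:
            raise ValueError(f"{plant.name}: bad intron spec {plant.intron}")
        blocks = (
            (plant.start, plant.start + e1),
            (plant.start + e1 + ilen, plant.start + ilen + len(q)),
        )
    else:
        blocks = ((plant.start, plant.start + len(q)),)
    return blocks, q


def plant_location(plant: Plant) -> GenomicLocation:
    blocks, q = _plant_geometry(plant)
    mcs = plant.resolved_mcs()
    support = tuple(
        ([p for s, e in blocks for p in range(s, e)][off], q[off])
        for off in plant.snv_offsets
    )
    return GenomicLocation(
        chrom=plant.chrom, strand=plant.strand, blocks=blocks, mcs=mcs,
        expected_forward=q, snv_support=support,
    )


def _other_base(rng: np.random.Generator, *exclude: str) -> str:
    choices = [b for b in _BASES if b not in exclude]
    return choices[int(rng.integers(len(choices)))]


def _write_fasta(path: str, sequences: dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def _gtf_attrs(gene_id, tid, biotype, gene_name=None):
    parts = [f'gene_id "{gene_id}"', f'transcript_id "{tid}"']
    if gene_name:
        parts.append(f'gene_name "{gene_name}"')
    parts.append(f'gene_type "{biotype}"')
    parts.append(f'transcript_type "{biotype}"')
    return "; ".join(parts) + ";"


def _transcript_gtf_lines(chrom, strand, tid, biotype, exons, cds_blocks=()):
    """GTF (1-based closed) lines for one transcript."""
    attrs = _gtf_attrs(f"gene_{tid}", tid, biotype, gene_name=f"G{tid}")
    lines = [
        "\t".join([chrom, "fixture", "transcript", str(exons[0][0] + 1),
                   str(exons[-1][1]), ".", strand, ".", attrs])
    ]
    for s, e in exons:
        lines.append("\t".join([chrom, "fixture", "exon", str(s + 1), str(e),
                                ".", strand, ".", attrs]))
    for s, e, frame in cds_blocks:
        lines.append("\t".join([chrom, "fixture", "CDS", str(s + 1), str(e),
                                ".", strand, str(frame), attrs]))
    return lines


def _cds_for_plant(exons, strand, plant_blocks, out_of_frame: bool):
    """CDS blocks placing the planted span in (or out of) frame.

    Works in transcript coordinates over the concatenated exons so that
    spliced plants are handled the same way as contiguous ones.
    """
    genomic = [p for s, e in exons for p in range(s, e)]
    order = genomic if strand == "+" else genomic[::-1]
    tindex = {p: i for i, p in enumerate(order)}
    span = [p for s, e in plant_blocks for p in range(s, e)]
    t_span = sorted(tindex[p] for p in span)
    t0, t1 = t_span[0], t_span[-1] + 1
    target = 1 if out_of_frame else 0
    # offset of the plant within the CDS must be ≡ target (mod 3)
    cds_t_start = (t0 - target) % 3
    if cds_t_start < 0:
        raise ValueError("not enough exon padding upstream for CDS")
    cds_t_end = t1 + ((3 - (t1 - cds_t_start) % 3) % 3)
    if cds_t_end > len(order):
        raise ValueError("not enough exon padding downstream for CDS")
    cds_positions = sorted(order[cds_t_start:cds_t_end])
    blocks = []
    run_start = cds_positions[0]
    prev = cds_positions[0]
    for p in cds_positions[1:]:
        if p != prev + 1:
            blocks.append((run_start, prev + 1))
            run_start = p
        prev = p
    blocks.append((run_start, prev + 1))
    # GTF frame: bases to skip to the next codon boundary, in transcription order
    ordered = blocks if strand == "+" else blocks[::-1]
    out = []
    cum = 0
    for s, e in ordered:
        out.append((s, e, (3 - cum % 3) % 3))
        cum += e - s
    return sorted(out)


def make_reference(spec: FixtureSpec, outdir: str) -> FixtureReference:
    """Build FASTA + GTF + ERE BED + VCF realizing the plants, with screening."""
    os.makedirs(outdir, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    ref: dict[str, np.ndarray] = {}
    for chrom, length in spec.chromosomes.items():
        ref[chrom] = rng.integers(0, 4, size=length).astype(np.uint8)
    base_codes = np.frombuffer("ACGT".encode(), dtype=np.uint8)

    def to_str(arr):
        return base_codes[arr].tobytes().decode("ascii")

    hap = {c: a.copy() for c, a in ref.items()}
    code = {b: i for i, b in enumerate(_BASES)}

    extents = []  # (chrom, start, end) spans that must stay untouched
    vcf_entries = []  # (chrom, pos0, ref, alt)
    gtf_lines = []
    bed_lines = []
    plant_locs = {}
    pad = 30

    for plant in spec.plants:
        if plant.chrom not in ref:
            raise ValueError(f"{plant.name}: unknown chromosome {plant.chrom}")
        blocks, q = _plant_geometry(plant)
        extent = (plant.chrom, blocks[0][0] - pad, blocks[-1][1] + pad)
        if extent[1] < 0 or extent[2] > spec.chromosomes[plant.chrom]:
            raise ValueError(f"{plant.name}: plant too close to chromosome edge")
        for c, s, e in extents:
            if c == extent[0] and s < extent[2] and extent[1] < e:
                raise ValueError(f"{plant.name}: overlaps another plant")
        extents.append(extent)
        span = [p for s, e in blocks for p in range(s, e)]
        for i, p in enumerate(span):
            ref[plant.chrom][p] = code[q[i]]
            hap[plant.chrom][p] = code[q[i]]
        for off in plant.snv_offsets:
            p = span[off]
            alt = q[off]
            refbase = _other_base(rng, alt)
            ref[plant.chrom][p] = code[refbase]
            vcf_entries.append((plant.chrom, p, refbase, alt))
        plant_locs[plant.name] = plant_location(plant)

        ann = plant.annotation
        if plant.intron and ann is None:
            ann = "ncRNA"  # spliced placements are only findable via annotation
        tid = f"t_{plant.name}"
        if plant.intron:
            exons = [(blocks[0][0] - pad, blocks[0][1]), (blocks[1][0], blocks[1][1] + pad)]
        else:
            exons = [(blocks[0][0] - pad, blocks[-1][1] + pad)]
        if ann in ("coding_in", "coding_out"):
            cds = _cds_for_plant(exons, plant.strand, blocks, ann == "coding_out")
            gtf_lines += _transcript_gtf_lines(
                plant.chrom, plant.strand, tid, "protein_coding", exons, cds
            )
        elif ann == "ncRNA":
            gtf_lines += _transcript_gtf_lines(plant.chrom, plant.strand, tid, "lncRNA", exons)
        elif ann == "pseudogene":
            gtf_lines += _transcript_gtf_lines(
                plant.chrom, plant.strand, tid, "processed_pseudogene", exons
            )
        elif ann == "intron":
            flank = 50
            exons = [
                (blocks[0][0] - pad - flank, blocks[0][0] - pad),
                (blocks[-1][1] + pad, blocks[-1][1] + pad + flank),
            ]
            if exons[0][0] < 0 or exons[1][1] > spec.chromosomes[plant.chrom]:
                raise ValueError(f"{plant.name}: no room for intron-host transcript")
            gtf_lines += _transcript_gtf_lines(
                plant.chrom, plant.strand, tid, "protein_coding", exons
            )
        elif ann and ann.startswith("ERE:"):
            repeat = ann.split(":", 1)[1]
            rclass, _, rfamily = repeat.partition("/")
            bed_lines.append(
                "\t".join(
                    [
                        plant.chrom, str(blocks[0][0] - 5), str(blocks[-1][1] + 5),
                        f"rep_{plant.name}", "0", plant.strand, rclass, rfamily or rclass,
                    ]
                )
            )
        elif ann is not None:
            raise ValueError(f"{plant.name}: unknown annotation {ann!r}")

    # random decorative SNVs outside plant extents
    for _ in range(spec.n_random_snvs):
        for _attempt in range(50):
            chrom = list(spec.chromosomes)[int(rng.integers(len(spec.chromosomes)))]
            p = int(rng.integers(0, spec.chromosomes[chrom]))
            if not any(c == chrom and s <= p < e for c, s, e in extents):
                refbase = _BASES[ref[chrom][p]]
                vcf_entries.append((chrom, p, refbase, _other_base(rng, refbase)))
                break

    _screen_background(spec, ref, hap, extents, plant_locs, rng)

    sequences = {c: to_str(a) for c, a in ref.items()}
    haplotype = {c: to_str(a) for c, a in hap.items()}

    fasta = os.path.join(outdir, "genome.fa")
    _write_fasta(fasta, sequences)
    gtf = os.path.join(outdir, "annotations.gtf")
    with open(gtf, "w") as fh:
        fh.write("\n".join(gtf_lines) + ("\n" if gtf_lines else ""))
    bed = os.path.join(outdir, "eres.bed")
    with open(bed, "w") as fh:
        fh.write("\n".join(bed_lines) + ("\n" if bed_lines else ""))
    vcf = os.path.join(outdir, "snvs.vcf")
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in spec.chromosomes.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, (chrom, pos, r, a) in enumerate(sorted(set(vcf_entries))):
            fh.write(f"{chrom}\t{pos + 1}\trs{i}\t{r}\t{a}\t.\t.\t.\n")

    genome = ReferenceGenome(sequences)
    return FixtureReference(
        spec=spec,
        fasta=fasta,
        gtf=gtf,
        ere_bed=bed,
        vcf=vcf,
        genome=genome,
        haplotype=haplotype,
        snv_catalog=load_snvs(vcf),
        annotations=load_annotations(gtf, bed),
        plant_locations=plant_locs,
    )


def _screen_background(spec, ref, hap, extents, plant_locs, rng):
    """Mutate background bases until no planted peptide's MCS occurs off-plant."""
    patterns: set[str] = set()
    for plant in spec.plants:
        if n_mcs(plant.peptide) <= spec.screen_mcs_limit:
            mcs_set = reverse_translate(plant.peptide)
        else:
            mcs_set = [plant.resolved_mcs()]
        for m in mcs_set:
            patterns.add(m)
            patterns.add(reverse_complement(m))
    lengths = sorted({len(p) for p in patterns})
    allowed = {
        (loc.chrom, loc.start): loc
        for loc in plant_locs.values()
        if not loc.spliced and not loc.snv_support
    }
    # spliced or SNV-bearing plants do not leave a contiguous reference match,
    # but their haplotype holds the contiguous variant sequence only if unspliced
    hap_allowed = {
        (loc.chrom, loc.start): loc for loc in plant_locs.values() if not loc.spliced
    }
    base_codes = np.frombuffer("ACGT".encode(), dtype=np.uint8)
    code = {b: i for i, b in enumerate(_BASES)}

    for _round in range(200):
        dirty = False
        for chrom in ref:
            for seqs, ok in ((ref, allowed), (hap, hap_allowed)):
                text = base_codes[seqs[chrom]].tobytes().decode("ascii")
                for L in lengths:
                    i = 0
                    while i <= len(text) - L:
                        window = text[i:i + L]
                        if window in patterns and (chrom, i) not in ok:
                            # mutate a background base inside the window
                            for j in rng.permutation(L):
                                p = i + int(j)
                                if not any(
                                    c == chrom and s <= p < e for c, s, e in extents
                                ):
                                    nb = _other_base(rng, text[p])
                                    ref[chrom][p] = code[nb]
                                    hap[chrom][p] = code[nb]
                                    dirty = True
                                    break
                            else:
                                raise ValueError(
                                    f"cannot screen MCS collision at {chrom}:{i}"
                                )
                            break
                        i += 1
                    if dirty:
                        break
                if dirty:
                    break
            if dirty:
                break
        if not dirty:
            return
    raise RuntimeError("background screening did not converge")


def _sense_flag(library: LibraryConfig, strand: str, mate: int) -> int:
    """SAM flag of a read transcribed from `strand` under this library.

    mate: 0 for single-end, 1 for R1, 2 for R2.
    """
    if library.layout == "single_end":
        orient = strand if library.chemistry == "forward" else ("-" if strand == "+" else "+")
        return 0x10 if orient == "-" else 0
    r1_orient = strand if library.chemistry == "forward" else ("-" if strand == "+" else "+")
    orient = r1_orient if mate == 1 else ("-" if r1_orient == "+" else "+")
    mate_orient = "-" if orient == "+" else "+"
    flag = 0x1 | (0x40 if mate == 1 else 0x80)
    if orient == "-":
        flag |= 0x10
    if mate_orient == "-":
        flag |= 0x20
    return flag


def make_bam(
    reference: FixtureReference,
    path: str,
    library: LibraryConfig | None = None,
    sample_name: str = "sample",
) -> FixtureBam:
    """Emit the spanning reads, decoys, and background of one sample.

    The truth table records, per plant: the stranded and unstranded expected
    spanning-read counts; per peptide: total expected counts; and the
    sample's total primary read count R_t.
    """
    spec = reference.spec
    library = library or spec.library
    rng = np.random.default_rng(spec.seed + 1)
    read_len = spec.read_length
    chroms = list(spec.chromosomes)
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": spec.chromosomes[c]} for c in chroms],
    }
    records = []  # (chrom_idx, pos, name, flag, cigar, seq)
    serial = 0

    def hap_slice(chrom, s, e):
        return reference.haplotype[chrom][s:e]

    def emit(chrom, pos, flag, cigar, seq, name=None):
        nonlocal serial
        serial += 1
        records.append((chroms.index(chrom), pos, name or f"r{serial:06d}", flag, cigar, seq))

    truth_plants = {}
    for plant in spec.plants:
        loc = reference.plant_locations[plant.name]
        blocks = loc.blocks
        span_len = loc.end - loc.start if not loc.spliced else sum(e - s for s, e in blocks)
        pad = 30
        genomic_span = sum(e - s for s, e in blocks)
        extra_total = max(0, read_len - genomic_span)

        def spanning(strand_sense, mate, trunc_right=0, clip_into_span=0, mismatch_at=None):
            max_left = min(pad, blocks[0][0])
            max_right = min(pad, spec.chromosomes[plant.chrom] - blocks[-1][1])
            left = int(rng.integers(0, min(extra_total, max_left) + 1))
            right = 0 if trunc_right else min(extra_total - left, max_right)
            b = blocks
            if len(b) == 1:
                s0 = b[0][0] - left
                e0 = b[0][1] + right - trunc_right
                seq = hap_slice(plant.chrom, s0, e0)
                cigar = [(0, len(seq))]
                pos = s0
            else:
                s0 = b[0][0] - left
                e1 = b[1][1] + right - trunc_right
                part1 = hap_slice(plant.chrom, s0, b[0][1])
                part2 = hap_slice(plant.chrom, b[1][0], e1)
                seq = part1 + part2
                cigar = [(0, len(part1)), (3, b[1][0] - b[0][1]), (0, len(part2))]
                pos = s0
            if mismatch_at is not None:
                if len(b) == 1 or mismatch_at < b[0][1]:
                    i = mismatch_at - pos
                else:
                    i = (b[0][1] - pos) + (mismatch_at - b[1][0])
                exp = seq[i]
                refbase = reference.genome.sequences[plant.chrom][mismatch_at]
                bad = next(x for x in _BASES if x != exp and x != refbase)
                seq = seq[:i] + bad + seq[i + 1:]
            if clip_into_span:
                clip = left + clip_into_span
                cigar0 = cigar[0]
                cigar = [(4, clip), (cigar0[0], cigar0[1] - clip)] + cigar[1:]
                pos += clip
            flag = _sense_flag(library, strand_sense, mate)
            emit(plant.chrom, pos, flag, cigar, seq)
            return flag

        mates = [1, 2] if library.layout == "paired_end" else [0]
        for j in range(plant.reads):
            spanning(plant.strand, mates[j % len(mates)])
        anti = "-" if plant.strand == "+" else "+"
        for j in range(plant.antisense_reads):
            spanning(anti, mates[j % len(mates)])
        if plant.decoys:
            spanning(plant.strand, mates[0], trunc_right=1)  # covers n-1 of n
            mid = loc.span_positions[genomic_span // 2]
            spanning(plant.strand, mates[0], mismatch_at=mid)
            spanning(plant.strand, mates[0], clip_into_span=3)
        truth_plants[plant.name] = {
            "peptide": plant.peptide,
            "stranded": plant.reads,
            "unstranded": plant.reads + plant.antisense_reads,
        }

    n_primary_so_far = len(records)
    spans = [
        (loc.chrom, loc.start, loc.end) for loc in reference.plant_locations.values()
    ]
    emitted = 0
    while emitted < spec.background_reads:
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, spec.chromosomes[chrom] - read_len))
        # background must not overlap any planted span, else it could span an MCS
        if any(c == chrom and start < e and s < start + read_len for c, s, e in spans):
            continue
        strand = "+" if rng.integers(2) == 0 else "-"
        mate = int(rng.integers(1, 3)) if library.layout == "paired_end" else 0
        seq = reference.genome.sequences[chrom][start:start + read_len]
        emit(chrom, start, _sense_flag(library, strand, mate), [(0, read_len)], seq)
        emitted += 1

    total_primary = len(records)
    for i in range(spec.secondary_copies):
        c, pos, name, flag, cigar, seq = records[i % n_primary_so_far] if n_primary_so_far else records[0]
        records.append((c, pos, name + "_sec", flag | 0x100, cigar, seq))

    records.sort(key=lambda r: (r[0], r[1], r[2]))
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for c, pos, name, flag, cigar, seq in records:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = flag
            a.reference_id = c
            a.reference_start = pos
            a.mapping_quality = 60
            a.cigartuples = cigar
            a.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            if flag & 0x1:
                a.next_reference_id = c
                a.next_reference_start = pos
            out.write(a)
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)

    per_peptide = {}
    for plant in spec.plants:
        t = truth_plants[plant.name]
        agg = per_peptide.setdefault(plant.peptide, {"stranded": 0, "unstranded": 0})
        agg["stranded"] += t["stranded"]
        agg["unstranded"] += t["unstranded"]
    truth = {
        "sample": sample_name,
        "total_primary_reads": total_primary,
        "plants": truth_plants,
        "peptides": per_peptide,
        "library": {
            "layout": library.layout,
            "chemistry": library.chemistry,
            "strandedness": library.strandedness,
        },
    }
    with open(path + ".truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    return FixtureBam(path=path, truth=truth)


def kmer_oracle(bam_path: str, k: int = 27, revcomp_read1: bool = False) -> dict[str, int]:
    """Occurrences of every k-mer across primary read sequences.

    Reproduces a Jellyfish-style database built from the reads: each primary
    record's sequence is chunked into all overlapping k-mers; with
    `revcomp_read1` the R1 mates are reverse-complemented first, as done for
    reverse-chemistry libraries.
    """
    if k not in (24, 27, 30, 33):
        raise ValueError(f"k must be an MCS length (24/27/30/33), got {k}")
    counts: dict[str, int] = {}
    with pysam.AlignmentFile(bam_path) as af:
        for read in af.fetch(until_eof=True):
            if read.flag & 0x100:
                continue
            seq = read.query_sequence or ""
            if revcomp_read1 and read.flag & 0x40:
                seq = reverse_complement(seq)
            for i in range(len(seq) - k + 1):
                w = seq[i:i + k]
                counts[w] = counts.get(w, 0) + 1
    return counts


def random_low_degeneracy_peptide(rng: np.random.Generator, length: int = 9) -> str:
    return "".join(
        LOW_DEGENERACY_AA[int(rng.integers(len(LOW_DEGENERACY_AA)))] for _ in range(length)
    )


def panel_spec(
    n_peptides: int = 60,
    seed: int = 0,
    max_reads: int = 25,
    read_length: int = 60,
    background_reads: int = 300,
) -> FixtureSpec:
    """A 9-mer peptide panel fixture for pipeline-versus-k-mer comparisons.

    Peptides are drawn from low-degeneracy residues so their full MCS sets
    stay enumerable; each is planted once on the plus strand with a random
    positive spanning-read count, and all reads are indel- and clip-free.
    """
    rng = np.random.default_rng(seed)
    peptides: list[str] = []
    seen = set()
    while len(peptides) < n_peptides:
        p = random_low_degeneracy_peptide(rng)
        if p not in seen:
            seen.add(p)
            peptides.append(p)
    spacing = 260
    length = n_peptides * spacing + 2000
    plants = [
        Plant(
            name=f"p{i:03d}",
            peptide=p,
            chrom="chr1",
            start=1000 + i * spacing,
            strand="+",
            reads=int(rng.integers(1, max_reads + 1)),
        )
        for i, p in enumerate(peptides)
    ]
    return FixtureSpec(
        seed=seed,
        chromosomes={"chr1": length},
        plants=plants,
        background_reads=background_reads,
        read_length=read_length,
        library=LibraryConfig("single_end", "forward", "unstranded"),
    )


def immunogenicity_dataset(
    n: int = 400,
    seed: int = 0,
    effect: float = 1.0,
    separable: bool = False,
    immunogenic_fraction: float = 0.3,
):
    """Synthetic (mTEC RPHM, DC RPHM, label) peptide set.

    Non-immunogenic peptides draw log-normal expression in both tolerance
    features; immunogenic peptides are shifted `effect` log10 units lower,
    emulating central-tolerance pruning of highly expressed sequences.
    `separable` plants a clean threshold on the mTEC feature instead.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    n_pos = int(n * immunogenic_fraction)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    if separable:
        mtec = np.where(labels == 1, rng.uniform(0, 1, n), rng.uniform(10, 100, n))
        dc = rng.uniform(0, 50, n)
    else:
        base = rng.normal(1.2, 0.6, size=(n, 2))
        base[labels == 1] -= effect
        mtec, dc = (10 ** base[:, 0]) - 1, (10 ** base[:, 1]) - 1
        mtec = np.clip(mtec, 0, None)
        dc = np.clip(dc, 0, None)
    df = pd.DataFrame(
        {"mTEC": mtec, "DC": dc}, index=[f"pep{i}" for i in range(n)]
    )
    return df, labels
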