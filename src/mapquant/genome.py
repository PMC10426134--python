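"""Reference genome, gene/repeat annotation, and SNV catalog containers.

All coordinates inside the package are 0-based half-open.  The parsers at the
boundary convert from the native conventions of each format: GTF is 1-based
closed (pyranges performs the shift on load), VCF positions are 1-based
(shifted here), BED is already 0-based half-open and passes through.

Soft-masked (lowercase) reference bases are folded to uppercase on load so
that repeat-derived peptide coding sequences remain findable; ``N`` is kept
verbatim and never matches a query base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pysam
from intervaltree import IntervalTree
from pyfaidx import Fasta

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


class ReferenceGenome:
    """In-memory uppercase reference sequences keyed by chromosome name."""

    def __init__(self, sequences: dict[str, str]):
        self.sequences = sequences
        self.lengths = {name: len(s) for name, s in sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return the half-open slice [start, end) of one chromosome."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if start < 0 or end > self.lengths[chrom] or start > end:
            raise ValueError(
                f"interval {chrom}:{start}-{end} outside chromosome "
                f"(length {self.lengths[chrom]})"
            )
        return self.sequences[chrom][start:end]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences


def load_genome(path_fasta: str) -> ReferenceGenome:
    """Load a FASTA reference, uppercasing soft-masked bases.

    Duplicate chromosome names are a fatal error (pyfaidx raises with the
    offending name), as is a missing file.
    """
    fa = Fasta(path_fasta, as_raw=True, sequence_always_upper=True)
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    if not sequences:
        raise ValueError(f"no sequences in {path_fasta}")
    return ReferenceGenome(sequences)


@dataclass
class TranscriptModel:
    """One transcript: ordered exons, optional CDS with frame offsets."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int, int]] = field(default_factory=list)  # (start, end, frame)
    transcript_biotype: str = ""

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons."""
        return [
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        ]

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    def utrs(self) -> list[tuple[int, int, str]]:
        """Exonic spans outside the CDS, labelled 5'/3' by strand."""
        if not self.cds:
            return []
        cds_start = min(s for s, _, _ in self.cds)
        cds_end = max(e for _, e, _ in self.cds)
        out = []
        for s, e in self.exons:
            if s < cds_start:
                left = (s, min(e, cds_start))
                out.append(left + (("5UTR" if self.strand == "+" else "3UTR"),))
            if e > cds_end:
                right = (max(s, cds_end), e)
                out.append(right + (("3UTR" if self.strand == "+" else "5UTR"),))
        return out

    def cds_sequence(self, genome: ReferenceGenome) -> str:
        """Spliced CDS in transcription order (reverse-complemented on -)."""
        parts = [genome.fetch(self.chrom, s, e) for s, e, _ in self.cds]
        seq = "".join(parts)
        return reverse_complement(seq) if self.strand == "-" else seq


@dataclass(frozen=True)
class EREElement:
    """A RepeatMasker-style endogenous retroelement annotation."""

    chrom: str
    start: int
    end: int
    strand: str
    repeat_name: str
    repeat_class: str
    repeat_family: str


@dataclass(frozen=True)
class Feature:
    """One interval dropped into the annotation index."""

    kind: str  # exon | CDS | intron | 5UTR | 3UTR | ERE
    chrom: str
    start: int
    end: int
    strand: str
    transcript: TranscriptModel | None = None
    ere: EREElement | None = None
    frame: int | None = None  # CDS only

    def __hash__(self):
        return hash((self.kind, self.chrom, self.start, self.end, self.strand, id(self.transcript), self.ere))


class AnnotationIndex:
    """Per-chromosome interval lookup over transcript features and EREs."""

    def __init__(self, transcripts: list[TranscriptModel], eres: list[EREElement]):
        self.transcripts = transcripts
        self.eres = eres
        self.features: list[Feature] = []
        for tr in transcripts:
            for s, e in tr.exons:
                self.features.append(Feature("exon", tr.chrom, s, e, tr.strand, transcript=tr))
            for s, e, fr in tr.cds:
                self.features.append(Feature("CDS", tr.chrom, s, e, tr.strand, transcript=tr, frame=fr))
            for s, e in tr.introns:
                self.features.append(Feature("intron", tr.chrom, s, e, tr.strand, transcript=tr))
            for s, e, label in tr.utrs():
                if e > s:
                    self.features.append(Feature(label, tr.chrom, s, e, tr.strand, transcript=tr))
        for ere in eres:
            self.features.append(
                Feature("ERE", ere.chrom, ere.start, ere.end, ere.strand, ere=ere)
            )
        self._trees: dict[str, IntervalTree] = {}
        for f in self.features:
            if f.end > f.start:
                self._trees.setdefault(f.chrom, IntervalTree()).addi(f.start, f.end, f)

    def query(self, chrom: str, start: int, end: int) -> list[Feature]:
        """All features whose interval intersects [start, end)."""
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end)]
        hits.sort(key=lambda f: (f.start, f.end, f.kind))
        return hits


def _parse_gtf_transcripts(path_gtf: str) -> list[TranscriptModel]:
    import pyranges

    with open(path_gtf) as fh:
        has_records = any(line.strip() and not line.startswith("#") for line in fh)
    if not has_records:
        return []
    df = pyranges.read_gtf(path_gtf).df
    required = {"Feature", "Chromosome", "Start", "End", "Strand"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GTF missing columns {missing}")
    skipped = 0
    by_tid: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        feat = row.Feature
        if feat not in ("exon", "CDS"):
            continue
        tid = getattr(row, "transcript_id", None)
        gid = getattr(row, "gene_id", None)
        if not isinstance(tid, str) or not isinstance(gid, str):
            skipped += 1
            continue
        entry = by_tid.setdefault(
            tid,
            {
                "gene_id": gid,
                "gene_name": getattr(row, "gene_name", "") if isinstance(getattr(row, "gene_name", ""), str) else "",
                "chrom": row.Chromosome,
                "strand": row.Strand,
                "biotype": "",
                "exons": [],
                "cds": [],
            },
        )
        bt = getattr(row, "transcript_type", None) or getattr(row, "transcript_biotype", None) or getattr(row, "gene_type", None)
        if isinstance(bt, str) and bt:
            entry["biotype"] = bt
        # pyranges has already shifted Start to 0-based
        if feat == "exon":
            entry["exons"].append((int(row.Start), int(row.End)))
        else:
            frame = row.Frame
            frame = int(frame) if str(frame) in {"0", "1", "2"} else 0
            entry["cds"].append((int(row.Start), int(row.End), frame))
    if skipped:
        log.warning("skipped %d GTF records without transcript_id/gene_id", skipped)
    transcripts = []
    for tid, entry in by_tid.items():
        exons = sorted(entry["exons"])
        cds = sorted(entry["cds"])
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=entry["gene_id"],
                gene_name=entry["gene_name"],
                chrom=entry["chrom"],
                strand=entry["strand"],
                exons=exons,
                cds=cds,
                transcript_biotype=entry["biotype"],
            )
        )
    return transcripts


def _parse_ere_bed(path_bed: str) -> list[EREElement]:
    eres = []
    with open(path_bed) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                fields = line.split()
            chrom, start, end, name, _score, strand = fields[:6]
            repeat_class = fields[6] if len(fields) > 6 else "Unknown"
            repeat_family = fields[7] if len(fields) > 7 else "Unknown"
            eres.append(
                EREElement(chrom, int(start), int(end), strand, name, repeat_class, repeat_family)
            )
    return eres


def load_annotations(path_gtf: str, path_ere_bed: str | None = None) -> AnnotationIndex:
    """Build the interval index from a GENCODE-dialect GTF and an ERE BED6+2."""
    transcripts = _parse_gtf_transcripts(path_gtf)
    eres = _parse_ere_bed(path_ere_bed) if path_ere_bed else []
    return AnnotationIndex(transcripts, eres)


class SNVCatalog:
    """Known single-nucleotide variants: (chrom, 0-based pos) -> ref, alt set."""

    def __init__(self, entries: dict[tuple[str, int], tuple[str, frozenset[str]]]):
        self._entries = entries

    def get(self, chrom: str, pos: int) -> tuple[str, frozenset[str]] | None:
        return self._entries.get((chrom, pos))

    def licenses(self, chrom: str, pos: int, base: str) -> bool:
        """True if `base` is a catalogued alternate allele at this position."""
        entry = self._entries.get((chrom, pos))
        return entry is not None and base in entry[1]

    def __len__(self) -> int:
        return len(self._entries)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._entries

    def items(self):
        return self._entries.items()


_BASES = frozenset("ACGT")


def load_snvs(path_vcf: str, region_filter=None) -> SNVCatalog:
    """Load single-nucleotide variants from a VCF; indels/MNVs are skipped.

    Multiallelic records keep every single-base alternate.  VCF positions are
    1-based and converted to 0-based here.
    """
    entries: dict[tuple[str, int], tuple[str, frozenset[str]]] = {}
    skipped = 0
    with pysam.VariantFile(path_vcf) as vf:
        for rec in vf:
            ref = rec.ref
            if ref is None or len(ref) != 1 or ref not in _BASES:
                skipped += 1
                continue
            alts = frozenset(
                a for a in (rec.alts or ()) if len(a) == 1 and a in _BASES
            )
            if not alts:
                skipped += 1
                continue
            pos0 = rec.pos - 1
            if region_filter is not None and not region_filter(rec.chrom, pos0):
                continue
            key = (rec.chrom, pos0)
            if key in entries:
                alts = alts | entries[key][1]
            entries[key] = (ref, alts)
    if skipped:
        log.info("skipped %d non-SNV VCF records", skipped)
    return SNVCatalog(entries)
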