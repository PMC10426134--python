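"""Per-sample read counting over MCS genomic locations, and normalization.

Only primary alignment records (SAM flag 0x100 unset) are considered, so
each record corresponds one-to-one to a sequenced read.  A read is counted
for a location iff its aligned bases cover every genomic position of every
block, occupy consecutive read bases (no indel, clip, or unannotated skip
inside the span), and equal the location's expected plus-strand sequence at
every position (reference base, or a licensed SNV alternate).

In stranded libraries reads are first filtered by the eight-way table of
(layout, chemistry, location strand) SAM-flag requirements; unstranded
libraries take every primary read, which is exactly the union of the two
stranded selections.

Normalization: RPHM = tr_MAP / R_t * 1e8, where tr_MAP is the summed count
over all of a peptide's locations and R_t the sample's total primary read
count; values are log-transformed as log10(RPHM + 1) for averaging across
samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pysam

from .locate import GenomicLocation

FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400

# (layout, chemistry, location strand) -> required flag bits for R1 / R2.
# None means "bit 0x10 must be unset" handled separately for single-end.
_PAIRED_REQUIRED = {
    ("forward", "-"): (0x50, 0xA0),  # R1 read1+reverse, R2 read2+mate-reverse
    ("forward", "+"): (0x60, 0x90),  # R1 read1+mate-reverse, R2 read2+reverse
    ("reverse", "-"): (0x60, 0x90),
    ("reverse", "+"): (0x50, 0xA0),
}


@dataclass(frozen=True)
class LibraryConfig:
    layout: str = "paired_end"  # single_end | paired_end
    chemistry: str = "forward"  # forward | reverse; ignored when unstranded
    strandedness: str = "stranded"  # stranded | unstranded

    def __post_init__(self):
        if self.layout not in ("single_end", "paired_end"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.chemistry not in ("forward", "reverse"):
            raise ValueError(f"unknown chemistry {self.chemistry!r}")
        if self.strandedness not in ("stranded", "unstranded"):
            raise ValueError(f"unknown strandedness {self.strandedness!r}")


def read_passes_strand_filter(flag: int, config: LibraryConfig, location_strand: str) -> bool:
    """Apply the stranded selection table to one SAM flag value."""
    if config.strandedness == "unstranded":
        return True
    if config.layout == "single_end":
        # forward chemistry: read orientation equals transcription strand;
        # reverse chemistry: opposite.
        want_reverse = (config.chemistry == "forward") == (location_strand == "-")
        return bool(flag & 0x10) == want_reverse
    # union of the two required-bit queries, one per mate rank
    r1_bits, r2_bits = _PAIRED_REQUIRED[(config.chemistry, location_strand)]
    return flag & r1_bits == r1_bits or flag & r2_bits == r2_bits


@dataclass
class SampleHandle:
    """One indexed BAM/CRAM plus its library configuration."""

    name: str
    path: str
    config: LibraryConfig = field(default_factory=LibraryConfig)
    _total_primary: int | None = None

    def open(self) -> pysam.AlignmentFile:
        return pysam.AlignmentFile(self.path)

    @property
    def total_primary_reads(self) -> int:
        if self._total_primary is None:
            self._total_primary = total_primary_reads(self.path)
        return self._total_primary


def total_primary_reads(path: str) -> int:
    """Count alignment records without the secondary flag, whole file.

    Supplementary (0x800) and duplicate (0x400) records are included, since
    they are present in the original fastq; an empty file is an error (a
    zero denominator makes RPHM undefined).
    """
    n = 0
    with pysam.AlignmentFile(path) as af:
        for read in af.fetch(until_eof=True):
            if not read.flag & FLAG_SECONDARY:
                n += 1
    if n == 0:
        raise ValueError(f"{path}: no primary reads (R_t = 0 is invalid)")
    return n


def select_reads(
    alignment_file: pysam.AlignmentFile,
    location: GenomicLocation,
    config: LibraryConfig,
    count_duplicates: bool = True,
):
    """Primary reads overlapping the location, strand-filtered if stranded."""
    seen = set()
    for s, e in location.blocks:
        for read in alignment_file.fetch(location.chrom, s, e):
            if read.flag & FLAG_SECONDARY:
                continue
            if not count_duplicates and read.flag & FLAG_DUPLICATE:
                continue
            if not read_passes_strand_filter(read.flag, config, location.strand):
                continue
            key = (read.query_name, read.flag, read.reference_start)
            if key in seen:
                continue
            seen.add(key)
            yield read


def read_spans_location(read: pysam.AlignedSegment, location: GenomicLocation) -> bool:
    """Exact-span rule for one alignment record.

    The MCS must occupy consecutive read bases covering every block position
    with the expected base at each; indels, clips, or skips inside the span
    disqualify the read.
    """
    seq = read.query_sequence
    if seq is None:
        return False
    refmap: dict[int, int] = {}
    for qpos, rpos in read.get_aligned_pairs(matches_only=True):
        refmap[rpos] = qpos
    qprev = None
    expected = location.expected_forward
    i = 0
    for s, e in location.blocks:
        for p in range(s, e):
            qpos = refmap.get(p)
            if qpos is None:
                return False
            if qprev is not None and qpos != qprev + 1:
                return False
            if seq[qpos] != expected[i]:
                return False
            qprev = qpos
            i += 1
    return True


def count_mcs_reads(
    alignment_file: pysam.AlignmentFile,
    location: GenomicLocation,
    config: LibraryConfig,
    count_duplicates: bool = True,
    fragments: bool = False,
) -> int:
    """Number of reads exactly spanning the MCS at one location.

    With `fragments`, both mates of a pair spanning the MCS count once
    (collapsed by read name) instead of twice.
    """
    names = set()
    n = 0
    for read in select_reads(alignment_file, location, config, count_duplicates):
        if not read_spans_location(read, location):
            continue
        if fragments:
            names.add(read.query_name)
        else:
            n += 1
    return len(names) if fragments else n


def count_by_barcode(
    alignment_file: pysam.AlignmentFile,
    location: GenomicLocation,
    config: LibraryConfig,
    tag: str = "CB",
) -> dict[str, int]:
    """Single-cell mode: spanning-read counts split by cell barcode tag."""
    counts: dict[str, int] = {}
    for read in select_reads(alignment_file, location, config):
        if not read_spans_location(read, location):
            continue
        try:
            barcode = read.get_tag(tag)
        except KeyError:
            barcode = "-"
        counts[barcode] = counts.get(barcode, 0) + 1
    return counts


def total_count(per_location_counts: dict[GenomicLocation, int]) -> int:
    """tr_MAP: sum over a peptide's unique locations in one sample.

    Locations with identical block sets are counted once.
    """
    seen = set()
    tr = 0
    for loc, c in per_location_counts.items():
        key = loc.key() if hasattr(loc, "key") else loc
        if key in seen:
            continue
        seen.add(key)
        tr += c
    return tr


def rphm(tr_map: int, r_t: int) -> float:
    """Reads per hundred million: tr_MAP / R_t * 1e8."""
    if r_t <= 0:
        raise ValueError(f"total primary reads must be positive, got {r_t}")
    return tr_map / r_t * 1e8


def log_rphm(rphm_value: float) -> float:
    """log10(RPHM + 1); zero expression maps to zero."""
    return math.log10(rphm_value + 1.0)


@dataclass
class ExpressionRecord:
    """Per-(peptide, sample) counts and normalized expression."""

    peptide: str
    sample: str
    tr_map: int
    per_location: dict = field(default_factory=dict)  # location key -> count
    rphm: float = 0.0
    log_rphm: float = 0.0
    has_location: bool = True

    @classmethod
    def from_counts(cls, peptide, sample, per_location_counts, r_t, has_location=True):
        tr = total_count(per_location_counts)
        value = rphm(tr, r_t)
        return cls(
            peptide=peptide,
            sample=sample,
            tr_map=tr,
            per_location={str(loc): c for loc, c in per_location_counts.items()},
            rphm=value,
            log_rphm=log_rphm(value),
            has_location=has_location,
        )


def quantify(
    sample: SampleHandle,
    locations_by_peptide: dict[str, list[GenomicLocation]],
    count_duplicates: bool = True,
    fragments: bool = False,
) -> tuple[list[ExpressionRecord], dict[str, dict[GenomicLocation, int]]]:
    """Count every peptide's locations in one sample and normalize."""
    r_t = sample.total_primary_reads
    records = []
    details: dict[str, dict[GenomicLocation, int]] = {}
    with sample.open() as af:
        for peptide in sorted(locations_by_peptide):
            locs = locations_by_peptide[peptide]
            counts = {
                loc: count_mcs_reads(af, loc, sample.config, count_duplicates, fragments)
                for loc in locs
            }
            details[peptide] = counts
            records.append(
                ExpressionRecord.from_counts(
                    peptide, sample.name, counts, r_t, has_location=bool(locs)
                )
            )
    return records, details
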