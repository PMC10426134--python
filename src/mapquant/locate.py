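"""SNV-aware exhaustive localization of MAP-coding sequences.

A placement is kept only when every base of the query either equals the
reference or is a catalogued single-nucleotide-variant alternate allele at
that exact position (the "perfect alignment" rule).  Both strands are
searched; spliced placements are restricted to annotated exon-exon junctions.

The search is seed-and-verify over a hash index of fixed-length reference
seeds.  Candidate starts are generated from every sliding seed of the query,
so by pigeonhole any placement with at most floor(|MCS| / seed_length) - 1
licensed mismatches is guaranteed to be found; with the default seed length
of 12 that covers all single-mismatch placements of 24-33 nt queries, and
placements with more mismatches are found whenever one clean seed-length
window survives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genome import AnnotationIndex, ReferenceGenome, SNVCatalog, reverse_complement

log = logging.getLogger(__name__)

DEFAULT_SEED_LENGTH = 12
DEFAULT_MAX_MISMATCH = 3

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i


@dataclass(frozen=True)
class GenomicLocation:
    """A stranded, possibly multi-block placement of one MCS.

    `blocks` are 0-based half-open intervals in ascending genomic order whose
    lengths sum to the MCS length.  `expected_forward` is the plus-strand
    sequence a perfectly matching read must exhibit over the blocks (for a
    minus-strand placement this is the reverse complement of the MCS);
    mismatches versus the reference are listed in `snv_support` as
    (genomic position, alternate allele).
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    mcs: str
    expected_forward: str
    snv_support: tuple[tuple[int, str], ...] = ()

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def spliced(self) -> bool:
        return len(self.blocks) > 1

    @property
    def span_positions(self) -> list[int]:
        return [p for s, e in self.blocks for p in range(s, e)]

    def key(self) -> tuple:
        return (self.chrom, self.blocks, self.strand)

    def __str__(self) -> str:
        blocks = ",".join(f"{s}-{e}" for s, e in self.blocks)
        return f"{self.chrom}:{blocks}:{self.strand}"


class LocationRejected(ValueError):
    """A stated (manual-mode) location failed the perfect-alignment rule."""


class SeedIndex:
    """Hash index from seed_length-mers to their plus-strand occurrences."""

    def __init__(self, seed_length: int):
        if seed_length < 8:
            raise ValueError(f"seed length {seed_length} < 8 is unusable")
        if seed_length < 12:
            log.warning("seed length %d < 12: large candidate lists likely", seed_length)
        if seed_length > 24:
            raise ValueError("seed length must not exceed the shortest MCS (24)")
        self.seed_length = seed_length
        self._buckets: dict[int, list[tuple[str, np.ndarray]]] = {}

    def _add_chrom(self, chrom: str, seq: str) -> None:
        L = self.seed_length
        n = len(seq)
        if n < L:
            return
        vals = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
        bad = (vals == 255).astype(np.int64)
        vals = np.where(vals == 255, 0, vals).astype(np.uint64)
        powers = (4 ** np.arange(L - 1, -1, -1, dtype=np.uint64))
        windows = np.lib.stride_tricks.sliding_window_view(vals, L)
        hashes = windows @ powers
        bad_in_window = np.convolve(bad, np.ones(L, dtype=np.int64), mode="valid")
        valid = bad_in_window == 0
        positions = np.nonzero(valid)[0]
        h = hashes[positions]
        order = np.argsort(h, kind="stable")
        h_sorted = h[order]
        pos_sorted = positions[order]
        uniq, starts = np.unique(h_sorted, return_index=True)
        bounds = np.append(starts, len(h_sorted))
        for i, hv in enumerate(uniq):
            self._buckets.setdefault(int(hv), []).append(
                (chrom, pos_sorted[bounds[i]:bounds[i + 1]])
            )

    def hash_seed(self, seed: str) -> int | None:
        h = 0
        for c in seed:
            v = _ENCODE[ord(c)]
            if v == 255:
                return None
            h = h * 4 + int(v)
        return h

    def lookup(self, seed: str) -> list[tuple[str, np.ndarray]]:
        h = self.hash_seed(seed)
        if h is None:
            return []
        return self._buckets.get(h, [])


def build_index(genome: ReferenceGenome, seed_length: int = DEFAULT_SEED_LENGTH) -> SeedIndex:
    """Index every ACGT seed of the reference (plus strand only)."""
    index = SeedIndex(seed_length)
    for chrom, seq in genome.sequences.items():
        index._add_chrom(chrom, seq)
    return index


def _verify(
    q: str,
    chrom: str,
    start: int,
    genome: ReferenceGenome,
    snv_catalog: SNVCatalog | None,
    max_mismatch: int,
) -> tuple[tuple[int, str], ...] | None:
    """SNV-licensed comparison of query q against the + reference at start.

    Returns the snv support tuple on success, None on rejection.
    """
    n = len(q)
    if start < 0 or start + n > genome.lengths[chrom]:
        return None
    ref = genome.sequences[chrom][start:start + n]
    support = []
    for i in range(n):
        if ref[i] == q[i]:
            continue
        if ref[i] == "N":
            return None
        if snv_catalog is None or not snv_catalog.licenses(chrom, start + i, q[i]):
            return None
        support.append((start + i, q[i]))
        if len(support) > max_mismatch:
            return None
    return tuple(support)


def locate(
    mcs: str,
    genome: ReferenceGenome,
    index: SeedIndex,
    snv_catalog: SNVCatalog | None = None,
    max_mismatch_positions: int = DEFAULT_MAX_MISMATCH,
) -> list[GenomicLocation]:
    """All contiguous perfect placements of one MCS, both strands.

    Deterministic order: (chrom, start, strand).  No hits returns an empty
    list, which callers report distinctly from "located but unexpressed".
    """
    L = index.seed_length
    n = len(mcs)
    out: dict[tuple, GenomicLocation] = {}
    for strand, q in (("+", mcs), ("-", reverse_complement(mcs))):
        candidates: set[tuple[str, int]] = set()
        for off in range(n - L + 1):
            for chrom, positions in index.lookup(q[off:off + L]):
                for pos in positions.tolist():
                    candidates.add((chrom, pos - off))
        for chrom, start in candidates:
            support = _verify(q, chrom, start, genome, snv_catalog, max_mismatch_positions)
            if support is None:
                continue
            loc = GenomicLocation(
                chrom=chrom,
                strand=strand,
                blocks=((start, start + n),),
                mcs=mcs,
                expected_forward=q,
                snv_support=support,
            )
            out.setdefault(loc.key(), loc)
    return sorted(out.values(), key=lambda l: (l.chrom, l.start, l.strand, l.blocks))


def locate_spliced(
    mcs: str,
    genome: ReferenceGenome,
    annotation_index: AnnotationIndex,
    snv_catalog: SNVCatalog | None = None,
    max_mismatch_positions: int = DEFAULT_MAX_MISMATCH,
) -> list[GenomicLocation]:
    """Placements spanning annotated exon-exon junctions.

    Each multi-exon transcript's exons are concatenated (plus-strand genomic
    order) and scanned at every offset with the same SNV-licensing rule;
    matches falling entirely within one exon are contiguous placements and
    are left to `locate` (deduplication contract).
    """
    n = len(mcs)
    out: dict[tuple, GenomicLocation] = {}
    for tr in annotation_index.transcripts:
        if len(tr.exons) < 2 or tr.chrom not in genome:
            continue
        posmap: list[int] = [p for s, e in tr.exons for p in range(s, e)]
        cseq = "".join(genome.sequences[tr.chrom][s:e] for s, e in tr.exons)
        if len(cseq) < n:
            continue
        for strand, q in (("+", mcs), ("-", reverse_complement(mcs))):
            for off in range(len(cseq) - n + 1):
                support = []
                ok = True
                for i in range(n):
                    r = cseq[off + i]
                    if r == q[i]:
                        continue
                    gpos = posmap[off + i]
                    if r == "N" or snv_catalog is None or not snv_catalog.licenses(tr.chrom, gpos, q[i]):
                        ok = False
                        break
                    support.append((gpos, q[i]))
                    if len(support) > max_mismatch_positions:
                        ok = False
                        break
                if not ok:
                    continue
                span = posmap[off:off + n]
                blocks = _runs(span)
                if len(blocks) < 2:
                    continue  # contiguous: locate()'s job
                loc = GenomicLocation(
                    chrom=tr.chrom,
                    strand=strand,
                    blocks=blocks,
                    mcs=mcs,
                    expected_forward=q,
                    snv_support=tuple(sorted(support)),
                )
                out.setdefault(loc.key(), loc)
    return sorted(out.values(), key=lambda l: (l.chrom, l.start, l.strand, l.blocks))


def _runs(positions: list[int]) -> tuple[tuple[int, int], ...]:
    """Maximal runs of consecutive integers as half-open intervals."""
    blocks = []
    run_start = positions[0]
    prev = positions[0]
    for p in positions[1:]:
        if p != prev + 1:
            blocks.append((run_start, prev + 1))
            run_start = p
        prev = p
    blocks.append((run_start, prev + 1))
    return tuple(blocks)


def locate_all(
    mcs: str,
    genome: ReferenceGenome,
    index: SeedIndex,
    snv_catalog: SNVCatalog | None = None,
    annotation_index: AnnotationIndex | None = None,
    max_mismatch_positions: int = DEFAULT_MAX_MISMATCH,
) -> list[GenomicLocation]:
    """Contiguous plus (optionally) annotated-junction spliced placements."""
    locs = locate(mcs, genome, index, snv_catalog, max_mismatch_positions)
    if annotation_index is not None:
        locs += locate_spliced(mcs, genome, annotation_index, snv_catalog, max_mismatch_positions)
    return sorted(locs, key=lambda l: (l.chrom, l.start, l.strand, l.blocks))


def resolve_manual(
    query,
    genome: ReferenceGenome,
    snv_catalog: SNVCatalog | None = None,
    max_mismatch_positions: int = DEFAULT_MAX_MISMATCH,
) -> GenomicLocation:
    """Verify a manual-mode query's MCS at its stated location and strand."""
    chrom, start, strand = query.given_location
    mcs = query.given_mcs
    n = len(mcs)
    if chrom not in genome:
        raise LocationRejected(f"{query.name}: unknown chromosome {chrom!r}")
    if start < 0 or start + n > genome.lengths[chrom]:
        raise LocationRejected(
            f"{query.name}: {chrom}:{start}-{start + n} out of bounds "
            f"(length {genome.lengths[chrom]})"
        )
    q = mcs if strand == "+" else reverse_complement(mcs)
    support = _verify(q, chrom, start, genome, snv_catalog, max_mismatch_positions)
    if support is None:
        ref = genome.fetch(chrom, start, start + n)
        diffs = [i for i in range(n) if ref[i] != q[i]]
        raise LocationRejected(
            f"{query.name}: MCS disagrees with reference at {chrom}:{start} ({strand}) "
            f"at offsets {diffs} without SNV support"
        )
    return GenomicLocation(
        chrom=chrom, strand=strand, blocks=((start, start + n),),
        mcs=mcs, expected_forward=q, snv_support=support,
    )


def to_bed12(locations: list[GenomicLocation], names: list[str] | None = None) -> str:
    """BED12 text, one line per location (blocks as BED blocks)."""
    lines = []
    for i, loc in enumerate(locations):
        name = names[i] if names else loc.mcs
        sizes = ",".join(str(e - s) for s, e in loc.blocks)
        starts = ",".join(str(s - loc.start) for s, e in loc.blocks)
        lines.append(
            "\t".join(
                [
                    loc.chrom, str(loc.start), str(loc.end), name, "0", loc.strand,
                    str(loc.start), str(loc.end), "0", str(len(loc.blocks)), sizes, starts,
                ]
            )
        )
    return "\n".join(lines) + ("\n" if lines else "")
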