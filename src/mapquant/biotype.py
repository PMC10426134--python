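"""Biotype attribution: overlap annotation, EM apportionment, best guess.

Each expressed genomic location of a peptide is intersected with the loaded
annotations; overlapping feature kinds map to biotype classes (in-frame or
out-of-frame coding exon, UTRs, non-coding/pseudogene exon, intron,
exon-intron junction, ERE classes by repeat class, intergenic when nothing
overlaps).  Because many locations carry several classes, reads are
apportioned by an expectation-maximization fit of per-class coefficients
over the whole queried peptide set:

  E-step:  Z_i(j) = sum_k r_k * phi_j / sum_{b in B_k} phi_b / R_i
  M-step:  phi_j <- mean over peptides of Z_i(j)

with every coefficient initialized to 0.1 and iteration until the vector is
unchanged (max absolute change < tol).  Per-location class shares are then
phi_j / sum_{b in B_k} phi_b, and peptide-level percentages distribute each
location's reads by those shares, normalized by the total read count in the
chosen sample scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import AnnotationIndex, Feature, TranscriptModel
from .locate import GenomicLocation

DEFAULT_TAXONOMY = (
    "in_frame",
    "out_of_frame_exon",
    "5UTR",
    "3UTR",
    "non_coding_exon",
    "pseudogene_exon",
    "intron",
    "ERE_LINE",
    "ERE_SINE",
    "ERE_LTR",
    "ERE_other",
    "exon_intron_junction",
    "intergenic",
)

IN_FRAME = "in_frame"
INTERGENIC = "intergenic"

EM_TOL = 1e-8
EM_MAX_ITER = 10_000
EM_INIT = 0.1


def frame_status(location: GenomicLocation, transcript: TranscriptModel) -> str:
    """in_frame / out_of_frame / not_applicable for one transcript.

    In frame requires: the transcript has a CDS on the location's strand,
    every block position falls in the CDS, the blocks are splice-consistent
    with the transcript (consecutive in spliced-CDS coordinates), and the
    first base sits on a codon boundary in transcription order.
    """
    if not transcript.cds:
        return "not_applicable"
    if transcript.strand != location.strand:
        return "out_of_frame"
    cds_positions = [p for s, e, _ in sorted(transcript.cds) for p in range(s, e)]
    if transcript.strand == "-":
        cds_positions = cds_positions[::-1]
    cds_index = {p: i for i, p in enumerate(cds_positions)}
    loc_positions = location.span_positions
    if transcript.strand == "-":
        loc_positions = loc_positions[::-1]
    indices = []
    for p in loc_positions:
        i = cds_index.get(p)
        if i is None:
            return "out_of_frame"
        indices.append(i)
    for a, b in zip(indices, indices[1:]):
        if b != a + 1:
            return "out_of_frame"
    return IN_FRAME if indices[0] % 3 == 0 else "out_of_frame"


def ere_class(repeat_class: str) -> str:
    head = repeat_class.split("/")[0].upper()
    if head in ("LINE", "SINE", "LTR"):
        return f"ERE_{head}"
    return "ERE_other"


@dataclass
class LocationBiotypes:
    """Overlap classes for one location, with per-class shares after EM."""

    location: GenomicLocation
    overlaps: dict[str, int]  # class -> overlap bp
    shares: dict[str, float] = field(default_factory=dict)
    in_frame: bool = False

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.overlaps)


def _overlap_bp(location: GenomicLocation, start: int, end: int) -> int:
    return sum(max(0, min(e, end) - max(s, start)) for s, e in location.blocks)


def overlap_biotypes(
    location: GenomicLocation,
    annotation_index: AnnotationIndex,
    strict_strand: bool = False,
) -> LocationBiotypes:
    """Classify one location by the features its blocks intersect.

    By default features are matched regardless of strand; `strict_strand`
    keeps only same-strand features.  A location overlapping both exonic and
    intronic parts of the same transcript contributes exon_intron_junction.
    """
    feats: list[Feature] = []
    for s, e in location.blocks:
        feats.extend(annotation_index.query(location.chrom, s, e))
    feats = list({id(f): f for f in feats}.values())
    if strict_strand:
        feats = [f for f in feats if f.strand == location.strand]

    overlaps: dict[str, int] = {}
    any_in_frame = False
    by_tr: dict[str, list[Feature]] = {}
    for f in feats:
        if f.transcript is not None:
            by_tr.setdefault(f.transcript.transcript_id, []).append(f)
        elif f.ere is not None:
            bp = _overlap_bp(location, f.start, f.end)
            cls = ere_class(f.ere.repeat_class)
            overlaps[cls] = overlaps.get(cls, 0) + bp

    for tid, tfeats in by_tr.items():
        tr = tfeats[0].transcript
        # exon blocks of one transcript are disjoint, so per-kind overlaps sum
        exonic = [f for f in tfeats if f.kind == "exon"]
        intronic = [f for f in tfeats if f.kind == "intron"]
        exonic_bp = sum(_overlap_bp(location, f.start, f.end) for f in exonic)
        intronic_bp = sum(_overlap_bp(location, f.start, f.end) for f in intronic)
        if exonic_bp and intronic_bp:
            cls = "exon_intron_junction"
            overlaps[cls] = max(overlaps.get(cls, 0), exonic_bp + intronic_bp)
            continue
        if intronic_bp:
            overlaps["intron"] = max(overlaps.get("intron", 0), intronic_bp)
            continue
        if not exonic_bp:
            continue
        if tr.cds:
            status = frame_status(location, tr)
            cds_bp = sum(
                _overlap_bp(location, f.start, f.end) for f in tfeats if f.kind == "CDS"
            )
            utr5_bp = sum(
                _overlap_bp(location, f.start, f.end) for f in tfeats if f.kind == "5UTR"
            )
            utr3_bp = sum(
                _overlap_bp(location, f.start, f.end) for f in tfeats if f.kind == "3UTR"
            )
            if cds_bp:
                if status == IN_FRAME:
                    any_in_frame = True
                    overlaps[IN_FRAME] = max(overlaps.get(IN_FRAME, 0), cds_bp)
                else:
                    overlaps["out_of_frame_exon"] = max(
                        overlaps.get("out_of_frame_exon", 0), cds_bp
                    )
            if utr5_bp:
                overlaps["5UTR"] = max(overlaps.get("5UTR", 0), utr5_bp)
            if utr3_bp:
                overlaps["3UTR"] = max(overlaps.get("3UTR", 0), utr3_bp)
        else:
            cls = (
                "pseudogene_exon"
                if "pseudogene" in (tr.transcript_biotype or "")
                else "non_coding_exon"
            )
            overlaps[cls] = max(overlaps.get(cls, 0), exonic_bp)

    if not overlaps:
        total = sum(e - s for s, e in location.blocks)
        overlaps[INTERGENIC] = total
    return LocationBiotypes(location=location, overlaps=overlaps, in_frame=any_in_frame)


@dataclass
class MapReadProfile:
    """EM input for one peptide: reads and classes per location."""

    name: str
    locations: list[tuple[int, frozenset[str]]]  # (reads r_k, classes B_k)

    @property
    def total_reads(self) -> int:
        return sum(r for r, _ in self.locations)


@dataclass
class EMState:
    phi: dict[str, float]
    iterations: int
    converged: bool
    z: dict[str, dict[str, float]]  # peptide -> class -> read share
    pooled: dict[str, float]  # read-weighted average of Z rows


def location_shares(classes: frozenset[str], phi: dict[str, float]) -> dict[str, float]:
    """Normalized per-class coefficients at one location."""
    denom = sum(phi.get(b, 0.0) for b in classes)
    if denom <= 0.0:
        return {b: 1.0 / len(classes) for b in classes}
    return {b: phi.get(b, 0.0) / denom for b in classes}


def _e_step(profile: MapReadProfile, phi: dict[str, float]) -> dict[str, float]:
    z: dict[str, float] = {}
    total = profile.total_reads
    for r_k, classes in profile.locations:
        if r_k == 0:
            continue
        for b, share in location_shares(classes, phi).items():
            z[b] = z.get(b, 0.0) + r_k * share / total
    return z


def em_fit(
    profiles: list[MapReadProfile],
    tol: float = EM_TOL,
    max_iter: int = EM_MAX_ITER,
) -> EMState:
    """Fit per-class read-distribution coefficients over all peptides.

    Peptides without reads are excluded; classes absent from every location
    keep coefficient zero.  Deterministic given the input.
    """
    active = [p for p in profiles if p.total_reads > 0]
    if not active:
        raise ValueError("EM undefined: no peptide has reads")
    classes = sorted({b for p in active for _, cs in p.locations for b in cs})
    phi = {b: EM_INIT for b in classes}
    converged = False
    it = 0
    z_rows: dict[str, dict[str, float]] = {}
    for it in range(1, max_iter + 1):
        z_rows = {p.name: _e_step(p, phi) for p in active}
        new_phi = {
            b: sum(z.get(b, 0.0) for z in z_rows.values()) / len(active) for b in classes
        }
        delta = max(abs(new_phi[b] - phi[b]) for b in classes)
        phi = new_phi
        if delta < tol:
            converged = True
            break
    total_reads = sum(p.total_reads for p in active)
    pooled = {
        b: sum(p.total_reads * z_rows[p.name].get(b, 0.0) for p in active) / total_reads
        for b in classes
    }
    return EMState(phi=phi, iterations=it, converged=converged, z=z_rows, pooled=pooled)


@dataclass
class BiotypeProfile:
    """Per-peptide biotype percentages at the three reporting scopes."""

    peptide: str
    global_pct: dict[str, float] | None
    per_location: dict[str, dict[str, float]]  # location id -> class -> share
    per_cohort: dict[str, dict[str, float] | None] = field(default_factory=dict)
    best_guess: tuple[tuple[str, ...], float] | None = None


def summarize_biotypes(
    peptide: str,
    counts_by_sample: dict[str, dict[str, int]],  # sample -> location id -> reads
    classes_by_location: dict[str, frozenset[str]],
    phi: dict[str, float],
    cohorts: dict[str, list[str]] | None = None,
) -> BiotypeProfile:
    """Percentages per location, globally, and per sample cohort.

    A scope with zero reads has an undefined profile (None), reported as
    such rather than as zeros.
    """
    per_location = {
        loc_id: location_shares(classes, phi)
        for loc_id, classes in classes_by_location.items()
    }

    def scoped(samples: list[str]) -> dict[str, float] | None:
        totals: dict[str, float] = {}
        total_reads = 0
        for sample in samples:
            for loc_id, r in counts_by_sample.get(sample, {}).items():
                if r == 0:
                    continue
                total_reads += r
                for b, share in per_location[loc_id].items():
                    totals[b] = totals.get(b, 0.0) + r * share
        if total_reads == 0:
            return None
        return {b: v / total_reads * 100.0 for b, v in totals.items()}

    all_samples = sorted(counts_by_sample)
    profile = BiotypeProfile(
        peptide=peptide,
        global_pct=scoped(all_samples),
        per_location=per_location,
    )
    if cohorts:
        for name, members in cohorts.items():
            if not members:
                raise ValueError(f"cohort {name!r} is empty")
            profile.per_cohort[name] = scoped(members)
    return profile


def best_guess(
    global_pct: dict[str, float] | None,
    has_in_frame_location: bool,
    tie_tol: float = 1e-9,
) -> tuple[tuple[str, ...], float]:
    """Most likely biotype for one peptide.

    Any in-frame origin anywhere forces in_frame, with certainty equal to
    its percentage.  Otherwise the highest-percentage class wins; exact ties
    are all reported.
    """
    if global_pct is None:
        raise ValueError("best guess undefined without an expression profile")
    if has_in_frame_location:
        return (IN_FRAME,), global_pct.get(IN_FRAME, 0.0)
    top = max(global_pct.values())
    winners = tuple(sorted(b for b, v in global_pct.items() if top - v <= tie_tol))
    return winners, top
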