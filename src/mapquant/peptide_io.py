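"""Peptide-list parsing, run configuration, pipeline orchestration, reports.

The peptide input file is whitespace-separated text, one record per line,
with the mode inferred from the field count:

  2 fields  name peptide                      -> peptide mode
  3 fields  name peptide mcs                  -> MCS mode
  5 fields  name peptide mcs chrom:start-end strand -> manual mode

Mixed files are allowed.  Lines whose MCS does not translate back to the
peptide are rejected with a message; duplicate names are a hard error.
"""

from __future__ import annotations

import json
import logging
import re
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import pandas as pd

from . import biotype as bt
from . import counting as cnt
from . import revtrans as rt
from .genome import load_annotations, load_genome, load_snvs
from .locate import (
    DEFAULT_MAX_MISMATCH,
    DEFAULT_SEED_LENGTH,
    GenomicLocation,
    build_index,
    locate_all,
    resolve_manual,
    to_bed12,
)

log = logging.getLogger(__name__)

_REGION_RE = re.compile(r"^([^:]+):(\d+)-(\d+)$")


def parse_peptides(path: str) -> list[rt.PeptideQuery]:
    queries: list[rt.PeptideQuery] = []
    names = set()
    errors = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                query = _parse_line(fields)
            except (rt.PeptideError, ValueError) as exc:
                errors.append(f"line {lineno}: {exc}")
                continue
            if query.name in names:
                raise ValueError(f"duplicate peptide name {query.name!r} (line {lineno})")
            names.add(query.name)
            queries.append(query)
    for msg in errors:
        log.warning("rejected peptide record: %s", msg)
    if errors and not queries:
        raise ValueError("no valid peptide records; first error: " + errors[0])
    return queries


def _parse_line(fields: list[str]) -> rt.PeptideQuery:
    if len(fields) == 2:
        return rt.PeptideQuery(name=fields[0], sequence=fields[1].upper())
    if len(fields) == 3:
        return rt.PeptideQuery(
            name=fields[0], sequence=fields[1].upper(), mode="mcs",
            given_mcs=fields[2].upper(),
        )
    if len(fields) == 5:
        m = _REGION_RE.match(fields[3])
        if not m:
            raise ValueError(f"bad region {fields[3]!r} (expected chrom:start-end)")
        chrom, start, _end = m.group(1), int(m.group(2)), int(m.group(3))
        strand = fields[4]
        if strand not in "+-":
            raise ValueError(f"bad strand {strand!r}")
        return rt.PeptideQuery(
            name=fields[0], sequence=fields[1].upper(), mode="manual",
            given_mcs=fields[2].upper(), given_location=(chrom, start, strand),
        )
    raise ValueError(f"expected 2, 3 or 5 fields, got {len(fields)}")


@dataclass
class RunConfig:
    genome_fasta: str
    gtf: str = ""
    ere_bed: str = ""
    vcf: str = ""
    peptide_file: str = ""
    samples: list[cnt.SampleHandle] = field(default_factory=list)
    output_dir: str = "."
    seed_length: int = DEFAULT_SEED_LENGTH
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    spliced_search: bool = True
    threads: int = 1
    count_duplicates: bool = True
    fragments: bool = False
    cohorts: dict[str, list[str]] = field(default_factory=dict)
    em_tol: float = bt.EM_TOL
    em_max_iter: int = bt.EM_MAX_ITER
    strict_strand: bool = False


@dataclass
class QueryResult:
    queries: list[rt.PeptideQuery]
    locations: dict[str, list[GenomicLocation]]
    records: list[cnt.ExpressionRecord]
    counts_by_sample: dict[str, dict[str, dict[str, int]]]  # peptide -> sample -> loc id -> n
    profiles: dict[str, bt.BiotypeProfile]
    em_state: bt.EMState | None

    def expression_frame(self, value: str = "rphm") -> pd.DataFrame:
        rows = [
            {"peptide": r.peptide, "sample": r.sample, "value": getattr(r, value)}
            for r in self.records
        ]
        return (
            pd.DataFrame(rows)
            .pivot(index="peptide", columns="sample", values="value")
            .sort_index()
        )


def run(config: RunConfig, queries: list[rt.PeptideQuery] | None = None) -> QueryResult:
    """Full pipeline: expand -> locate -> count -> normalize -> biotype.

    Samples are processed in a deterministic order (ordered reduction), so
    results are independent of the thread count.
    """
    genome = load_genome(config.genome_fasta)
    annotations = load_annotations(config.gtf, config.ere_bed or None) if config.gtf else None
    snvs = load_snvs(config.vcf) if config.vcf else None
    if queries is None:
        queries = parse_peptides(config.peptide_file)
    index = build_index(genome, config.seed_length)

    locations: dict[str, list[GenomicLocation]] = {}
    for q in queries:
        if q.mode == "manual":
            locations[q.name] = [resolve_manual(q, genome, snvs, config.max_mismatch)]
            continue
        found: dict[tuple, GenomicLocation] = {}
        for mcs in rt.expand_query(q):
            for hit in locate_all(
                mcs, genome, index, snvs,
                annotations if config.spliced_search else None,
                config.max_mismatch,
            ):
                found.setdefault(hit.key(), hit)
        locations[q.name] = sorted(
            found.values(), key=lambda l: (l.chrom, l.start, l.strand, l.blocks)
        )
        if not locations[q.name]:
            log.info("no genomic location for %s", q.name)

    def quantify_sample(sample: cnt.SampleHandle):
        return cnt.quantify(sample, locations, config.count_duplicates, config.fragments)

    if config.threads > 1 and len(config.samples) > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            results = list(pool.map(quantify_sample, config.samples))
    else:
        results = [quantify_sample(s) for s in config.samples]

    records: list[cnt.ExpressionRecord] = []
    counts_by_sample: dict[str, dict[str, dict[str, int]]] = {}
    for sample, (recs, details) in zip(config.samples, results):
        records.extend(recs)
        for peptide, per_loc in details.items():
            counts_by_sample.setdefault(peptide, {})[sample.name] = {
                str(l): c for l, c in per_loc.items()
            }

    profiles: dict[str, bt.BiotypeProfile] = {}
    em_state = None
    if annotations is not None and config.samples:
        loc_classes: dict[str, dict[str, frozenset[str]]] = {}
        loc_inframe: dict[str, bool] = {}
        em_inputs = []
        for q in queries:
            classes = {}
            for l in locations[q.name]:
                lb = bt.overlap_biotypes(l, annotations, config.strict_strand)
                classes[str(l)] = lb.classes
                loc_inframe[str(l)] = loc_inframe.get(str(l), False) or lb.in_frame
            loc_classes[q.name] = classes
            pooled: dict[str, int] = {}
            for per_loc in counts_by_sample.get(q.name, {}).values():
                for lid, c in per_loc.items():
                    pooled[lid] = pooled.get(lid, 0) + c
            em_inputs.append(
                bt.MapReadProfile(
                    q.name,
                    [(pooled.get(lid, 0), cls) for lid, cls in classes.items()],
                )
            )
        with_reads = [p for p in em_inputs if p.total_reads > 0]
        if with_reads:
            em_state = bt.em_fit(with_reads, config.em_tol, config.em_max_iter)
            for q in queries:
                if not locations[q.name]:
                    continue
                profile = bt.summarize_biotypes(
                    q.name,
                    counts_by_sample.get(q.name, {}),
                    loc_classes[q.name],
                    em_state.phi,
                    config.cohorts or None,
                )
                if profile.global_pct is not None:
                    has_if = any(
                        loc_inframe.get(lid, False) for lid in loc_classes[q.name]
                    )
                    profile.best_guess = bt.best_guess(profile.global_pct, has_if)
                profiles[q.name] = profile

    return QueryResult(
        queries=queries,
        locations=locations,
        records=records,
        counts_by_sample=counts_by_sample,
        profiles=profiles,
        em_state=em_state,
    )


def write_reports(result: QueryResult, outdir: str) -> dict[str, str]:
    """Write the report bundle; every queried peptide appears in each table."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}

    rows = []
    for r in sorted(result.records, key=lambda r: (r.peptide, r.sample)):
        rows.append(
            {
                "peptide": r.peptide,
                "sample": r.sample,
                "tr_map": r.tr_map,
                "rphm": round(r.rphm, 4),
                "log_rphm": round(r.log_rphm, 4),
                "status": "ok" if r.has_location else "no_location",
            }
        )
    paths["expression"] = os.path.join(outdir, "expression.tsv")
    pd.DataFrame(rows).to_csv(paths["expression"], sep="\t", index=False)

    detail_rows = []
    for peptide in sorted(result.counts_by_sample):
        for sample in sorted(result.counts_by_sample[peptide]):
            for lid, c in sorted(result.counts_by_sample[peptide][sample].items()):
                detail_rows.append(
                    {"peptide": peptide, "sample": sample, "location": lid, "reads": c}
                )
    paths["locations_detail"] = os.path.join(outdir, "per_location.tsv")
    pd.DataFrame(detail_rows).to_csv(paths["locations_detail"], sep="\t", index=False)

    bed_locs, bed_names = [], []
    for name in sorted(result.locations):
        for l in result.locations[name]:
            bed_locs.append(l)
            bed_names.append(name)
    paths["bed"] = os.path.join(outdir, "locations.bed")
    with open(paths["bed"], "w") as fh:
        fh.write(to_bed12(bed_locs, bed_names))

    bio_rows = []
    for name in sorted(n.name for n in result.queries):
        p = result.profiles.get(name)
        if p is None or p.global_pct is None:
            bio_rows.append({"peptide": name, "scope": "global", "biotype": "NA", "percent": ""})
            continue
        for b, v in sorted(p.global_pct.items()):
            bio_rows.append({"peptide": name, "scope": "global", "biotype": b, "percent": round(v, 4)})
        for cohort, pct in p.per_cohort.items():
            for b, v in sorted((pct or {}).items()):
                bio_rows.append({"peptide": name, "scope": cohort, "biotype": b, "percent": round(v, 4)})
        if p.best_guess:
            classes, certainty = p.best_guess
            bio_rows.append(
                {
                    "peptide": name, "scope": "best_guess",
                    "biotype": ";".join(classes), "percent": round(certainty, 4),
                }
            )
    paths["biotypes"] = os.path.join(outdir, "biotypes.tsv")
    pd.DataFrame(bio_rows).to_csv(paths["biotypes"], sep="\t", index=False)

    summary = {
        "peptides": len(result.queries),
        "with_location": sum(1 for q in result.queries if result.locations.get(q.name)),
        "samples": sorted({r.sample for r in result.records}),
        "em_converged": bool(result.em_state.converged) if result.em_state else None,
        "em_iterations": result.em_state.iterations if result.em_state else None,
    }
    paths["summary"] = os.path.join(outdir, "summary.json")
    with open(paths["summary"], "w") as fh:
        json.dump(summary, fh, indent=1)
    return paths
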