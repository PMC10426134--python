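"""Locator correctness against a brute-force sliding-window oracle."""

import numpy as np
import pytest

from mapquant.genome import ReferenceGenome, SNVCatalog, reverse_complement
from mapquant.locate import (
    GenomicLocation,
    LocationRejected,
    SeedIndex,
    build_index,
    locate,
    locate_spliced,
    resolve_manual,
    to_bed12,
)
from mapquant.revtrans import PeptideQuery, reverse_translate


def brute_force_locate(mcs, genome, catalog, max_mismatch=3):
    """Independent oracle: test every offset on both strands with the SNV rule."""
    hits = set()
    for strand, q in (("+", mcs), ("-", reverse_complement(mcs))):
        n = len(q)
        for chrom, seq in genome.sequences.items():
            for start in range(len(seq) - n + 1):
                mismatches = 0
                ok = True
                for i in range(n):
                    r = seq[start + i]
                    if r == q[i]:
                        continue
                    if r == "N" or catalog is None or not catalog.licenses(chrom, start + i, q[i]):
                        ok = False
                        break
                    mismatches += 1
                    if mismatches > max_mismatch:
                        ok = False
                        break
                if ok:
                    hits.add((chrom, start, start + n, strand))
    return hits


def random_genome(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))


class TestSeedIndex:
    def test_every_planted_seed_retrievable(self):
        rng = np.random.default_rng(0)
        seq = random_genome(rng, 1000)
        genome = ReferenceGenome({"chr1": seq})
        index = build_index(genome, 12)
        for start in (0, 100, 500, 988):
            seed = seq[start:start + 12]
            found = {
                (chrom, int(p))
                for chrom, positions in index.lookup(seed)
                for p in positions
            }
            assert (("chr1", start) in found)

    def test_seeds_with_n_not_indexed(self):
        genome = ReferenceGenome({"chr1": "ACGTACGTACGN" + "ACGT" * 10})
        index = build_index(genome, 12)
        assert index.lookup("ACGTACGTACGN") == []

    def test_empty_genome_empty_index(self):
        index = build_index(ReferenceGenome({"chr1": "ACGT"}), 12)
        assert index.lookup("ACGTACGTACGT") == []

    def test_seed_length_bounds(self):
        genome = ReferenceGenome({"chr1": "ACGT" * 20})
        with pytest.raises(ValueError):
            build_index(genome, 7)
        with pytest.raises(ValueError):
            build_index(genome, 25)


class TestLocate:
    def test_verbatim_plant_found_once(self):
        rng = np.random.default_rng(1)
        mcs = reverse_translate("MWNKFCEDH")[0]
        seq = random_genome(rng, 2000)
        seq = seq[:300] + mcs + seq[300 + 27:]
        genome = ReferenceGenome({"chr1": seq})
        index = build_index(genome, 12)
        locs = locate(mcs, genome, index, None)
        keys = {(l.chrom, l.start, l.strand) for l in locs}
        assert ("chr1", 300, "+") in keys
        plus_hits = [l for l in locs if l.start == 300 and l.strand == "+"]
        assert plus_hits[0].snv_support == ()

    def test_snv_licensed_mismatch(self):
        rng = np.random.default_rng(2)
        mcs = reverse_translate("MWNKFCEDH")[0]
        altered = mcs[:10] + ("A" if mcs[10] != "A" else "C") + mcs[11:]
        seq = random_genome(rng, 2000)
        seq = seq[:300] + mcs + seq[327:]
        genome = ReferenceGenome({"chr1": seq})
        index = build_index(genome, 12)
        catalog = SNVCatalog({("chr1", 310): (mcs[10], frozenset({altered[10]}))})
        with_snv = {(l.start, l.strand): l for l in locate(altered, genome, index, catalog)}
        assert (300, "+") in with_snv
        assert with_snv[(300, "+")].snv_support == ((310, altered[10]),)
        # same mismatch without the catalog entry: discarded
        without = locate(altered, genome, index, None)
        assert all(l.start != 300 for l in without)

    @pytest.mark.parametrize("fixture_seed", range(12))
    def test_oracle_equivalence_random_fixtures(self, fixture_seed):
        """Seed-and-verify equals the exhaustive scan, exact set equality."""
        rng = np.random.default_rng(fixture_seed)
        length = int(rng.integers(800, 3000))
        seq = list(random_genome(rng, length))
        mcs = reverse_translate("".join(
            "CDEFHKMNQWY"[i] for i in rng.integers(0, 11, 9)
        ))[int(rng.integers(0, 4))]
        entries = {}
        # plant several copies: verbatim, reverse-complement, one SNV-bearing
        for start, kind in [(50, "fwd"), (300, "rc"), (600, "snv")]:
            q = mcs if kind != "rc" else reverse_complement(mcs)
            for i, b in enumerate(q):
                seq[start + i] = b
            if kind == "snv":
                off = int(rng.integers(0, 27))
                alt = q[off]
                refbase = "ACGT"[(("ACGT".index(alt)) + 1) % 4]
                seq[start + off] = refbase
                entries[("chr1", start + off)] = (refbase, frozenset({alt}))
        # decorative random SNVs
        for _ in range(10):
            p = int(rng.integers(0, length))
            ref = seq[p]
            alt = "ACGT"[("ACGT".index(ref) + 2) % 4]
            entries.setdefault(("chr1", p), (ref, frozenset({alt})))
        genome = ReferenceGenome({"chr1": "".join(seq)})
        catalog = SNVCatalog(entries)
        index = build_index(genome, 12)
        got = {
            (l.chrom, l.start, l.end, l.strand)
            for l in locate(mcs, genome, index, catalog)
        }
        assert got == brute_force_locate(mcs, genome, catalog)

    def test_strand_symmetry(self):
        rng = np.random.default_rng(3)
        mcs = reverse_translate("MWNKFCEDH")[0]
        seq = random_genome(rng, 1500)
        seq = seq[:400] + mcs + seq[427:]
        fwd = ReferenceGenome({"chr1": seq})
        rev = ReferenceGenome({"chr1": reverse_complement(seq)})
        hits_f = {
            (l.start, l.strand) for l in locate(mcs, fwd, build_index(fwd, 12), None)
        }
        hits_r = {
            (len(seq) - l.end, {"+": "-", "-": "+"}[l.strand])
            for l in locate(mcs, rev, build_index(rev, 12), None)
        }
        assert hits_f == hits_r

    def test_adding_snvs_never_removes_locations(self):
        rng = np.random.default_rng(4)
        mcs = reverse_translate("MWNKFCEDH")[0]
        seq = random_genome(rng, 1200)
        seq = seq[:200] + mcs + seq[227:]
        genome = ReferenceGenome({"chr1": seq})
        index = build_index(genome, 12)
        base = {l.key() for l in locate(mcs, genome, index, None)}
        entries = {
            ("chr1", p): (seq[p], frozenset({"ACGT"[("ACGT".index(seq[p]) + 1) % 4]}))
            for p in range(100, 400, 13)
        }
        enriched = {l.key() for l in locate(mcs, genome, index, SNVCatalog(entries))}
        assert base <= enriched


class TestSpliced:
    def test_junction_spanning_match(self, mixed_reference):
        loc = mixed_reference.plant_locations["spliced"]
        hits = locate_spliced(
            loc.mcs, mixed_reference.genome, mixed_reference.annotations,
            mixed_reference.snv_catalog,
        )
        assert any(h.key() == loc.key() for h in hits)
        assert all(len(h.blocks) >= 2 for h in hits)

    def test_contiguous_matches_left_to_locate(self, mixed_reference):
        loc = mixed_reference.plant_locations["snvp"]  # contiguous plant
        hits = locate_spliced(
            loc.mcs, mixed_reference.genome, mixed_reference.annotations,
            mixed_reference.snv_catalog,
        )
        assert all(h.key() != loc.key() for h in hits)

    def test_unannotated_junction_not_searched(self, mixed_reference):
        # a sequence straddling the spliced plant's junction but with the
        # wrong intron length matches no annotated junction
        loc = mixed_reference.plant_locations["spliced"]
        genome = mixed_reference.genome
        wrong = (
            genome.fetch(loc.chrom, loc.blocks[0][0], loc.blocks[0][1])
            + genome.fetch(loc.chrom, loc.blocks[1][0] - 7, loc.blocks[1][1] - 7)
        )
        hits = locate_spliced(
            wrong, genome, mixed_reference.annotations, mixed_reference.snv_catalog
        )
        assert hits == []


class TestManual:
    def make_setup(self):
        rng = np.random.default_rng(5)
        pep = "MWNKFCEDH"
        mcs = reverse_translate(pep)[0]
        seq = random_genome(rng, 600)
        seq = seq[:100] + mcs + seq[127:]
        rc_start = 300
        rc = reverse_complement(mcs)
        seq = seq[:rc_start] + rc + seq[rc_start + 27:]
        return pep, mcs, ReferenceGenome({"chr1": seq})

    def test_correct_triple_resolves(self):
        pep, mcs, genome = self.make_setup()
        q = PeptideQuery("m", pep, mode="manual", given_mcs=mcs,
                         given_location=("chr1", 100, "+"))
        loc = resolve_manual(q, genome, None)
        assert loc.blocks == ((100, 127),) and loc.strand == "+"

    def test_minus_strand_uses_reverse_complement(self):
        pep, mcs, genome = self.make_setup()
        q = PeptideQuery("m", pep, mode="manual", given_mcs=mcs,
                         given_location=("chr1", 300, "-"))
        loc = resolve_manual(q, genome, None)
        assert loc.strand == "-"
        assert loc.expected_forward == reverse_complement(mcs)

    def test_mismatch_without_snv_rejected(self):
        pep, mcs, genome = self.make_setup()
        q = PeptideQuery("m", pep, mode="manual", given_mcs=mcs,
                         given_location=("chr1", 101, "+"))  # off by one
        with pytest.raises(LocationRejected):
            resolve_manual(q, genome, None)

    def test_out_of_bounds_rejected(self):
        pep, mcs, genome = self.make_setup()
        q = PeptideQuery("m", pep, mode="manual", given_mcs=mcs,
                         given_location=("chr1", 590, "+"))
        with pytest.raises(LocationRejected):
            resolve_manual(q, genome, None)


def test_bed12_blocks():
    loc = GenomicLocation("chr1", "+", ((100, 111), (200, 216)), "A" * 27, "A" * 27)
    line = to_bed12([loc], ["p"]).strip().split("\t")
    assert line[0:4] == ["chr1", "100", "216", "p"]
    assert line[9:12] == ["2", "11,16", "0,100"]
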