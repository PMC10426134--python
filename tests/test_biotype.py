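"""Biotype overlap classes, frame checking, EM apportionment, best guess."""

import math

import pytest

from mapquant.biotype import (
    EMState,
    MapReadProfile,
    best_guess,
    em_fit,
    frame_status,
    location_shares,
    overlap_biotypes,
    summarize_biotypes,
)
from mapquant.genome import TranscriptModel, reverse_complement
from mapquant.locate import GenomicLocation
from mapquant.revtrans import reverse_translate, translate


def loc(start, end, strand="+", blocks=None, chrom="chr1"):
    blocks = blocks or ((start, end),)
    n = sum(e - s for s, e in blocks)
    return GenomicLocation(chrom, strand, tuple(blocks), "A" * n, "A" * n)


class TestOverlap:
    def test_fixture_plants_get_their_designed_classes(self, mixed_reference):
        expected = {
            "snvp": {"intergenic"},
            "minus": {"in_frame"},
            "spliced": {"non_coding_exon"},
            "oframe": {"out_of_frame_exon"},
            "erep": {"ERE_LTR"},
            "intr": {"intron"},
        }
        for name, classes in expected.items():
            lb = overlap_biotypes(
                mixed_reference.plant_locations[name], mixed_reference.annotations
            )
            assert set(lb.overlaps) == classes, name
            assert lb.in_frame == (classes == {"in_frame"})

    def test_full_span_overlap_lengths(self, mixed_reference):
        lb = overlap_biotypes(
            mixed_reference.plant_locations["spliced"], mixed_reference.annotations
        )
        assert lb.overlaps["non_coding_exon"] == 27  # both blocks inside exons

    def test_exon_intron_junction(self, mixed_reference):
        # shift the intronic plant's window to straddle the host's exon edge
        host = mixed_reference.plant_locations["intr"]
        straddle = loc(host.start - 45, host.start - 18, chrom=host.chrom)
        lb = overlap_biotypes(straddle, mixed_reference.annotations)
        assert "exon_intron_junction" in lb.overlaps

    def test_agrees_with_linear_scan(self, mixed_reference):
        idx = mixed_reference.annotations
        for l in mixed_reference.plant_locations.values():
            got = {id(f) for s, e in l.blocks for f in idx.query(l.chrom, s, e)}
            exp = {
                id(f)
                for f in idx.features
                if any(f.start < e and s < f.end for s, e in l.blocks)
            }
            assert got == exp


class TestFrameStatus:
    @pytest.fixture()
    def coding_tr(self):
        # CDS 100-190 on +, frame starts at 100
        return TranscriptModel(
            "t", "g", "G", "chr1", "+", [(50, 250)], cds=[(100, 190, 0)]
        )

    def test_codon_boundary_in_frame(self, coding_tr):
        assert frame_status(loc(103, 130), coding_tr) == "in_frame"

    def test_shifted_by_one_out_of_frame(self, coding_tr):
        assert frame_status(loc(104, 131), coding_tr) == "out_of_frame"

    def test_outside_cds_not_in_frame(self, coding_tr):
        assert frame_status(loc(60, 87), coding_tr) == "out_of_frame"

    def test_no_cds_not_applicable(self):
        tr = TranscriptModel("t", "g", "G", "chr1", "+", [(50, 250)])
        assert frame_status(loc(100, 127), tr) == "not_applicable"

    def test_wrong_strand_never_in_frame(self, coding_tr):
        assert frame_status(loc(103, 130, strand="-"), coding_tr) == "out_of_frame"

    def test_spliced_cds_frame_via_protein_oracle(self, mixed_reference):
        """An in-frame location's peptide must appear in the translated CDS."""
        tr = next(
            t
            for t in mixed_reference.annotations.transcripts
            if t.cds and t.transcript_id == "t_minus"
        )
        location = mixed_reference.plant_locations["minus"]
        assert frame_status(location, tr) == "in_frame"
        protein = translate(tr.cds_sequence(mixed_reference.genome), allow_stop=True)
        assert translate(location.mcs) in protein


class TestEM:
    def test_single_class_degenerate_fixed_point(self):
        profiles = [
            MapReadProfile("a", [(10, frozenset({"intron"}))]),
            MapReadProfile("b", [(30, frozenset({"intron"}))]),
        ]
        state = em_fit(profiles)
        assert state.converged and state.iterations <= 2
        assert state.phi["intron"] == pytest.approx(1.0)
        assert state.z["a"] == {"intron": pytest.approx(1.0)}

    def test_disjoint_single_class_closed_form(self):
        # E-step rows are deltas; phi averages them; pooled shares are
        # read-weighted: 75/25
        profiles = [
            MapReadProfile("a", [(75, frozenset({"in_frame"}))]),
            MapReadProfile("b", [(25, frozenset({"intron"}))]),
        ]
        state = em_fit(profiles)
        assert state.z["a"] == {"in_frame": pytest.approx(1.0)}
        assert state.z["b"] == {"intron": pytest.approx(1.0)}
        assert state.phi["in_frame"] == pytest.approx(0.5)
        assert state.pooled["in_frame"] == pytest.approx(0.75)
        assert state.pooled["intron"] == pytest.approx(0.25)

    def test_symmetric_two_class_location(self):
        profiles = [
            MapReadProfile("a", [(40, frozenset({"intron", "ERE_LINE"}))]),
        ]
        state = em_fit(profiles)
        assert state.phi["intron"] == pytest.approx(state.phi["ERE_LINE"])
        assert sum(state.phi.values()) == pytest.approx(1.0)

    def test_fixed_point_stable_after_convergence(self):
        profiles = [
            MapReadProfile("a", [(60, frozenset({"in_frame", "intron"})),
                                 (40, frozenset({"intron"}))]),
            MapReadProfile("b", [(10, frozenset({"in_frame"}))]),
            MapReadProfile("c", [(5, frozenset({"ERE_LTR", "intron"}))]),
        ]
        state = em_fit(profiles)
        assert state.converged
        again = em_fit(profiles, max_iter=state.iterations + 1)
        for b in state.phi:
            assert state.phi[b] == pytest.approx(again.phi[b], abs=1e-7)

    def test_no_reads_anywhere_is_an_error(self):
        with pytest.raises(ValueError, match="EM undefined"):
            em_fit([MapReadProfile("a", [(0, frozenset({"intron"}))])])

    def test_zero_read_maps_excluded_but_harmless(self):
        with_zero = [
            MapReadProfile("a", [(75, frozenset({"in_frame"}))]),
            MapReadProfile("b", [(25, frozenset({"intron"}))]),
            MapReadProfile("z", [(0, frozenset({"pseudogene_exon"}))]),
        ]
        state = em_fit(with_zero)
        assert state.phi["in_frame"] == pytest.approx(0.5)
        assert "z" not in state.z


class TestSummaries:
    def test_single_location_single_class_100_percent(self):
        phi = {"in_frame": 1.0}
        profile = summarize_biotypes(
            "p",
            {"s1": {"L1": 12}},
            {"L1": frozenset({"in_frame"})},
            phi,
            cohorts={"c1": ["s1"]},
        )
        assert profile.global_pct == {"in_frame": pytest.approx(100.0)}
        assert profile.per_cohort["c1"] == {"in_frame": pytest.approx(100.0)}
        assert profile.per_location["L1"] == {"in_frame": pytest.approx(1.0)}

    def test_two_location_read_split(self):
        phi = {"in_frame": 0.5, "intron": 0.5}
        profile = summarize_biotypes(
            "p",
            {"s1": {"L1": 90, "L2": 10}},
            {"L1": frozenset({"in_frame"}), "L2": frozenset({"intron"})},
            phi,
        )
        assert profile.global_pct["in_frame"] == pytest.approx(90.0)
        assert profile.global_pct["intron"] == pytest.approx(10.0)

    def test_conservation_at_all_scopes(self):
        phi = {"in_frame": 0.6, "intron": 0.3, "ERE_LINE": 0.1}
        profile = summarize_biotypes(
            "p",
            {"s1": {"L1": 7, "L2": 3}, "s2": {"L1": 11, "L2": 0}},
            {
                "L1": frozenset({"in_frame", "intron"}),
                "L2": frozenset({"intron", "ERE_LINE"}),
            },
            phi,
            cohorts={"c1": ["s1"], "c2": ["s2"]},
        )
        assert sum(profile.global_pct.values()) == pytest.approx(100.0, abs=1e-6)
        for pct in profile.per_cohort.values():
            assert sum(pct.values()) == pytest.approx(100.0, abs=1e-6)
        for shares in profile.per_location.values():
            assert sum(shares.values()) == pytest.approx(1.0, abs=1e-9)

    def test_zero_read_location_changes_nothing(self):
        phi = {"in_frame": 0.5, "intron": 0.5}
        base = summarize_biotypes(
            "p", {"s1": {"L1": 20}}, {"L1": frozenset({"in_frame"})}, phi
        )
        padded = summarize_biotypes(
            "p",
            {"s1": {"L1": 20, "L2": 0}},
            {"L1": frozenset({"in_frame"}), "L2": frozenset({"intron"})},
            phi,
        )
        assert base.global_pct == padded.global_pct

    def test_empty_scope_undefined(self):
        phi = {"in_frame": 1.0}
        profile = summarize_biotypes(
            "p",
            {"s1": {"L1": 5}, "s2": {"L1": 0}},
            {"L1": frozenset({"in_frame"})},
            phi,
            cohorts={"dead": ["s2"]},
        )
        assert profile.per_cohort["dead"] is None


class TestBestGuess:
    def test_in_frame_override_with_certainty(self):
        classes, certainty = best_guess({"in_frame": 5.0, "intron": 95.0}, True)
        assert classes == ("in_frame",)
        assert certainty == pytest.approx(5.0)

    def test_argmax_without_in_frame(self):
        classes, certainty = best_guess({"intron": 60.0, "ERE_LTR": 40.0}, False)
        assert classes == ("intron",)
        assert certainty == pytest.approx(60.0)

    def test_exact_tie_reports_all(self):
        classes, certainty = best_guess(
            {"non_coding_exon": 50.0, "intron": 50.0}, False
        )
        assert classes == ("intron", "non_coding_exon")
        assert certainty == pytest.approx(50.0)

    def test_undefined_profile_raises(self):
        with pytest.raises(ValueError):
            best_guess(None, False)
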