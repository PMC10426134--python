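"""Shared synthetic-data fixtures; everything is generated at test time."""

import os

import pytest

from mapquant import fixtures as fx
from mapquant.counting import LibraryConfig


@pytest.fixture(scope="session")
def mixed_reference(tmp_path_factory):
    """A small genome exercising every plant kind: SNV-bearing, minus-strand,
    spliced, in/out-of-frame coding, ERE, intronic, and one decoy-rich plant."""
    d = tmp_path_factory.mktemp("mixed_ref")
    plants = [
        fx.Plant("snvp", "MWNKFCEDH", start=500, strand="+", reads=6,
                 snv_offsets=(5,), decoys=True),
        fx.Plant("minus", "KKDEFWHMC", start=1500, strand="-", reads=4,
                 antisense_reads=3, decoys=True, annotation="coding_in"),
        fx.Plant("spliced", "CEDHWMKNF", start=2500, strand="+", reads=5,
                 intron=(11, 80), annotation="ncRNA"),
        fx.Plant("oframe", "FFWWMMHHK", start=4000, strand="+", reads=2,
                 annotation="coding_out"),
        fx.Plant("erep", "WCDMKEFHN", start=5000, strand="+", reads=7,
                 annotation="ERE:LTR/ERVK"),
        fx.Plant("intr", "HHCCDDWWM", start=6000, strand="+", reads=3,
                 annotation="intron"),
    ]
    spec = fx.FixtureSpec(
        seed=11,
        chromosomes={"chr1": 9000},
        plants=plants,
        background_reads=120,
        read_length=60,
        library=LibraryConfig("paired_end", "forward", "stranded"),
        n_random_snvs=10,
        secondary_copies=5,
    )
    return fx.make_reference(spec, str(d))


@pytest.fixture(scope="session")
def mixed_bam(mixed_reference, tmp_path_factory):
    d = tmp_path_factory.mktemp("mixed_bam")
    return fx.make_bam(mixed_reference, os.path.join(str(d), "sample.bam"))


@pytest.fixture(scope="session")
def panel(tmp_path_factory):
    """The 9-mer panel fixture used for pipeline-vs-k-mer comparisons."""
    d = tmp_path_factory.mktemp("panel")
    spec = fx.panel_spec(n_peptides=52, seed=7)
    ref = fx.make_reference(spec, str(d))
    bam = fx.make_bam(ref, os.path.join(str(d), "panel.bam"))
    return spec, ref, bam
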