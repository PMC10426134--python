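"""Reverse translation of peptides into the complete set of coding sequences.

An 8-11 residue MHC-I-associated peptide (MAP) can be encoded by any of the
nucleotide sequences (MAP-coding sequences, MCS, 24-33 nt) produced by the
degeneracy of the genetic code; the number of MCS is the product of the
per-residue codon degeneracies (up to 6 for R/L/S).  Every MCS is searched
genome-wide downstream, so the expansion must be exhaustive and deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable

# Standard genetic code, stop codons excluded.
CODON_TABLE: dict[str, str] = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "CAT": "H", "CAC": "H",
    "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D",
    "GAA": "E", "GAG": "E", "TGT": "C", "TGC": "C",
    "TGG": "W", "CGT": "R", "CGC": "R", "CGA": "R",
    "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R",
    "AGG": "R", "GGT": "G", "GGC": "G", "GGA": "G",
    "GGG": "G",
}
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

CODONS_BY_AA: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TABLE.items()):
    CODONS_BY_AA.setdefault(_aa, ())
    CODONS_BY_AA[_aa] = CODONS_BY_AA[_aa] + (_codon,)

CANONICAL_AA = frozenset(CODONS_BY_AA)

MIN_PEPTIDE_LEN = 8
MAX_PEPTIDE_LEN = 11


class PeptideError(ValueError):
    pass


@dataclass
class PeptideQuery:
    """One queried peptide with its input mode and optional constraints.

    mode 'peptide': search every possible MCS genome-wide.
    mode 'mcs':     search only the given MCS genome-wide.
    mode 'manual':  verify and count the given MCS at the stated location.
    """

    name: str
    sequence: str
    mode: str = "peptide"
    given_mcs: str | None = None
    given_location: tuple[str, int, str] | None = None  # (chrom, start0, strand)

    def __post_init__(self):
        validate_peptide(self.sequence)
        if self.mode not in ("peptide", "mcs", "manual"):
            raise PeptideError(f"unknown mode {self.mode!r}")
        if self.mode in ("mcs", "manual"):
            if not self.given_mcs:
                raise PeptideError(f"{self.name}: mode {self.mode} requires an MCS")
            if translate(self.given_mcs) != self.sequence:
                raise PeptideError(
                    f"{self.name}: MCS does not translate to peptide "
                    f"({translate(self.given_mcs)} != {self.sequence})"
                )
        if self.mode == "manual" and self.given_location is None:
            raise PeptideError(f"{self.name}: manual mode requires a genomic location")


def validate_peptide(sequence: str, min_len: int = MIN_PEPTIDE_LEN, max_len: int = MAX_PEPTIDE_LEN) -> None:
    bad = set(sequence) - CANONICAL_AA
    if bad:
        raise PeptideError(f"non-canonical residue(s) {sorted(bad)} in {sequence!r}")
    if not (min_len <= len(sequence) <= max_len):
        raise PeptideError(
            f"peptide length {len(sequence)} outside supported range "
            f"[{min_len}, {max_len}]: {sequence!r}"
        )


def codon_degeneracy(amino_acid: str) -> int:
    """Number of standard-genetic-code codons encoding one residue."""
    try:
        return len(CODONS_BY_AA[amino_acid])
    except KeyError:
        raise PeptideError(f"unknown amino acid {amino_acid!r}") from None


def n_mcs(peptide: str) -> int:
    """Size of the full MCS set without enumerating it."""
    n = 1
    for aa in peptide:
        n *= codon_degeneracy(aa)
    return n


def reverse_translate(peptide: str, _validate: bool = True) -> list[str]:
    """All nucleotide sequences encoding `peptide`, lexicographically sorted."""
    if _validate:
        validate_peptide(peptide)
    pools = [CODONS_BY_AA[aa] for aa in peptide]
    return ["".join(codons) for codons in itertools.product(*pools)]


def translate(mcs: str, allow_stop: bool = False) -> str:
    """Translate a coding sequence under the standard genetic code.

    A stop codon raises unless `allow_stop`, in which case '*' is emitted.
    """
    if len(mcs) % 3 != 0:
        raise PeptideError(f"sequence length {len(mcs)} not a multiple of 3")
    out = []
    for i in range(0, len(mcs), 3):
        codon = mcs[i:i + 3]
        if codon in STOP_CODONS:
            if allow_stop:
                out.append("*")
                continue
            raise PeptideError(f"stop codon {codon} at nt {i} of {mcs!r}")
        try:
            out.append(CODON_TABLE[codon])
        except KeyError:
            raise PeptideError(f"invalid codon {codon!r} at nt {i}") from None
    return "".join(out)


def expand_query(query: PeptideQuery) -> list[str]:
    """The MCS set to search for one query (respects mcs/manual modes)."""
    if query.mode in ("mcs", "manual"):
        return [query.given_mcs]
    return reverse_translate(query.sequence)


def emit_mcs_fastq(queries: Iterable[PeptideQuery], quality_char: str = "I") -> str:
    """FASTQ text with one record per searchable MCS.

    Manual-mode queries are bound to a stated location and bypass the
    genome-wide search, so they are not emitted here.
    """
    records = []
    for q in queries:
        if q.mode == "manual":
            continue
        for i, mcs in enumerate(expand_query(q)):
            records.append(f"@{q.name}|mcs{i}\n{mcs}\n+\n{quality_char * len(mcs)}\n")
    return "".join(records)
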