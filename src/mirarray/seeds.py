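"""Seed derivation and exact seed-match scanning in 3'UTRs.

The seed of a mature miRNA is nucleotides 2-8 counted 1-based from the 5'
end (seven nucleotides). A target site is an exact, Watson-Crick reverse
complement of the seed on the mRNA, so UTRs are scanned (as DNA) for the
reverse-complement DNA of the seed.

Two seed interpretations are supported:

``standard``
    Seed = miRNA nt 2-8; the UTR is searched for its reverse-complement DNA.
``literal_revcomp``
    The whole miRNA is first reverse complemented (as DNA) and nt 2-8 of
    *that* string are used as the search pattern directly. This variant
    corresponds to reading the derivation recipe word for word rather than
    by its canonical intent; it targets the complement of miRNA nt 15-21
    for a 22-nt miRNA and is kept behind this flag for comparison only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

from .errors import InputError
from .orfs import UtrRecord

_RNA_TO_DNA_COMPLEMENT = str.maketrans("ACGU", "TGCA")
_DNA_COMPLEMENT = str.maketrans("ACGT", "TGCA")

SeedMode = Literal["standard", "literal_revcomp"]


def rna_reverse_complement_dna(rna: str) -> str:
    """Reverse complement of an RNA string, written as DNA."""
    return rna.translate(_RNA_TO_DNA_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SeedPattern:
    """A miRNA's seed and the DNA pattern to search for in UTRs."""

    mirna_name: str
    seed_rna: str   # miRNA nt 2-8, 5'->3'
    match_dna: str  # pattern searched in UTR DNA


@dataclass(frozen=True)
class SeedMatch:
    """One exact seed-site occurrence, with UTR- and contig-relative coordinates."""

    mirna_name: str
    contig_id: str
    utr_pos: int
    contig_pos: int


def derive_seed(name: str, sequence: str, mode: SeedMode = "standard") -> SeedPattern:
    """Derive the 7-nt seed pattern of a mature miRNA (5'->3' RNA).

    Raises for sequences shorter than 8 nt (positions 2-8 must exist).
    """
    seq = sequence.upper().replace("T", "U")
    if len(seq) < 8:
        raise InputError(f"miRNA {name!r} is shorter than 8 nt; no seed positions 2-8")
    if set(seq) - set("ACGU"):
        raise InputError(f"miRNA {name!r} contains non-RNA characters")
    seed_rna = seq[1:8]  # 1-based positions 2-8
    if mode == "standard":
        match_dna = rna_reverse_complement_dna(seed_rna)
    elif mode == "literal_revcomp":
        full_rc = rna_reverse_complement_dna(seq)
        match_dna = full_rc[1:8]
    else:
        raise InputError(f"unknown seed mode {mode!r}")
    return SeedPattern(name, seed_rna, match_dna)


def scan_seed_matches(utrs: Iterable[UtrRecord],
                      patterns: Iterable[SeedPattern]) -> list[SeedMatch]:
    """All exact (possibly overlapping) occurrences of each pattern in each UTR."""
    patterns = list(patterns)
    if not patterns:
        raise InputError("no seed patterns supplied")
    matches: list[SeedMatch] = []
    for utr in utrs:
        seq = utr.sequence
        for pat in patterns:
            pos = seq.find(pat.match_dna)
            while pos != -1:
                matches.append(SeedMatch(pat.mirna_name, utr.contig_id,
                                         pos, utr.utr_start + pos))
                pos = seq.find(pat.match_dna, pos + 1)
    return matches
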