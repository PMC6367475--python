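"""ORF discovery and putative 3'UTR extraction in transcriptome contigs.

Contigs are treated as mRNA-sense assembled transcripts, so only forward
strand ORFs are considered. An ORF runs from an ATG to the first in-frame
stop codon (TAA/TAG/TGA), stop included; ORFs that run off the contig end
without a stop are reported as incomplete. The putative 3'UTR of a contig
is everything downstream of its *reference* ORF -- the complete ORF whose
stop codon lies furthest 3'.

All coordinates are 0-based, half-open.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

from .errors import InputError, IntegrityError

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"
_IUPAC_DNA = frozenset("ACGTN")

DEFAULT_MIN_ORF_CODONS = 30
DEFAULT_MIN_UTR_LEN = 7  # the seed-match length


@dataclass(frozen=True)
class Contig:
    """A transcriptome contig (DNA, uppercase, may contain N)."""

    id: str
    sequence: str

    def __post_init__(self):
        if not self.sequence:
            raise InputError(f"contig {self.id!r} has empty sequence")
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        bad = set(seq) - _IUPAC_DNA
        if bad:
            raise InputError(f"contig {self.id!r} has non-IUPAC characters: {sorted(bad)}")


@dataclass(frozen=True)
class OrfAnnotation:
    """A forward-strand ORF: ``[start, end)`` nt coordinates, frame = start % 3."""

    contig_id: str
    start: int
    end: int
    frame: int
    complete: bool

    @property
    def length_codons(self) -> int:
        return (self.end - self.start) // 3


@dataclass(frozen=True)
class UtrRecord:
    """Putative 3'UTR: the contig suffix downstream of the reference ORF."""

    contig_id: str
    utr_start: int
    sequence: str


def find_orfs(contig: Contig, min_len_codons: int = DEFAULT_MIN_ORF_CODONS) -> list[OrfAnnotation]:
    """Report every forward-strand ORF of at least ``min_len_codons`` codons.

    Each ATG opens a candidate which is walked codon by codon to the first
    in-frame stop. Nested ATGs sharing a stop yield separate ORFs. Candidates
    containing N are skipped with a warning. Results are sorted by start,
    then end.
    """
    seq = contig.sequence
    n = len(seq)
    out: list[OrfAnnotation] = []
    start = seq.find(START_CODON)
    starts = []
    while start != -1:
        starts.append(start)
        start = seq.find(START_CODON, start + 1)
    for s in starts:
        end = None
        complete = False
        pos = s
        while pos + 3 <= n:
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS and pos > s:
                end = pos + 3
                complete = True
                break
            pos += 3
        if end is None:
            end = pos  # last full codon boundary; incomplete
            complete = False
        if (end - s) // 3 < min_len_codons:
            continue
        candidate = seq[s:end]
        if "N" in candidate:
            warnings.warn(
                f"contig {contig.id!r}: ORF candidate at {s} contains N; skipped",
                stacklevel=2,
            )
            continue
        out.append(OrfAnnotation(contig.id, s, end, s % 3, complete))
    out.sort(key=lambda o: (o.start, o.end))
    return out


def select_reference_orf(orfs: list[OrfAnnotation]) -> Optional[OrfAnnotation]:
    """The complete ORF with the 3'-most stop; ties -> longer, then 5'-most.

    Returns None when no complete ORF exists (such contigs contribute no UTR).
    """
    complete = [o for o in orfs if o.complete]
    if not complete:
        return None
    return max(complete, key=lambda o: (o.end, o.end - o.start, -o.start))


def extract_3utr(contig: Contig, ref: OrfAnnotation,
                 min_utr_len: int = DEFAULT_MIN_UTR_LEN) -> Optional[UtrRecord]:
    """The contig suffix downstream of ``ref``; None if shorter than ``min_utr_len``."""
    if ref.contig_id != contig.id:
        raise IntegrityError(f"ORF {ref.contig_id!r} does not belong to contig {contig.id!r}")
    if ref.end > len(contig.sequence):
        raise IntegrityError(
            f"ORF end {ref.end} exceeds contig {contig.id!r} length {len(contig.sequence)}"
        )
    tail = contig.sequence[ref.end:]
    if len(tail) < min_utr_len:
        return None
    return UtrRecord(contig.id, ref.end, tail)


def annotate_contigs(contigs: list[Contig], min_len_codons: int = DEFAULT_MIN_ORF_CODONS,
                     min_utr_len: int = DEFAULT_MIN_UTR_LEN,
                     ) -> tuple[list[OrfAnnotation], list[UtrRecord]]:
    """Convenience wrapper: all ORFs plus one UTR per contig with a complete ORF."""
    all_orfs: list[OrfAnnotation] = []
    utrs: list[UtrRecord] = []
    for contig in contigs:
        orfs = find_orfs(contig, min_len_codons)
        all_orfs.extend(orfs)
        ref = select_reference_orf(orfs)
        if ref is None:
            continue
        utr = extract_3utr(contig, ref, min_utr_len)
        if utr is not None:
            utrs.append(utr)
    return all_orfs, utrs
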