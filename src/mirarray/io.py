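"""FASTA and TSV I/O helpers.

All tabular artifacts are TSV with optional ``#``-prefixed metadata header
lines; FASTA is wrapped at 70 columns. FASTA parsing/writing goes through
Biopython so the files interoperate with standard tooling.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

FASTA_WIDTH = 70


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write ``(name, sequence)`` pairs as 70-column-wrapped FASTA."""
    seqrecords = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=FASTA_WIDTH)
        writer.write_file(seqrecords)


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA as ``(name, sequence)`` pairs, sequences uppercased."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def write_tsv(df: pd.DataFrame, path: str | Path, metadata: Mapping[str, str] | None = None,
              index: bool = False) -> None:
    """Write a DataFrame as TSV, prefixed by ``# key: value`` metadata lines."""
    buf = _io.StringIO()
    if metadata:
        for key, value in metadata.items():
            buf.write(f"# {key}: {value}\n")
    df.to_csv(buf, sep="\t", index=index)
    Path(path).write_text(buf.getvalue())


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_tsv`, skipping metadata lines."""
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)
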