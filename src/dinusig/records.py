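"""Transcript sequence records and FASTA input/output.

Transcripts are handled on the given (sense) strand only.  RNA and DNA
alphabets are unified at ingest: residues are uppercased and U is mapped
to T, so every downstream statistic sees a DNA-alphabet string.  IUPAC
ambiguity codes (N, R, Y, ...) are preserved; counting code skips any
window that touches one.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

__all__ = ["SequenceRecord", "read_fasta", "write_fasta"]

_TRANSLATE = str.maketrans("uU", "tT")


@dataclass
class SequenceRecord:
    """One transcript: accession, free-text header remainder, residues.

    ``residues`` are normalised (uppercase, U->T) in ``__post_init__``;
    ``source`` carries provenance tags such as the originating file.
    """

    id: str
    description: str = ""
    residues: str = ""
    source: str = ""

    def __post_init__(self) -> None:
        self.residues = self.residues.translate(_TRANSLATE).upper()

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def header(self) -> str:
        """Full FASTA header line (without '>')."""
        return f"{self.id} {self.description}".strip()


def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a (possibly gzipped) multi-record FASTA file.

    Raises ``ValueError`` when the file contains no parsable sequence.
    """
    out: list[SequenceRecord] = []
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            out.append(
                SequenceRecord(
                    id=rec.id,
                    description=rec.description[len(rec.id) :].strip()
                    if rec.description.startswith(rec.id)
                    else rec.description,
                    residues=str(rec.seq),
                    source=str(path),
                )
            )
    if not out:
        raise ValueError(f"no parsable FASTA record in {path}")
    return out


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA; deterministic byte output."""
    path = Path(path)
    with open(path, "wt") as handle:
        for rec in records:
            bio = _BioRecord(Seq(rec.residues), id=rec.id, description=rec.description)
            SeqIO.write(bio, handle, "fasta")
    # Biopython wraps at 60 columns; width kept for API symmetry.


def iter_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream records without materialising the whole file (genome-scale input)."""
    with _open_text(path) as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            yield SequenceRecord(
                id=rec.id,
                description=rec.description[len(rec.id) :].strip()
                if rec.description.startswith(rec.id)
                else rec.description,
                residues=str(rec.seq),
                source=str(path),
            )
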