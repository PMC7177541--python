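"""Protein sequence records, sanitization rules and FASTA I/O.

The :class:`ProteinRecord` is the atom of every scanning operation in this
package.  It couples an accession-like identifier with an uppercase
amino-acid sequence and a *numbering offset*: the residue number, in
full-protein coordinates, of the first residue of the stored sequence.
A construct spanning residues 194-362 of a full-length protein is therefore
stored with ``numbering_offset=194`` and every profile, run and motif hit is
reported in full-protein numbering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: The twenty canonical amino-acid one-letter codes.
CANONICAL = "ACDEFGHIKLMNPQRSTVWY"

#: Non-canonical letters that are tolerated on input (unknown residue,
#: selenocysteine, Asx, Glx).  They are retained in the sequence so that
#: coordinates stay faithful, but they are excluded from compositional
#: statistics and break homopolymer runs.
AMBIGUOUS = "XUBZ"

_ALLOWED = frozenset(CANONICAL + AMBIGUOUS)


class SequenceError(ValueError):
    """Raised when a sequence or a sequence-level argument is invalid."""


def sanitize_sequence(raw: str) -> str:
    """Uppercase ``raw``, strip whitespace/gaps, and validate the alphabet.

    ``*`` (stop) is tolerated only at the end and removed.  Any letter
    outside the canonical twenty plus ``X/U/B/Z`` raises
    :class:`SequenceError`.  Ambiguous letters are logged.
    """
    seq = "".join(raw.split()).upper().replace("-", "")
    if seq.endswith("*"):
        seq = seq[:-1]
    if not seq:
        raise SequenceError("empty sequence")
    bad = sorted(set(seq) - _ALLOWED)
    if bad:
        raise SequenceError(f"unexpected letters in sequence: {''.join(bad)}")
    ambiguous = sorted(set(seq) & set(AMBIGUOUS))
    if ambiguous:
        logger.info("sequence contains ambiguous letters %s; they are "
                    "excluded from statistics", "".join(ambiguous))
    return seq


@dataclass(frozen=True)
class ProteinRecord:
    """An identified amino-acid sequence with a residue-numbering offset.

    Parameters
    ----------
    id :
        Accession-like identifier (first whitespace-delimited token of a
        FASTA header).
    sequence :
        Amino-acid sequence; sanitized (uppercased, whitespace removed,
        alphabet-checked) on construction.
    numbering_offset :
        Full-protein residue number of the first stored residue (>= 1).
    """

    id: str
    sequence: str
    numbering_offset: int = 1

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "sequence", sanitize_sequence(self.sequence))
        if int(self.numbering_offset) < 1:
            raise SequenceError("numbering_offset must be >= 1")
        object.__setattr__(self, "numbering_offset", int(self.numbering_offset))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def residue_numbers(self) -> range:
        """Full-protein residue numbers covered by this record."""
        return range(self.numbering_offset, self.numbering_offset + len(self))

    def residue_at(self, number: int) -> str:
        """One-letter code of the residue at full-protein position ``number``."""
        idx = number - self.numbering_offset
        if not 0 <= idx < len(self.sequence):
            raise SequenceError(
                f"residue number {number} outside record range "
                f"{self.numbering_offset}-{self.numbering_offset + len(self) - 1}")
        return self.sequence[idx]


def read_fasta(path: str | Path, numbering_offset: int = 1) -> list[ProteinRecord]:
    """Read a (possibly multi-record, line-wrapped) FASTA file.

    The first whitespace-delimited token of each header becomes the record
    id; ``numbering_offset`` applies to every record in the file.
    """
    records = [
        ProteinRecord(id=rec.id, sequence=str(rec.seq),
                      numbering_offset=numbering_offset)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapping)."""
    seqs = [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records]
    SeqIO.write(seqs, str(path), "fasta")


def iter_fasta(path: str | Path, numbering_offset: int = 1) -> Iterator[ProteinRecord]:
    """Stream records from a FASTA file without loading them all."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield ProteinRecord(id=rec.id, sequence=str(rec.seq),
                            numbering_offset=numbering_offset)
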