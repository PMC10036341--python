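"""Sequence I/O and translation.

Reads and writes FASTA (via Biopython), translates nucleotide transcript
models in all six reading frames, and extracts stop-to-stop open reading
frames so that protein queries can be searched against translated models.

Coordinates are 1-based and inclusive throughout the package.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO as _BioSeqIO
from Bio.Data import CodonTable
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X*")

FRAMES = (1, 2, 3, -1, -2, -3)

# Standard genetic code (NCBI table 1), with explicit stop codons.
_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
_CODON_TABLE: dict[str, str] = dict(_TABLE1.forward_table)
_CODON_TABLE.update({codon: "*" for codon in _TABLE1.stop_codons})


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: a transcript model, precursor, or translation."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("record id must be non-empty")
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")

    def is_nucleotide(self) -> bool:
        return set(self.sequence) <= NUCLEOTIDE_ALPHABET

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class OrfSegment:
    """A stop-to-stop translated segment with its source coordinates.

    ``start``/``end`` are 1-based inclusive positions on the *source
    nucleotide* sequence; for negative frames they refer to the forward
    strand, with start < end.
    """

    source_id: str
    frame: int
    start: int
    end: int
    protein: str

    def __post_init__(self) -> None:
        if self.frame not in FRAMES:
            raise ValueError(f"invalid frame {self.frame}")
        if len(self.protein) * 3 != self.end - self.start + 1:
            raise ValueError("ORF coordinates do not span 3x protein length")
        if "*" in self.protein:
            raise ValueError("ORF protein must not contain stop characters")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into records (upper-cased, whitespace-stripped).

    Raises ``ValueError`` on duplicate ids or empty sequences.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in _BioSeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = re.sub(r"\s", "", str(rec.seq)).upper()
        desc = rec.description[len(rec.id):].strip()
        records.append(SequenceRecord(id=rec.id, sequence=seq, description=desc))
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                wrap_width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``wrap_width``."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be positive")
    path = Path(path)
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), wrap_width):
                fh.write(rec.sequence[i:i + wrap_width] + "\n")


def translate_frame(nucleotides: str, frame: int) -> str:
    """Translate one reading frame with the standard code.

    Codons containing N translate to 'X'; partial trailing codons are
    dropped; stops are rendered '*'. Negative frames translate the
    reverse complement.
    """
    bad = set(nucleotides) - NUCLEOTIDE_ALPHABET
    if bad:
        raise ValueError(f"non-nucleotide characters: {sorted(bad)}")
    if frame not in FRAMES:
        raise ValueError(f"invalid frame {frame}")
    seq = nucleotides if frame > 0 else str(Seq(nucleotides).reverse_complement())
    offset = abs(frame) - 1
    out: list[str] = []
    for i in range(offset, len(seq) - 2, 3):
        codon = seq[i:i + 3]
        out.append("X" if "N" in codon else _CODON_TABLE[codon])
    return "".join(out)


def six_frame_translate(record: SequenceRecord) -> dict[int, str]:
    """Translate a nucleotide record in all six frames, keyed by frame."""
    if not record.is_nucleotide():
        raise ValueError(f"record {record.id!r} is not nucleotide (ACGTN)")
    return {frame: translate_frame(record.sequence, frame) for frame in FRAMES}


def extract_orfs(protein_frame: str, frame: int, source_id: str,
                 source_len: int, min_len: int = 50) -> list[OrfSegment]:
    """Extract stop-to-stop segments of length >= ``min_len`` from one frame.

    Segments do not require an initiator Met: transcript models are often
    5'-incomplete, and requiring Met would truncate precursors. Source
    coordinates are recovered from the frame offset.
    """
    offset = abs(frame) - 1
    orfs: list[OrfSegment] = []
    pos = 0
    for segment in protein_frame.split("*"):
        if len(segment) >= min_len:
            i0, i1 = pos, pos + len(segment)  # codon indices [i0, i1)
            if frame > 0:
                start = offset + 3 * i0 + 1
                end = offset + 3 * i1
            else:
                start = source_len - offset - 3 * i1 + 1
                end = source_len - offset - 3 * i0
            orfs.append(OrfSegment(source_id=source_id, frame=frame,
                                   start=start, end=end, protein=segment))
        pos += len(segment) + 1  # the '*' consumes one codon
    return orfs


def orfs_from_record(record: SequenceRecord, min_len: int = 50) -> list[OrfSegment]:
    """Six-frame translate a nucleotide record and extract all ORFs."""
    frames = six_frame_translate(record)
    out: list[OrfSegment] = []
    for frame in FRAMES:
        out.extend(extract_orfs(frames[frame], frame, record.id,
                                len(record.sequence), min_len=min_len))
    return out


def translate_records(records: Sequence[SequenceRecord],
                      min_len: int = 50) -> list[SequenceRecord]:
    """Translate nucleotide records into candidate protein records.

    Each ORF becomes one protein record named ``<id>|f<frame>|<start>-<end>``.
    """
    out: list[SequenceRecord] = []
    for rec in records:
        for orf in orfs_from_record(rec, min_len=min_len):
            out.append(SequenceRecord(
                id=f"{rec.id}|f{orf.frame:+d}|{orf.start}-{orf.end}",
                sequence=orf.protein,
                description=f"ORF of {rec.id}",
            ))
    return out
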