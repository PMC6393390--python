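"""FASTA input/output, translation, and ORF deduction for cDNA clones.

Dehydrin coding sequences are typically obtained as directionally sequenced
full-length cDNA clones; the protein is deduced by locating the longest
ATG-to-stop open reading frame in the three forward frames.  All coordinates
are 1-based inclusive (GenBank/BLAST convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX*")
NUCLEOTIDE_ALPHABET = set("ACGTN")


class FastaParseError(ValueError):
    """Raised when a FASTA file or record violates the format contract."""


@dataclass
class SequenceRecord:
    """One FASTA entry: accession-like id, free-text description, residues."""

    id: str
    residues: str
    description: str = ""
    moltype: str = "protein"  # "protein" or "nucleotide"

    def __post_init__(self) -> None:
        self.residues = self.residues.upper()
        if not self.id:
            raise FastaParseError("record has an empty id")
        alphabet = NUCLEOTIDE_ALPHABET if self.moltype == "nucleotide" else PROTEIN_ALPHABET
        bad = set(self.residues) - alphabet
        if bad:
            raise FastaParseError(
                f"record {self.id!r}: invalid {self.moltype} characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class OrfCall:
    """An ATG-to-stop open reading frame call on a nucleotide record.

    ``start``/``end`` are 1-based inclusive nucleotide positions; ``end`` is
    the last base of the stop codon, so the span length is a multiple of 3
    and the peptide (stop excluded) has (end - start + 1) / 3 - 1 residues.
    """

    frame: int
    start: int
    end: int
    peptide: str
    strand: str = "+"


def _guess_moltype(residues: str) -> str:
    return "nucleotide" if set(residues) <= NUCLEOTIDE_ALPHABET and residues else "protein"


def read_fasta(path: str | Path, moltype: Optional[str] = None) -> list[SequenceRecord]:
    """Parse a (possibly line-wrapped) FASTA file into SequenceRecords.

    Residues are uppercased and whitespace-stripped; ids must be unique and
    sequences non-empty.  When ``moltype`` is None it is guessed per record
    (all-ACGTN means nucleotide).
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).replace(" ", "").upper()
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty header")
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        mt = moltype or _guess_moltype(residues)
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description, moltype=mt)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 60) -> None:
    """Write records as wrapped FASTA (round-trips with :func:`read_fasta`)."""
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def translate(codons: str) -> str:
    """Standard-table translation of an in-frame nucleotide string.

    Stops are rendered as ``*``.  Length must be divisible by 3.
    """
    codons = codons.upper()
    if len(codons) % 3 != 0:
        raise ValueError(f"length {len(codons)} is not divisible by 3")
    if not codons:
        return ""
    return str(Seq(codons).translate(table=1))


def _orfs_in_frames(seq: str) -> Iterable[tuple[int, int, int, str]]:
    """Yield (frame, start, end, peptide) for every ATG-to-stop ORF, 1-based."""
    stops = {"TAA", "TAG", "TGA"}
    for frame in range(3):
        codons = [seq[i : i + 3] for i in range(frame, len(seq) - 2, 3)]
        open_starts: list[int] = []
        for ci, codon in enumerate(codons):
            if codon == "ATG":
                open_starts.append(ci)
            elif codon in stops:
                for s in open_starts:
                    start = frame + 3 * s + 1
                    end = frame + 3 * ci + 3
                    peptide = translate(seq[start - 1 : end - 3])
                    yield frame, start, end, peptide
                open_starts = []


def find_longest_orf(
    record: SequenceRecord, min_aa: int = 50, both_strands: bool = False
) -> Optional[OrfCall]:
    """Longest ATG-to-stop ORF (peptide length >= min_aa) in the 3 forward frames.

    Ties are broken by smaller start position.  Returns None when no ORF
    qualifies.  ``both_strands=True`` additionally scans the reverse
    complement (coordinates then refer to the reverse strand, strand "-").
    """
    if record.moltype != "nucleotide":
        raise ValueError(f"record {record.id!r} is not a nucleotide record")
    candidates: list[OrfCall] = []
    strands = [("+", record.residues)]
    if both_strands:
        strands.append(("-", str(Seq(record.residues).reverse_complement())))
    for strand, seq in strands:
        for frame, start, end, peptide in _orfs_in_frames(seq):
            if len(peptide) >= min_aa:
                candidates.append(OrfCall(frame, start, end, peptide, strand))
    if not candidates:
        return None
    candidates.sort(key=lambda c: (-len(c.peptide), c.strand != "+", c.start))
    return candidates[0]


def orf_table(records: Iterable[SequenceRecord], min_aa: int = 50):
    """ORF report as a DataFrame: id, frame, start, end, length_aa."""
    import pandas as pd

    rows = []
    for rec in records:
        call = find_longest_orf(rec, min_aa=min_aa)
        if call is not None:
            rows.append(
                {
                    "id": rec.id,
                    "frame": call.frame,
                    "start": call.start,
                    "end": call.end,
                    "length_aa": len(call.peptide),
                }
            )
    return pd.DataFrame(rows, columns=["id", "frame", "start", "end", "length_aa"])
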