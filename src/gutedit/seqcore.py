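"""Sequence and coordinate primitives shared by every pipeline stage.

DNA is handled as uppercase strings over ``{A, C, G, T, N}``. Coordinates are
0-based half-open internally; everything written for human consumption
(TSV reports, CLI output) is converted to 1-based inclusive at the boundary.
``N`` is carried through and treated conservatively: it mismatches every base.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

import numpy as np
from Bio import SeqIO
from Bio.Data.CodonTable import standard_dna_table
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")

#: integer codes used by the vectorized scanners: A=0 C=1 G=2 T=3 N=4
BASE_CODES = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_BASES = "ACGTN"

#: IUPAC nucleotide codes -> set of concrete bases they match.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG",
    "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class SequenceFormatError(ValueError):
    """Raised for malformed FASTA records or non-DNA input."""


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA sequence (one FASTA record / one replicon)."""

    name: str
    seq: str

    def __post_init__(self) -> None:
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise SequenceFormatError(
                f"sequence {self.name!r} contains non-DNA characters: {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def __len__(self) -> int:
        return len(self.seq)

    def codes(self) -> np.ndarray:
        """Sequence as a uint8 code array (A=0 C=1 G=2 T=3 N=4)."""
        arr = np.frombuffer(self.seq.encode("ascii"), dtype=np.uint8)
        out = np.full(arr.shape, 4, dtype=np.uint8)
        for base, code in BASE_CODES.items():
            out[arr == ord(base)] = code
        return out


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open, 0-based, stranded interval on a named contig."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.contig}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def as_1based(self) -> tuple[int, int]:
        """(start, end) as 1-based inclusive, for reports."""
        return self.start + 1, self.end


def revcomp(seq: str) -> str:
    """Reverse complement; ``N`` maps to ``N``."""
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise SequenceFormatError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


def translate_codon(codon: str) -> str:
    """Translate one codon under the standard genetic code.

    Returns the one-letter amino acid, or ``"*"`` for a stop codon.
    """
    if len(codon) != 3:
        raise ValueError(f"codon must be exactly 3 nt, got {codon!r}")
    codon = codon.upper()
    if set(codon) - (DNA_ALPHABET - {"N"}):
        raise ValueError(f"codon contains non-ACGT characters: {codon!r}")
    if codon in standard_dna_table.stop_codons:
        return "*"
    return standard_dna_table.forward_table[codon]


def is_stop(codon: str) -> bool:
    return translate_codon(codon) == "*"


def read_fasta(path: Union[str, Path, io.TextIOBase]) -> list[GenomeSequence]:
    """Read a (multi-record) FASTA file into :class:`GenomeSequence` records.

    Sequences are uppercased; ``U`` is rejected (DNA only); empty sequences
    or duplicate/empty headers raise :class:`SequenceFormatError`.
    """
    records = []
    seen: set[str] = set()
    for rec in SeqIO.parse(path if not isinstance(path, Path) else str(path), "fasta"):
        name = rec.id
        if not name:
            raise SequenceFormatError("FASTA record with empty header")
        if name in seen:
            raise SequenceFormatError(f"duplicate FASTA header {name!r}")
        seen.add(name)
        seq = str(rec.seq).upper()
        if not seq:
            raise SequenceFormatError(f"FASTA record {name!r} has an empty sequence")
        if "U" in seq:
            raise SequenceFormatError(
                f"record {name!r} contains U; RNA input is not accepted"
            )
        try:
            records.append(GenomeSequence(name=name, seq=seq))
        except SequenceFormatError as exc:
            raise SequenceFormatError(f"record {name!r}: {exc}") from exc
    if not records:
        raise SequenceFormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[GenomeSequence], path: Union[str, Path]) -> None:
    """Write records as wrapped FASTA (70 columns)."""
    seq_records = [
        SeqRecord(Seq(r.seq), id=r.name, description="") for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=70)
        writer.write_file(seq_records)


def iupac_match(pattern_char: str, base: str) -> bool:
    """Does ``base`` satisfy the IUPAC ``pattern_char``? ``N`` in the genome
    matches nothing (conservative)."""
    if pattern_char not in IUPAC:
        raise ValueError(f"invalid IUPAC code {pattern_char!r}")
    return base in IUPAC[pattern_char]


def iupac_lut(pattern_char: str) -> np.ndarray:
    """Boolean lookup over base codes 0..4 for one IUPAC pattern position."""
    if pattern_char not in IUPAC:
        raise ValueError(f"invalid IUPAC code {pattern_char!r}")
    lut = np.zeros(5, dtype=bool)
    for b in IUPAC[pattern_char]:
        lut[BASE_CODES[b]] = True
    return lut
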