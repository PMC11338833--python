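"""Per-position nucleotide counts from aligned reads.

The central statistic is the *read mismatch frequency*: at each reference
position, the number of aligned reads differing from the reference divided
by total aligned coverage. Only aligned (match/mismatch) bases contribute;
insertions add nothing, deleted positions add nothing to coverage, and
unmapped, secondary and supplementary records are skipped. No base- or
mapping-quality filtering is applied by default and duplicates are not
removed; both are exposed as optional thresholds.

Columns with zero coverage, or whose reference base is ``N``, carry an
undefined mismatch frequency (NaN) and are excluded from downstream
comparisons rather than treated as zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
import pysam

from .seqcore import CODE_BASES, GenomeSequence, GenomicInterval

_BASES = "ACGT"


class ContigMismatchError(ValueError):
    """SAM header contigs do not match the provided reference."""


@dataclass(frozen=True)
class PileupColumn:
    """Counts at one reference position.

    ``mismatch_frequency`` is None when undefined (zero coverage or
    reference N).
    """

    contig: str
    pos: int  # 0-based
    ref_base: str
    counts: dict[str, int]
    coverage: int
    mismatch_frequency: Optional[float]

    @property
    def defined(self) -> bool:
        return self.mismatch_frequency is not None


def base_frequencies(column: PileupColumn) -> dict[str, float]:
    """Per-base fractions at a covered column; they sum to 1."""
    if column.coverage == 0:
        raise ValueError(
            f"base frequencies undefined at {column.contig}:{column.pos + 1} "
            "(zero coverage)"
        )
    return {b: column.counts[b] / column.coverage for b in _BASES}


class PileupTable:
    """Nucleotide count matrices for one sample over a reference.

    Internally one ``(length, 4)`` uint32 matrix per contig (columns A,C,G,T
    in that order). Rows with zero coverage or reference N have NaN mismatch
    frequency.
    """

    def __init__(
        self,
        references: Sequence[GenomeSequence],
        counts: dict[str, np.ndarray],
        sample_label: str = "",
    ) -> None:
        self.refs = {r.name: r for r in references}
        for name, mat in counts.items():
            if name not in self.refs:
                raise ContigMismatchError(f"counts for unknown contig {name!r}")
            if mat.shape != (len(self.refs[name]), 4):
                raise ValueError(f"count matrix shape mismatch for {name!r}")
        self.counts = counts
        self.sample_label = sample_label
        self._ref_codes = {name: r.codes() for name, r in self.refs.items()}

    @property
    def contigs(self) -> list[str]:
        return list(self.refs)

    def coverage(self, contig: str) -> np.ndarray:
        return self.counts[contig].sum(axis=1)

    @property
    def mean_coverage(self) -> float:
        total = sum(int(self.coverage(c).sum()) for c in self.contigs)
        length = sum(len(r) for r in self.refs.values())
        return total / length if length else 0.0

    def ref_match_counts(self, contig: str) -> np.ndarray:
        """Count of reads agreeing with the reference at each position."""
        codes = self._ref_codes[contig]
        mat = self.counts[contig]
        out = np.zeros(len(codes), dtype=np.uint32)
        acgt = codes < 4
        out[acgt] = mat[acgt, codes[acgt]]
        return out

    def mismatch_frequency(self, contig: str) -> np.ndarray:
        """Read mismatch frequency per position; NaN where undefined."""
        cov = self.coverage(contig).astype(float)
        match = self.ref_match_counts(contig).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = (cov - match) / cov
        freq[cov == 0] = np.nan
        freq[self._ref_codes[contig] == 4] = np.nan
        return freq

    def max_base_frequency(self, contig: str) -> np.ndarray:
        """Highest non-reference per-base fraction at each position.

        Ties between bases are irrelevant for the value itself; NaN where
        the column is undefined.
        """
        mat = self.counts[contig].astype(float)
        codes = self._ref_codes[contig]
        masked = mat.copy()
        acgt = codes < 4
        masked[acgt, codes[acgt]] = 0.0
        cov = mat.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = masked.max(axis=1) / cov
        out[cov == 0] = np.nan
        out[codes == 4] = np.nan
        return out

    def column(self, contig: str, pos: int) -> PileupColumn:
        row = self.counts[contig][pos]
        cov = int(row.sum())
        ref_code = int(self._ref_codes[contig][pos])
        ref_base = CODE_BASES[ref_code]
        if cov == 0 or ref_base == "N":
            freq = None
        else:
            freq = float(cov - row[ref_code]) / cov
        return PileupColumn(
            contig=contig,
            pos=pos,
            ref_base=ref_base,
            counts={b: int(row[i]) for i, b in enumerate(_BASES)},
            coverage=cov,
            mismatch_frequency=freq,
        )

    def to_frame(
        self, intervals: Optional[Sequence[GenomicInterval]] = None
    ) -> pd.DataFrame:
        """Per-position TSV-ready table (pos 1-based inclusive)."""
        if intervals is None:
            intervals = [
                GenomicInterval(name, 0, len(r))
                for name, r in self.refs.items()
            ]
        frames = []
        for iv in intervals:
            mat = self.counts[iv.contig][iv.start : iv.end]
            codes = self._ref_codes[iv.contig][iv.start : iv.end]
            freq = self.mismatch_frequency(iv.contig)[iv.start : iv.end]
            frames.append(
                pd.DataFrame(
                    {
                        "contig": iv.contig,
                        "pos": np.arange(iv.start + 1, iv.end + 1),
                        "ref": [CODE_BASES[c] for c in codes],
                        "A": mat[:, 0], "C": mat[:, 1],
                        "G": mat[:, 2], "T": mat[:, 3],
                        "coverage": mat.sum(axis=1),
                        "mismatch_frequency": freq,
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        references: Sequence[GenomeSequence],
        sample_label: str = "",
    ) -> "PileupTable":
        """Rebuild count matrices from a ``to_frame`` table."""
        counts = {
            r.name: np.zeros((len(r), 4), dtype=np.uint32) for r in references
        }
        for contig, sub in frame.groupby("contig"):
            if contig not in counts:
                raise ContigMismatchError(f"unknown contig {contig!r} in table")
            idx = sub["pos"].to_numpy() - 1
            for i, b in enumerate(_BASES):
                counts[contig][idx, i] = sub[b].to_numpy()
        return cls(references, counts, sample_label=sample_label)


def _read_codes(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.uint8)
    for i, base in enumerate(_BASES):
        out[arr == ord(base)] = i
    return out


def build_pileup(
    alignments: Union[str, Path, pysam.AlignmentFile],
    reference: Union[GenomeSequence, Sequence[GenomeSequence]],
    intervals: Optional[Sequence[GenomicInterval]] = None,
    sample_label: str = "",
    min_baseq: int = 0,
    min_mapq: int = 0,
) -> PileupTable:
    """Build a :class:`PileupTable` from a SAM file.

    ``intervals`` restricts which positions are *counted* (reads overlapping
    an interval still contribute only inside it); by default the whole
    reference is piled up.
    """
    refs = [reference] if isinstance(reference, GenomeSequence) else list(reference)
    ref_by_name = {r.name: r for r in refs}

    own_handle = not isinstance(alignments, pysam.AlignmentFile)
    sam = (
        pysam.AlignmentFile(str(alignments), "r", check_sq=False)
        if own_handle
        else alignments
    )
    try:
        for name, length in zip(sam.references, sam.lengths):
            if name not in ref_by_name:
                raise ContigMismatchError(
                    f"SAM contig {name!r} absent from the reference"
                )
            if length != len(ref_by_name[name]):
                raise ContigMismatchError(
                    f"SAM contig {name!r} length {length} != reference "
                    f"{len(ref_by_name[name])}"
                )

        counts = {r.name: np.zeros((len(r), 4), dtype=np.uint32) for r in refs}
        pos_buf: dict[str, list[np.ndarray]] = {r.name: [] for r in refs}
        code_buf: dict[str, list[np.ndarray]] = {r.name: [] for r in refs}

        for read in sam:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            if read.mapping_quality < min_mapq:
                continue
            qseq = read.query_sequence
            if qseq is None:
                continue
            contig = read.reference_name
            cigar = read.cigartuples
            if cigar is not None and len(cigar) == 1 and cigar[0][0] == 0:
                # fast path: a single M run
                n = cigar[0][1]
                rpos = np.arange(read.reference_start, read.reference_start + n)
                codes = _read_codes(qseq[:n])
            else:
                pairs = read.get_aligned_pairs(matches_only=True)
                if not pairs:
                    continue
                qidx = np.fromiter((q for q, _ in pairs), dtype=np.int64)
                rpos = np.fromiter((r for _, r in pairs), dtype=np.int64)
                codes = _read_codes(qseq)[qidx]
            if min_baseq > 0 and read.query_qualities is not None:
                quals = np.asarray(read.query_qualities, dtype=np.int16)
                if cigar is not None and len(cigar) == 1 and cigar[0][0] == 0:
                    qmask = quals[: len(codes)] >= min_baseq
                else:
                    qmask = quals[qidx] >= min_baseq
                rpos, codes = rpos[qmask], codes[qmask]
            valid = codes < 4  # drop read Ns
            pos_buf[contig].append(rpos[valid])
            code_buf[contig].append(codes[valid])
    finally:
        if own_handle:
            sam.close()

    for name in counts:
        if pos_buf[name]:
            allpos = np.concatenate(pos_buf[name])
            allcodes = np.concatenate(code_buf[name])
            np.add.at(counts[name], (allpos, allcodes), 1)

    if intervals is not None:
        mask = {name: np.zeros(len(r), dtype=bool) for name, r in ref_by_name.items()}
        for iv in intervals:
            mask[iv.contig][iv.start : iv.end] = True
        for name in counts:
            counts[name][~mask[name]] = 0

    return PileupTable(refs, counts, sample_label=sample_label)
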