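"""Genome-wide enumeration of candidate off-target protospacers.

A candidate is any 20-nt window on either strand followed 3′ by a PAM match,
with at most ``max_mm`` mismatches to the guide spacer, of which at most
``max_mm_proximal`` fall in the PAM-proximal nucleotides (positions 11–20
for a proximal length of 10). Mismatches there most strongly abolish
Cas9-family targeting, hence the tighter constraint. The PAM itself is
matched against its IUPAC pattern and never counted as a mismatch; genomic
``N`` mismatches everything and never satisfies a PAM position.

``find_candidates`` is a vectorized scan over the base-code array;
``brute_force_candidates`` is a deliberately naive per-window comparison
kept as the correctness oracle — the two must agree exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .guide_design import SPACER_LENGTH, GuideSpec, ProtospacerSite
from .seqcore import GenomeSequence, GenomicInterval, iupac_lut, IUPAC, revcomp

DEFAULT_MAX_MM = 7
DEFAULT_MAX_MM_PROXIMAL = 2
DEFAULT_PROXIMAL_LEN = 10


@dataclass(frozen=True)
class CandidateSite:
    """A protospacer occurrence similar enough to the guide to audit."""

    site: ProtospacerSite
    mismatches_total: int
    mismatches_proximal: int
    mismatch_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.mismatch_positions) != self.mismatches_total:
            raise ValueError("mismatch_positions inconsistent with total count")

    @property
    def is_on_target(self) -> bool:
        return self.mismatches_total == 0

    def sort_key(self):
        iv = self.site.interval
        return (iv.contig, iv.start, iv.strand)


def _validate(spec: GuideSpec, max_mm: int, max_mm_proximal: int,
              proximal_len: int) -> None:
    if proximal_len > len(spec.spacer):
        raise ValueError(
            f"proximal_len {proximal_len} exceeds spacer length {len(spec.spacer)}"
        )
    if max_mm < 0 or max_mm_proximal < 0:
        raise ValueError("mismatch limits must be non-negative")


def _strand_sites(
    genome: GenomeSequence,
    strand: str,
    spacer_codes: np.ndarray,
    luts: list[np.ndarray],
    max_mm: int,
    max_mm_proximal: int,
    proximal_len: int,
) -> list[CandidateSite]:
    length = len(spacer_codes)
    pam_len = len(luts)
    L = len(genome)
    seq = genome.seq if strand == "+" else revcomp(genome.seq)
    codes = GenomeSequence(name=genome.name, seq=seq).codes()
    n_win = L - length - pam_len + 1
    if n_win <= 0:
        return []

    pam_ok = np.ones(n_win, dtype=bool)
    for j, lut in enumerate(luts):
        pam_ok &= lut[codes[length + j : length + j + n_win]]
    idx = np.flatnonzero(pam_ok)
    if idx.size == 0:
        return []

    # mismatch matrix only at PAM-anchored windows; N (code 4) never equals
    # a spacer code so it is automatically a mismatch
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)[idx]
    mm = windows != spacer_codes[np.newaxis, :]
    total = mm.sum(axis=1)
    proximal = mm[:, length - proximal_len :].sum(axis=1)
    keep = (total <= max_mm) & (proximal <= max_mm_proximal)

    out: list[CandidateSite] = []
    for k in np.flatnonzero(keep):
        i = int(idx[k])
        positions = tuple(int(p) + 1 for p in np.flatnonzero(mm[k]))
        if strand == "+":
            proto = GenomicInterval(genome.name, i, i + length, "+")
            pam = GenomicInterval(genome.name, i + length, i + length + pam_len, "+")
        else:
            g_start = L - (i + length)
            proto = GenomicInterval(genome.name, g_start, g_start + length, "-")
            pam = GenomicInterval(genome.name, g_start - pam_len, g_start, "-")
        out.append(
            CandidateSite(
                site=ProtospacerSite(
                    interval=proto,
                    pam_interval=pam,
                    protospacer_seq=seq[i : i + length],
                    pam_seq=seq[i + length : i + length + pam_len],
                ),
                mismatches_total=int(total[k]),
                mismatches_proximal=int(proximal[k]),
                mismatch_positions=positions,
            )
        )
    return out


def find_candidates(
    genome: GenomeSequence,
    spec: GuideSpec,
    max_mm: int = DEFAULT_MAX_MM,
    max_mm_proximal: int = DEFAULT_MAX_MM_PROXIMAL,
    proximal_len: int = DEFAULT_PROXIMAL_LEN,
) -> list[CandidateSite]:
    """Vectorized candidate scan over both strands of ``genome``.

    The on-target site (zero mismatches) is returned and flagged, not
    suppressed. Result sorted by (contig, start, strand).
    """
    _validate(spec, max_mm, max_mm_proximal, proximal_len)
    spacer_codes = GenomeSequence(name="spacer", seq=spec.spacer).codes()
    luts = [iupac_lut(ch) for ch in spec.pam_pattern]
    sites: list[CandidateSite] = []
    for strand in "+-":
        sites.extend(
            _strand_sites(
                genome, strand, spacer_codes, luts,
                max_mm, max_mm_proximal, proximal_len,
            )
        )
    sites.sort(key=CandidateSite.sort_key)
    return sites


def brute_force_candidates(
    genome: GenomeSequence,
    spec: GuideSpec,
    max_mm: int = DEFAULT_MAX_MM,
    max_mm_proximal: int = DEFAULT_MAX_MM_PROXIMAL,
    proximal_len: int = DEFAULT_PROXIMAL_LEN,
) -> list[CandidateSite]:
    """Literal per-window character comparison; the test oracle."""
    _validate(spec, max_mm, max_mm_proximal, proximal_len)
    length = len(spec.spacer)
    pam_len = len(spec.pam_pattern)
    pam_sets = [set(IUPAC[ch]) for ch in spec.pam_pattern]
    L = len(genome)
    out: list[CandidateSite] = []
    for strand in "+-":
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        for i in range(L - length - pam_len + 1):
            pam = seq[i + length : i + length + pam_len]
            if any(pam[j] not in pam_sets[j] for j in range(pam_len)):
                continue
            window = seq[i : i + length]
            positions = [
                p + 1 for p in range(length)
                if window[p] != spec.spacer[p] or window[p] == "N"
            ]
            proximal = sum(1 for p in positions if p > length - proximal_len)
            if len(positions) > max_mm or proximal > max_mm_proximal:
                continue
            if strand == "+":
                proto = GenomicInterval(genome.name, i, i + length, "+")
                pam_iv = GenomicInterval(
                    genome.name, i + length, i + length + pam_len, "+"
                )
            else:
                g_start = L - (i + length)
                proto = GenomicInterval(genome.name, g_start, g_start + length, "-")
                pam_iv = GenomicInterval(genome.name, g_start - pam_len, g_start, "-")
            out.append(
                CandidateSite(
                    site=ProtospacerSite(
                        interval=proto, pam_interval=pam_iv,
                        protospacer_seq=window, pam_seq=pam,
                    ),
                    mismatches_total=len(positions),
                    mismatches_proximal=proximal,
                    mismatch_positions=tuple(positions),
                )
            )
    out.sort(key=CandidateSite.sort_key)
    return out


def candidates_to_frame(candidates: list[CandidateSite]) -> pd.DataFrame:
    """TSV-ready report; coordinates 1-based inclusive."""
    rows = []
    for c in candidates:
        s1, e1 = c.site.interval.as_1based()
        rows.append(
            {
                "contig": c.site.interval.contig,
                "start": s1,
                "end": e1,
                "strand": c.site.strand,
                "protospacer": c.site.protospacer_seq,
                "pam": c.site.pam_seq,
                "mm_total": c.mismatches_total,
                "mm_proximal": c.mismatches_proximal,
                "mismatch_positions": ",".join(map(str, c.mismatch_positions)),
                "is_on_target": c.is_on_target,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "protospacer", "pam",
            "mm_total", "mm_proximal", "mismatch_positions", "is_on_target",
        ],
    )
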