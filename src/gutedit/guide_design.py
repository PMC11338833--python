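"""Protospacer enumeration and inactivating guide design.

Two design goals are supported, matching how base editors are used to knock
out bacterial genes:

* **CBE premature stop** — a cytosine base editor (C→T on the protospacer
  strand) converts a sense codon into a stop codon. Achievable through the
  sense-strand codons CAA→TAA, CAG→TAG, CGA→TGA, or through TGG, whose
  antisense CCA offers two editable cytosines (products TAG, TGA or TAA).
* **ABE start-codon disruption** — an adenine base editor (A→G) destroys the
  ATG start codon, either from a template-strand protospacer (coding
  ATG→ACG) or from a coding-strand protospacer (ATG→GTG).

Protospacer positions are numbered 1–20 from the PAM-distal 5′ end, so
"position 7" sits 14 nt from the PAM. The canonical deaminase editing window
is positions 4–8; editable bystander bases are additionally reported over
positions 1–12 because edits outside the canonical window are routinely
observed at high coverage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .seqcore import (
    GenomeSequence,
    GenomicInterval,
    is_stop,
    iupac_lut,
    revcomp,
    translate_codon,
)

SPACER_LENGTH = 20
DEFAULT_WINDOW = (4, 8)
#: positions over which editable bystander bases are reported
BYSTANDER_SCAN = (1, 12)

_EDITOR_CHEMISTRY = {"ABE": ("A", "G"), "CBE": ("C", "T")}


@dataclass(frozen=True)
class GuideSpec:
    """A guide RNA plus the base-editor chemistry acting through it.

    ``spacer`` is written 5′→3′ on the protospacer strand; position 1 is the
    PAM-distal end. ``edited_base``/``product_base`` follow from the editor:
    A→G for ABE, C→T for CBE.
    """

    spacer: str
    editor: str
    pam_pattern: str = "NGG"
    window: tuple[int, int] = DEFAULT_WINDOW

    def __post_init__(self) -> None:
        if len(self.spacer) != SPACER_LENGTH:
            raise ValueError(
                f"spacer must be {SPACER_LENGTH} nt, got {len(self.spacer)}"
            )
        if set(self.spacer) - set("ACGT"):
            raise ValueError(f"spacer must be over ACGT: {self.spacer!r}")
        if self.editor not in _EDITOR_CHEMISTRY:
            raise ValueError(f"editor must be ABE or CBE, got {self.editor!r}")
        lo, hi = self.window
        if not (1 <= lo <= hi <= SPACER_LENGTH):
            raise ValueError(f"window {self.window} must lie within [1, 20]")
        for ch in self.pam_pattern:
            iupac_lut(ch)  # raises on invalid IUPAC

    @property
    def edited_base(self) -> str:
        return _EDITOR_CHEMISTRY[self.editor][0]

    @property
    def product_base(self) -> str:
        return _EDITOR_CHEMISTRY[self.editor][1]

    def in_window(self, position: int) -> bool:
        return self.window[0] <= position <= self.window[1]


@dataclass(frozen=True)
class ProtospacerSite:
    """A 20-nt protospacer occurrence with its adjacent PAM.

    ``protospacer_seq`` is on the protospacer strand; for minus-strand sites
    the PAM interval lies at lower genomic coordinates than the protospacer.
    """

    interval: GenomicInterval
    pam_interval: GenomicInterval
    protospacer_seq: str
    pam_seq: str

    @property
    def strand(self) -> str:
        return self.interval.strand

    def genomic_position(self, position: int) -> int:
        """0-based genomic coordinate of protospacer ``position`` (1–20)."""
        if not 1 <= position <= len(self.protospacer_seq):
            raise ValueError(f"protospacer position {position} out of range")
        if self.strand == "+":
            return self.interval.start + position - 1
        return self.interval.end - position

    def protospacer_position(self, genomic_pos: int) -> Optional[int]:
        """Protospacer position (1–20) of a genomic coordinate, or None."""
        if not self.interval.start <= genomic_pos < self.interval.end:
            return None
        if self.strand == "+":
            return genomic_pos - self.interval.start + 1
        return self.interval.end - genomic_pos

    def base_at(self, position: int) -> str:
        return self.protospacer_seq[position - 1]


@dataclass(frozen=True)
class GuideDesign:
    """One way a protospacer can inactivate its target gene."""

    site: ProtospacerSite
    goal: str  # STOP_INTRODUCTION | START_DISRUPTION
    edited_positions: tuple[int, ...]
    predicted_codon_change: tuple[str, str]
    bystander_positions: tuple[int, ...]
    codon_index: Optional[int] = None  # 0-based codon within the CDS
    design_class: Optional[str] = None  # ABE: template_ACG | coding_GTG

    @property
    def spacer(self) -> str:
        return self.site.protospacer_seq


def enumerate_protospacers(
    genome: GenomeSequence,
    pam_pattern: str = "NGG",
    length: int = SPACER_LENGTH,
) -> list[ProtospacerSite]:
    """All length-nt windows followed 3′ by a PAM match, on both strands.

    Overlapping sites are all reported; the result is sorted by
    (contig, start, strand).
    """
    pam_len = len(pam_pattern)
    luts = [iupac_lut(ch) for ch in pam_pattern]
    sites: list[ProtospacerSite] = []
    L = len(genome)
    if L < length + pam_len:
        return sites

    for strand in "+-":
        seq = genome.seq if strand == "+" else revcomp(genome.seq)
        codes = GenomeSequence(name=genome.name, seq=seq).codes()
        n_win = L - length - pam_len + 1
        pam_ok = np.ones(n_win, dtype=bool)
        for j, lut in enumerate(luts):
            pam_ok &= lut[codes[length + j : length + j + n_win]]
        for i in np.flatnonzero(pam_ok):
            i = int(i)
            if strand == "+":
                proto = GenomicInterval(genome.name, i, i + length, "+")
                pam = GenomicInterval(genome.name, i + length, i + length + pam_len, "+")
            else:
                g_start = L - (i + length)
                proto = GenomicInterval(genome.name, g_start, g_start + length, "-")
                pam = GenomicInterval(genome.name, g_start - pam_len, g_start, "-")
            sites.append(
                ProtospacerSite(
                    interval=proto,
                    pam_interval=pam,
                    protospacer_seq=seq[i : i + length],
                    pam_seq=seq[i + length : i + length + pam_len],
                )
            )
    sites.sort(key=lambda s: (s.interval.contig, s.interval.start, s.strand))
    return sites


def _coding_base_after_edit(
    genome_base: str, proto_strand: str, cds_strand: str, edited: str, product: str
) -> Optional[str]:
    """Coding-strand base after applying the editor at one genomic position.

    Returns None when the protospacer-strand base is not the editable base.
    """
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    proto_base = genome_base if proto_strand == "+" else comp[genome_base]
    if proto_base != edited:
        return None
    new_genome_base = product if proto_strand == "+" else comp[product]
    return new_genome_base if cds_strand == "+" else comp[new_genome_base]


def _cds_offset(genomic_pos: int, cds: GenomicInterval) -> Optional[int]:
    """0-based offset within the CDS (reading direction), or None if outside."""
    if not cds.start <= genomic_pos < cds.end:
        return None
    if cds.strand == "+":
        return genomic_pos - cds.start
    return cds.end - 1 - genomic_pos


def _window_centre(spec: GuideSpec) -> float:
    return (spec.window[0] + spec.window[1]) / 2.0


def _sort_designs(designs: list[GuideDesign], spec: GuideSpec) -> list[GuideDesign]:
    centre = _window_centre(spec)
    return sorted(
        designs,
        key=lambda d: (
            min(abs(p - centre) for p in d.edited_positions),
            d.site.interval.start,
            d.site.strand,
            d.predicted_codon_change[1],
        ),
    )


def _editable_positions(site: ProtospacerSite, spec: GuideSpec,
                        lo: int, hi: int) -> list[int]:
    return [
        p for p in range(lo, hi + 1)
        if p <= SPACER_LENGTH and site.base_at(p) == spec.edited_base
    ]


def design_cbe_stop_guides(
    cds_seq: str,
    cds_interval: GenomicInterval,
    genome: GenomeSequence,
    spec: GuideSpec,
) -> list[GuideDesign]:
    """Find every protospacer whose in-window C→T edits create an in-frame stop.

    For each candidate protospacer, editable in-window cytosines are grouped
    by the CDS codon they fall in, and all edit subsets of a codon are tried;
    a design is emitted per (site, codon, achievable stop product). Each
    predicted codon change is re-verified through translation.
    """
    if len(cds_seq) % 3 != 0:
        raise ValueError("CDS length must be a multiple of 3")
    if spec.editor != "CBE":
        raise ValueError("stop-introduction design requires a CBE spec")
    genomic_cds = genome.seq[cds_interval.start : cds_interval.end]
    if cds_interval.strand == "-":
        genomic_cds = revcomp(genomic_cds)
    if genomic_cds != cds_seq.upper():
        raise ValueError("cds_seq does not match the genome at cds_interval")

    designs: list[GuideDesign] = []
    for site in enumerate_protospacers(genome, spec.pam_pattern):
        window_cs = _editable_positions(site, spec, *spec.window)
        if not window_cs:
            continue
        # group editable window positions by the codon they fall in
        by_codon: dict[int, list[tuple[int, int]]] = {}
        for p in window_cs:
            g = site.genomic_position(p)
            off = _cds_offset(g, cds_interval)
            if off is None:
                continue
            by_codon.setdefault(off // 3, []).append((p, off % 3))

        bystander_all = _editable_positions(site, spec, *BYSTANDER_SCAN)
        for codon_idx, placed in by_codon.items():
            from_codon = cds_seq[codon_idx * 3 : codon_idx * 3 + 3]
            if is_stop(from_codon):
                continue
            seen_products: set[str] = set()
            for r in range(1, len(placed) + 1):
                for subset in itertools.combinations(placed, r):
                    codon = list(from_codon)
                    ok = True
                    for p, frame in subset:
                        g = site.genomic_position(p)
                        new = _coding_base_after_edit(
                            genome.seq[g], site.strand, cds_interval.strand,
                            spec.edited_base, spec.product_base,
                        )
                        if new is None:
                            ok = False
                            break
                        codon[frame] = new
                    product = "".join(codon)
                    if not ok or product in seen_products or not is_stop(product):
                        continue
                    seen_products.add(product)
                    assert translate_codon(product) == "*"
                    edited = tuple(sorted(p for p, _ in subset))
                    designs.append(
                        GuideDesign(
                            site=site,
                            goal="STOP_INTRODUCTION",
                            edited_positions=edited,
                            predicted_codon_change=(from_codon, product),
                            bystander_positions=tuple(
                                p for p in bystander_all if p not in edited
                            ),
                            codon_index=codon_idx,
                        )
                    )
    return _sort_designs(designs, spec)


def design_abe_start_disruption(
    cds_interval: GenomicInterval,
    genome: GenomeSequence,
    spec: GuideSpec,
) -> list[GuideDesign]:
    """Find ABE protospacers that destroy a CDS's ATG start codon.

    Class ``template_ACG``: the protospacer lies on the template strand and
    the adenine pairing with the coding-strand T of ATG falls in-window
    (coding ATG→ACG). Class ``coding_GTG``: the protospacer lies on the
    coding strand and the start A itself falls in-window (ATG→GTG).
    """
    if spec.editor != "ABE":
        raise ValueError("start-disruption design requires an ABE spec")
    start_codon = genome.seq[cds_interval.start : cds_interval.end][:3]
    if cds_interval.strand == "-":
        start_codon = revcomp(
            genome.seq[cds_interval.end - 3 : cds_interval.end]
        )
    if start_codon != "ATG":
        raise ValueError(f"CDS does not begin with ATG (got {start_codon!r})")

    # genomic coordinates of the coding A and T of the start codon
    if cds_interval.strand == "+":
        g_a, g_t = cds_interval.start, cds_interval.start + 1
    else:
        g_a, g_t = cds_interval.end - 1, cds_interval.end - 2

    template_strand = "-" if cds_interval.strand == "+" else "+"
    designs: list[GuideDesign] = []
    for site in enumerate_protospacers(genome, spec.pam_pattern):
        if site.strand == template_strand:
            p = site.protospacer_position(g_t)
            change, klass = ("ATG", "ACG"), "template_ACG"
        elif site.strand == cds_interval.strand:
            p = site.protospacer_position(g_a)
            change, klass = ("ATG", "GTG"), "coding_GTG"
        else:  # pragma: no cover
            continue
        if p is None or not spec.in_window(p) or site.base_at(p) != "A":
            continue
        bystanders = tuple(
            q for q in _editable_positions(site, spec, *BYSTANDER_SCAN) if q != p
        )
        designs.append(
            GuideDesign(
                site=site,
                goal="START_DISRUPTION",
                edited_positions=(p,),
                predicted_codon_change=change,
                bystander_positions=bystanders,
                codon_index=0,
                design_class=klass,
            )
        )
    return _sort_designs(designs, spec)


def designs_to_frame(designs: list[GuideDesign]) -> pd.DataFrame:
    """Tabular report of designs; coordinates 1-based inclusive."""
    rows = []
    for d in designs:
        s1, e1 = d.site.interval.as_1based()
        rows.append(
            {
                "contig": d.site.interval.contig,
                "start": s1,
                "end": e1,
                "strand": d.site.strand,
                "spacer": d.spacer,
                "pam": d.site.pam_seq,
                "goal": d.goal,
                "edited_positions": ",".join(map(str, d.edited_positions)),
                "codon_change": "->".join(d.predicted_codon_change),
                "bystanders": ",".join(map(str, d.bystander_positions)),
                "design_class": d.design_class or "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "start", "end", "strand", "spacer", "pam", "goal",
            "edited_positions", "codon_change", "bystanders", "design_class",
        ],
    )
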