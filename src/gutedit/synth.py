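"""Synthetic data with the statistical structure the analysis assumes.

Four generators, one per experimental readout:

* ``make_genome`` — an i.i.d. random genome with one planted on-target
  protospacer (concrete PAM) and optional near-match decoys at exact
  (total, PAM-proximal) mismatch counts;
* ``simulate_reads`` — fixed-length single-end reads at a target fold
  coverage, edited per molecule at the target/bystander fractions, with a
  uniform per-base substitution error, written as FASTQ plus a truth SAM
  (exact coordinates, M-only CIGARs — no aligner in the loop);
* ``simulate_droplets`` — two genotypes multinomially partitioned into
  droplets, a channel positive when at least one copy of its genotype lands
  in the droplet;
* ``simulate_plating`` — binomial survival of unedited cells on selective
  plates, with the fold-reduction computed against an untreated control.

All randomness flows through one ``numpy`` generator seeded from the
config, so identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pysam

from .ddpcr import DropletCounts
from .edit_quant import PlateCounts, compute_fold_reduction
from .guide_design import SPACER_LENGTH, GuideSpec, ProtospacerSite
from .seqcore import CODE_BASES, GenomeSequence, GenomicInterval, IUPAC

_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)  # A<->T, C<->G


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for read simulation.

    Defaults mirror the deep-sequencing arm of a base-editing audit:
    ~6,000-fold coverage of 150-nt reads with a 0.3% per-base substitution
    error, on a small (2 kb) surrogate genome.
    """

    seed: int
    genome_length: int = 2000
    gc: float = 0.5
    coverage: float = 6000.0
    read_length: int = 150
    error_rate: float = 0.003
    decoy_sites: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.gc <= 1:
            raise ValueError("gc must be in [0, 1]")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")
        for mm, prox in self.decoy_sites:
            if prox > mm:
                raise ValueError(
                    f"decoy proximal mismatches {prox} exceed total {mm}"
                )


@dataclass(frozen=True)
class EditTruth:
    """Ground-truth per-molecule editing state for one site."""

    site: ProtospacerSite
    spec: GuideSpec
    target_position: int
    target_fraction: float
    bystander_fractions: dict[int, float] = field(default_factory=dict)
    linkage: str = "independent"  # or "conditional-on-target"

    def __post_init__(self) -> None:
        fractions = [self.target_fraction, *self.bystander_fractions.values()]
        if any(not 0 <= f <= 1 for f in fractions):
            raise ValueError("edit fractions must lie in [0, 1]")
        if self.linkage not in ("independent", "conditional-on-target"):
            raise ValueError(f"unknown linkage model {self.linkage!r}")
        if self.linkage == "conditional-on-target":
            for p, f in self.bystander_fractions.items():
                if f > self.target_fraction:
                    raise ValueError(
                        f"conditional linkage needs bystander fraction at {p} "
                        "<= target fraction"
                    )


def _concrete_pam(pattern: str) -> str:
    """A deterministic concrete PAM satisfying the IUPAC pattern."""
    return "".join(sorted(IUPAC[ch])[0] for ch in pattern)


def make_genome(
    config: SimConfig, spec: GuideSpec
) -> tuple[GenomeSequence, dict]:
    """Random genome with the on-target site and requested decoys planted.

    Sites (protospacer + concrete PAM, plus strand) are placed at evenly
    spaced, non-overlapping offsets; each decoy carries exactly the
    requested (total, proximal) mismatch counts against the spacer, with
    mismatch positions and substituted bases drawn from the seeded RNG. The
    manifest records every planted site's truth coordinates.
    """
    if config.genome_length < 1000:
        raise ValueError("genome_length must be at least 1 kb")
    rng = np.random.default_rng(config.seed)
    L = config.genome_length
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    codes = rng.choice(4, size=L, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)

    pam = _concrete_pam(spec.pam_pattern)
    site_len = SPACER_LENGTH + len(pam)
    n_sites = 1 + len(config.decoy_sites)
    if L < n_sites * (site_len + 100):
        raise ValueError(
            f"genome of {L} nt too short to plant {n_sites} spaced sites"
        )
    anchors = [
        int(round((k + 1) * L / (n_sites + 1))) for k in range(n_sites)
    ]

    proximal_len = 10
    sites_manifest = []
    contig = f"synthetic_genome_seed{config.seed}"
    planted: list[ProtospacerSite] = []
    for k, start in enumerate(anchors):
        if k == 0:
            proto_seq = spec.spacer
            mm_positions: list[int] = []
        else:
            mm, prox = config.decoy_sites[k - 1]
            distal = mm - prox
            if distal > SPACER_LENGTH - proximal_len or prox > proximal_len:
                raise ValueError(
                    f"cannot place {mm} mismatches with {prox} proximal "
                    f"in a {SPACER_LENGTH}-nt protospacer"
                )
            distal_pos = rng.choice(
                np.arange(1, SPACER_LENGTH - proximal_len + 1),
                size=distal, replace=False,
            )
            prox_pos = rng.choice(
                np.arange(SPACER_LENGTH - proximal_len + 1, SPACER_LENGTH + 1),
                size=prox, replace=False,
            )
            mm_positions = sorted(int(p) for p in np.concatenate([distal_pos, prox_pos]))
            proto = list(spec.spacer)
            for p in mm_positions:
                alternatives = [b for b in "ACGT" if b != proto[p - 1]]
                proto[p - 1] = alternatives[int(rng.integers(3))]
            proto_seq = "".join(proto)
        full = proto_seq + pam
        codes[start : start + site_len] = [
            "ACGT".index(b) for b in full
        ]
        interval = GenomicInterval(contig, start, start + SPACER_LENGTH, "+")
        pam_iv = GenomicInterval(
            contig, start + SPACER_LENGTH, start + site_len, "+"
        )
        planted.append(
            ProtospacerSite(
                interval=interval, pam_interval=pam_iv,
                protospacer_seq=proto_seq, pam_seq=pam,
            )
        )
        sites_manifest.append(
            {
                "kind": "on_target" if k == 0 else "decoy",
                "contig": contig,
                "start": start,
                "end": start + SPACER_LENGTH,
                "strand": "+",
                "protospacer": proto_seq,
                "pam": pam,
                "mm_total": len(mm_positions),
                "mm_proximal": sum(
                    1 for p in mm_positions if p > SPACER_LENGTH - proximal_len
                ),
                "mismatch_positions": mm_positions,
            }
        )

    genome = GenomeSequence(
        name=contig, seq="".join(CODE_BASES[c] for c in codes)
    )
    manifest = {
        "seed": config.seed,
        "genome_length": L,
        "gc": config.gc,
        "spacer": spec.spacer,
        "pam_pattern": spec.pam_pattern,
        "sites": sites_manifest,
    }
    return genome, manifest


def planted_on_target(genome: GenomeSequence, manifest: dict) -> ProtospacerSite:
    """Reconstruct the planted on-target :class:`ProtospacerSite`."""
    entry = next(s for s in manifest["sites"] if s["kind"] == "on_target")
    return ProtospacerSite(
        interval=GenomicInterval(
            entry["contig"], entry["start"], entry["end"], entry["strand"]
        ),
        pam_interval=GenomicInterval(
            entry["contig"], entry["end"], entry["end"] + len(entry["pam"]),
            entry["strand"],
        ),
        protospacer_seq=entry["protospacer"],
        pam_seq=entry["pam"],
    )


@dataclass(frozen=True)
class SimulatedReads:
    """Paths and bookkeeping for one simulated readset."""

    sam_path: Path
    fastq_path: Optional[Path]
    n_reads: int
    read_length: int


def simulate_reads(
    genome: GenomeSequence,
    truth: EditTruth,
    config: SimConfig,
    sam_path: Union[str, Path],
    fastq_path: Optional[Union[str, Path]] = None,
) -> SimulatedReads:
    """Simulate per-molecule edited reads and write FASTQ + truth SAM.

    Each read is one molecule: molecules covering the target genomic
    position carry the product base with probability ``target_fraction``;
    bystander positions follow the linkage model ("independent" draws per
    position, or "conditional-on-target" where a bystander edit can only
    ride on a target-edited molecule while keeping its marginal fraction).
    Uniform substitution errors are applied afterwards. Alignments are
    written with exact coordinates and M-only CIGARs.
    """
    rl = config.read_length
    L = len(genome)
    if rl > L:
        raise ValueError(f"read_length {rl} exceeds genome length {L}")
    rng = np.random.default_rng(config.seed)
    n_reads = int(np.ceil(L * config.coverage / rl))
    starts = np.sort(rng.integers(0, L - rl + 1, size=n_reads))
    gcodes = genome.codes()
    if (gcodes == 4).any():
        raise ValueError("read simulation requires an N-free genome")
    reads = gcodes[starts[:, None] + np.arange(rl)[None, :]].copy()

    # --- per-molecule edits (target first, then bystanders by position) ---
    site, spec = truth.site, truth.spec
    edit_plan = [(truth.target_position, truth.target_fraction)] + sorted(
        truth.bystander_fractions.items()
    )
    target_mask = rng.random(n_reads) < truth.target_fraction
    for position, fraction in edit_plan:
        g = site.genomic_position(position)
        ref_code = gcodes[g]
        proto_ref = CODE_BASES[ref_code] if site.strand == "+" else CODE_BASES[
            _COMP_CODE[ref_code]
        ]
        if proto_ref != spec.edited_base:
            raise ValueError(
                f"protospacer position {position} is {proto_ref}, not the "
                f"editable base {spec.edited_base}"
            )
        product_code = np.uint8("ACGT".index(spec.product_base))
        if site.strand == "-":
            product_code = _COMP_CODE[product_code]
        if position == truth.target_position:
            edited = target_mask
        elif truth.linkage == "independent":
            edited = rng.random(n_reads) < fraction
        else:  # conditional-on-target
            cond = fraction / truth.target_fraction if truth.target_fraction else 0.0
            edited = target_mask & (rng.random(n_reads) < cond)
        covers = (starts <= g) & (g < starts + rl)
        hit = np.flatnonzero(edited & covers)
        reads[hit, g - starts[hit]] = product_code

    # --- uniform substitution errors ---
    if config.error_rate > 0:
        err = rng.random((n_reads, rl), dtype=np.float32) < config.error_rate
        n_err = int(err.sum())
        if n_err:
            shift = rng.integers(1, 4, size=n_err).astype(np.uint8)
            reads[err] = (reads[err] + shift) % 4

    # --- write outputs ---
    sam_path = Path(sam_path)
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": genome.name, "LN": L}],
        }
    )
    lookup = np.frombuffer(b"ACGT", dtype=np.uint8)
    qual = pysam.qualitystring_to_array("I" * rl)
    with pysam.AlignmentFile(str(sam_path), "w", header=header) as out:
        for i in range(n_reads):
            seg = pysam.AlignedSegment(header)
            seg.query_name = f"sim{config.seed}_{i:07d}"
            seg.query_sequence = lookup[reads[i]].tobytes().decode("ascii")
            seg.flag = 0
            seg.reference_id = 0
            seg.reference_start = int(starts[i])
            seg.mapping_quality = 60
            seg.cigartuples = [(0, rl)]
            seg.query_qualities = qual
            out.write(seg)

    fq = None
    if fastq_path is not None:
        fq = Path(fastq_path)
        qline = "I" * rl
        with open(fq, "w") as handle:
            for i in range(n_reads):
                seq = lookup[reads[i]].tobytes().decode("ascii")
                handle.write(
                    f"@sim{config.seed}_{i:07d}\n{seq}\n+\n{qline}\n"
                )

    return SimulatedReads(
        sam_path=sam_path, fastq_path=fq, n_reads=n_reads, read_length=rl
    )


def simulate_droplets(
    copies_edited: int,
    copies_unedited: int,
    n_partitions: int,
    seed: int,
) -> DropletCounts:
    """Partition two genotypes into droplets; FAM reads unedited, HEX edited.

    Each genotype's copies are distributed multinomially (uniform) over the
    partitions; a channel is positive when at least one copy of its
    genotype is present.
    """
    if n_partitions <= 0:
        raise ValueError("n_partitions must be positive")
    if copies_edited < 0 or copies_unedited < 0:
        raise ValueError("copy numbers must be non-negative")
    rng = np.random.default_rng(seed)
    probs = np.full(n_partitions, 1.0 / n_partitions)
    per_part_edited = rng.multinomial(copies_edited, probs)
    per_part_unedited = rng.multinomial(copies_unedited, probs)
    return DropletCounts(
        n_total=n_partitions,
        n_pos_fam=int((per_part_unedited > 0).sum()),
        n_pos_hex=int((per_part_edited > 0).sum()),
    )


def simulate_plating(
    n_cells: int, edited_fraction: float, seed: int
) -> tuple[PlateCounts, PlateCounts]:
    """Selective/non-selective plating of an edited population.

    Only unedited cells grow on the selective plate, so the treated
    selective count is Binomial(n_cells, 1 - edited_fraction); the
    untreated control plates all cells on both media. Returns
    (treated-with-fold-reduction, control).
    """
    if not 0 <= edited_fraction <= 1:
        raise ValueError("edited_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    selective = int(rng.binomial(n_cells, 1.0 - edited_fraction))
    treated = PlateCounts(cfu_selective=selective, cfu_nonselective=n_cells)
    control = PlateCounts(cfu_selective=n_cells, cfu_nonselective=n_cells)
    return compute_fold_reduction(treated, control), control


def write_manifest(manifest: dict, path: Union[str, Path]) -> None:
    with open(path, "w") as handle:
        json.dump(manifest, handle, indent=2)
        handle.write("\n")
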