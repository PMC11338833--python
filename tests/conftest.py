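"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import gutedit as g

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: spacers with editable bases placed where the recovery protocols need them
ABE_SPACER_T7 = "ATGCCGAAATGCGCTGGTCG"  # A at 1, 7, 8, 9
ABE_SPACER_T6 = "GTCGCATCGAATGCTTGCGT"  # A at 6, 10, 11
CBE_SPACER_T5 = "GATGCTGGTAAGTTAGGTCA"  # C at 5


@pytest.fixture
def abe_spec() -> g.GuideSpec:
    return g.GuideSpec(spacer=ABE_SPACER_T7, editor="ABE")


@pytest.fixture
def cbe_spec() -> g.GuideSpec:
    return g.GuideSpec(spacer=CBE_SPACER_T5, editor="CBE")


def random_genome(rng: np.random.Generator, length: int, name: str = "chr") -> g.GenomeSequence:
    return g.GenomeSequence(
        name=name, seq="".join(rng.choice(list("ACGT"), size=length))
    )


def recover_target_fraction(
    tmp_path,
    seed: int,
    spacer: str,
    editor: str,
    target_position: int,
    target_fraction: float,
    bystander_fractions: dict[int, float],
    coverage: float = 6000.0,
    error_rate: float = 0.003,
    genome_length: int = 1200,
):
    """Full-loop protocol: plant a site, simulate reads, pile up, profile.

    Returns (EditProfile, SimConfig). The estimator sees reads carrying both
    per-molecule edits and uniform substitution errors.
    """
    spec = g.GuideSpec(spacer=spacer, editor=editor)
    config = g.SimConfig(
        seed=seed, genome_length=genome_length, coverage=coverage,
        error_rate=error_rate,
    )
    genome, manifest = g.make_genome(config, spec)
    site = g.planted_on_target(genome, manifest)
    truth = g.EditTruth(
        site=site, spec=spec, target_position=target_position,
        target_fraction=target_fraction,
        bystander_fractions=bystander_fractions,
    )
    sam = tmp_path / f"reads_{seed}.sam"
    g.simulate_reads(genome, truth, config, sam_path=sam)
    table = g.build_pileup(sam, genome, sample_label="treated")
    profile = g.window_profile(table, site, spec, target_position=target_position)
    return profile, config


def expected_read_fraction(truth_fraction: float, error_rate: float) -> float:
    """Expected product-base read fraction after the substitution channel.

    An edited base survives with probability 1-e; an unedited base is
    miscalled to the product base with probability e/3.
    """
    return truth_fraction * (1.0 - error_rate) + (1.0 - truth_fraction) * error_rate / 3.0


def binomial_99_halfwidth(p: float, n: int) -> float:
    z99 = 2.5758293035489004
    return z99 * float(np.sqrt(p * (1.0 - p) / n))


def binomial_pileup(
    rng: np.random.Generator,
    genome: g.GenomeSequence,
    coverage: int,
    error_rate: float,
    label: str,
    extra_ag_rate: float = 0.0,
    spike: tuple[int, float, str] | None = None,
) -> g.PileupTable:
    """Directly constructed pileup: per position, ``coverage`` reads with a
    uniform substitution error, optionally an extra A→G rate at adenines
    (deaminase-like excess) or a single-position spike (pos, fraction, base).
    """
    codes = genome.codes()
    L = len(codes)
    counts = np.zeros((L, 4), dtype=np.uint32)
    n_err = rng.binomial(coverage, error_rate, size=L)
    counts[np.arange(L), codes] = coverage - n_err
    # errors split uniformly over the three non-reference bases
    for c in range(4):
        rows = np.flatnonzero(codes == c)
        if rows.size == 0:
            continue
        split = rng.multinomial(n_err[rows], [1 / 3] * 3)
        others = [b for b in range(4) if b != c]
        for j, b in enumerate(others):
            counts[rows, b] += split[:, j].astype(np.uint32)
    if extra_ag_rate > 0:
        a_rows = np.flatnonzero(codes == 0)
        extra = rng.binomial(coverage - n_err[a_rows], extra_ag_rate)
        extra = np.minimum(extra, counts[a_rows, 0])
        counts[a_rows, 0] -= extra.astype(np.uint32)
        counts[a_rows, 2] += extra.astype(np.uint32)
    if spike is not None:
        pos, fraction, base = spike
        b = "ACGT".index(base)
        ref = codes[pos]
        moved = int(round(counts[pos, ref] * fraction))
        counts[pos, ref] -= moved
        counts[pos, b] += moved
    return g.PileupTable([genome], {genome.name: counts}, sample_label=label)
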