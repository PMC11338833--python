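# Methods

This note documents the models, conventions and numerical choices behind
`gutedit`, and what the synthetic-data generator does and does not emulate.

## Coordinate and orientation conventions

All internal coordinates are 0-based half-open; every user-facing table and
report is 1-based inclusive. Protospacer positions are numbered 1–20 from
the PAM-distal 5′ end, so position 20 abuts the PAM; the "10 PAM-proximal
nucleotides" are positions 11–20. This is the standard SpCas9 convention;
statements such as "an edit at position 7A" are read in this frame. For
minus-strand sites every per-position quantity is oriented to the
protospacer strand: the genomic complement of the product base is counted,
and position 1 sits at the highest genomic coordinate of the site.

`N` bases are carried through and treated conservatively: an `N` in the
genome mismatches every spacer base and satisfies no PAM position, and a
pileup column whose reference base is `N` is undefined rather than zero.

## Guide design

A `GuideSpec` couples a 20-nt spacer to an editor chemistry — A→G for an
adenine base editor (ABE), C→T for a cytosine base editor (CBE) — and an
editing window, default positions 4–8 (the canonical deaminase window).
Editable bases are additionally reported as candidate bystanders over
positions 1–12, because high-coverage experiments routinely observe edits
outside the canonical window (e.g. at positions 1, 9, 10 or 11).

**CBE stop introduction.** For every NGG protospacer on either strand, the
editable in-window cytosines are grouped by the CDS codon they fall in and
all edit subsets of a codon are enumerated; a design is emitted for each
achievable stop product. Restricting subsets to one codon is exact: an edit
outside a codon cannot affect that codon's translation, so the set of
achievable (site, codon, stop product) triples is unchanged — the test
suite asserts equality against a brute-force designer that enumerates every
in-window subset. The reachable conversions are CAA→TAA, CAG→TAG, CGA→TGA
on the sense strand and TGG→{TAG, TGA, TAA} through the antisense CCA
(one or both cytosines edited). Every predicted codon change is re-verified
through translation (standard genetic code) before the design is returned.

**ABE start disruption.** Two design classes: a template-strand protospacer
placing the adenine that pairs with the coding-strand T of ATG in-window
(coding ATG→ACG), or a coding-strand protospacer placing the start adenine
in-window (ATG→GTG). These are the only single-base A→G routes to a non-ATG
start, since the template bases opposite the coding A and G are T and C.

Ties between equally valid designs are broken deterministically: smaller
distance of the edited position to the window centre, then leftmost genomic
start, then strand, then product codon.

## Off-target candidate enumeration

A candidate site is a 20-nt window on either strand, immediately 5′ of an
IUPAC PAM match (default NGG), with at most `max_mm = 7` total mismatches
to the spacer and at most `max_mm_proximal = 2` among the
`proximal_len = 10` PAM-proximal positions. The PAM is matched, never
mismatch-counted, and the on-target (0-mismatch) site is returned flagged
rather than suppressed so that on- and off-target editing can be reported
side by side. Both strands are scanned; results are sorted by
(contig, start, strand).

The production scan encodes the genome as a base-code array, locates PAM
anchors with boolean lookup tables and evaluates the mismatch matrix only
at anchored windows with vectorized comparisons (about half a second for a
4.6 Mb genome on one core). A deliberately naive per-window character
comparison (`brute_force_candidates`) is retained as the correctness
oracle; the suite asserts exact set equality on hundreds of random genomes
with decoy sites planted at the rule boundary, including (7,3) and (8,0)
decoys that must be excluded.

## Pileup and the read mismatch frequency

`build_pileup` consumes plain-text SAM. Only aligned (match/mismatch) bases
are counted: insertions contribute nothing, deleted reference positions
gain no coverage, and unmapped, secondary and supplementary records are
skipped. No base-quality or mapping-quality filter is applied by default
and duplicates are not removed — the statistic is computed literally as
stated; `min_baseq`/`min_mapq` thresholds are available but default to 0.
The read mismatch frequency at a position is
`(coverage − reads matching the reference) / coverage`, undefined (NaN, and
excluded from all downstream comparisons) at zero coverage or reference N.

## Outcome quantification

**Window profile.** For each protospacer position whose reference base
(protospacer-oriented) equals the editor's substrate base, the edit
fraction is the fraction of covering reads carrying the product base.
Positions whose reference base is not editable carry a null entry, not
zero. The on-target efficiency is the target-position fraction; a
complementary "any in-window edit" estimate is provided under an
independence assumption across positions, since column-wise counts cannot
resolve per-molecule linkage. Sequencing errors attenuate the estimator
slightly: at error rate e an edited base is observed with probability
1 − e, so the expected read-level fraction is f(1 − e) + (1 − f)e/3. The
recovery tests compare estimates against this expectation within the 99%
interval of the binomial sampling distribution at the realised coverage.

**Bystander calls.** Editable positions other than the target with an edit
fraction ≥ 0.05. The default separates genuine bystanders from sequencing
error by a wide margin at several-thousand-fold coverage (error-scale
fractions are ~0.001–0.003); it is configurable.

**Off-target comparison.** Per candidate site, the statistic is the highest
non-reference per-base frequency across the site's 20 positions, computed
separately in treated and control; a site is flagged when the treated
excess exceeds an absolute threshold of 0.005 (about 3× the 0.1–0.3%
Illumina substitution-error scale) with coverage ≥ 100 in both samples.
Candidates below the coverage floor are reported with an
insufficient-coverage status, never silently dropped. Ties between bases at
the maximum resolve alphabetically (A<C<G<T) for determinism. Calibration
is property-tested: zero flags across 100 null simulations, and a planted
5% spike flagged in 100/100.

**Genome-wide scan.** Positions covered ≥ 100× in both samples (optionally
restricted to one reference base, e.g. adenines for an ABE) are compared;
exceedances of the 0.005 threshold are counted in each direction and a
two-sided exact binomial sign test at level 0.05 decides the verdict:
"elevated" only when significant *and* the treated count is larger. With no
exceedances at all the verdict is "no elevation". The sign test is this
package's operationalisation of "a similar number of elevated positions in
both directions"; any direction-symmetric test would serve.

**Plate counts.** `edited_fraction = 1 − 1/fold_reduction`, where the fold
reduction is the control/treated ratio of selective colony counts
(optionally normalised by non-selective counts). A zero treated count
censors the fold at the control count, reported as a lower bound.

**Delivery model.** Dose–response of payload delivery versus multiplicity
of infection (MOI, particles per cell) is fitted as a single-hit Poisson
model f(MOI) = 1 − exp(−a·MOI), with a ∈ (0, 1] the per-particle effective
delivery probability; f(0) = 0 is structural. A single point is solved in
closed form; multiple points by bounded least squares seeded from the
median closed-form solution.

## ddPCR quantification

The dual-probe assay reads FAM for the unedited allele and HEX for the
edited allele on separate template molecules, so the two channels are
independent Poisson loadings: λ = −ln(n_neg/n_total) per channel and
edited fraction λ_HEX/(λ_FAM + λ_HEX). Double-positive droplets need no
special treatment under this model, and probe cross-reactivity is taken as
zero (locked-nucleic-acid probes are designed for large match/mismatch Tm
separation). The 95% CI uses the delta method: Var(λ̂) ≈ (1 − p̂)/(n·p̂)
with p̂ the negative fraction, propagated to the ratio and clipped to
[0, 1]. A saturated channel (no negatives) is an error — the sample must
be diluted — not a quantification.

## Synthetic-data generator

The generator supplies every estimator with inputs of known truth:

* **Genomes** — i.i.d. bases at a chosen GC content with one planted
  on-target protospacer (concrete PAM) and decoys at exact
  (total, proximal) mismatch counts, placed at spaced, non-overlapping
  offsets on the plus strand; a manifest records all truth coordinates.
* **Reads** — fixed-length single-end reads (default 150 nt, emulating the
  read length of paired-end Illumina runs) at a target fold coverage
  (default 6,000), uniform start positions. Each read is one molecule:
  target and bystander edits are drawn per molecule (independently by
  default; a conditional-on-target linkage is available for sensitivity
  checks), then a uniform substitution error (default 0.3% per base) is
  applied. Alignments are emitted directly as truth SAM with exact
  coordinates and M-only CIGARs — no aligner runs, so alignment artefacts
  are out of frame by construction.
* **Droplets** — multinomial partitioning of each genotype's copies over
  droplets; a channel is positive when ≥ 1 copy of its genotype is present.
* **Plating** — binomial survival of unedited cells on selective plates
  against an untreated control.

All draws flow through one seeded `numpy` generator; identical
configurations produce byte-identical FASTQ/SAM/JSON outputs.

What the generator does **not** emulate — and hence what passing recovery
tests do not certify for real data: alignment and mapping errors (including
multi-mapping near repetitive off-targets), indels and structural errors,
PCR duplicates and amplification bias, quality-score miscalibration,
position-dependent or strand-biased error profiles, droplet "rain" and
fluorescence thresholding, and probe cross-hybridisation. Real analyses
must additionally trust their aligner and instrument-side preprocessing.

## Problem sizes in the shipped checks

The recovery protocols run on 1.2-kb surrogate genomes at 6,000× coverage
(~48,000 reads), which gives the target position the same per-column
statistics as a full-genome run at equal depth while keeping each protocol
in the seconds range; oracle-equivalence properties use 100 random genomes
of 3–12 kb with five boundary decoys each; guide-designer soundness runs on
1,000 randomized CDSs. The ddPCR check uses 20,000 partitions at total
occupancy ~1, the scale of a standard droplet run.

## Known limitations

* Per-molecule linkage of target and bystander edits is not estimable from
  column-wise pileups; the "any in-window edit" statistic is an
  independence approximation and is labelled as such.
* The elevation threshold (0.005) and coverage floor (100) are declared
  defaults, not values inferred from data; experiments with different error
  structure should recalibrate them.
* The off-target rule is mismatch-only (no DNA/RNA bulges) and PAM-strict
  (NGG by default, no NAG relaxation); no off-target activity scoring is
  attempted.
* CDS inputs are explicit intervals; no annotation-format parsing is
  provided.
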