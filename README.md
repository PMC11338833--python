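# gutedit

Analysis toolkit for **bacterial base-editing experiments**: designing
inactivating guides, auditing genome-wide off-target candidates, quantifying
editing outcomes from deep sequencing, and converting droplet-PCR and
plate-count readouts into edited-population fractions.

The experimental setting is a CRISPR base editor (an adenine editor, A→G, or
a cytosine editor, C→T) delivered to a bacterial population — for example by
phage-derived particles — to knock out a target gene either by introducing a
premature stop codon (CBE) or by destroying the ATG start codon (ABE). The
package answers the computational questions such an experiment raises:

* **Guide design** — which NGG protospacers can inactivate a given CDS?
  For a CBE, every in-window C→T edit that drives a sense codon to a stop
  (CAA→TAA, CAG→TAG, CGA→TGA, or TGG via its antisense CCA cytosines); for
  an ABE, start-codon disruption from the template strand (ATG→ACG) or the
  coding strand (ATG→GTG). Protospacer positions are numbered 1–20 from the
  PAM-distal end; the deaminase window defaults to positions 4–8.
* **Off-target enumeration** — all protospacers on either strand with at
  most 7 mismatches to the spacer, of which at most 2 in the 10 PAM-proximal
  nucleotides, next to an NGG PAM. A vectorized scan (sub-second on a
  4.6 Mb genome) is verified bit-identical against a naive brute-force
  oracle.
* **Pileup statistics** — per-position nucleotide counts from SAM
  alignments and the *read mismatch frequency*
  `(coverage − reads matching reference) / coverage`.
* **Outcome quantification** — editing-window profiles (edit fraction per
  protospacer position, strand-oriented), bystander calls,
  treated-vs-control comparison of candidate off-targets via the maximal
  non-reference base frequency per site, a genome-wide mutation-rate scan
  with a sign-test verdict, the plate-count identity
  `edited_fraction = 1 − 1/fold_reduction`, and a single-hit Poisson
  dose–response model `f(MOI) = 1 − exp(−a·MOI)`.
* **ddPCR quantification** — dual-probe (FAM = unedited, HEX = edited)
  Poisson estimation: `λ = −ln(n_neg/n_total)` per channel and
  `edited_fraction = λ_HEX / (λ_FAM + λ_HEX)` with a delta-method 95% CI.
* **Synthetic data** — seeded generators for planted genomes, per-molecule
  edited reads with uniform sequencing error, droplet partitions and plate
  counts, so every estimator can be exercised against known truth.

## Worked example

Simulate a deep-sequencing experiment at 6,000× coverage with 0.3% per-base
error in which 98% of molecules carry an A→G edit at protospacer position 7
(with bystander edits at positions 1, 8 and 9), then recover the editing
profile:

```python
from pathlib import Path
import gutedit as g

spec = g.GuideSpec(spacer="ATGCCGAAATGCGCTGGTCG", editor="ABE")
config = g.SimConfig(seed=7, genome_length=1200, coverage=6000, error_rate=0.003)
genome, manifest = g.make_genome(config, spec)
site = g.planted_on_target(genome, manifest)
truth = g.EditTruth(
    site=site, spec=spec, target_position=7, target_fraction=0.98,
    bystander_fractions={1: 0.10, 8: 0.30, 9: 0.20},
)
g.simulate_reads(genome, truth, config, sam_path=Path("reads.sam"))

table = g.build_pileup("reads.sam", genome, sample_label="treated")
profile = g.window_profile(table, site, spec, target_position=7)
print(f"on-target efficiency at position 7: {profile.target_fraction:.1%}")
print(f"bystander positions (>=5%): {g.call_bystanders(profile)}")

counts = g.simulate_droplets(18600, 1400, n_partitions=20000, seed=7)
quant = g.quantify_genotypes(counts)
print(f"ddPCR edited fraction: {quant.edited_fraction:.1%} "
      f"(95% CI {quant.ci95[0]:.1%}-{quant.ci95[1]:.1%})")
print(f"fold-reduction 1e4 -> edited fraction "
      f"{g.edited_fraction_from_fold_reduction(1e4):.2%}")
```

prints

```
on-target efficiency at position 7: 97.7%
bystander positions (>=5%): [1, 8, 9]
ddPCR edited fraction: 92.9% (95% CI 92.5%-93.3%)
fold-reduction 1e4 -> edited fraction 99.99%
```

The recovered 97.7% sits just below the simulated 98% because sequencing
errors occasionally corrupt the product base; at 0.3% error this attenuation
(≈ 0.3 percentage points) is part of the estimator's expected behaviour.

The same stages are available from the shell via the `gutedit` console
script (`design`, `offtargets`, `pileup`, `quantify`, `ddpcr`, `simulate`
and the `audit` composite); run `gutedit --help` for the options.

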