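# meipop

Population genetics of polymorphic mobile element insertions (MEI) — the
Alu, L1, and SVA retrotransposon copies that segregate among human genomes.
`meipop` is a library for simulating, detecting, genotyping, and analysing
MEI polymorphism in sequenced cohorts, written for researchers who work with
structural-variant call sets and want the population-genetic layer (allele
frequency spectra, diversity parameters, insertion rates, selection) on top
of them.

## What it does

MEI come in two ascertainment classes. A **non-reference** insertion is
present in a sample but absent from the reference assembly; it is detected
from read-pair (RP) clusters spanning into element sequence from both sides
of the breakpoint, or from split reads (SR) whose reference-mapped extents
overlap across the target-site duplication. A **reference** insertion is
carried by the reference assembly and absent from samples (and from the
chimpanzee genome); it is selected from deletion calls that match an
annotated element. The package implements:

- a **simulator** producing neutral-model catalogs (the number of loci at
  derived-allele count *i* among 2N chromosomes is Poisson with mean θ/*i*),
  reference-genome ascertainment, Hardy–Weinberg genotypes, per-locus
  fragment evidence, deletion calls, and annotation tracks;
- **detection**: RP calling (≥2 fragments per breakpoint side, same-family
  annotation masking within one fragment length), SR calling (≥1 fragment,
  TSD from extent overlap), and reference-MEI selection (>50% reciprocal
  overlap, 20/200 bp endpoint windows, ≥75% chimpanzee-gap coverage);
- **catalog** operations: 100 bp merge preferring SR coordinates, 200 bp /
  50%-reciprocal cross-study matching, Poisson density scanning for
  hotspots, trio de-novo screening;
- **genotyping**: posterior(g) ∝ P(g)·Binom(N_ALT; N_ALT+N_REF, p_g) with a
  flat prior and p_g ≈ 0 / 0.5 / ≈ 1, phred GQ = −10·log₁₀(1 − max
  posterior), concordance tables, Hardy–Weinberg and Mendelian QC;
- **sensitivity**: validation FDRs with Wilson intervals, and Lincoln–
  Petersen capture–recapture across two independent detection methods,
  ε_RP = n_both/[(1−f_SR)·n_SR], combined ε = 1−(1−ε_RP)(1−ε_SR);
- **population genetics**: ascertainment-aware spectra (reference mode flat
  at θ/2N, non-reference at (θ/i)(2N−i)/2N), correction factors
  K = 1/(ε_DET·ε_GEN), closed-form Poisson ML fit θ̂ = Σn(i)/Σ(1/i) over
  allele counts 7–47, μ = θ/(4N_e), heterozygote-dropout correction
  K_HET = N_loci/Σ(1−0.5^NF), per-sample corrected heterozygosity π_MEI,
  mutation rates μ_MEI = (π_MEI/π_SNP)·μ_SNP·L, coalescent times, and
  corrected pairwise presence/absence differences;
- **functional analysis**: region containment counts and random-placement
  suppression factors with log-space binomial placement p-values.

## Worked example

`examples/05_spectrum_and_theta.py` simulates a catalog at θ = 1500, loses
loci to detection (sensitivity 0.7) and genotyping (efficiency 0.4), and
fits θ before and after correction:

```
true theta 1500
uncorrected fit 407 (biased low by ~eps_det*eps_gen = 0.28)
corrected fit 1455 [95% CI 1355-1555], chi2/dof = 3.39
implied insertion rate mu = theta/(4 Ne) = 0.0364 per genome per generation
```

The uncorrected fit is depressed by the product of the two efficiencies;
after applying K = 1/(ε_DET·ε_GEN) per detection mode the fit recovers the
simulated diversity parameter within its confidence interval. The χ²/d.f.
above 1 reflects the correction-inflated variance of the corrected counts.
`examples/07_functional_suppression.py` prints the selection signal:

```
gene: expected   2020  observed 1718  suppression   1.2x  log10 p = -17.4
 UTR: expected    105  observed   36  suppression   2.9x  log10 p = -14.4
 CDS: expected    137  observed    3  suppression  45.7x  log10 p = -54.6
```

i.e. insertions are ~46× rarer in coding sequence than random placement
predicts.

## Layout

- `src/meipop/` — `simulate`, `detection`, `catalog`, `genotyping`,
  `sensitivity`, `popgen`, `functional`, `io`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — model assumptions, parameter choices, and limitations
- `tests/` — unit, property, and acceptance suites
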