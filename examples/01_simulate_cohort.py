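"""Simulate an MEI polymorphism cohort and inspect its structure.

Draws a neutral-model catalog (loci per allele count i ~ Poisson(theta/i)),
splits it by reference-genome ascertainment, and samples Hardy-Weinberg
genotypes plus fragment evidence for one population.
"""

import numpy as np

import meipop as mp

cfg = mp.SimConfig(
    theta_by_family={"Alu": 400.0, "L1": 60.0, "SVA": 15.0},
    n_samples_by_pop={"CEU": 60},
    genome_length=200_000_000,
    seed=1,
)
loci, tracks = mp.simulate_catalog(cfg)
genotypes = mp.simulate_cohort(loci, cfg)
support, _ = mp.simulate_evidence(genotypes, loci, cfg)

n_ref = sum(l.on_reference for l in loci)
print(f"{len(loci)} segregating loci "
      f"({n_ref} on the reference haplotype, {len(loci) - n_ref} non-reference)")
h = np.sum(1.0 / np.arange(1, cfg.n_chrom_sampled))
print(f"expected under theta*H(2N-1): {sum(cfg.theta_by_family.values()) * h:.0f}")
by_fam = {f: sum(l.family == f for l in loci) for f in ("Alu", "L1", "SVA")}
print("family breakdown:", by_fam)
print(f"genotype matrix: {genotypes.shape[0]} samples x {genotypes.shape[1]} loci; "
      f"mean fragment coverage {support[['n_alt5', 'n_alt3', 'n_ref']].sum(axis=1).mean():.1f}")
# The locus count tracks theta times the harmonic number, the reference
# fraction is (2N-1)/(2N*H) of loci, and coverage matches the configured mean.
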