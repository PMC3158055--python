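"""Corrected heterozygosity, the MEI mutation rate, and coalescent time.

Per-sample heterozygous-locus counts are corrected for heterozygote dropout
(K_HET), detection sensitivity, and genotyping efficiency; the ratio to SNP
heterozygosity converts to insertions per genome per generation.
"""

import numpy as np

import meipop as mp
from meipop.model import NON_REFERENCE, REFERENCE

# K_HET from per-locus fragment totals: low coverage hides heterozygotes
rng = np.random.default_rng(5)
nf = rng.poisson(4.0, size=2000)
kh = mp.k_het(nf)
print(f"K_HET at Poisson(4) coverage: {kh:.3f} "
      "(fraction of hets producing no insertion fragment is 0.5^NF)")

pi_mei = mp.sample_pi(
    pi_nref_raw=500, pi_ref_raw=600, k_het=kh,
    eps_det={NON_REFERENCE: 0.75, REFERENCE: 0.9},
    eps_gen={NON_REFERENCE: 0.5, REFERENCE: 0.8},
)
print(f"corrected pi_MEI: {pi_mei:.0f} heterozygous loci per genome")

pi_snp = 9.0e-4 * 2.85e9  # per-genome SNP heterozygosity
mu_mei, t_coal = mp.mutation_rates(pi_mei, pi_snp)
print(f"mu_MEI = (pi_MEI/pi_SNP) * mu_SNP * L = {mu_mei:.4f} "
      "insertions/genome/generation")
print(f"coalescent time from SNP heterozygosity: {t_coal:,.0f} years")

# presence/absence differences between two individuals, corrected for
# detection losses and false calls
a = {NON_REFERENCE: {("chr1", k, "Alu") for k in range(800)}, REFERENCE: set()}
b = {NON_REFERENCE: {("chr1", k, "Alu") for k in range(300, 1100)},
     REFERENCE: set()}
count, sigma, raw = mp.pairwise_differences(
    a, b, eps={NON_REFERENCE: 0.8, REFERENCE: 0.9},
    fdr={NON_REFERENCE: 0.05, REFERENCE: 0.0})
print(f"pairwise MEI differences: raw {sum(raw.values())}, "
      f"corrected {count:.0f} +/- {sigma:.0f}")
# The corrected pairwise count scales linearly with the pair's coalescent
# time, so it acts as an insertion-rate clock.
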