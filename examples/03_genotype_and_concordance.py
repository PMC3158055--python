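"""Bayesian genotype calling from fragment counts, with phred GQ.

The posterior is P(g) * Binomial(n_alt; n_alt+n_ref, p_g) with a flat prior
and p_g ~ 0 / 0.5 / ~1 for the three genotypes; GQ = -10 log10(1 - max
posterior).
"""

import meipop as mp

for n_alt, n_ref in [(0, 0), (1, 1), (0, 3), (5, 5), (12, 0)]:
    call = mp.call_genotype(n_alt, n_ref)
    print(f"n_alt={n_alt:2d} n_ref={n_ref:2d} -> {call.g}  GQ={call.gq:5.1f}  "
          f"posterior={tuple(round(p, 4) for p in call.posterior)}")
print("GQ 7 implies", f"{100 * mp.phred_accuracy(7):.0f}% accuracy;",
      "GQ 10 implies", f"{100 * mp.phred_accuracy(10):.0f}%")

# agreement of sequenced vs PCR genotypes from a 3x3 contingency table
trio = [[901, 5, 0], [2, 671, 54], [0, 10, 144]]
print(f"trio contingency agreement: {100 * mp.concordance_from_table(trio):.1f}%")
# Zero evidence yields a flat posterior (GQ 0); mixed evidence is confidently
# heterozygous; agreement is the diagonal fraction of the table.
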