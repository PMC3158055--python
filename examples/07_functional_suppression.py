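"""Selection against insertions in functional sequence.

Counts loci whose breakpoint confidence interval falls entirely inside
annotated regions and compares with uniform random placement: the suppression
factor is expected/observed and the placement p-value is a binomial tail
computed in log space.
"""

import meipop as mp
from meipop.functional import RegionCounts

GENOME = 2_850_000_000
for label, expected, observed in [("gene", 2020, 1718), ("UTR", 105, 36),
                                  ("CDS", 137, 3)]:
    l_obs = int(round(expected / 5370 * GENOME))
    st = mp.suppression_stats(RegionCounts(label, l_obs, observed, 5370, GENOME))
    print(f"{label:>4}: expected {st.expected:6.0f}  observed {observed:4d}  "
          f"suppression {st.suppression:5.1f}x  log10 p = {st.log10_p:.1f}")
# Coding sequence shows ~46x suppression with a depletion p-value far below
# 1e-50 — strong negative selection against insertions disrupting genes.
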