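"""Functional placement of MEI: observed vs random-placement expectations.

Under uniform random placement across the accessible genome the number of
loci falling in an annotated class of total length L_obs is binomial,
N_obs ~ Binomial(N_tot, L_obs/L_tot).  The suppression factor is the ratio of
the expected to the observed count (a boost when < 1); the placement p-value
is the lower binomial tail for depletion (upper tail for excess), computed in
log space because coding-region depletion drives it far below double
underflow thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .model import Interval, MeiLocus, NON_REFERENCE

DEFAULT_GENOME_LENGTH = 2_850_000_000


@dataclass
class RegionCounts:
    region_label: str
    l_obs: int
    n_obs: int
    n_tot: int
    l_tot: int = DEFAULT_GENOME_LENGTH

    def __post_init__(self) -> None:
        if not 0 <= self.n_obs <= self.n_tot:
            raise ValueError("need 0 <= n_obs <= n_tot")
        if not 0 <= self.l_obs <= self.l_tot:
            raise ValueError("need 0 <= l_obs <= l_tot")


@dataclass
class SuppressionStats:
    region_label: str
    expected: float
    observed: int
    suppression: float  # expected/observed; lower bound (n_obs=1) when obs=0
    is_lower_bound: bool
    log10_p: float  # one-sided placement p-value, sign chosen by direction
    direction: str  # "depletion" | "excess"

    @property
    def p_value(self) -> float:
        return 10.0**self.log10_p


def count_by_region(
    loci: list[MeiLocus],
    regions: dict,
    l_tot: int = DEFAULT_GENOME_LENGTH,
    invalidated: set | None = None,
) -> dict:
    """Count loci whose confidence interval lies entirely inside a region.

    ``regions`` maps class label -> list[Interval].  A locus counts for a
    class iff [ci_lo, ci_hi] is contained in some interval of that class;
    loci listed in ``invalidated`` (by locus key) are excluded everywhere, and
    for the CDS class only non-reference loci are eligible (a reference MEI
    embedded in the assembly precludes the region being annotated as coding).
    """
    import numpy as np

    invalidated = invalidated or set()
    kept = [l for l in loci if l.key not in invalidated]
    out = {}
    for label, intervals in regions.items():
        eligible = [
            l for l in kept
            if label != "CDS" or l.detection_mode == NON_REFERENCE
        ]
        # per chromosome: sorted starts with a running max of ends, so
        # containment is one binary search per locus
        index: dict = {}
        for iv in intervals:
            index.setdefault(iv.chrom, []).append((iv.start, iv.end))
        for chrom, pairs in index.items():
            pairs.sort()
            starts = np.array([p[0] for p in pairs])
            ends = np.maximum.accumulate(np.array([p[1] for p in pairs]))
            index[chrom] = (starts, ends)
        n_obs = 0
        for locus in eligible:
            if locus.chrom not in index:
                continue
            starts, ends = index[locus.chrom]
            k = int(np.searchsorted(starts, locus.ci_lo, side="right")) - 1
            if k >= 0 and locus.ci_hi <= ends[k]:
                n_obs += 1
        l_obs = sum(len(iv) for iv in intervals)
        out[label] = RegionCounts(label, l_obs, n_obs, len(eligible), l_tot)
    return out


def suppression_stats(counts: RegionCounts) -> SuppressionStats:
    """Random-placement expectation, suppression factor, and placement p-value.

    Expected = N_tot * L_obs / L_tot.  Suppression = expected/observed; when
    no locus is observed the factor is reported as a lower bound using
    observed = 1.  The p-value is the one-sided binomial tail in the
    direction of the deviation, evaluated in log space.
    """
    if counts.l_obs <= 0:
        raise ValueError("region length must be positive")
    if counts.n_tot <= 0:
        raise ValueError("need at least one locus")
    p = counts.l_obs / counts.l_tot
    expected = counts.n_tot * p
    if counts.n_obs == 0:
        suppression, bound = expected / 1.0, True
    else:
        suppression, bound = expected / counts.n_obs, False
    if counts.n_obs <= expected:
        direction = "depletion"
        logp = stats.binom.logcdf(counts.n_obs, counts.n_tot, p)
    else:
        direction = "excess"
        logp = stats.binom.logsf(counts.n_obs - 1, counts.n_tot, p)
    return SuppressionStats(
        counts.region_label, expected, counts.n_obs, suppression, bound,
        logp / math.log(10.0), direction,
    )
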