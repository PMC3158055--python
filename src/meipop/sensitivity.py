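"""Detection error rates: PCR-validation false-detection rates and
capture-recapture (Lincoln-Petersen) detection sensitivity.

The two insertion-detection methods (read-pair and split-read) use
independent sequencing libraries, so the overlap between their call sets in
the same sample behaves like a two-sample mark-recapture experiment: with
per-method false-detection rates f deflating the capture counts,

    eps_RP = n_both / ((1 - f_SR) * n_SR)
    eps_SR = n_both / ((1 - f_RP) * n_RP)

and the sensitivity of the union of the two independent methods is

    eps_combined = 1 - (1 - eps_RP) (1 - eps_SR).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ValidationBatch:
    """PCR-validation outcome for one stratum of tested loci."""

    n_tested: int
    n_validated: int
    stratum: tuple = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_validated <= self.n_tested:
            raise ValueError("need 0 <= n_validated <= n_tested")


@dataclass
class FdrEstimate:
    rate: float | None
    ci_lo: float | None
    ci_hi: float | None

    @property
    def rate_pct(self) -> float | None:
        return None if self.rate is None else 100.0 * self.rate


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion k/n."""
    z = stats.norm.ppf(0.5 + conf / 2.0)
    p = k / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo = 0.0 if k == 0 else max(0.0, centre - half)
    hi = 1.0 if k == n else min(1.0, centre + half)
    return lo, hi


def estimate_fdr(batch: ValidationBatch, conf: float = 0.95) -> FdrEstimate:
    """False-detection rate (tested - validated) / tested with a Wilson CI.

    The Wilson interval is preferred over the Wald form because validation
    strata are small (tens to low hundreds of loci).
    """
    if batch.n_tested == 0:
        return FdrEstimate(None, None, None)
    k = batch.n_tested - batch.n_validated
    lo, hi = wilson_interval(k, batch.n_tested, conf)
    return FdrEstimate(k / batch.n_tested, lo, hi)


@dataclass
class OverlapCounts:
    """Cross-method locus counts within one sample."""

    n_rp: int
    n_sr: int
    n_both: int
    f_rp: float = 0.0
    f_sr: float = 0.0

    def __post_init__(self) -> None:
        if self.n_both > min(self.n_rp, self.n_sr):
            raise ValueError("overlap cannot exceed either call set")
        for f in (self.f_rp, self.f_sr):
            if not 0.0 <= f <= 1.0:
                raise ValueError("false-detection rates must be in [0, 1]")


@dataclass
class SensitivityEstimate:
    eps_rp: float
    eps_sr: float
    eps_combined: float
    se_rp: float
    se_sr: float
    se_combined: float


def combined_sensitivity(eps_rp: float, eps_sr: float) -> float:
    """Union sensitivity of two independent detection methods."""
    return 1.0 - (1.0 - eps_rp) * (1.0 - eps_sr)


def lincoln_petersen(counts: OverlapCounts) -> SensitivityEstimate:
    """Capture-recapture sensitivity estimates with binomial standard errors.

    With ``n_both`` = 0 the point estimates are undefined and reported as NaN
    with infinite standard errors.
    """
    if counts.n_both == 0:
        nan, inf = float("nan"), float("inf")
        return SensitivityEstimate(nan, nan, nan, inf, inf, inf)
    true_sr = (1.0 - counts.f_sr) * counts.n_sr
    true_rp = (1.0 - counts.f_rp) * counts.n_rp
    eps_rp = counts.n_both / true_sr
    eps_sr = counts.n_both / true_rp
    eps_rp_c = min(eps_rp, 1.0)
    eps_sr_c = min(eps_sr, 1.0)
    se_rp = math.sqrt(max(eps_rp_c * (1 - eps_rp_c), 0.0) / true_sr)
    se_sr = math.sqrt(max(eps_sr_c * (1 - eps_sr_c), 0.0) / true_rp)
    comb = combined_sensitivity(eps_rp_c, eps_sr_c)
    # error propagation through the union formula
    se_comb = math.sqrt(
        ((1 - eps_sr_c) * se_rp) ** 2 + ((1 - eps_rp_c) * se_sr) ** 2
    )
    return SensitivityEstimate(eps_rp, eps_sr, comb, se_rp, se_sr, se_comb)


def estimated_true_count(counts: OverlapCounts,
                         est: SensitivityEstimate) -> float:
    """Implied number of true loci N = (1 - f_RP) n_RP / eps_RP."""
    return (1.0 - counts.f_rp) * counts.n_rp / est.eps_rp


def sensitivity_by_af(
    gold: pd.DataFrame,
    callset: list,
    af_bins: np.ndarray | None = None,
    window_bp: int = 200,
) -> pd.DataFrame:
    """Binned detection sensitivity against a gold-standard locus table.

    ``gold`` columns: chrom, pos, family, af (allele-frequency estimate from
    validation genotypes).  A gold locus counts as detected when the call set
    holds a same-family locus within ``window_bp``.  Returns per-bin
    sensitivity with one-sigma binomial errors; empty bins are omitted.
    """
    if af_bins is None:
        af_bins = np.linspace(0.0, 1.0, 11)
    detected = []
    for row in gold.itertuples():
        hit = any(
            c.chrom == row.chrom
            and c.family == row.family
            and abs(c.pos - row.pos) <= window_bp
            for c in callset
        )
        detected.append(hit)
    gold = gold.assign(detected=detected)
    rows = []
    for k in range(len(af_bins) - 1):
        lo, hi = af_bins[k], af_bins[k + 1]
        sel = (gold["af"] > lo) & (gold["af"] <= hi)
        if k == 0:
            sel |= gold["af"] == lo
        sub = gold[sel]
        if sub.empty:
            continue
        n, d = len(sub), int(sub["detected"].sum())
        eps = d / n
        rows.append(
            {
                "af_lo": lo,
                "af_hi": hi,
                "n_gold": n,
                "n_detected": d,
                "sensitivity": eps,
                "se": math.sqrt(eps * (1 - eps) / n),
            }
        )
    return pd.DataFrame(rows)
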