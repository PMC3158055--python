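"""Allele-frequency spectra, diversity-parameter fitting, and heterozygosity.

Under the standard neutral (infinite-sites) model the expected number of loci
with derived-allele count ``i`` among ``2N`` sampled chromosomes is
``theta/i``.  Reference-genome ascertainment splits the observable loci into
two detection modes whose expectations are

    reference MEI:      theta / 2N                    (flat in i)
    non-reference MEI:  (theta/i) * (2N - i) / 2N

which sum back to ``theta/i``.  Each mode is under-observed by its detection
sensitivity ``eps_det`` and genotyping efficiency ``eps_gen``; the combined
corrected spectrum is

    n_MEI(i) = K_REF * n_REF(i) + K_NREF * n_NREF(i),   K = 1/(eps_det*eps_gen)

and theta is fit to the ``theta/i`` form over allele counts 7..47 (population
frequency 0.15..0.95 for 2N = 50) by Poisson maximum likelihood, which has
the closed form ``theta_hat = sum n(i) / sum (1/i)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import NON_REFERENCE, REFERENCE

DEFAULT_FIT_RANGE = (7, 47)
DEFAULT_NE = 10_000
DEFAULT_MU_SNP = 1.8e-8
DEFAULT_T_GEN = 25.0
DEFAULT_GENOME_LENGTH = 2_850_000_000
GQ_THRESHOLDS = {NON_REFERENCE: 7.0, REFERENCE: 10.0}


@dataclass
class Spectrum:
    """Allele-count histogram for a fixed diploid sample size N.

    ``counts_ref`` / ``counts_nref`` index allele counts 0..2N; bin 0 is
    always empty (unobservable loci are dropped).
    """

    n_samples: int
    counts_ref: np.ndarray
    counts_nref: np.ndarray
    k_ref: float = 1.0
    k_nref: float = 1.0
    fit_range: tuple = DEFAULT_FIT_RANGE
    eps_gen: dict = field(default_factory=dict)  # mode -> genotyping efficiency

    def __post_init__(self) -> None:
        two_n = 2 * self.n_samples
        for arr in (self.counts_ref, self.counts_nref):
            if len(arr) != two_n + 1:
                raise ValueError("count arrays must span allele counts 0..2N")
        if self.k_ref < 1.0 or self.k_nref < 1.0:
            raise ValueError("correction factors must be >= 1")
        lo, hi = self.fit_range
        if not 1 <= lo <= hi <= two_n - 1:
            raise ValueError("fit range must lie within 1..2N-1")

    @property
    def two_n(self) -> int:
        return 2 * self.n_samples

    @property
    def combined(self) -> np.ndarray:
        """Corrected combined spectrum K_REF*n_REF + K_NREF*n_NREF."""
        return self.k_ref * self.counts_ref + self.k_nref * self.counts_nref

    @property
    def total(self) -> np.ndarray:
        return self.counts_ref + self.counts_nref


@dataclass
class ThetaFit:
    theta: float
    ci_lo: float
    ci_hi: float
    chi2: float
    dof: int
    mu_theta: float
    mu_ci: tuple = (0.0, 0.0)
    n_e: int = DEFAULT_NE


def empty_spectrum(n_samples: int = 25) -> Spectrum:
    z = np.zeros(2 * n_samples + 1)
    return Spectrum(n_samples, z, z.copy())


def build_spectrum(
    genotypes: pd.DataFrame,
    gq: pd.DataFrame,
    loci_meta: pd.DataFrame,
    populations: dict | None = None,
    gq_thresholds: dict | None = None,
    n_spectrum_samples: int = 25,
    seed: int = 0,
    family: str | None = None,
) -> dict:
    """Allele-count spectra per population from a genotyped cohort.

    ``genotypes`` and ``gq`` are aligned samples x loci frames (dosage 0/1/2
    and phred GQ); ``loci_meta`` is indexed by locus id with a
    ``detection_mode`` column (and optionally ``family``).  A locus enters a
    population's spectrum when at least ``n_spectrum_samples`` of that
    population's samples pass the mode's GQ threshold; ``family`` restricts
    the spectrum to one element family (requires a ``family`` column in
    ``loci_meta``); exactly
    ``n_spectrum_samples`` passing samples (a seeded random subset) define the
    allele count.  Loci with allele count 0 are dropped.  Returns
    population -> Spectrum; each spectrum records the per-mode genotyping
    efficiency (fraction of loci with enough qualifying genotypes).
    """
    thresholds = dict(GQ_THRESHOLDS)
    if gq_thresholds:
        thresholds.update(gq_thresholds)
    if populations is None:
        populations = genotypes.attrs.get("population")
    if populations is None:
        populations = {s: "ALL" for s in genotypes.index}
    rng = np.random.default_rng(seed)
    two_n = 2 * n_spectrum_samples
    pops = sorted(set(populations.values()))
    sample_idx = {
        pop: np.array([k for k, s in enumerate(genotypes.index)
                       if populations[s] == pop])
        for pop in pops
    }
    g = genotypes.to_numpy()
    q = gq.to_numpy()
    out: dict = {}
    for pop in pops:
        idx = sample_idx[pop]
        counts = {
            REFERENCE: np.zeros(two_n + 1),
            NON_REFERENCE: np.zeros(two_n + 1),
        }
        n_loci = {REFERENCE: 0, NON_REFERENCE: 0}
        n_ok = {REFERENCE: 0, NON_REFERENCE: 0}
        for j, locus_id in enumerate(genotypes.columns):
            if family is not None and loci_meta.loc[locus_id, "family"] != family:
                continue
            mode = loci_meta.loc[locus_id, "detection_mode"]
            thr = thresholds[mode]
            n_loci[mode] += 1
            ok = idx[q[idx, j] >= thr]
            if len(ok) < n_spectrum_samples:
                continue
            n_ok[mode] += 1
            chosen = rng.choice(ok, size=n_spectrum_samples, replace=False)
            i = int(g[chosen, j].sum())
            if i == 0:
                continue
            counts[mode][i] += 1
        spec = Spectrum(n_spectrum_samples, counts[REFERENCE],
                        counts[NON_REFERENCE])
        spec.eps_gen = {
            m: (n_ok[m] / n_loci[m]) if n_loci[m] else float("nan")
            for m in (REFERENCE, NON_REFERENCE)
        }
        out[pop] = spec
    return out


def hypergeometric_projection(
    allele_counts: np.ndarray,
    chrom_counts: np.ndarray,
    n_project: int,
) -> np.ndarray:
    """Project loci genotyped in varying sample sizes down to ``n_project``
    chromosomes.

    Each locus with ``n`` derived alleles among ``m`` genotyped chromosomes
    contributes hypergeometric weights P(j | m, n, n_project) to projected
    bins j.  Returns the expected spectrum over bins 0..n_project.
    """
    out = np.zeros(n_project + 1)
    j = np.arange(n_project + 1)
    for n, m in zip(np.asarray(allele_counts), np.asarray(chrom_counts)):
        if m < n_project:
            continue
        out += stats.hypergeom.pmf(j, int(m), int(n), n_project)
    return out


def correct_spectrum(spectrum: Spectrum, eps_det: dict, eps_gen: dict | None = None
                     ) -> Spectrum:
    """Attach detection/genotyping correction factors K = 1/(eps_det*eps_gen).

    ``eps_det`` / ``eps_gen`` map detection mode -> efficiency in (0, 1];
    ``eps_gen`` defaults to the efficiencies recorded on the spectrum.
    """
    if eps_gen is None:
        eps_gen = spectrum.eps_gen
    k = {}
    for mode in (REFERENCE, NON_REFERENCE):
        ed, eg = eps_det[mode], eps_gen[mode]
        if not (0.0 < ed <= 1.0 and 0.0 < eg <= 1.0):
            raise ValueError("efficiencies must be in (0, 1]")
        k[mode] = 1.0 / (ed * eg)
    return Spectrum(
        spectrum.n_samples,
        spectrum.counts_ref.copy(),
        spectrum.counts_nref.copy(),
        k_ref=k[REFERENCE],
        k_nref=k[NON_REFERENCE],
        fit_range=spectrum.fit_range,
        eps_gen=dict(spectrum.eps_gen),
    )


def ascertained_expectation(theta: float, n_samples: int, mode: str) -> np.ndarray:
    """Neutral-model expected counts per allele count i = 1..2N-1, under the
    reference-genome ascertainment condition for the given detection mode."""
    two_n = 2 * n_samples
    i = np.arange(1, two_n)
    if mode == REFERENCE:
        return np.full(two_n - 1, theta / two_n)
    if mode == NON_REFERENCE:
        return (theta / i) * (two_n - i) / two_n
    if mode == "all":
        return theta / i
    raise ValueError(f"unknown mode {mode!r}")


def fit_theta(
    spectrum: Spectrum,
    fit_range: tuple | None = None,
    n_e: int = DEFAULT_NE,
    corrected: bool = True,
) -> ThetaFit:
    """Poisson maximum-likelihood fit of theta to the ``theta/i`` spectrum.

    The ML estimate over the fit range is closed-form,
    ``theta_hat = sum n(i) / sum (1/i)``.  The 95% CI uses the variance of
    the corrected counts: each mode contributes Poisson noise inflated by its
    correction factor K, so Var n_MEI(i) = K_REF*theta/2N +
    K_NREF*(theta/i)(2N-i)/2N, which reduces to the plain Poisson profile
    when K = 1.  Chi-square is reported against the fitted curve with
    dof = bins - 1.
    """
    lo, hi = fit_range or spectrum.fit_range
    two_n = spectrum.two_n
    i = np.arange(lo, hi + 1)
    n = (spectrum.combined if corrected else spectrum.total)[lo : hi + 1]
    s = float(np.sum(1.0 / i))
    total = float(n.sum())
    theta = total / s
    if total == 0.0:
        fit = ThetaFit(0.0, 0.0, 0.0, 0.0, len(i) - 1, 0.0, (0.0, 0.0), n_e)
        return fit
    k_ref = spectrum.k_ref if corrected else 1.0
    k_nref = spectrum.k_nref if corrected else 1.0
    var = float(
        np.sum(k_ref * theta / two_n + k_nref * (theta / i) * (two_n - i) / two_n)
    )
    se = math.sqrt(var) / s
    ci_lo, ci_hi = max(0.0, theta - 1.96 * se), theta + 1.96 * se
    expected = theta / i
    chi2 = float(np.sum((n - expected) ** 2 / expected))
    mu = theta / (4.0 * n_e)
    return ThetaFit(theta, ci_lo, ci_hi, chi2, len(i) - 1, mu,
                    (ci_lo / (4.0 * n_e), ci_hi / (4.0 * n_e)), n_e)


def k_het(nf: np.ndarray) -> float:
    """Heterozygote-dropout correction from per-locus fragment totals.

    A heterozygous locus covered by NF fragments produces only
    reference-supporting evidence with probability Binomial(0; NF, 0.5) =
    0.5^NF, so the observable fraction of heterozygous loci is the mean of
    1 - 0.5^NF and K_HET = N_loci / sum(1 - 0.5^NF) >= 1.
    """
    nf = np.asarray(nf, dtype=float)
    if nf.size == 0:
        raise ValueError("no loci supplied")
    if np.any(nf < 0):
        raise ValueError("fragment counts must be non-negative")
    denom = float(np.sum(1.0 - np.power(0.5, nf)))
    if denom == 0.0:
        raise ValueError("all loci have zero coverage; K_HET undefined")
    return nf.size / denom


@dataclass
class SampleDiversity:
    sample_id: str
    pi_nref_raw: float
    pi_ref_raw: float
    k_het: float
    pi_mei: float
    pi_snp: float | None = None
    mu_mei: float | None = None
    t_coal: float | None = None


def sample_pi(
    pi_nref_raw: float,
    pi_ref_raw: float,
    k_het: float,
    eps_det: dict,
    eps_gen: dict,
) -> float:
    """Corrected heterozygous-locus count per genome for one sample.

    The heterozygote-dropout factor applies only to the non-reference
    component (reference-MEI genotypes come from an imputation-backed caller
    that does not lose heterozygotes to fragment sampling).
    """
    for d in (eps_det, eps_gen):
        for mode in (REFERENCE, NON_REFERENCE):
            if not 0.0 < d[mode] <= 1.0:
                raise ValueError("efficiencies must be in (0, 1]")
    nref = k_het * pi_nref_raw / (eps_det[NON_REFERENCE] * eps_gen[NON_REFERENCE])
    ref = pi_ref_raw / (eps_det[REFERENCE] * eps_gen[REFERENCE])
    return nref + ref


def mutation_rates(
    pi_mei: float,
    pi_snp: float,
    mu_snp_per_site: float = DEFAULT_MU_SNP,
    genome_length: float = DEFAULT_GENOME_LENGTH,
    t_gen: float = DEFAULT_T_GEN,
) -> tuple[float, float]:
    """MEI mutation rate and coalescent time from paired heterozygosities.

    Demography affects SNP and MEI heterozygosity identically, so the ratio
    pi_MEI/pi_SNP times the genome-wide SNP mutation rate
    (mu_SNP * genome length, per generation) estimates mu_MEI in insertions
    per genome per generation.  The coalescent time is the per-site SNP
    heterozygosity divided by 2*mu_SNP, in generations, times the generation
    time in years.
    """
    if pi_snp <= 0:
        raise ValueError("SNP heterozygosity must be positive")
    mu_mei = (pi_mei / pi_snp) * mu_snp_per_site * genome_length
    t_coal = (pi_snp / genome_length) / (2.0 * mu_snp_per_site) * t_gen
    return mu_mei, t_coal


def pairwise_differences(
    calls_a: dict,
    calls_b: dict,
    eps: dict,
    fdr: dict,
) -> tuple[float, float, dict]:
    """Corrected count of MEI presence/absence differences between two samples.

    ``calls_a`` / ``calls_b`` map detection mode -> set of locus keys present
    in that sample.  Per mode the raw count is the symmetric difference,
    corrected by (1 - FDR)/eps; the one-sigma error propagates binomial
    detection noise through the correction.
    """
    corrected = 0.0
    var = 0.0
    raw_by_mode = {}
    for mode in (REFERENCE, NON_REFERENCE):
        a = set(calls_a.get(mode, set()))
        b = set(calls_b.get(mode, set()))
        raw = len(a ^ b)
        raw_by_mode[mode] = raw
        factor = (1.0 - fdr.get(mode, 0.0)) / eps[mode]
        corrected += raw * factor
        var += raw * factor**2
    return corrected, math.sqrt(var), raw_by_mode
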