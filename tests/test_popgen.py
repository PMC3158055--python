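"""Spectra, ascertainment expectations, theta fitting, heterozygosity."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import meipop as mp
from meipop.model import NON_REFERENCE, REFERENCE
from meipop.popgen import Spectrum


def make_spectrum(counts_by_i, n_samples=25, mode=NON_REFERENCE):
    two_n = 2 * n_samples
    ref = np.zeros(two_n + 1)
    nref = np.zeros(two_n + 1)
    target = ref if mode == REFERENCE else nref
    for i, n in counts_by_i.items():
        target[i] = n
    return Spectrum(n_samples, ref, nref)


class TestBuildSpectrum:
    def build(self, n_genotyped, n_samples_total=30, dosage=1):
        cols = ["locus"]
        g = pd.DataFrame(
            {c: [dosage] * n_samples_total for c in cols},
            index=[f"s{k}" for k in range(n_samples_total)],
        )
        q = pd.DataFrame(
            {c: [99.0] * n_genotyped + [0.0] * (n_samples_total - n_genotyped)
             for c in cols},
            index=g.index,
        )
        meta = pd.DataFrame({"detection_mode": [NON_REFERENCE]}, index=cols)
        return mp.build_spectrum(g, q, meta, seed=3)

    def test_locus_below_25_genotyped_excluded(self):
        spec = self.build(24)["ALL"]
        assert spec.total.sum() == 0
        assert spec.eps_gen[NON_REFERENCE] == 0.0

    def test_all_het_panel_gives_allele_count_25(self):
        spec = self.build(25)["ALL"]
        assert spec.counts_nref[25] == 1
        assert spec.eps_gen[NON_REFERENCE] == 1.0

    def test_monomorphic_reference_loci_dropped(self):
        spec = self.build(30, dosage=0)["ALL"]
        assert spec.total.sum() == 0


def test_hypergeometric_projection_conserves_mass_and_mean():
    # one locus: 30 derived alleles among 80 chromosomes projected to 50
    proj = mp.hypergeometric_projection([30], [80], 50)
    assert proj.sum() == pytest.approx(1.0)
    mean = np.sum(np.arange(51) * proj)
    assert mean == pytest.approx(30 * 50 / 80)


@pytest.mark.parametrize(
    "eps_det,eps_gen,k",
    [(1.0, 1.0, 1.0), (0.75, 0.4, 10 / 3), (0.9, 0.8, 1.3889)],
)
def test_correction_factor_reciprocal(eps_det, eps_gen, k):
    spec = make_spectrum({10: 5})
    out = mp.correct_spectrum(
        spec,
        {REFERENCE: 1.0, NON_REFERENCE: eps_det},
        {REFERENCE: 1.0, NON_REFERENCE: eps_gen},
    )
    assert out.k_nref == pytest.approx(k, abs=1e-4)


def test_zero_efficiency_rejected():
    spec = make_spectrum({10: 5})
    with pytest.raises(ValueError):
        mp.correct_spectrum(spec, {REFERENCE: 1.0, NON_REFERENCE: 0.0},
                            {REFERENCE: 1.0, NON_REFERENCE: 1.0})


class TestAscertainedExpectation:
    def test_reference_mode_flat(self):
        e = mp.ascertained_expectation(1000.0, 25, REFERENCE)
        assert np.allclose(e, 1000.0 / 50)

    def test_nonreference_vanishes_at_fixation(self):
        e = mp.ascertained_expectation(1000.0, 25, NON_REFERENCE)
        i = np.arange(1, 50)
        assert np.allclose(e, (1000.0 / i) * (50 - i) / 50)
        assert e[-1] == pytest.approx(1000.0 / 49 / 50)

    def test_modes_partition_the_neutral_spectrum(self):
        theta = 1860.0
        total = (mp.ascertained_expectation(theta, 25, REFERENCE)
                 + mp.ascertained_expectation(theta, 25, NON_REFERENCE))
        assert np.allclose(total, mp.ascertained_expectation(theta, 25, "all"))


class TestFitTheta:
    def test_rounded_neutral_spectrum_self_consistency(self):
        theta = 1000.0
        counts = {i: round(theta / i) for i in range(1, 50)}
        fit = mp.fit_theta(make_spectrum(counts), corrected=False)
        assert abs(fit.theta - theta) / theta < 0.01
        assert fit.chi2 < 1.0  # rounding noise only
        assert fit.dof == 40

    def test_mu_theta_scaling(self):
        counts = {i: round(1700.0 / i) for i in range(1, 50)}
        fit = mp.fit_theta(make_spectrum(counts), corrected=False)
        assert fit.mu_theta == pytest.approx(fit.theta / 40_000)

    def test_all_zero_spectrum(self):
        fit = mp.fit_theta(make_spectrum({}), corrected=False)
        assert fit.theta == 0.0

    def test_unbiased_with_calibrated_ci_coverage(self):
        # Poisson replicates of the theta/i spectrum: the estimator is
        # unbiased and the 95% CI covers the truth >= 93% of the time
        rng = np.random.default_rng(31)
        theta, reps = 1860.0, 500
        i = np.arange(7, 48)
        s = np.sum(1.0 / i)
        draws = rng.poisson(theta / i, size=(reps, len(i)))
        theta_hat = draws.sum(axis=1) / s
        se_mean = np.sqrt(theta / s) / np.sqrt(reps)
        assert abs(theta_hat.mean() - theta) < 2 * se_mean
        covered = 0
        for t in theta_hat:
            half = 1.96 * np.sqrt(t / s)
            covered += (t - half) <= theta <= (t + half)
        assert covered / reps >= 0.93


def test_simulated_ascertainment_split_reproduces_both_shapes():
    # chi-square goodness of fit of the flagged catalog against the two
    # ascertained expectation curves
    theta = 5000.0
    cfg = mp.SimConfig(theta_by_family={"Alu": theta, "L1": 0.0, "SVA": 0.0},
                       n_samples_by_pop={"CEU": 25}, genome_length=2_850_000_000,
                       seed=37)
    loci, _ = mp.simulate_catalog(cfg)
    ref = np.zeros(51)
    nref = np.zeros(51)
    for l in loci:
        (ref if l.on_reference else nref)[l.allele_count] += 1
    i = np.arange(1, 50)
    for obs, expect in [
        (ref[1:50], np.full(49, theta / 50)),
        (nref[1:50], (theta / i) * (50 - i) / 50),
    ]:
        chi2 = np.sum((obs - expect) ** 2 / expect)
        p = stats.chi2.sf(chi2, len(i))
        assert p > 0.001


class TestKHet:
    def test_large_coverage_limit(self):
        assert mp.k_het(np.full(100, 20)) == pytest.approx(1.0, abs=1e-5)

    def test_two_fragment_coverage(self):
        # Binomial(0; 2, 0.5) = 0.25 -> K_HET = 1/(1 - 0.25) = 4/3
        assert mp.k_het(np.full(10, 2)) == pytest.approx(4 / 3)

    def test_zero_coverage_undefined(self):
        with pytest.raises(ValueError):
            mp.k_het(np.zeros(5))

    def test_corrected_het_count_unbiased_at_poisson_coverage(self):
        # observable het loci after fragment sampling, corrected by K_HET,
        # recover the true count over replicates
        rng = np.random.default_rng(41)
        n_het, reps = 1000, 300
        errs = []
        for _ in range(reps):
            nf = rng.poisson(4.0, size=n_het)
            seen = rng.random(n_het) > 0.5**nf  # at least one alt fragment
            corrected = mp.k_het(nf) * seen.sum()
            errs.append(corrected - n_het)
        errs = np.array(errs)
        se = errs.std() / np.sqrt(reps)
        assert abs(errs.mean()) < 2 * se + 2.0


def test_sample_pi_arithmetic():
    pi = mp.sample_pi(
        500, 600, 4 / 3,
        {NON_REFERENCE: 0.75, REFERENCE: 0.9},
        {NON_REFERENCE: 0.5, REFERENCE: 0.8},
    )
    assert pi == pytest.approx(500 * (4 / 3) / 0.375 + 600 / 0.72)
    assert pi == pytest.approx(2611.1, abs=0.1)


def test_all_unit_corrections_sum_raw_counts():
    ones = {NON_REFERENCE: 1.0, REFERENCE: 1.0}
    assert mp.sample_pi(500, 600, 1.0, ones, ones) == 1100


def test_mutation_rates_closed_form():
    # per-site SNP heterozygosity 9e-4 -> t = 9e-4/(2*1.8e-8)*25 = 625,000 y
    L = 2_850_000_000
    mu, t = mp.mutation_rates(0.0, 9e-4 * L)
    assert mu == 0.0
    assert t == pytest.approx(625_000.0)
    mu2, _ = mp.mutation_rates(2160.0, 9e-4 * L)
    assert mu2 == pytest.approx((2160.0 / (9e-4 * L)) * 1.8e-8 * L)


def test_mutation_rates_rejects_nonpositive_snp_het():
    with pytest.raises(ValueError):
        mp.mutation_rates(100.0, 0.0)


class TestPairwiseDifferences:
    def test_identical_call_sets(self):
        calls = {NON_REFERENCE: {("chr1", 1, "Alu")}, REFERENCE: set()}
        eps = {NON_REFERENCE: 0.8, REFERENCE: 0.9}
        count, sigma, raw = mp.pairwise_differences(calls, calls, eps, {})
        assert count == 0.0 and sigma == 0.0

    def test_recovery_of_true_difference_count(self):
        rng = np.random.default_rng(43)
        eps, fdr, n_true = 0.8, 0.05, 1000
        keys = [("chr1", k, "Alu") for k in range(n_true)]
        # each true difference is seen when detected in exactly the carrier
        seen = {k for k in keys if rng.random() < eps}
        n_false = rng.binomial(len(seen), fdr / (1 - fdr))
        false = {("chr1", -k - 1, "Alu") for k in range(n_false)}
        a = {NON_REFERENCE: seen | false, REFERENCE: set()}
        b = {NON_REFERENCE: set(), REFERENCE: set()}
        count, sigma, _ = mp.pairwise_differences(
            a, b, {NON_REFERENCE: eps, REFERENCE: 1.0},
            {NON_REFERENCE: fdr, REFERENCE: 0.0},
        )
        assert abs(count - n_true) < 2 * sigma + 2 * np.sqrt(n_true)

    def test_corrected_counts_linear_in_divergence(self):
        # pairs of samples at increasing divergence: corrected counts scale
        # linearly (the property that makes the pairwise count a clock)
        rng = np.random.default_rng(44)
        eps, fdr = 0.7, 0.05
        times = np.array([1, 2, 3, 4, 5], dtype=float)
        rate = 400  # differences per unit time
        counts = []
        for t in times:
            n = rng.poisson(rate * t)
            seen = rng.binomial(n, eps)
            n_false = rng.binomial(seen, fdr / (1 - fdr))
            a = {NON_REFERENCE: {("chr1", k, "Alu") for k in range(seen + n_false)},
                 REFERENCE: set()}
            b = {NON_REFERENCE: set(), REFERENCE: set()}
            c, _, _ = mp.pairwise_differences(
                a, b, {NON_REFERENCE: eps, REFERENCE: 1.0},
                {NON_REFERENCE: fdr, REFERENCE: 0.0})
            counts.append(c)
        r = np.corrcoef(times, counts)[0, 1]
        assert r**2 > 0.95
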