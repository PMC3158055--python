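"""Generator contracts: neutral spectrum, ascertainment split, Hardy-Weinberg
genotypes, evidence model, and deletion emulation."""

import numpy as np
import pandas as pd
import pytest

import meipop as mp
from meipop.model import NON_REFERENCE, REFERENCE
from meipop.simulate import TrueLocus


def test_zero_theta_gives_empty_catalog():
    cfg = mp.SimConfig(theta_by_family={"Alu": 0.0, "L1": 0.0, "SVA": 0.0},
                       n_samples_by_pop={"CEU": 10}, genome_length=10_000_000)
    loci, _ = mp.simulate_catalog(cfg)
    assert loci == []


def test_negative_config_rejected():
    cfg = mp.SimConfig(theta_by_family={"Alu": -1.0, "L1": 0.0, "SVA": 0.0})
    with pytest.raises(ValueError):
        mp.simulate_catalog(cfg)


def test_total_segregating_loci_matches_harmonic_sum():
    # E[total] = theta * sum_{i=1}^{2N-1} 1/i; Poisson noise around it
    theta = 1860.0
    cfg = mp.SimConfig(theta_by_family={"Alu": theta, "L1": 0.0, "SVA": 0.0},
                       n_samples_by_pop={"CEU": 25}, genome_length=2_850_000_000,
                       seed=13)
    loci, _ = mp.simulate_catalog(cfg)
    expected = theta * np.sum(1.0 / np.arange(1, 50))
    sd = np.sqrt(expected)
    assert abs(len(loci) - expected) < 4 * sd


def test_reference_flagging_probability_scales_with_allele_count():
    cfg = mp.SimConfig(theta_by_family={"Alu": 5000.0, "L1": 0.0, "SVA": 0.0},
                       n_samples_by_pop={"CEU": 25}, genome_length=2_850_000_000,
                       seed=17)
    loci, _ = mp.simulate_catalog(cfg)
    # at i = N (frequency 1/2) the reference carries the allele half the time
    mid = [l for l in loci if l.allele_count == 25]
    frac = np.mean([l.on_reference for l in mid])
    assert abs(frac - 0.5) < 4 * np.sqrt(0.25 / len(mid))
    # overall fraction: sum(theta/2N) / sum(theta/i) = (2N-1)/(2N * H)
    h = np.sum(1.0 / np.arange(1, 50))
    overall = 49 / (50 * h)
    frac_all = np.mean([l.on_reference for l in loci])
    assert abs(frac_all - overall) < 4 * np.sqrt(overall * (1 - overall) / len(loci))


@pytest.mark.parametrize("freq,expect", [(0.0, 0), (1.0, 2)])
def test_cohort_fixed_frequencies(freq, expect):
    locus = TrueLocus("chr1", 100, "Alu", "+", 15, {"CEU": freq}, False,
                      "intergenic", "CEU", allele_count=25, locus_id="x")
    cfg = mp.SimConfig(n_samples_by_pop={"CEU": 50}, exact_panel=False, seed=1)
    g = mp.simulate_cohort([locus], cfg)
    assert (g.to_numpy() == expect).all()


def test_cohort_hardy_weinberg_heterozygosity():
    # f = 0.5 -> het fraction 2f(1-f) = 0.5 within +/- 0.015 at 10,000 samples
    locus = TrueLocus("chr1", 100, "Alu", "+", 15, {"POP": 0.5}, False,
                      "intergenic", "POP", allele_count=25, locus_id="x")
    cfg = mp.SimConfig(n_samples_by_pop={"POP": 10_000}, exact_panel=False, seed=2)
    g = mp.simulate_cohort([locus], cfg)
    het = (g.to_numpy() == 1).mean()
    assert abs(het - 0.5) < 0.015


def test_exact_panel_realises_drawn_allele_counts(small_sim_config):
    loci, _ = mp.simulate_catalog(small_sim_config)
    g = mp.simulate_cohort(loci, small_sim_config)
    arr = g.to_numpy()
    n_panel = small_sim_config.n_chrom_sampled // 2
    for j, locus in enumerate(loci[:200]):
        assert arr[:n_panel, j].sum() == locus.allele_count


def test_evidence_pure_reference_for_homozygous_reference():
    locus = TrueLocus("chr1", 100, "Alu", "+", 15, {"P": 0.0}, False,
                      "intergenic", "P", allele_count=1, locus_id="x")
    cfg = mp.SimConfig(n_samples_by_pop={"P": 200}, exact_panel=False,
                       genotype_error=0.0, seed=3)
    g = mp.simulate_cohort([locus], cfg)
    support, _ = mp.simulate_evidence(g, [locus], cfg)
    assert (support["n_alt5"] + support["n_alt3"]).sum() == 0


def test_evidence_heterozygote_alt_fraction_half():
    locus = TrueLocus("chr1", 100, "Alu", "+", 15, {"P": 0.5}, False,
                      "intergenic", "P", allele_count=25, locus_id="x")
    cfg = mp.SimConfig(n_samples_by_pop={"P": 2000}, exact_panel=False,
                       coverage_mean=20.0, seed=4)
    g = mp.simulate_cohort([locus], cfg)
    support, _ = mp.simulate_evidence(g, [locus], cfg)
    het = support.merge(
        g.iloc[:, 0].rename("g"), left_on="sample_id", right_index=True)
    het = het[het["g"] == 1]
    alt = (het["n_alt5"] + het["n_alt3"]).sum()
    tot = alt + het["n_ref"].sum()
    assert abs(alt / tot - 0.5) < 0.01


def test_zero_alt_probability_at_het_matches_poisson_thinning():
    # P(no insertion-supporting fragment | het, coverage 4) = e^{-2}
    locus = TrueLocus("chr1", 100, "Alu", "+", 15, {"P": 1.0}, False,
                      "intergenic", "P", allele_count=25, locus_id="x")
    cfg = mp.SimConfig(n_samples_by_pop={"P": 20_000}, exact_panel=False,
                       coverage_mean=4.0, seed=5)
    g = mp.simulate_cohort([locus], cfg)
    g.iloc[:, 0] = 1  # force heterozygous
    support, _ = mp.simulate_evidence(g, [locus], cfg)
    p0 = ((support["n_alt5"] + support["n_alt3"]) == 0).mean()
    expect = np.exp(-2.0)
    assert abs(p0 - expect) < 4 * np.sqrt(expect * (1 - expect) / len(support))


def test_evidence_rejects_bad_coverage():
    cfg = mp.SimConfig(coverage_mean=0.0)
    with pytest.raises(ValueError):
        mp.simulate_evidence(pd.DataFrame(), [], cfg)


def test_clean_deletions_all_pass_reference_selection(small_sim_config):
    cfg = small_sim_config
    cfg.deletion_jitter_sd = 0.0
    cfg.decoy_fraction = 0.0
    loci, _ = mp.simulate_catalog(cfg)
    dels, anns, gaps = mp.simulate_deletions(loci, cfg)
    selected = mp.select_reference_mei(dels, anns, gaps)
    assert len(selected) == len(dels) == sum(l.on_reference for l in loci)


def test_decoy_deletions_are_rejected(small_sim_config):
    cfg = small_sim_config
    cfg.decoy_fraction = 0.3
    loci, _ = mp.simulate_catalog(cfg)
    dels, anns, gaps = mp.simulate_deletions(loci, cfg)
    selected = mp.select_reference_mei(dels, anns, gaps)
    true_ids = {l.locus_id for l in loci if l.on_reference}
    assert {s.locus_id for s in selected} <= true_ids
    assert len(selected) == len(true_ids)


def test_jittered_alu_deletions_rejected_at_predictable_rate():
    # Alu window is 20 bp: with endpoint jitter sd 30 the survival probability
    # is P(|N(0,30)| <= 20)^2 (both endpoints), ignoring the weaker overlap rule
    from scipy import stats

    cfg = mp.SimConfig(theta_by_family={"Alu": 600.0, "L1": 0.0, "SVA": 0.0},
                       n_samples_by_pop={"CEU": 25}, genome_length=500_000_000,
                       deletion_jitter_sd=30.0, seed=19)
    loci, _ = mp.simulate_catalog(cfg)
    dels, anns, gaps = mp.simulate_deletions(loci, cfg)
    selected = mp.select_reference_mei(dels, anns, gaps)
    p_end = stats.norm.cdf(20.5, 0, 30) - stats.norm.cdf(-20.5, 0, 30)
    expect = p_end**2
    frac = len(selected) / len(dels)
    assert abs(frac - expect) < 4 * np.sqrt(expect * (1 - expect) / len(dels))


def test_identical_seed_reproduces_outputs(small_sim_config):
    import dataclasses

    loci_a, _ = mp.simulate_catalog(small_sim_config)
    loci_b, _ = mp.simulate_catalog(small_sim_config)
    assert [dataclasses.asdict(a) for a in loci_a] == [
        dataclasses.asdict(b) for b in loci_b
    ]
    ga = mp.simulate_cohort(loci_a, small_sim_config)
    gb = mp.simulate_cohort(loci_b, small_sim_config)
    pd.testing.assert_frame_equal(ga, gb)


def test_tsd_lengths_nonnegative_with_configured_moments(small_catalog):
    loci, _ = small_catalog
    tsd = np.array([l.tsd_len for l in loci])
    assert (tsd >= 0).all()
    assert abs(tsd.mean() - 15.2) < 1.0  # truncation at 0 shifts the mean up a touch
    assert abs(tsd.std() - 7.0) < 1.0
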