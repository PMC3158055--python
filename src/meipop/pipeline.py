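"""End-to-end driver: simulate a cohort, detect, genotype, and analyse.

Detection at pipeline scale is emulated by thinning the true catalog at the
configured per-mode dropout rates and admixing false calls at the configured
false-detection rate; fragment-level detection (read-pair/split-read
clustering) is exercised by the detection module directly on fragment records
and is too slow to run genome-wide here.  Every stage is seeded from the
single pipeline seed, so identical configurations reproduce identical
artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as mio
from .catalog import Catalog, merge_callsets, scan_density
from .functional import count_by_region, suppression_stats
from .genotyping import GenotypeModel, call_genotype_matrix
from .model import FAMILIES, MeiLocus, NON_REFERENCE, REFERENCE
from .popgen import (
    GQ_THRESHOLDS,
    build_spectrum,
    correct_spectrum,
    fit_theta,
    k_het,
    mutation_rates,
    sample_pi,
)
from .simulate import SimConfig, TrueLocus, simulate_catalog, simulate_cohort, simulate_evidence

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    genotype_model: GenotypeModel = field(default_factory=GenotypeModel)
    gq_thresholds: dict = field(default_factory=lambda: dict(GQ_THRESHOLDS))
    ref_gq_efficiency: float = 0.8  # fraction of reference-MEI genotypes at GQ 10
    pi_snp_per_site: float = 9.0e-4  # per-site SNP heterozygosity of the cohort
    n_spectrum_samples: int = 25
    out_dir: str | None = None
    seed: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {
                "sim": vars(self.sim),
                "model": vars(self.genotype_model),
                "gq": self.gq_thresholds,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    catalog: Catalog
    loci: list
    spectra: dict  # population -> corrected Spectrum
    fits: dict  # population -> ThetaFit
    diversity: pd.DataFrame
    functional: dict  # region -> SuppressionStats
    density: object
    log: dict


def _as_call(locus: TrueLocus, locus_id: str | None = None) -> MeiLocus:
    return MeiLocus(
        chrom=locus.chrom,
        pos=locus.pos,
        family=locus.family,
        detection_mode=locus.detection_mode,
        tsd_len=locus.tsd_len,
        locus_id=locus_id or locus.locus_id,
    )


def _emulate_detection(loci, config: PipelineConfig, rng):
    """Thin true loci by per-mode dropout and admix false calls."""
    detected = [
        l for l in loci if rng.random() >= config.sim.dropout_sim[l.detection_mode]
    ]
    fdr = config.sim.fdr_sim
    n_false = rng.binomial(len(detected), fdr / (1.0 - fdr)) if fdr > 0 else 0
    fams = list(config.sim.family_props)
    props = np.array([config.sim.family_props[f] for f in fams])
    false_loci = []
    for k in range(n_false):
        fam = str(rng.choice(fams, p=props / props.sum()))
        false_loci.append(
            TrueLocus(
                chrom="chr1",
                pos=int(rng.integers(1, config.sim.genome_length + 1)),
                family=fam,
                strand="+",
                tsd_len=0,
                popn_freq={},
                on_reference=False,
                region_class="intergenic",
                population="",
                allele_count=0,
                locus_id=f"false{k:05d}",
            )
        )
    return detected, false_loci


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis on one simulated cohort."""
    rng = np.random.default_rng(config.seed + 10)
    config.sim.seed = config.sim.seed or config.seed
    logger.info("simulating catalog (seed %d)", config.sim.seed)
    true_loci, tracks = simulate_catalog(config.sim)
    detected, false_loci = _emulate_detection(true_loci, config, rng)
    all_loci = sorted(detected + false_loci, key=lambda l: (l.chrom, l.pos))
    logger.info(
        "loci: %d true, %d detected, %d false calls",
        len(true_loci), len(detected), len(false_loci),
    )
    genotypes = simulate_cohort(all_loci, config.sim)
    support, _ = simulate_evidence(genotypes, all_loci, config.sim)

    # genotype non-reference loci from fragment support; reference loci are an
    # imputation-backed input channel emulated at the configured efficiency
    nref_ids = {l.locus_id for l in all_loci if not l.on_reference}
    called = call_genotype_matrix(
        support[support["locus_id"].isin(nref_ids)], config.genotype_model
    )
    g_nref = called.pivot(index="sample_id", columns="locus_id", values="g")
    q_nref = called.pivot(index="sample_id", columns="locus_id", values="gq")
    ref_ids = [l.locus_id for l in all_loci if l.on_reference]
    g_ref = genotypes[ref_ids].astype(float)
    q_ref = pd.DataFrame(
        np.where(rng.random(g_ref.shape) < config.ref_gq_efficiency, 10.0, 0.0),
        index=g_ref.index, columns=g_ref.columns,
    )
    order = [l.locus_id for l in all_loci]
    g_all = pd.concat([g_nref, g_ref], axis=1)[order]
    q_all = pd.concat([q_nref, q_ref], axis=1)[order]
    g_all.attrs["population"] = genotypes.attrs["population"]

    loci_meta = pd.DataFrame(
        {
            "detection_mode": [l.detection_mode for l in all_loci],
            "family": [l.family for l in all_loci],
        },
        index=pd.Index(order, name="locus_id"),
    )

    logger.info("building spectra and fitting theta")
    spectra = build_spectrum(
        g_all, q_all, loci_meta,
        gq_thresholds=config.gq_thresholds,
        n_spectrum_samples=config.n_spectrum_samples,
        seed=config.seed + 20,
    )
    eps_det = {m: 1.0 - config.sim.dropout_sim[m] for m in (REFERENCE, NON_REFERENCE)}
    corrected = {}
    fits = {}
    for pop, spec in spectra.items():
        eps_gen = {
            m: (v if np.isfinite(v) and v > 0 else 1.0)
            for m, v in spec.eps_gen.items()
        }
        corrected[pop] = correct_spectrum(spec, eps_det, eps_gen)
        fits[pop] = fit_theta(corrected[pop])

    logger.info("per-sample heterozygosity")
    diversity = _diversity_table(g_all, q_all, support, loci_meta, eps_det, config)

    calls = [_as_call(l) for l in all_loci]
    catalog = merge_callsets({"pipeline": calls},
                             genome_length=config.sim.genome_length)
    density = scan_density(catalog)
    func_counts = count_by_region(
        [c for c in catalog.loci if c.detection_mode == NON_REFERENCE],
        tracks.regions, l_tot=config.sim.genome_length,
    )
    functional = {label: suppression_stats(rc) for label, rc in func_counts.items()
                  if rc.l_obs > 0 and rc.n_tot > 0}

    log = {
        "config_digest": config.digest(),
        "seed": config.seed,
        "n_true": len(true_loci),
        "n_detected": len(detected),
        "n_false": len(false_loci),
        "n_catalog": len(catalog),
        "mean_spacing_bp": catalog.mean_spacing,
        "theta": {pop: fit.theta for pop, fit in fits.items()},
    }
    result = PipelineResult(catalog, all_loci, corrected, fits, diversity,
                            functional, density, log)
    if config.out_dir:
        _write_outputs(result, g_all, q_all, config)
    return result


def _diversity_table(g_all, q_all, support, loci_meta, eps_det, config):
    thr = config.gq_thresholds
    nf = (support["n_alt5"] + support["n_alt3"] + support["n_ref"]).to_numpy()
    support = support.assign(nf=nf)
    nf_wide = support.pivot(index="sample_id", columns="locus_id", values="nf")
    nf_wide = nf_wide[g_all.columns]
    mode = loci_meta["detection_mode"]
    is_ref = (mode == REFERENCE).to_numpy()
    rows = []
    g = g_all.to_numpy()
    q = q_all.to_numpy()
    nfm = nf_wide.to_numpy()
    thr_vec = np.where(is_ref, thr[REFERENCE], thr[NON_REFERENCE])
    pi_snp = config.pi_snp_per_site * config.sim.genome_length
    for s_idx, sample in enumerate(g_all.index):
        ok = q[s_idx] >= thr_vec
        het = g[s_idx] == 1
        pi_ref_raw = float(np.sum(ok & het & is_ref))
        pi_nref_raw = float(np.sum(ok & het & ~is_ref))
        nf_het = nfm[s_idx][ok & ~is_ref]
        kh = k_het(nf_het[nf_het > 0]) if np.any(nf_het > 0) else 1.0
        eps_gen = {
            REFERENCE: max(float(np.mean(ok[is_ref])) if is_ref.any() else 1.0, 1e-9),
            NON_REFERENCE: max(float(np.mean(ok[~is_ref])) if (~is_ref).any() else 1.0,
                               1e-9),
        }
        pi_mei = sample_pi(pi_nref_raw, pi_ref_raw, kh, eps_det, eps_gen)
        mu_mei, t_coal = mutation_rates(
            pi_mei, pi_snp,
            genome_length=config.sim.genome_length,
        )
        rows.append(
            {
                "sample_id": sample,
                "pi_nref_raw": pi_nref_raw,
                "pi_ref_raw": pi_ref_raw,
                "k_het": kh,
                "pi_mei": pi_mei,
                "pi_snp": pi_snp,
                "mu_mei": mu_mei,
                "t_coal_years": t_coal,
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")


def _write_outputs(result: PipelineResult, g_all, q_all, config: PipelineConfig):
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mio.write_vcf(out / "catalog.vcf", result.catalog.loci,
                  contigs={"chr1": config.sim.genome_length})
    for pop, spec in result.spectra.items():
        df = pd.DataFrame(
            {
                "i": np.arange(spec.two_n + 1),
                "n_ref": spec.counts_ref,
                "n_nref": spec.counts_nref,
                "n_mei_corrected": spec.combined,
            }
        )
        df.to_csv(out / f"spectrum_{pop}.tsv", sep="\t", index=False)
    mio.write_json(
        out / "fits.json",
        {
            pop: {
                "theta": fit.theta,
                "ci": [fit.ci_lo, fit.ci_hi],
                "chi2": fit.chi2,
                "dof": fit.dof,
                "mu_theta": fit.mu_theta,
            }
            for pop, fit in result.fits.items()
        },
    )
    result.diversity.to_csv(out / "diversity.tsv", sep="\t")
    func = pd.DataFrame(
        [
            {
                "region": st.region_label,
                "expected": st.expected,
                "observed": st.observed,
                "suppression": st.suppression,
                "log10_p": st.log10_p,
                "direction": st.direction,
            }
            for st in result.functional.values()
        ]
    )
    func.to_csv(out / "functional.tsv", sep="\t", index=False)
    mio.write_json(out / "run_log.json", result.log)
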