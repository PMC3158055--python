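# Methods

## Model

The simulator and estimators are built on the standard neutral
(infinite-sites) model of allele drift. For a sample of 2N chromosomes the
expected number of segregating loci at derived-allele count *i* is θ/*i*,
where θ is the family-specific diversity parameter on the locus scale
(θ = 4·N_e·μ with μ the insertion rate per genome per generation). The
catalog generator draws the count of loci at each *i* ∈ {1, …, 2N−1} from
Poisson(θ/*i*) directly rather than running a coalescent: the fitted model
is exactly this form, so the generator and the estimator share no hidden
approximation, and an external coalescent simulator can serve as an
independent cross-check when population history matters.

Reference-genome ascertainment is modelled by designating one sampled
chromosome as "the reference". A locus whose derived allele lands on that
chromosome (probability *i*/2N) is a *reference* MEI — present in the
assembly, observed as a deletion in samples. The remaining loci are
*non-reference* MEI, observed as insertions. Conditioning reshapes the
observable spectra into

    reference:      θ/2N                 (flat in i)
    non-reference:  (θ/i)·(2N−i)/2N

whose sum restores θ/*i* for every *i*. This treats the reference as a
random population sample — simplistic, but it is the assumption the
expectations encode, and the simulator realises it exactly (the designated
reference haplotype is chromosome 0 of the first panel sample, seedable).

## Simulator parameters

| parameter | default | meaning |
|---|---|---|
| `theta_by_family` | Alu 1570, L1 224, SVA 80 | per-population diversity parameters (locus scale) |
| `n_samples_by_pop` | CEU 60, YRI 59, CHBJPT 60 | diploid cohort sizes |
| `n_chrom_sampled` | 50 | haploid spectrum panel size 2N (25 diploids) |
| `genome_length` | 2.85×10⁹ bp | accessible genome |
| `coverage_mean` | 4.0 | mean informative fragments per sample per locus |
| `frag_len_mean/sd` | 200 / 30 bp | read-pair library fragment length |
| `tsd_mean/sd` | 15 / 7 bp | target-site duplication length (truncated normal at 0) |
| `family_props` | 0.855 / 0.120 / 0.025 | Alu / L1 / SVA proportions |
| `fdr_sim` | 0.045 | simulated false-call fraction of the detected set |
| `dropout_sim` | non-ref 0.25, ref 0.07 | per-mode detection dropout |

TSD lengths are drawn from a normal truncated at zero because lengths are
non-negative and only the mode and spread are specified; truncation shifts
the realised mean up by ≈0.3 bp. Genotypes are Hardy–Weinberg binomial
draws; with `exact_panel` (default) the first 2N chromosomes of each
population carry exactly the drawn allele count, dealt uniformly and
conditioned on the reference-haplotype flag, so panel spectra sit exactly on
the drawn counts. Fragment evidence per sample×locus is NF ~
Poisson(coverage), insertion-supporting fragments Binomial(NF, p_g) with
p_g = 0 / 0.5 / 1 by genotype, split evenly between the 5′ and 3′ sides.

Population structure is deliberately absent: per-population catalogs are
independent draws (a shared-frequency mode is not provided), and there is no
linkage, selection, or demography in the generator. Passing tests therefore
demonstrate correctness of the estimators under the neutral equilibrium
model, not robustness to demographic history — spectra from
real populations deviate from θ/*i* in exactly the ways a single-θ model
cannot capture.

The annotation track tiles one gene per slot across the genome with nested
UTR/CDS blocks, matching target genomic fractions (gene 0.376, UTR 0.0196,
CDS 0.0255 — the ratios implied by region-placement expectations over the
accessible genome). The element-annotation track used by the masking rule is
sparse (2 elements/Mb by default): enough to exercise the detection filters,
far below the real repeat density of a mammalian genome.

## Detection

RP calling clusters element-supporting fragments per (chromosome, family) by
single linkage with gap ≤ the median library fragment length — an open
design choice, made because two mates of one insertion cannot anchor further
apart than a fragment length. A cluster becomes a call only with ≥2
fragments on each side; the breakpoint is the leftmost coordinate compatible
with the cluster (one past the innermost 5′ anchor, clipped at the first 3′
anchor), with CI ± half a fragment length. Calls within one fragment length
of a same-family annotated element are suppressed, removing the
background-pair artifact in which library-tail fragment lengths bracketing a
reference element mimic the insertion signature.

SR calling needs one split fragment; the cluster gap is 35 bp (≈ mean TSD +
2 sd). With both sides present, the TSD is the overlap of the 5′ and 3′
reference-mapped extents and the call sits at the leftmost TSD coordinate;
the TSD interval is the CI. One-sided SR calls use the split point with TSD
unknown.

Reference-MEI selection requires reciprocal overlap > 50% with an annotated
element, endpoint agreement within 20 bp (Alu) or 200 bp (L1/SVA), and ≥75%
of deleted bases inside chimpanzee-assembly gaps. Intervals are compared
1-based inclusive; BED is converted at the I/O boundary.

Merging uses a 100 bp single-linkage window within (family, detection mode),
keeping the SR coordinate when available (best position resolution),
otherwise the highest-support RP member, with per-side support summed.
Cross-catalog matching is greedy nearest-first one-to-one with ties broken
toward the lower coordinate, families required to agree.

## Genotyping

Posterior(g) ∝ P(g)·Binomial(N_ALT; N_ALT+N_REF, p_g), flat prior 1/3,
p_het = 0.5, p_hom_ref = 0.02 (and p_hom_alt = 0.98) to allow a small
fragment-misassignment rate; GQ = −10·log₁₀(1 − max posterior), capped at
99, and defined as 0 when there is no evidence. Ties break toward
0/0 < 0/1 < 1/1.

Two properties of this model are worth knowing. First, *two concordant
fragments cannot reach GQ 7* under a flat prior: the heterozygote likelihood
of two same-allele fragments is 0.25, so the best attainable posterior is
1/(1+0.25) = 0.8 exactly as p_hom_ref → 0, i.e. GQ → 6.99 from below. The
crossing points are one fragment of each allele (GQ 8.7) or three concordant
fragments (GQ 9.3) — consistent with the rule of thumb that GQ ≥ 7 sites
carry at least two supporting fragments, but not driven by the
p_hom_ref value. Second, GQ ≥ 7 selection *depletes heterozygotes*: mixed
evidence like 1 alt + 3 ref is genuinely ambiguous and fails the threshold
more often than concordant homozygous evidence. In cohort simulations at
coverage 4 this depresses the fitted θ by ≈5%; it is the same phenomenon the
K_HET heterozygosity correction addresses, and it is left uncorrected in the
spectrum path; users comparing rate estimates across thresholds should
expect scale shifts of this order.

Reference-MEI genotyping is treated as an external input channel (in
practice an imputation-backed deletion genotyper supplies it): the pipeline
emulates
it by passing true genotypes at GQ 10 with a configurable per-sample
efficiency (default 0.8), thresholded at GQ ≥ 10 versus GQ ≥ 7 for
non-reference calls.

## Spectra, θ, and heterozygosity

A locus enters a population's allele-count spectrum when ≥25 samples pass
the mode's GQ threshold; exactly 25 passing samples (a seeded random subset)
define the allele count, and monomorphic outcomes are dropped. Per-mode
genotyping efficiency ε_GEN is the fraction of loci reaching 25 genotyped
samples. The corrected spectrum is n_MEI(i) = K_REF·n_REF(i) +
K_NREF·n_NREF(i) with K = 1/(ε_DET·ε_GEN). Hypergeometric projection onto
50 chromosomes is provided for display spectra only; fitting always uses the
count spectra, since projection correlates bins.

θ is fitted by Poisson maximum likelihood over allele counts 7–47
(frequency 0.15–0.95, avoiding the poorly detected tails), which for the
θ/*i* mean has the closed form θ̂ = Σn(i)/Σ(1/i). The 95% CI uses the
variance of the corrected counts — each mode contributes Poisson noise
inflated by its K factor — which reduces to the plain Poisson profile at
K = 1; χ² against the fitted curve is reported with dof = bins − 1 for
comparability (χ²/dof exceeds 1 for corrected spectra because the correction
inflates the variance). μ(θ) = θ/(4·N_e) with N_e = 10,000.

Per-sample heterozygosity applies three corrections to the raw heterozygous
locus counts: K_HET = N_loci/Σ(1−0.5^NF) for heterozygotes whose fragments
all sampled one allele (non-reference mode only — the reference channel's
imputation does not lose heterozygotes this way), detection sensitivity, and
per-sample genotyping efficiency. μ_MEI = (π_MEI/π_SNP)·μ_SNP·L with
μ_SNP = 1.8×10⁻⁸ per site per generation and L = 2.85 Gb, so the rate is
per genome per generation; demography cancels in the ratio. Coalescent time
is the standard pairwise form t = (π_SNP/L)/(2·μ_SNP)·T_GEN with T_GEN =
25 y, validated by the 625,000-year magnitude at per-site heterozygosity
9×10⁻⁴.

Pairwise differences between two individuals are the symmetric difference of
presence sets per detection mode, corrected by (1−FDR)/ε and summed, with
binomial error propagation.

## Functional placement

A locus counts for a region class only when its breakpoint CI lies entirely
inside one interval of that class; invalidated loci are excluded, and only
non-reference loci are eligible for CDS (an element embedded in the
reference precludes the region being annotated as coding). Under uniform
placement N_obs ~ Binomial(N_tot, L_obs/L_tot); the suppression factor is
expected/observed (reported as a lower bound via observed = 1 when nothing
is observed), and the placement p-value is the one-sided binomial tail in
the deviation's direction, computed via log-space CDF/SF so CDS-scale
depletion (p < 10⁻⁵⁰) does not underflow.

## Sensitivity estimation

FDR = (tested − validated)/tested with a Wilson score interval (validation
strata are small, so Wald intervals undercover). The two insertion-detection
methods use independent libraries, so their overlap in one sample is a
two-capture mark–recapture experiment; the estimator deflates each capture
count by its FDR: ε_RP = n_both/[(1−f_SR)·n_SR] and symmetrically, with
binomial standard errors and the union formula for the combined sensitivity.
This standard Lincoln–Petersen form is validated by simulated thinning
recovery. The estimator is internally consistent:
N̂·ε_RP·ε_SR = n_both identically.

## Pipeline and problem sizes

`run_pipeline` chains simulation → detection → genotyping → spectra/fits →
heterozygosity → catalog/density → functional analysis, all seeded from one
integer, writing VCF/TSV/JSON artifacts stamped with a config digest.
Detection inside the pipeline is emulated by thinning the true catalog at
the configured dropout rates and admixing false calls at the configured FDR;
fragment-level RP/SR clustering is exercised directly by the detection
module on fragment records, where it is tested for perfect recall and for
the masking behaviour, but is not run genome-wide. Test and demonstration
configurations use sub-genome lengths (tens to hundreds of Mb) and θ values
of a few hundred per family so the full suite completes in seconds; the
estimators are scale-free in these choices, and the acceptance checks that
concern genome-scale magnitudes (suppression factors, spacing, θ fits) run
at the full 2.85 Gb scale with realistic θ values.

## Known limitations

- No demography, linkage, or selection in the generator; the θ estimators
  are only as meaningful as the neutral equilibrium assumption.
- GQ-threshold heterozygote depletion biases spectrum-based θ a few percent
  low at low coverage (quantified above); heterozygosity-based estimates are
  corrected via K_HET, spectrum-based ones are not.
- The reference-MEI genotype channel is emulated, not re-implemented; its
  accuracy enters only through the configured efficiency.
- BAM/CRAM ingestion and read-level simulation are out of scope; fragment
  records are the detection interface.
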