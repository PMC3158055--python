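"""Synthetic cohorts of mobile-element insertion (MEI) polymorphism.

The generator produces every input the downstream pipeline consumes: a catalog
of true insertion loci with neutral-model allele frequencies, diploid
genotypes under Hardy-Weinberg sampling, per-locus fragment evidence, deletion
calls for reference-genome insertions, and annotation tracks.

The allele-frequency model is the standard neutral (infinite-sites) site
frequency spectrum: the number of loci with derived-allele count ``i`` among
``2N`` sampled chromosomes is Poisson with mean ``theta/i``.  Ascertainment by
the reference assembly is emulated by designating one sampled chromosome as
"the reference": a locus whose derived allele lands on that chromosome is a
*reference* MEI (visible as a deletion in samples), all others are
*non-reference* MEI (visible as insertions).  Conditioning on the flag
reshapes the observable spectra into the flat ``theta/2N`` (reference) and
``(theta/i)(2N-i)/2N`` (non-reference) forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import FAMILIES, Interval, MappedFragment, NON_REFERENCE, REFERENCE

__all__ = [
    "SimConfig",
    "TrueLocus",
    "AnnotationTracks",
    "simulate_catalog",
    "simulate_cohort",
    "simulate_evidence",
    "simulate_deletions",
]


def _default_theta() -> dict:
    # Diversity parameters per element family (loci scale), all-population fits
    return {"Alu": 1570.0, "L1": 224.0, "SVA": 80.0}


def _default_pops() -> dict:
    return {"CEU": 60, "YRI": 59, "CHBJPT": 60}


def _default_props() -> dict:
    # genomic family proportions ~85% Alu / 12% L1 / 2.5% SVA, renormalised
    return {"Alu": 0.855, "L1": 0.120, "SVA": 0.025}


def _default_dropout() -> dict:
    # per-mode detection dropout: non-reference sensitivity 70-80%,
    # reference >90%
    return {NON_REFERENCE: 0.25, REFERENCE: 0.07}


def _default_regions() -> dict:
    # genomic fractions of annotated classes (gene includes UTR and CDS)
    return {"gene": 0.376, "UTR": 0.0196, "CDS": 0.0255}


def _default_ins_len() -> dict:
    return {"Alu": 300, "L1": 6000, "SVA": 1500}


@dataclass
class SimConfig:
    """Study conditions for the simulator.

    ``theta_by_family`` applies per population group.  ``n_chrom_sampled`` is
    the haploid spectrum sample size 2N (50 chromosomes = 25 diploids).
    Coverage is mean informative-fragment spanning coverage per sample
    (fragments per base at a locus).  TSD lengths follow a truncated normal
    peaked at 15 bp with sd 7 bp.
    """

    theta_by_family: dict = field(default_factory=_default_theta)
    n_samples_by_pop: dict = field(default_factory=_default_pops)
    n_chrom_sampled: int = 50
    genome_length: int = 2_850_000_000
    coverage_mean: float = 4.0
    frag_len_mean: float = 200.0
    frag_len_sd: float = 30.0
    tsd_mean: float = 15.0
    tsd_sd: float = 7.0
    family_props: dict = field(default_factory=_default_props)
    fdr_sim: float = 0.045
    dropout_sim: dict = field(default_factory=_default_dropout)
    seed: int = 0
    # evidence-model details
    genotype_error: float = 0.0  # P(insertion-supporting fragment | hom-ref)
    sr_coverage_mean: float = 2.0  # split-read fragments per carrier sample
    background_per_element: float = 0.0  # artifact read pairs per annotation
    # annotation-track shape
    region_fractions: dict = field(default_factory=_default_regions)
    gene_len_mean: int = 30_000
    element_density_per_mb: float = 2.0  # same-family annotated elements
    # deletion-call emulation
    ins_len_by_family: dict = field(default_factory=_default_ins_len)
    deletion_jitter_sd: float = 0.0
    decoy_fraction: float = 0.0
    # exact allele dealing on the first 2N panel chromosomes per population
    exact_panel: bool = True

    def validate(self) -> None:
        if abs(sum(self.family_props.values()) - 1.0) > 1e-9:
            raise ValueError("family proportions must sum to 1")
        for name, val in (
            ("fdr_sim", self.fdr_sim),
            ("genotype_error", self.genotype_error),
            ("decoy_fraction", self.decoy_fraction),
        ):
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for rate in self.dropout_sim.values():
            if not 0.0 <= rate <= 1.0:
                raise ValueError("dropout rates must be in [0, 1]")
        if any(t < 0 for t in self.theta_by_family.values()):
            raise ValueError("theta must be non-negative")
        if self.n_chrom_sampled < 2:
            raise ValueError("need at least 2 sampled chromosomes")
        if self.coverage_mean <= 0:
            raise ValueError("coverage must be positive")
        if self.genome_length <= 0:
            raise ValueError("genome length must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TrueLocus:
    """Ground-truth insertion polymorphism."""

    chrom: str
    pos: int
    family: str
    strand: str
    tsd_len: int
    popn_freq: dict  # population -> derived-allele frequency
    on_reference: bool
    region_class: str  # intergenic | gene | UTR | CDS
    population: str  # population whose panel segregates this locus
    allele_count: int  # derived-allele count among the 2N panel chromosomes
    locus_id: str = ""

    @property
    def detection_mode(self) -> str:
        return REFERENCE if self.on_reference else NON_REFERENCE


@dataclass
class AnnotationTracks:
    """Generated genome annotation: functional regions and element positions."""

    regions: dict  # class -> list[Interval]; CDS/UTR nest inside gene
    elements: dict  # family -> list[Interval]
    genome_length: int

    def _index(self) -> dict:
        if not hasattr(self, "_sorted"):
            idx = {}
            for cls, ivs in self.regions.items():
                starts = np.array([iv.start for iv in ivs])
                ends = np.array([iv.end for iv in ivs])
                order = np.argsort(starts)
                idx[cls] = (starts[order], ends[order])
            self._sorted = idx
        return self._sorted

    def classify(self, pos: int) -> str:
        """Most specific annotation class containing ``pos`` (intervals within
        a class are disjoint)."""
        idx = self._index()
        for cls in ("CDS", "UTR", "gene"):
            starts, ends = idx.get(cls, (None, None))
            if starts is None or len(starts) == 0:
                continue
            k = int(np.searchsorted(starts, pos, side="right")) - 1
            if k >= 0 and pos <= ends[k]:
                return cls
        return "intergenic"


def _make_regions(config: SimConfig, rng: np.random.Generator) -> dict:
    """Tile genes (with nested UTR/CDS blocks) across the genome.

    One gene per equal-width slot at a random offset keeps genes disjoint by
    construction.  Within each gene the two UTR halves flank a central CDS
    block; lengths are set so genomic class fractions match the configured
    targets.
    """
    L = config.genome_length
    fr = config.region_fractions
    n_genes = max(1, int(round(L * fr["gene"] / config.gene_len_mean)))
    slot = L // n_genes
    gene_len = min(config.gene_len_mean, slot)
    utr_len = max(2, int(round(gene_len * fr["UTR"] / fr["gene"])))
    cds_len = max(1, int(round(gene_len * fr["CDS"] / fr["gene"])))
    genes, utrs, cdss = [], [], []
    offsets = rng.integers(0, max(1, slot - gene_len), size=n_genes)
    for k in range(n_genes):
        start = int(k * slot + offsets[k] + 1)
        end = start + gene_len - 1
        genes.append(Interval("chr1", start, end, "gene"))
        half = utr_len // 2
        utrs.append(Interval("chr1", start, start + half - 1, "UTR"))
        utrs.append(Interval("chr1", end - (utr_len - half) + 1, end, "UTR"))
        mid = (start + end) // 2
        cdss.append(Interval("chr1", mid - cds_len // 2, mid - cds_len // 2 + cds_len - 1, "CDS"))
    return {"gene": genes, "UTR": utrs, "CDS": cdss}


def _make_elements(config: SimConfig, rng: np.random.Generator) -> dict:
    out = {}
    n_total = int(config.genome_length / 1e6 * config.element_density_per_mb)
    for fam in FAMILIES:
        n = int(round(n_total * config.family_props.get(fam, 0.0)))
        starts = np.sort(rng.integers(1, config.genome_length, size=n))
        length = config.ins_len_by_family.get(fam, 300)
        out[fam] = [Interval("chr1", int(s), int(s) + length - 1, fam) for s in starts]
    return out


def _draw_tsd(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    a = (0.0 - config.tsd_mean) / config.tsd_sd
    vals = stats.truncnorm.rvs(
        a, np.inf, loc=config.tsd_mean, scale=config.tsd_sd, size=size, random_state=rng
    )
    return np.rint(vals).astype(int)


def simulate_catalog(config: SimConfig) -> tuple[list[TrueLocus], AnnotationTracks]:
    """Draw the true-locus catalog and annotation tracks.

    Per population and family, loci at derived-allele count ``i`` (of the 2N
    panel chromosomes) number Poisson(theta/i) for i = 1..2N-1.  Each locus is
    flagged ``on_reference`` with probability i/2N — the chance that the
    designated reference chromosome carries the derived allele.
    """
    config.validate()
    rng = config.rng()
    tracks = AnnotationTracks(
        regions=_make_regions(config, rng),
        elements=_make_elements(config, rng),
        genome_length=config.genome_length,
    )
    two_n = config.n_chrom_sampled
    loci: list[TrueLocus] = []
    idx = 0
    for pop in config.n_samples_by_pop:
        for fam in FAMILIES:
            theta = float(config.theta_by_family.get(fam, 0.0))
            if theta == 0.0:
                continue
            counts = rng.poisson(theta / np.arange(1, two_n), size=two_n - 1)
            for i, n_i in zip(range(1, two_n), counts):
                if n_i == 0:
                    continue
                pos = rng.integers(1, config.genome_length + 1, size=n_i)
                tsd = _draw_tsd(config, rng, n_i)
                strands = rng.choice(["+", "-"], size=n_i)
                on_ref = rng.random(n_i) < i / two_n
                for k in range(n_i):
                    p = int(pos[k])
                    loci.append(
                        TrueLocus(
                            chrom="chr1",
                            pos=p,
                            family=fam,
                            strand=str(strands[k]),
                            tsd_len=int(tsd[k]),
                            popn_freq={pop: i / two_n},
                            on_reference=bool(on_ref[k]),
                            region_class=tracks.classify(p),
                            population=pop,
                            allele_count=i,
                            locus_id=f"mei{idx:06d}",
                        )
                    )
                    idx += 1
    loci.sort(key=lambda l: (l.chrom, l.pos))
    return loci, tracks


def _deal_exact(
    rng: np.random.Generator, n_chrom: int, count: int, force_first: bool
) -> np.ndarray:
    """Indicator over chromosomes with exactly ``count`` carriers.

    ``force_first`` conditions chromosome 0 (the designated reference
    haplotype) to carry / not carry the derived allele.
    """
    carriers = np.zeros(n_chrom, dtype=bool)
    if force_first:
        carriers[0] = True
        extra = rng.choice(n_chrom - 1, size=count - 1, replace=False) + 1
    else:
        extra = rng.choice(n_chrom - 1, size=count, replace=False) + 1
    carriers[extra] = True
    return carriers


def simulate_cohort(loci: list[TrueLocus], config: SimConfig) -> pd.DataFrame:
    """Diploid genotype matrix (samples x loci, 0/1/2 derived-allele copies).

    Genotypes are Hardy-Weinberg binomial draws Binomial(2, f) per sample.
    When ``config.exact_panel`` is set, the first 2N chromosomes of each
    population (the spectrum panel) instead receive exactly the locus's true
    allele count, dealt uniformly and conditioned on the reference-haplotype
    flag; this keeps panel spectra exactly on the drawn counts.
    """
    rng = np.random.default_rng(config.seed + 1)
    sample_ids, sample_pop = [], []
    for pop, n in config.n_samples_by_pop.items():
        for k in range(n):
            sample_ids.append(f"{pop}{k:03d}")
            sample_pop.append(pop)
    geno = np.zeros((len(sample_ids), len(loci)), dtype=np.int8)
    pop_slices = {}
    start = 0
    for pop, n in config.n_samples_by_pop.items():
        pop_slices[pop] = slice(start, start + n)
        start += n
    n_panel = config.n_chrom_sampled // 2
    for j, locus in enumerate(loci):
        for pop, f in locus.popn_freq.items():
            if f <= 0.0:
                continue
            sl = pop_slices[pop]
            n_pop = sl.stop - sl.start
            g = rng.binomial(2, f, size=n_pop)
            if config.exact_panel and n_pop >= n_panel:
                carriers = _deal_exact(
                    rng, config.n_chrom_sampled, locus.allele_count, locus.on_reference
                )
                g[:n_panel] = carriers.reshape(n_panel, 2).sum(axis=1)
            geno[sl, j] = g
    df = pd.DataFrame(
        geno, index=pd.Index(sample_ids, name="sample_id"),
        columns=[l.locus_id for l in loci],
    )
    df.attrs["population"] = dict(zip(sample_ids, sample_pop))
    return df


def simulate_evidence(
    genotypes: pd.DataFrame,
    loci: list[TrueLocus],
    config: SimConfig,
    tracks: AnnotationTracks | None = None,
    fragments: bool = False,
) -> tuple[pd.DataFrame, list[MappedFragment]]:
    """Fragment-support evidence per sample x locus.

    Informative fragments per locus are Poisson(coverage_mean); of those,
    insertion-supporting fragments are Binomial(NF, p_g) with p_g = 0/0.5/1
    for genotype 0/1/2 (perturbed by ``genotype_error``), split evenly between
    the 5' and 3' breakpoint sides.  With ``fragments=True`` per-fragment
    read-pair and split-read records are emitted, plus background artifact
    pairs near annotated elements when ``background_per_element`` > 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 2)
    n_samples, n_loci = genotypes.shape
    if n_loci != len(loci):
        raise ValueError("genotype matrix does not align with loci")
    p_err = config.genotype_error
    p_by_g = np.array([p_err, 0.5, 1.0 - p_err])
    g = genotypes.to_numpy()
    nf = rng.poisson(config.coverage_mean, size=g.shape)
    n_alt = rng.binomial(nf, p_by_g[g])
    n_alt5 = rng.binomial(n_alt, 0.5)
    n_alt3 = n_alt - n_alt5
    n_ref = nf - n_alt
    samp = np.repeat(genotypes.index.to_numpy(), n_loci)
    locs = np.tile(np.array([l.locus_id for l in loci]), n_samples)
    support = pd.DataFrame(
        {
            "locus_id": locs,
            "sample_id": samp,
            "n_alt5": n_alt5.ravel(),
            "n_alt3": n_alt3.ravel(),
            "n_ref": n_ref.ravel(),
        }
    )
    frags: list[MappedFragment] = []
    if fragments:
        frags = _emit_fragments(genotypes, loci, config, tracks, rng, n_alt5, n_alt3, nf)
    return support, frags


def _frag_lengths(config: SimConfig, rng: np.random.Generator, size: int) -> np.ndarray:
    return np.maximum(
        60, np.rint(rng.normal(config.frag_len_mean, config.frag_len_sd, size=size))
    ).astype(int)


def _emit_fragments(genotypes, loci, config, tracks, rng, n_alt5, n_alt3, nf):
    frags: list[MappedFragment] = []
    sample_ids = genotypes.index.to_numpy()
    for j, locus in enumerate(loci):
        if locus.on_reference:
            continue  # reference MEI leave no insertion signature
        for s in range(len(sample_ids)):
            sid = str(sample_ids[s])
            for _ in range(int(n_alt5[s, j])):
                fl = int(_frag_lengths(config, rng, 1)[0])
                off = int(rng.integers(30, max(31, fl - 30)))
                frags.append(
                    MappedFragment(sid, locus.chrom, locus.pos - off, "5p", fl,
                                   locus.family)
                )
            for _ in range(int(n_alt3[s, j])):
                fl = int(_frag_lengths(config, rng, 1)[0])
                off = int(rng.integers(30, max(31, fl - 30)))
                frags.append(
                    MappedFragment(sid, locus.chrom, locus.pos + locus.tsd_len + off,
                                   "3p", fl, locus.family)
                )
            # split-read channel: reference-mapped extents bracket the TSD
            g_s = genotypes.iloc[s, j]
            if g_s > 0:
                n_split = rng.poisson(config.sr_coverage_mean)
                for _ in range(n_split):
                    span = int(rng.integers(40, 160))
                    if rng.random() < 0.5:
                        ref_lo = locus.pos - span
                        ref_hi = locus.pos + locus.tsd_len - 1
                        side = "5p"
                    else:
                        ref_lo = locus.pos
                        ref_hi = locus.pos + span
                        side = "3p"
                    frags.append(
                        MappedFragment(sid, locus.chrom, ref_lo, side,
                                       ref_hi - ref_lo + 1, locus.family,
                                       split=True, ref_start=ref_lo, ref_end=ref_hi)
                    )
    if tracks is not None and config.background_per_element > 0:
        # mapping-artifact pairs bracketing annotated elements whose fragment
        # lengths sample the library tails; masking is meant to remove these
        tail = config.frag_len_mean + 4 * config.frag_len_sd
        for fam, ivs in tracks.elements.items():
            for iv in ivs:
                n_bg = rng.poisson(config.background_per_element)
                for _ in range(n_bg):
                    sid = str(rng.choice(sample_ids))
                    fl = int(tail + rng.integers(0, 40))
                    frags.append(MappedFragment(sid, iv.chrom, iv.start - 35, "5p", fl, fam))
                    frags.append(MappedFragment(sid, iv.chrom, iv.start - 30, "5p", fl, fam))
                    frags.append(MappedFragment(sid, iv.chrom, iv.start + 30, "3p", fl, fam))
                    frags.append(MappedFragment(sid, iv.chrom, iv.start + 35, "3p", fl, fam))
    return frags


def simulate_deletions(
    loci: list[TrueLocus], config: SimConfig
) -> tuple[list[Interval], dict, list[Interval]]:
    """Deletion calls, element annotations, and chimpanzee-gap intervals.

    Every reference-flagged locus yields a deletion interval over the inserted
    element (endpoints jittered by ``deletion_jitter_sd``), a matching element
    annotation, and a chimpanzee-assembly gap covering it.  A
    ``decoy_fraction`` of extra deletions violate the selection filters
    (poor reciprocal overlap, or no chimpanzee gap).
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 3)
    deletions: list[Interval] = []
    annotations: dict = {fam: [] for fam in FAMILIES}
    gaps: list[Interval] = []
    ref_loci = [l for l in loci if l.on_reference]
    for locus in ref_loci:
        ins_len = config.ins_len_by_family.get(locus.family, 300)
        start, end = locus.pos, locus.pos + ins_len - 1
        annotations[locus.family].append(Interval(locus.chrom, start, end, locus.family))
        gaps.append(Interval(locus.chrom, start - 10, end + 10, "gap"))
        if config.deletion_jitter_sd > 0:
            js, je = np.rint(rng.normal(0, config.deletion_jitter_sd, 2)).astype(int)
        else:
            js = je = 0
        d_start, d_end = start + int(js), end + int(je)
        if d_end > d_start:
            deletions.append(Interval(locus.chrom, d_start, d_end, locus.locus_id))
    n_decoys = rng.binomial(len(ref_loci), config.decoy_fraction) if ref_loci else 0
    occupied = np.sort(np.array([l.pos for l in ref_loci], dtype=np.int64))
    margin = max(config.ins_len_by_family.values()) + 1000

    def clear_position() -> int:
        # decoys are clean negatives: keep them away from real loci so they
        # cannot be rescued by a neighbouring gap or annotation
        while True:
            p = int(rng.integers(1, config.genome_length))
            k = np.searchsorted(occupied, p)
            near = [occupied[j] for j in (k - 1, k) if 0 <= j < len(occupied)]
            if all(abs(p - q) > margin for q in near):
                return p

    for k in range(n_decoys):
        fam = str(rng.choice(FAMILIES))
        ins_len = config.ins_len_by_family.get(fam, 300)
        pos = clear_position()
        if k % 2 == 0:
            # overlaps its annotation by only ~40% -> fails reciprocal overlap
            annotations[fam].append(Interval("chr1", pos, pos + ins_len - 1, fam))
            gaps.append(Interval("chr1", pos, pos + 2 * ins_len, "gap"))
            shift = int(0.6 * ins_len)
            deletions.append(Interval("chr1", pos + shift, pos + shift + ins_len - 1,
                                      f"decoy{k}"))
        else:
            # matches an annotation but has no chimpanzee gap
            annotations[fam].append(Interval("chr1", pos, pos + ins_len - 1, fam))
            deletions.append(Interval("chr1", pos, pos + ins_len - 1, f"decoy{k}"))
    return deletions, annotations, gaps
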