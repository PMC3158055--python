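"""Unified MEI catalog: merging call sets, cross-study matching, genomic
density scanning, and trio de-novo screening.

Calls from different methods at the same locus are merged with a 100 bp
single-linkage window, preferring the split-read coordinate (best breakpoint
resolution) for the merged record.  Cross-study matching uses a 200 bp window
for insertions or 50% reciprocal overlap for deletions, one-to-one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import Interval, MeiLocus

MERGE_WINDOW = 100
MATCH_WINDOW = 200


@dataclass
class Catalog:
    """Sorted, non-redundant set of MEI loci."""

    loci: list[MeiLocus]
    genome_length: int = 2_850_000_000
    provenance: dict = field(default_factory=dict)  # locus key -> source labels

    def __post_init__(self) -> None:
        self.loci = sorted(self.loci, key=lambda l: (l.chrom, l.pos))

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def mean_spacing(self) -> float:
        """Mean inter-locus spacing in bp (genome length / locus count)."""
        if not self.loci:
            return float("inf")
        return self.genome_length / len(self.loci)


def _merge_group(members: list[tuple[MeiLocus, str]]) -> tuple[MeiLocus, set]:
    """Collapse transitively linked same-family calls into one record.

    Position comes from an SR member when present, else from the RP member
    with the highest fragment support; methods are unioned and per-side
    support counts summed.
    """
    sources = {src for _, src in members}
    loci = [m for m, _ in members]
    sr = [l for l in loci if "SR" in l.methods]
    if sr:
        rep = max(sr, key=lambda l: (l.n_alt5 + l.n_alt3, -l.pos))
    else:
        rep = max(loci, key=lambda l: (l.n_alt5 + l.n_alt3, -l.pos))
    methods = frozenset().union(*(l.methods for l in loci))
    merged = rep.with_(
        methods=methods,
        n_alt5=sum(l.n_alt5 for l in loci),
        n_alt3=sum(l.n_alt3 for l in loci),
        tsd_len=next((l.tsd_len for l in loci if l.tsd_len is not None), None),
    )
    return merged, sources


def merge_callsets(
    callsets: dict | list,
    window_bp: int = MERGE_WINDOW,
    genome_length: int = 2_850_000_000,
) -> Catalog:
    """Merge call sets into a catalog with single-linkage position clustering.

    ``callsets`` is a mapping source-label -> list[MeiLocus] (a bare list is
    treated as one anonymous source).  Same-family calls within ``window_bp``
    are merged transitively.
    """
    if isinstance(callsets, list):
        callsets = {"calls": callsets}
    tagged: list[tuple[MeiLocus, str]] = []
    for src, calls in callsets.items():
        tagged.extend((c, src) for c in calls)
    tagged.sort(key=lambda t: (t[0].chrom, t[0].family, t[0].detection_mode, t[0].pos))
    merged_loci: list[MeiLocus] = []
    provenance: dict = {}
    group: list[tuple[MeiLocus, str]] = []

    def flush() -> None:
        if not group:
            return
        rec, sources = _merge_group(group)
        merged_loci.append(rec)
        provenance[rec.key] = sources

    for item in tagged:
        locus = item[0]
        if group and (
            locus.chrom != group[-1][0].chrom
            or locus.family != group[-1][0].family
            or locus.detection_mode != group[-1][0].detection_mode
            or locus.pos - group[-1][0].pos > window_bp
        ):
            flush()
            group = []
        group.append(item)
    flush()
    return Catalog(merged_loci, genome_length=genome_length, provenance=provenance)


@dataclass
class MatchResult:
    matched: list[tuple[MeiLocus, MeiLocus]]
    only_a: list[MeiLocus]
    only_b: list[MeiLocus]

    @property
    def n_matched(self) -> int:
        return len(self.matched)


def match_loci(
    catalog_a: Catalog | list,
    catalog_b: Catalog | list,
    mode: str = "window200",
    window_bp: int = MATCH_WINDOW,
) -> MatchResult:
    """One-to-one greedy nearest-first matching between two catalogs.

    ``mode`` is "window200" (insertion positions within ``window_bp``,
    families must agree) or "reciprocal50" (deletion intervals with >=50%
    reciprocal overlap).  Ties break toward the lower coordinate so matching
    is deterministic, and no locus is counted twice.
    """
    a = catalog_a.loci if isinstance(catalog_a, Catalog) else list(catalog_a)
    b = catalog_b.loci if isinstance(catalog_b, Catalog) else list(catalog_b)
    pairs: list[tuple[float, int, int]] = []
    if mode == "window200":
        for i, la in enumerate(a):
            for j, lb in enumerate(b):
                if la.chrom != lb.chrom or la.family != lb.family:
                    continue
                d = abs(la.pos - lb.pos)
                if d <= window_bp:
                    pairs.append((d, i, j))
    elif mode == "reciprocal50":
        for i, la in enumerate(a):
            iv_a = Interval(la.chrom, la.ci_lo, max(la.ci_hi, la.ci_lo))
            if la.insertion_len:
                iv_a = Interval(la.chrom, la.pos, la.pos + la.insertion_len - 1)
            for j, lb in enumerate(b):
                iv_b = Interval(lb.chrom, lb.ci_lo, max(lb.ci_hi, lb.ci_lo))
                if lb.insertion_len:
                    iv_b = Interval(lb.chrom, lb.pos, lb.pos + lb.insertion_len - 1)
                ro = iv_a.reciprocal_overlap(iv_b)
                if ro >= 0.5:
                    pairs.append((1.0 - ro, i, j))
    else:
        raise ValueError(f"unknown matching mode {mode!r}")
    pairs.sort(key=lambda t: (t[0], a[t[1]].pos, b[t[2]].pos))
    used_a: set[int] = set()
    used_b: set[int] = set()
    matched = []
    for _, i, j in pairs:
        if i in used_a or j in used_b:
            continue
        used_a.add(i)
        used_b.add(j)
        matched.append((a[i], b[j]))
    only_a = [a[i] for i in range(len(a)) if i not in used_a]
    only_b = [b[j] for j in range(len(b)) if j not in used_b]
    return MatchResult(matched, only_a, only_b)


@dataclass
class DensityScan:
    bin_bp: int
    counts: np.ndarray
    expected: float
    p_values: np.ndarray
    hotspots: list[int]  # bin indices with Bonferroni-significant excess
    mean_spacing: float


def scan_density(catalog: Catalog, bin_bp: int = 1_000_000,
                 alpha: float = 0.05) -> DensityScan:
    """Per-bin locus counts against a uniform-placement Poisson null.

    The expected count per bin is n_loci * bin_bp / genome_length; each bin
    gets an upper-tail Poisson p-value and a Bonferroni-adjusted hotspot flag.
    """
    if catalog.genome_length <= 0:
        raise ValueError("genome length must be positive")
    n_bins = int(np.ceil(catalog.genome_length / bin_bp))
    counts = np.zeros(n_bins, dtype=int)
    for locus in catalog.loci:
        counts[min((locus.pos - 1) // bin_bp, n_bins - 1)] += 1
    lam = len(catalog.loci) * bin_bp / catalog.genome_length
    # upper tail P(X >= k) under Poisson(lam)
    p = stats.poisson.sf(counts - 1, lam)
    p = np.maximum(p, np.finfo(float).tiny)
    hot = [int(k) for k in np.nonzero(p < alpha / n_bins)[0]]
    return DensityScan(
        bin_bp=bin_bp, counts=counts, expected=lam, p_values=p,
        hotspots=hot, mean_spacing=catalog.mean_spacing,
    )


@dataclass
class DeNovoCandidate:
    locus: MeiLocus
    nearest_parent_bp: float
    nearest_cohort_bp: float


def find_de_novo(
    child_calls: list[MeiLocus],
    parent_calls: list[MeiLocus],
    cohort_calls: list[MeiLocus],
    window_bp: int = MATCH_WINDOW,
) -> list[DeNovoCandidate]:
    """Child loci matching no parental and no other-cohort locus.

    A candidate must have no same-family locus within ``window_bp`` in either
    parent or in any other sample of the cohort; each candidate is annotated
    with the nearest parental/cohort locus distance for triage.
    """

    def nearest(locus: MeiLocus, pool: list[MeiLocus]) -> float:
        dists = [
            abs(locus.pos - other.pos)
            for other in pool
            if other.chrom == locus.chrom and other.family == locus.family
        ]
        return float(min(dists)) if dists else float("inf")

    out = []
    for locus in child_calls:
        d_parent = nearest(locus, parent_calls)
        d_cohort = nearest(locus, cohort_calls)
        if d_parent <= window_bp or d_cohort <= window_bp:
            continue
        out.append(DeNovoCandidate(locus, d_parent, d_cohort))
    return out
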