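"""Insertion calling from read-pair (RP) and split-read (SR) signatures, and
selection of reference MEI from deletion calls.

RP evidence is a read pair with one end uniquely anchored on the reference and
the other mapping into a mobile-element consensus; a true insertion shows such
pairs spanning in from both the 5' and the 3' side.  Because pairs bracketing
an *annotated* element with a fragment length on the tail of the library
distribution mimic this signature, RP calling requires >=2 supporting
fragments on each side and masks candidate positions within one fragment
length of an annotated element of the same family.

SR evidence is a single read split-mapped across a breakpoint; one fragment on
either side suffices.  When both sides are seen, the overlap of their
reference-mapped extents measures the target-site duplication (TSD).
"""

from __future__ import annotations

import logging
from collections import defaultdict

from .model import FAMILIES, Interval, MappedFragment, MeiLocus, REFERENCE

logger = logging.getLogger(__name__)

#: single-linkage gap for split-read clusters: ~2 TSD standard deviations
#: beyond the mean TSD length
SR_CLUSTER_GAP = 35

#: start/end match windows for reference-MEI selection, by family (bp)
REF_MATCH_WINDOW = {"Alu": 20, "L1": 200, "SVA": 200}


def _single_linkage(positions: list[int], gap: int) -> list[list[int]]:
    """Indices of clusters under single linkage with inter-point gap <= gap."""
    order = sorted(range(len(positions)), key=lambda k: positions[k])
    clusters, current = [], []
    last = None
    for k in order:
        if last is not None and positions[k] - last > gap:
            clusters.append(current)
            current = []
        current.append(k)
        last = positions[k]
    if current:
        clusters.append(current)
    return clusters


def _near_same_family(pos: int, chrom: str, annotations: dict, family: str,
                      window: int) -> bool:
    for iv in annotations.get(family, []):
        if iv.chrom != chrom:
            continue
        dist = max(iv.start - pos, pos - iv.end, 0)
        if dist <= window:
            return True
    return False


def call_rp_insertions(
    fragments: list[MappedFragment],
    annotations: dict,
    frag_len_median: int,
) -> list[MeiLocus]:
    """Cluster read-pair evidence into non-reference MEI calls.

    Element-supporting fragments are clustered per (chrom, family) by single
    linkage with gap <= ``frag_len_median``.  A cluster is called iff it holds
    >=2 fragments on the 5' side AND >=2 on the 3' side; calls within one
    fragment length of a same-family annotated element are suppressed.  The
    breakpoint is the leftmost position compatible with the cluster extents
    (just right of the innermost 5' anchor), with CI +/- frag_len_median/2.
    """
    groups: dict[tuple, list[MappedFragment]] = defaultdict(list)
    for fr in fragments:
        if fr.split or fr.side == "ref":
            continue
        if fr.element_family not in FAMILIES:
            logger.warning("rejecting fragment with unknown family %r", fr.element_family)
            continue
        groups[(fr.chrom, fr.element_family)].append(fr)
    calls: list[MeiLocus] = []
    for (chrom, family), frs in sorted(groups.items()):
        positions = [f.anchor_pos for f in frs]
        for idx in _single_linkage(positions, frag_len_median):
            members = [frs[k] for k in idx]
            five = [f for f in members if f.side == "5p"]
            three = [f for f in members if f.side == "3p"]
            if len(five) < 2 or len(three) < 2:
                continue
            pos = max(f.anchor_pos for f in five) + 1
            pos = min(pos, min(f.anchor_pos for f in three))
            if _near_same_family(pos, chrom, annotations, family, frag_len_median):
                continue
            half = frag_len_median // 2
            calls.append(
                MeiLocus(
                    chrom=chrom, pos=pos, family=family,
                    ci_lo=pos - half, ci_hi=pos + half,
                    methods=frozenset({"RP"}),
                    n_alt5=len(five), n_alt3=len(three),
                )
            )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def call_sr_insertions(fragments: list[MappedFragment]) -> list[MeiLocus]:
    """Cluster split-read evidence into non-reference MEI calls.

    One supporting fragment suffices.  With evidence on both sides, the TSD is
    the overlap of the 5' and 3' reference-mapped extents (0 if disjoint) and
    the call position is the leftmost TSD coordinate; one-sided clusters get
    the split point with TSD unknown.
    """
    groups: dict[tuple, list[MappedFragment]] = defaultdict(list)
    for fr in fragments:
        if not fr.split:
            continue
        if fr.element_family not in FAMILIES:
            logger.warning("rejecting split fragment with unknown family %r",
                           fr.element_family)
            continue
        groups[(fr.chrom, fr.element_family)].append(fr)
    calls: list[MeiLocus] = []
    for (chrom, family), frs in sorted(groups.items()):
        # cluster on the breakpoint-proximal coordinate of each split read
        brk = [f.ref_end if f.side == "5p" else f.ref_start for f in frs]
        for idx in _single_linkage(brk, SR_CLUSTER_GAP):
            members = [frs[k] for k in idx]
            five = [f for f in members if f.side == "5p"]
            three = [f for f in members if f.side == "3p"]
            if five and three:
                ext5 = (min(f.ref_start for f in five), max(f.ref_end for f in five))
                ext3 = (min(f.ref_start for f in three), max(f.ref_end for f in three))
                ov_lo = max(ext5[0], ext3[0])
                ov_hi = min(ext5[1], ext3[1])
                if ov_hi >= ov_lo:
                    tsd = ov_hi - ov_lo + 1
                    pos, ci_lo, ci_hi = ov_lo, ov_lo, ov_hi
                else:
                    tsd = 0
                    pos = min(ext5[1], ext3[0])
                    ci_lo = ci_hi = pos
                calls.append(
                    MeiLocus(chrom=chrom, pos=pos, family=family,
                             ci_lo=ci_lo, ci_hi=ci_hi,
                             methods=frozenset({"SR"}), tsd_len=tsd,
                             n_alt5=len(five), n_alt3=len(three))
                )
            else:
                if five:
                    pos = max(f.ref_end for f in five)
                else:
                    pos = min(f.ref_start for f in three)
                calls.append(
                    MeiLocus(chrom=chrom, pos=pos, family=family,
                             methods=frozenset({"SR"}), tsd_len=None,
                             n_alt5=len(five), n_alt3=len(three))
                )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls


def _reciprocal_overlap(a: Interval, b: Interval) -> float:
    return a.reciprocal_overlap(b)


def _gap_coverage(deletion: Interval, gaps: list[Interval]) -> float:
    """Fraction of deleted bases inside chimpanzee-gap intervals."""
    covered = 0
    for g in gaps:
        covered += deletion.overlap_len(g)
    return covered / len(deletion)


def select_reference_mei(
    deletions: list[Interval],
    element_annotations: dict,
    chimp_gaps: list[Interval],
) -> list[MeiLocus]:
    """Select deletions that are mobile elements present in the reference but
    absent from samples (and from the chimpanzee assembly).

    A deletion is selected iff (a) some annotated Alu/L1/SVA element has
    reciprocal overlap > 50% with it, with both start and end coordinates
    matching within a family window (20 bp for Alu, 200 bp for L1/SVA), and
    (b) at least 75% of the deleted bases fall in chimpanzee-assembly gaps.
    """
    calls: list[MeiLocus] = []
    for deletion in deletions:
        matched_family = None
        for family in FAMILIES:
            w = REF_MATCH_WINDOW[family]
            for ann in element_annotations.get(family, []):
                if ann.chrom != deletion.chrom:
                    continue
                if (
                    _reciprocal_overlap(deletion, ann) > 0.5
                    and abs(deletion.start - ann.start) <= w
                    and abs(deletion.end - ann.end) <= w
                ):
                    matched_family = family
                    break
            if matched_family:
                break
        if matched_family is None:
            continue
        if _gap_coverage(deletion, chimp_gaps) < 0.75:
            continue
        calls.append(
            MeiLocus(
                chrom=deletion.chrom, pos=deletion.start, family=matched_family,
                detection_mode=REFERENCE,
                ci_lo=deletion.start, ci_hi=deletion.start,
                insertion_len=len(deletion),
                locus_id=deletion.label,
            )
        )
    calls.sort(key=lambda c: (c.chrom, c.pos))
    return calls
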