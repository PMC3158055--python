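"""Core record types shared across the detection and population modules.

Coordinates are 1-based inclusive throughout the library, using the leftmost
insertion-point convention: an insertion whose exact placement is ambiguous
within its target-site duplication (TSD) is reported at the smallest compatible
coordinate.  BED input/output is converted at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

FAMILIES = ("Alu", "L1", "SVA")

#: detection modes: an insertion seen in a sample but absent from the reference
#: assembly ("non_reference"), or carried by the reference and seen as a
#: deletion in samples ("reference").
NON_REFERENCE = "non_reference"
REFERENCE = "reference"


@dataclass(frozen=True)
class MappedFragment:
    """One informative mapped fragment.

    A fragment either anchors uniquely on the reference and spans into a
    mobile-element sequence (side "5p" or "3p"), or spans the locus entirely
    within reference sequence (side "ref").  Split-read fragments carry the
    reference-mapped segment interval [ref_start, ref_end].
    """

    sample_id: str
    chrom: str
    anchor_pos: int
    side: str  # "5p" | "3p" | "ref"
    frag_len: int
    element_family: str = ""  # empty for reference-spanning fragments
    split: bool = False
    ref_start: int = 0  # split reads: reference-mapped segment (1-based incl.)
    ref_end: int = 0

    def __post_init__(self) -> None:
        if self.frag_len <= 0:
            raise ValueError("frag_len must be positive")
        if self.side == "ref" and self.element_family:
            raise ValueError("reference-spanning fragments carry no family")
        if self.side not in ("5p", "3p", "ref"):
            raise ValueError(f"unknown side {self.side!r}")


@dataclass
class MeiLocus:
    """One mobile-element insertion polymorphism."""

    chrom: str
    pos: int  # leftmost insertion coordinate, 1-based
    family: str
    detection_mode: str = NON_REFERENCE
    ci_lo: int = 0
    ci_hi: int = 0
    strand: str = "+"
    methods: frozenset = field(default_factory=frozenset)  # subset of {RP, SR}
    tsd_len: int | None = None
    n_alt5: int = 0
    n_alt3: int = 0
    insertion_len: int | None = None
    locus_id: str = ""

    def __post_init__(self) -> None:
        if self.ci_lo == 0 and self.ci_hi == 0:
            self.ci_lo = self.ci_hi = self.pos
        if not (self.ci_lo <= self.pos <= self.ci_hi):
            raise ValueError("confidence interval must bracket pos")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown element family {self.family!r}")
        self.methods = frozenset(self.methods)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.family)

    def with_(self, **kw) -> "MeiLocus":
        return replace(self, **kw)


@dataclass(frozen=True)
class Interval:
    """1-based inclusive genomic interval with an optional label."""

    chrom: str
    start: int
    end: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"degenerate interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)

    def reciprocal_overlap(self, other: "Interval") -> float:
        """min(overlap/len(self), overlap/len(other))."""
        ov = self.overlap_len(other)
        return min(ov / len(self), ov / len(other))
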