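"""Readers and writers for the standard formats the pipeline speaks.

All coordinate-convention conversion happens here: the library is 1-based
inclusive (leftmost insertion convention); BED is 0-based half-open; VCF is
1-based.  Catalogs round-trip through VCF 4.2 with MEI-specific INFO keys
(SVTYPE, FAMILY, TSDLEN, NALT5, NALT3, DET, METHODS) and GT/GQ FORMAT fields.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .model import Interval, MeiLocus, NON_REFERENCE, REFERENCE

_ALT_BY_FAMILY = {"Alu": "<INS:ME:ALU>", "L1": "<INS:ME:LINE1>", "SVA": "<INS:ME:SVA>"}
_FAMILY_BY_ALT = {v: k for k, v in _ALT_BY_FAMILY.items()}


def _vcf_header(contigs: dict, samples: list[str]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta("INFO", items=[("ID", "SVTYPE"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Structural variant type")])
    header.add_meta("INFO", items=[("ID", "FAMILY"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Mobile element family")])
    header.add_meta("INFO", items=[("ID", "TSDLEN"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "Target site duplication length")])
    header.add_meta("INFO", items=[("ID", "NALT5"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "5' insertion-supporting fragments")])
    header.add_meta("INFO", items=[("ID", "NALT3"), ("Number", 1), ("Type", "Integer"),
                                   ("Description", "3' insertion-supporting fragments")])
    header.add_meta("INFO", items=[("ID", "DET"), ("Number", 1), ("Type", "String"),
                                   ("Description", "Detection mode: INS or DEL")])
    header.add_meta("INFO", items=[("ID", "METHODS"), ("Number", "."), ("Type", "String"),
                                   ("Description", "Detection methods (RP, SR)")])
    header.add_meta("INFO", items=[("ID", "CIPOS"), ("Number", 2), ("Type", "Integer"),
                                   ("Description", "Confidence interval around POS")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"),
                                     ("Description", "Genotype")])
    header.add_meta("FORMAT", items=[("ID", "GQ"), ("Number", 1), ("Type", "Integer"),
                                     ("Description", "Phred-scaled genotype quality")])
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    path: str | Path,
    loci: list[MeiLocus],
    genotypes: pd.DataFrame | None = None,
    gq: pd.DataFrame | None = None,
    contigs: dict | None = None,
) -> None:
    """Write a catalog (optionally with a genotyped cohort) as uncompressed VCF.

    ``genotypes``/``gq`` are samples x loci frames keyed by locus id.
    """
    if contigs is None:
        max_pos = max((l.pos for l in loci), default=1)
        contigs = {c: max_pos + 10_000 for c in sorted({l.chrom for l in loci})} or {
            "chr1": max_pos + 10_000
        }
    samples = list(genotypes.index) if genotypes is not None else []
    header = _vcf_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for k, locus in enumerate(loci):
            rec = vcf.new_record(
                contig=locus.chrom,
                start=locus.pos - 1,  # pysam start is 0-based
                stop=locus.pos,
                alleles=("N", _ALT_BY_FAMILY[locus.family]),
                id=locus.locus_id or f"MEI{k:06d}",
            )
            rec.info["SVTYPE"] = "INS" if locus.detection_mode == NON_REFERENCE else "DEL"
            rec.info["FAMILY"] = locus.family
            rec.info["DET"] = "INS" if locus.detection_mode == NON_REFERENCE else "DEL"
            if locus.tsd_len is not None:
                rec.info["TSDLEN"] = int(locus.tsd_len)
            rec.info["NALT5"] = int(locus.n_alt5)
            rec.info["NALT3"] = int(locus.n_alt3)
            if locus.methods:
                rec.info["METHODS"] = tuple(sorted(locus.methods))
            rec.info["CIPOS"] = (int(locus.ci_lo - locus.pos), int(locus.ci_hi - locus.pos))
            if genotypes is not None:
                col = locus.locus_id
                for s in samples:
                    dosage = int(genotypes.loc[s, col])
                    rec.samples[s]["GT"] = [(0, 0), (0, 1), (1, 1)][dosage]
                    if gq is not None:
                        val = gq.loc[s, col]
                        if pd.notna(val):
                            rec.samples[s]["GQ"] = int(round(float(val)))
            vcf.write(rec)


def read_vcf(path: str | Path) -> tuple[list[MeiLocus], pd.DataFrame | None, pd.DataFrame | None]:
    """Read a catalog VCF back into loci (+ genotype/GQ frames when present)."""
    loci: list[MeiLocus] = []
    gt_rows: dict = {}
    gq_rows: dict = {}
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            family = rec.info.get("FAMILY")
            if family is None:
                family = _FAMILY_BY_ALT.get(rec.alts[0] if rec.alts else "", "Alu")
            ci = rec.info.get("CIPOS", (0, 0))
            methods = rec.info.get("METHODS", ())
            if isinstance(methods, str):
                methods = (methods,)
            locus = MeiLocus(
                chrom=rec.chrom,
                pos=rec.pos,
                family=family,
                detection_mode=(NON_REFERENCE if rec.info.get("DET", "INS") == "INS"
                                else REFERENCE),
                ci_lo=rec.pos + int(ci[0]),
                ci_hi=rec.pos + int(ci[1]),
                methods=frozenset(methods),
                tsd_len=rec.info.get("TSDLEN"),
                n_alt5=int(rec.info.get("NALT5", 0)),
                n_alt3=int(rec.info.get("NALT3", 0)),
                locus_id=rec.id or "",
            )
            loci.append(locus)
            if samples:
                for s in samples:
                    sd = rec.samples[s]
                    gt = sd.get("GT")
                    dosage = (sum(a or 0 for a in gt)
                              if gt is not None and gt[0] is not None else np.nan)
                    gt_rows.setdefault(s, {})[locus.locus_id] = dosage
                    gq_rows.setdefault(s, {})[locus.locus_id] = sd.get("GQ", np.nan)
    if gt_rows:
        gt_df = pd.DataFrame(gt_rows).T
        gt_df.index.name = "sample_id"
        gq_df = pd.DataFrame(gq_rows).T
        gq_df.index.name = "sample_id"
        return loci, gt_df, gq_df
    return loci, None, None


def write_bed(path: str | Path, intervals: list[Interval]) -> None:
    """1-based inclusive intervals -> BED (0-based half-open)."""
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start - 1}\t{iv.end}\t{iv.label}\n")


def read_bed(path: str | Path) -> list[Interval]:
    """BED (0-based half-open) -> 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            label = parts[3] if len(parts) > 3 else ""
            out.append(Interval(parts[0], int(parts[1]) + 1, int(parts[2]), label))
    return out


def write_support_tsv(path: str | Path, support: pd.DataFrame) -> None:
    cols = ["locus_id", "sample_id", "n_alt5", "n_alt3", "n_ref"]
    support[cols].to_csv(path, sep="\t", index=False)


def read_support_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(path: str | Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=float)
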