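"""Bayesian genotype calling from fragment-support counts.

At an insertion locus a sample's evidence is ``n_alt`` fragments supporting
the insertion allele and ``n_ref`` supporting the reference allele.  The
posterior over genotypes g in {0/0, 0/1, 1/1} is

    P(g | n_alt, n_ref)  propto  P(g) * Binomial(n_alt; n_alt + n_ref, p_g)

with a flat prior P(g) = 1/3 and expected insertion-fragment fractions
p_g ~ 0 for 0/0, 0.5 for 0/1, and ~1 for 1/1.  Genotype quality follows the
phred convention GQ = -10 log10(1 - max posterior), so GQ 7 implies roughly
80% accuracy and GQ 10 implies 90%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

GENOTYPES = ("0/0", "0/1", "1/1")


@dataclass
class GenotypeModel:
    prior: tuple = (1 / 3, 1 / 3, 1 / 3)
    p_hom_ref: float = 0.02
    p_het: float = 0.5
    gq_cap: float = 99.0

    @property
    def p_hom_alt(self) -> float:
        return 1.0 - self.p_hom_ref

    def validate(self) -> None:
        if abs(sum(self.prior) - 1.0) > 1e-9 or any(p < 0 for p in self.prior):
            raise ValueError("genotype priors must be a probability vector")
        for p in (self.p_hom_ref, self.p_het):
            if not 0.0 <= p <= 1.0:
                raise ValueError("fragment fractions must be in [0, 1]")


@dataclass
class GenotypeCall:
    g: str
    posterior: tuple
    gq: float
    n_alt: int
    n_ref: int

    @property
    def dosage(self) -> int:
        return GENOTYPES.index(self.g)


def phred_accuracy(gq: float) -> float:
    """Implied genotype accuracy at a phred-scaled quality: 1 - 10^(-GQ/10)."""
    return 1.0 - 10.0 ** (-gq / 10.0)


def gq_from_posterior(p_max: float, cap: float = 99.0) -> float:
    err = 1.0 - p_max
    if err <= 10.0 ** (-cap / 10.0):
        return cap
    return min(cap, -10.0 * np.log10(err))


def call_genotype(n_alt: int, n_ref: int,
                  model: GenotypeModel | None = None) -> GenotypeCall:
    """Maximum-posterior genotype from fragment counts.

    Zero total fragments yields the flat prior and GQ = 0.  Posterior ties
    break toward 0/0 < 0/1 < 1/1.
    """
    if n_alt < 0 or n_ref < 0:
        raise ValueError("fragment counts must be non-negative")
    model = model or GenotypeModel()
    model.validate()
    n = n_alt + n_ref
    if n == 0:
        return GenotypeCall("0/0", (1 / 3, 1 / 3, 1 / 3), 0.0, 0, 0)
    p_g = (model.p_hom_ref, model.p_het, model.p_hom_alt)
    like = np.array([stats.binom.pmf(n_alt, n, p) for p in p_g])
    post = np.asarray(model.prior) * like
    total = post.sum()
    if total == 0.0:  # degenerate model (e.g. p_hom_ref = 0 with mixed counts)
        return GenotypeCall("0/0", (1 / 3, 1 / 3, 1 / 3), 0.0, n_alt, n_ref)
    post = post / total
    best = int(np.argmax(post))  # argmax takes the first maximum: 0/0 < 0/1 < 1/1
    gq = gq_from_posterior(float(post[best]), model.gq_cap)
    return GenotypeCall(GENOTYPES[best], tuple(float(p) for p in post), gq,
                        n_alt, n_ref)


def call_genotype_matrix(support: pd.DataFrame,
                         model: GenotypeModel | None = None) -> pd.DataFrame:
    """Vectorised genotype calls for a support-count table.

    ``support`` columns: locus_id, sample_id, n_alt5, n_alt3, n_ref.  Returns
    the table with added columns g (0/1/2 dosage), gq.
    """
    model = model or GenotypeModel()
    model.validate()
    n_alt = (support["n_alt5"] + support["n_alt3"]).to_numpy()
    n_ref = support["n_ref"].to_numpy()
    n = n_alt + n_ref
    p_g = np.array([model.p_hom_ref, model.p_het, model.p_hom_alt])
    like = stats.binom.pmf(n_alt[:, None], n[:, None], p_g[None, :])
    post = like * np.asarray(model.prior)[None, :]
    tot = post.sum(axis=1, keepdims=True)
    flat = (tot[:, 0] == 0.0) | (n == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        post = np.where(tot > 0, post / tot, 1 / 3)
    g = np.argmax(post, axis=1)
    p_max = post[np.arange(len(g)), g]
    err = np.maximum(1.0 - p_max, 10.0 ** (-model.gq_cap / 10.0))
    gq = np.minimum(-10.0 * np.log10(err), model.gq_cap)
    g = np.where(flat, 0, g)
    gq = np.where(flat, 0.0, gq)
    out = support.copy()
    out["g"] = g.astype(np.int8)
    out["gq"] = gq
    return out


@dataclass
class ConcordanceResult:
    table: pd.DataFrame  # 3x3 sequenced (rows) x truth (cols)
    agreement: float | None  # diagonal / total, None when empty
    efficiency: float  # fraction of site x sample cells entering the table

    @property
    def agreement_pct(self) -> float | None:
        return None if self.agreement is None else 100.0 * self.agreement


def concordance_from_table(table: pd.DataFrame | np.ndarray) -> float:
    """Agreement (diagonal / total) of a 3x3 genotype contingency table."""
    arr = np.asarray(table, dtype=float)
    return float(np.trace(arr) / arr.sum())


def concordance(calls: pd.DataFrame, truth: pd.DataFrame,
                gq_threshold: float = 7.0) -> ConcordanceResult:
    """Contingency of called vs truth genotypes for calls with GQ >= threshold.

    ``calls`` needs columns locus_id, sample_id, g, gq; ``truth`` needs
    locus_id, sample_id, g.  Efficiency is the fraction of truth cells with a
    qualifying call.
    """
    merged = calls.merge(truth, on=["locus_id", "sample_id"],
                         suffixes=("_call", "_true"))
    total_cells = len(truth)
    kept = merged[merged["gq"] >= gq_threshold]
    table = pd.DataFrame(0, index=list(GENOTYPES), columns=list(GENOTYPES))
    for gc, gt in zip(kept["g_call"], kept["g_true"]):
        table.iloc[int(gc), int(gt)] += 1
    n = table.to_numpy().sum()
    agreement = float(np.trace(table.to_numpy()) / n) if n else None
    efficiency = len(kept) / total_cells if total_cells else 0.0
    return ConcordanceResult(table, agreement, efficiency)


@dataclass
class QcResult:
    hwe: pd.DataFrame  # per-frequency-bin observed vs expected proportions
    mendelian_errors: int
    n_trio_tests: int


def _mendelian_ok(child: int, mother: int, father: int) -> bool:
    """Insertion-allele transmission consistency for dosage genotypes."""
    allowed = {
        a + b
        for a in ({0} if mother == 0 else {1} if mother == 2 else {0, 1})
        for b in ({0} if father == 0 else {1} if father == 2 else {0, 1})
    }
    return child in allowed


def genotype_qc(
    genotypes: pd.DataFrame,
    pedigrees: list[tuple[str, str, str]] | None = None,
    n_bins: int = 10,
) -> QcResult:
    """Hardy-Weinberg proportion curves and Mendelian-error count.

    ``genotypes`` is samples x loci with dosages 0/1/2; ``pedigrees`` lists
    (child, mother, father) sample ids.  Per allele-frequency bin the observed
    genotype proportions are compared with the HWE expectations
    (1-f)^2, 2f(1-f), f^2.
    """
    g = genotypes.to_numpy()
    freq = g.sum(axis=0) / (2 * g.shape[0])
    rows = []
    edges = np.linspace(0, 1, n_bins + 1)
    for k in range(n_bins):
        lo, hi = edges[k], edges[k + 1]
        sel = (freq > lo) & (freq <= hi) if k else (freq >= lo) & (freq <= hi)
        if not sel.any():
            continue
        sub = g[:, sel]
        f = freq[sel].mean()
        n = sub.size
        rows.append(
            {
                "f_mid": f,
                "n_genotypes": n,
                "obs_hom_ref": (sub == 0).mean(),
                "obs_het": (sub == 1).mean(),
                "obs_hom_alt": (sub == 2).mean(),
                "exp_hom_ref": (1 - f) ** 2,
                "exp_het": 2 * f * (1 - f),
                "exp_hom_alt": f**2,
            }
        )
    errors = 0
    tests = 0
    for child, mother, father in pedigrees or []:
        gc = genotypes.loc[child].to_numpy()
        gm = genotypes.loc[mother].to_numpy()
        gf = genotypes.loc[father].to_numpy()
        for c, m, f_ in zip(gc, gm, gf):
            tests += 1
            if not _mendelian_ok(int(c), int(m), int(f_)):
                errors += 1
    return QcResult(pd.DataFrame(rows), errors, tests)
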