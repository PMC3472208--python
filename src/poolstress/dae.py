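"""Differential allelic expression between treatment pools.

Each consistent SNP contributes a 2x2 table of its two alleles' read counts
in the control (S0) and stress (S1) pools.  Under the null of identical
allelic expression, allele counts are proportional between pools; a Pearson
chi-squared test (df=1, no continuity correction by default — counts in
the pooled data are large) detects shifts.  P-values are adjusted with
Benjamini–Hochberg and significance declared at the FDR threshold.

DAE/DE concordance labels each significant DAE SNP "concordant" when its
host gene is itself significant in the differential-expression results,
with a secondary directional report comparing the sign of the allele-
frequency shift against the gene's log fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .pool_counts import AlleleTable2x2


@dataclass(frozen=True)
class DaeResult:
    snp_id: str
    gene_id: str | None
    allele_a: str
    allele_b: str
    a_s0: int
    b_s0: int
    a_s1: int
    b_s1: int
    freq_s0: float
    freq_s1: float
    chi2: float
    p_value: float
    q_value: float = float("nan")
    significant: bool = False
    effect: str = "unassigned"  # syn/nonsyn/UTR5/UTR3/intronic/noncoding
    substitution_class: str = "unknown"


def allele_frequency(count_a: int, count_b: int) -> float:
    """Frequency of allele A among the two-allele reads: A/(A+B)."""
    total = count_a + count_b
    if total <= 0:
        raise ValueError("zero total count")
    return count_a / total


def chi2_dae(
    table: AlleleTable2x2, yates: bool = False
) -> tuple[float, float] | None:
    """Pearson chi-squared (df=1) on the pool-by-allele 2x2.

    Returns (statistic, p).  A zero column — an allele absent from both
    pools — leaves the test undefined and returns None.
    """
    t = np.asarray(table.table, dtype=float)
    if t[:, 0].sum() == 0 or t[:, 1].sum() == 0:
        return None
    if t[0].sum() == 0 or t[1].sum() == 0:
        raise ValueError(f"{table.snp_id}: empty pool row")
    stat, p, _dof, _exp = stats.chi2_contingency(t, correction=yates)
    return float(stat), float(p)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_dae(
    tables: Iterable[AlleleTable2x2],
    alpha: float = 0.05,
    yates: bool = False,
) -> list[DaeResult]:
    """Chi-squared DAE test over all consistent SNPs with BH-FDR control."""
    results: list[DaeResult] = []
    for tab in tables:
        out = chi2_dae(tab, yates=yates)
        if out is None:
            continue
        stat, p = out
        results.append(
            DaeResult(
                snp_id=tab.snp_id,
                gene_id=None,
                allele_a=tab.allele_a,
                allele_b=tab.allele_b,
                a_s0=tab.a_s0,
                b_s0=tab.b_s0,
                a_s1=tab.a_s1,
                b_s1=tab.b_s1,
                freq_s0=allele_frequency(tab.a_s0, tab.b_s0),
                freq_s1=allele_frequency(tab.a_s1, tab.b_s1),
                chi2=stat,
                p_value=p,
            )
        )
    if not results:
        return results
    q = bh_fdr([r.p_value for r in results])
    return [
        replace(r, q_value=float(qi), significant=bool(qi < alpha))
        for r, qi in zip(results, q)
    ]


test_dae.__test__ = False  # not a pytest test


@dataclass(frozen=True)
class ConcordanceSummary:
    n_significant_dae: int
    n_concordant: int
    n_intergenic: int
    fraction_concordant: float
    n_sign_concordant: int
    fraction_sign_concordant: float


def dae_de_concordance(
    dae_results: Iterable[DaeResult],
    de_significant: dict[str, float],
) -> ConcordanceSummary:
    """Relate significant DAE SNPs to differential gene expression.

    ``de_significant`` maps DE-significant gene ids to their logFC.  A DAE
    SNP is concordant when its host gene is in that map; SNPs outside any
    gene are tallied separately as intergenic.  The secondary directional
    count asks whether the allele-frequency shift (freq_S1 − freq_S0 of
    allele A) and the host gene's logFC share a sign.
    """
    sig = [r for r in dae_results if r.significant]
    n_conc = n_inter = n_sign = 0
    for r in sig:
        if r.gene_id is None:
            n_inter += 1
            continue
        if r.gene_id in de_significant:
            n_conc += 1
            shift = r.freq_s1 - r.freq_s0
            if shift * de_significant[r.gene_id] > 0:
                n_sign += 1
    n = len(sig)
    return ConcordanceSummary(
        n_significant_dae=n,
        n_concordant=n_conc,
        n_intergenic=n_inter,
        fraction_concordant=n_conc / n if n else 0.0,
        n_sign_concordant=n_sign,
        fraction_sign_concordant=n_sign / n_conc if n_conc else 0.0,
    )
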