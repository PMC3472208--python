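"""Lightweight differential expression over per-gene count matrices.

This is a deliberately simple, self-contained stand-in that feeds the
enrichment and DAE-concordance steps: per gene, a two-sided Fisher exact
test on the 2x2 of (gene reads, all other reads) summed within each
treatment, with BH-FDR across genes.  It ignores biological overdispersion
between replicate libraries, so on real data it would be anticonservative;
negative-binomial modelling is intentionally out of scope here, where the
role of this module is exercising the pipeline on synthetic counts.

Log fold-changes are computed on CPM (counts per million of library total)
with a pseudocount, averaged within treatment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dae import bh_fdr


@dataclass(frozen=True)
class CountMatrix:
    """Genes x libraries integer counts with a library -> treatment map."""

    counts: pd.DataFrame  # index: gene ids, columns: library ids
    treatments: dict[str, str]  # library id -> treatment label

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("negative counts")
        missing = set(self.counts.columns) - set(self.treatments)
        if missing:
            raise ValueError(f"libraries without treatment label: {sorted(missing)}")
        if len(set(self.treatments.values())) < 2:
            raise ValueError("need at least two treatments")

    def libraries(self, treatment: str) -> list[str]:
        return [lib for lib in self.counts.columns if self.treatments[lib] == treatment]


@dataclass(frozen=True)
class DeResult:
    gene_id: str
    log_fc: float
    p_value: float
    q_value: float
    significant: bool


def filter_low_counts(matrix: CountMatrix, min_total: int = 10) -> CountMatrix:
    """Drop genes whose total count across all libraries is below ``min_total``."""
    keep = matrix.counts.sum(axis=1) >= min_total
    return CountMatrix(counts=matrix.counts.loc[keep], treatments=matrix.treatments)


def log_fold_change(
    matrix: CountMatrix,
    gene: str,
    treatment_num: str,
    treatment_den: str,
    pseudocount: float = 0.5,
) -> float:
    """log2 ratio of mean CPM between two treatments for one gene.

    The pseudocount is added on the CPM scale (scaled to 0.5 reads in a
    library of the mean size), keeping the ratio finite when a treatment
    has zero counts.
    """
    lib_sizes = matrix.counts.sum(axis=0)
    cpm = matrix.counts.loc[gene] / lib_sizes * 1e6
    scale = pseudocount / lib_sizes.mean() * 1e6
    num = cpm[matrix.libraries(treatment_num)].mean() + scale
    den = cpm[matrix.libraries(treatment_den)].mean() + scale
    return float(np.log2(num / den))


def de_test(
    matrix: CountMatrix,
    treatment_num: str,
    treatment_den: str,
    fdr: float = 0.01,
    pseudocount: float = 0.5,
    adjust: str = "fdr_bh",
) -> list[DeResult]:
    """Fisher-exact differential expression across all genes.

    For each gene the 2x2 is [[gene reads, other reads] in treatment_num,
    [gene reads, other reads] in treatment_den]; p-values are two-sided.
    ``adjust`` may be ``fdr_bh`` (default) or ``bonferroni``.
    """
    num_libs = matrix.libraries(treatment_num)
    den_libs = matrix.libraries(treatment_den)
    num_counts = matrix.counts[num_libs].sum(axis=1)
    den_counts = matrix.counts[den_libs].sum(axis=1)
    num_total = int(num_counts.sum())
    den_total = int(den_counts.sum())

    genes = list(matrix.counts.index)
    pvals = np.empty(len(genes))
    for i, g in enumerate(genes):
        a, c = int(num_counts[g]), int(den_counts[g])
        table = [[a, num_total - a], [c, den_total - c]]
        pvals[i] = stats.fisher_exact(table, alternative="two-sided")[1]

    if adjust == "bonferroni":
        qvals = np.minimum(pvals * len(pvals), 1.0)
    elif adjust == "fdr_bh":
        qvals = bh_fdr(pvals)
    else:
        raise ValueError(f"unknown adjustment {adjust!r}")

    return [
        DeResult(
            gene_id=g,
            log_fc=log_fold_change(matrix, g, treatment_num, treatment_den, pseudocount),
            p_value=float(p),
            q_value=float(q),
            significant=bool(q < fdr),
        )
        for g, p, q in zip(genes, pvals, qvals)
    ]


de_test.__test__ = False


def read_count_matrix(counts_path, treatments_path) -> CountMatrix:
    """Load a genes-x-libraries TSV and its two-column library->treatment map."""
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    tmap = pd.read_csv(
        treatments_path, sep="\t", header=None, names=["library", "treatment"]
    )
    return CountMatrix(
        counts=counts.astype(int),
        treatments=dict(zip(tmap["library"], tmap["treatment"])),
    )


def write_count_matrix(matrix: CountMatrix, counts_path, treatments_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t")
    with open(treatments_path, "w") as fh:
        for lib, tr in matrix.treatments.items():
            fh.write(f"{lib}\t{tr}\n")
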