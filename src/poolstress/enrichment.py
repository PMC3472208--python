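"""Gene-category over-representation tests.

For each category the 2x2 is [[subset∩cat, subset∖cat], [rest∩cat,
rest∖cat]] over a stated background universe, tested with a one-sided
(over-representation) Fisher exact test by default, BH-FDR across
categories.  Genes mapping to no category stay in the background and count
only in the complements.

``select_gene_sets`` builds the study's standard contrasts from upstream
results: positively selected (Ka/Ks > 1.5) vs rest, strongly purifying
(Ka/Ks < 0.20) vs rest, DAE SNP-bearing genes split by DE significance,
and up- vs down-regulated DE genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .dae import DaeResult, bh_fdr
from .de import DeResult
from .selection import GeneKaKs, POSITIVE_CUTOFF, STRONG_PURIFYING_CUTOFF

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class EnrichmentResult:
    category: str
    total_genes: int  # background members of the category
    changed_genes: int  # subset members of the category
    p_value: float
    q_value: float


def enrich(
    subset: Iterable[str],
    background: Iterable[str],
    category_map: Mapping[str, Sequence[str]],
    alternative: str = "greater",
) -> list[EnrichmentResult]:
    """Fisher-exact over-representation of every category in ``subset``.

    ``category_map`` maps gene id -> categories (many-to-many).  The subset
    must be a non-empty sub-collection of the background.
    """
    bg = set(background)
    sub = set(subset)
    if not sub:
        raise ValueError("empty gene subset")
    if not sub <= bg:
        raise ValueError("subset is not contained in the background")

    cat_members: dict[str, set[str]] = {}
    for gene in bg:
        for cat in category_map.get(gene, ()):
            cat_members.setdefault(cat, set()).add(gene)

    results: list[tuple[str, int, int, float]] = []
    n_sub, n_bg = len(sub), len(bg)
    for cat, members in sorted(cat_members.items()):
        in_sub = len(members & sub)
        table = [
            [in_sub, n_sub - in_sub],
            [len(members) - in_sub, (n_bg - n_sub) - (len(members) - in_sub)],
        ]
        p = stats.fisher_exact(table, alternative=alternative)[1]
        results.append((cat, len(members), in_sub, float(p)))

    qvals = bh_fdr([r[3] for r in results]) if results else []
    return [
        EnrichmentResult(
            category=cat, total_genes=tot, changed_genes=chg, p_value=p, q_value=float(q)
        )
        for (cat, tot, chg, p), q in zip(results, qvals)
    ]


def select_gene_sets(
    kaks_results: Iterable[GeneKaKs] = (),
    de_results: Iterable[DeResult] = (),
    dae_results: Iterable[DaeResult] = (),
    positive_cutoff: float = POSITIVE_CUTOFF,
    strong_purifying_cutoff: float = STRONG_PURIFYING_CUTOFF,
) -> dict[str, set[str]]:
    """Build the standard enrichment contrasts as named gene sets."""
    kaks = list(kaks_results)
    de = list(de_results)
    dae = list(dae_results)

    sets: dict[str, set[str]] = {}
    if kaks:
        sets["positive_selection"] = {
            g.gene_id for g in kaks if g.ratio > positive_cutoff
        }
        sets["strong_purifying"] = {
            g.gene_id for g in kaks if g.ratio < strong_purifying_cutoff
        }
        if not sets["positive_selection"]:
            logger.warning("no gene exceeds the positive-selection cutoff")
    if de:
        de_sig = {r.gene_id for r in de if r.significant}
        sets["de_up"] = {r.gene_id for r in de if r.significant and r.log_fc > 0}
        sets["de_down"] = {r.gene_id for r in de if r.significant and r.log_fc < 0}
        if dae:
            dae_genes = {
                r.gene_id for r in dae if r.significant and r.gene_id is not None
            }
            sets["dae_with_de"] = dae_genes & de_sig
            sets["dae_without_de"] = dae_genes - de_sig
    return sets


def read_category_map(path) -> dict[str, list[str]]:
    """Two-column TSV (gene_id, category_id), many-to-many."""
    out: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, cat = line.split("\t")[:2]
            out.setdefault(gene, []).append(cat)
    return out


def write_category_map(cmap: Mapping[str, Sequence[str]], path) -> None:
    with open(path, "w") as fh:
        for gene in sorted(cmap):
            for cat in cmap[gene]:
                fh.write(f"{gene}\t{cat}\n")
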