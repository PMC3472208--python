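"""Quality-filtered allele counting and pooled SNP calling.

Implements a VarScan-style gate on pooled pileup columns: a site becomes a
SNP call when filtered depth reaches ``min_coverage``, the minor allele
reaches ``min_minor_count`` reads and ``min_freq`` frequency, and a
one-sided binomial test rejects the hypothesis that the minor-allele reads
are sequencing error at the configured per-base error rate.

Two calling profiles are shipped: the allelic-expression branch
(min_coverage 8, minor count 2, paired-pool depth >= 20 in each pool) and
the selection branch (min_coverage 20, max coverage 8000, minor count 4),
matching the thresholds used for DAE testing and Ka/Ks estimation
respectively.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

from scipy import stats

from .io_formats import PileupColumn

logger = logging.getLogger(__name__)

ALLELES = "ACGT"


@dataclass(frozen=True)
class SiteAlleleCounts:
    """Base counts at one site in one pool, after quality filtering."""

    contig: str
    pos: int
    ref_base: str
    counts: dict[str, int]  # A/C/G/T only

    @property
    def filtered_depth(self) -> int:
        return sum(self.counts.values())


@dataclass(frozen=True)
class SnpCall:
    contig: str
    pos: int
    major_allele: str
    minor_allele: str
    major_count: int
    minor_count: int
    p_value: float

    @property
    def minor_freq(self) -> float:
        return self.minor_count / (self.major_count + self.minor_count)

    @property
    def snp_id(self) -> str:
        return f"{self.contig}:{self.pos}"


@dataclass(frozen=True)
class AlleleTable2x2:
    """Counts of a consistent SNP's two alleles in the two treatment pools."""

    snp_id: str
    allele_a: str
    allele_b: str
    a_s0: int
    b_s0: int
    a_s1: int
    b_s1: int

    def __post_init__(self) -> None:
        if min(self.a_s0, self.b_s0, self.a_s1, self.b_s1) < 0:
            raise ValueError(f"{self.snp_id}: negative cell count")

    @property
    def table(self) -> list[list[int]]:
        return [[self.a_s0, self.b_s0], [self.a_s1, self.b_s1]]


def count_alleles(column: PileupColumn, min_quality: int = 20) -> SiteAlleleCounts:
    """Count A/C/G/T calls at phred >= ``min_quality``; N and deletion
    placeholders are never counted."""
    counts = dict.fromkeys(ALLELES, 0)
    for call, qual in zip(column.calls, column.quals):
        if qual >= min_quality and call in counts:
            counts[call] += 1
    return SiteAlleleCounts(
        contig=column.contig,
        pos=column.pos,
        ref_base=column.ref_base,
        counts=counts,
    )


def call_snp(
    site: SiteAlleleCounts,
    min_coverage: int = 8,
    min_freq: float = 0.01,
    min_minor_count: int = 2,
    alpha: float = 0.05,
    error_rate: float = 0.01,
    max_coverage: int | None = None,
) -> SnpCall | None:
    """Call a biallelic SNP from filtered allele counts, or return None.

    The significance gate is a one-sided binomial test of the minor-allele
    count against the per-base ``error_rate``: P(X >= minor | depth,
    error_rate) must fall below ``alpha``.  Ties between the 2nd and 3rd
    most frequent alleles are broken alphabetically.
    """
    depth = site.filtered_depth
    if depth < min_coverage:
        return None
    if max_coverage is not None and depth > max_coverage:
        return None
    # sort by count descending, then alphabetically for deterministic ties
    ranked = sorted(site.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    (major, major_n), (minor, minor_n) = ranked[0], ranked[1]
    if len(ranked) > 2 and ranked[2][1] == minor_n and minor_n > 0:
        logger.debug(
            "%s:%d: tie between %s and %s at count %d; kept %s",
            site.contig, site.pos, minor, ranked[2][0], minor_n, minor,
        )
    if minor_n < min_minor_count:
        return None
    if minor_n / (major_n + minor_n) < min_freq:
        return None
    p = stats.binom.sf(minor_n - 1, depth, error_rate)
    if p >= alpha:
        return None
    return SnpCall(
        contig=site.contig,
        pos=site.pos,
        major_allele=major,
        minor_allele=minor,
        major_count=major_n,
        minor_count=minor_n,
        p_value=float(p),
    )


def pair_pools(
    calls_s0: Iterable[SnpCall],
    calls_s1: Iterable[SnpCall],
    sites_s0: dict[tuple[str, int], SiteAlleleCounts],
    sites_s1: dict[tuple[str, int], SiteAlleleCounts],
    min_depth_per_pool: int = 20,
) -> list[AlleleTable2x2]:
    """Pair SNP calls across pools into 2x2 allele tables.

    Only consistent SNPs — the same unordered allele pair called in both
    pools — are kept, and each pool's two-allele depth must reach
    ``min_depth_per_pool``.  The counts entering the table are the pools'
    quality-filtered allele counts for the shared pair, with allele A and
    allele B ordered as (major, minor) of pool S0.
    """
    by_site_s1 = {(c.contig, c.pos): c for c in calls_s1}
    tables: list[AlleleTable2x2] = []
    for c0 in calls_s0:
        key = (c0.contig, c0.pos)
        c1 = by_site_s1.get(key)
        if c1 is None:
            continue
        pair0 = frozenset((c0.major_allele, c0.minor_allele))
        pair1 = frozenset((c1.major_allele, c1.minor_allele))
        if pair0 != pair1:
            continue
        a, b = c0.major_allele, c0.minor_allele
        n0, n1 = sites_s0[key].counts, sites_s1[key].counts
        a_s0, b_s0 = n0[a], n0[b]
        a_s1, b_s1 = n1[a], n1[b]
        if a_s0 + b_s0 < min_depth_per_pool or a_s1 + b_s1 < min_depth_per_pool:
            continue
        tables.append(
            AlleleTable2x2(
                snp_id=f"{c0.contig}:{c0.pos}",
                allele_a=a,
                allele_b=b,
                a_s0=a_s0,
                b_s0=b_s0,
                a_s1=a_s1,
                b_s1=b_s1,
            )
        )
    return tables


def merge_site_counts(
    sites_a: dict[tuple[str, int], SiteAlleleCounts],
    sites_b: dict[tuple[str, int], SiteAlleleCounts],
) -> dict[tuple[str, int], SiteAlleleCounts]:
    """Sum per-allele counts across two pools (reads combined, as for the
    selection branch where both treatments' reads are pooled)."""
    merged: dict[tuple[str, int], SiteAlleleCounts] = {}
    for key in set(sites_a) | set(sites_b):
        if key in sites_a and key in sites_b:
            sa, sb = sites_a[key], sites_b[key]
            counts = {al: sa.counts[al] + sb.counts[al] for al in ALLELES}
            merged[key] = SiteAlleleCounts(
                contig=sa.contig, pos=sa.pos, ref_base=sa.ref_base, counts=counts
            )
        else:
            merged[key] = sites_a.get(key) or sites_b[key]
    return merged
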