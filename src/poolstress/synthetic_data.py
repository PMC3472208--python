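"""Synthetic miniature study generator with recorded ground truth.

Generates everything the pipeline consumes — a multi-gene reference with
plus/minus-strand, multi-exon CDS models; two treatment pools' pileups with
segregating SNPs, sequencing error and optional allelic-expression shifts;
per-gene count matrices with treatment fold-changes; gene-category maps —
together with a truth table for recovery testing.

The pools are modelled at the expressed-allele-fraction level: a pool of N
diploid individuals expresses a site's alternate allele at some fraction p
(a multiple of 1/2N), and each pool's reads at the site are binomial draws
of that fraction at a negative-binomially distributed depth.  This is the
minimal sufficient statistic for pooled allele-count tests; read-level
structure (individual identity, positional error profiles, mapping
artefacts) is intentionally not simulated.

Selection signatures are planted per gene: each gene is assigned a target
selection class and receives the nonsynonymous/synonymous SNP counts that
its weighted site lengths require for the pseudocounted Ka/Ks ratio to land
in that class.  Planted substitution effects are verified against an
independent translation (Biopython) of the mutated codon.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .codon_sites import gene_site_lengths, reverse_complement
from .de import CountMatrix, write_count_matrix
from .io_formats import (
    CdsModel,
    GenomeRef,
    PileupColumn,
    write_fasta,
    write_gff3_cds,
    write_pileup,
)
from .selection import classify_selection

STOPS = {"TAA", "TAG", "TGA"}
NON_STOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in STOPS
]


@dataclass
class SimConfig:
    """Study-design knobs for the synthetic generator.

    Defaults mirror the emulated study: two pools of 10 diploid seedlings
    (the same individuals before and after treatment), three populations as
    biological replicates per treatment in the count matrices, RNA-seq-like
    overdispersed depth (negative binomial, mean 80, dispersion 0.5), and a
    purifying-dominated selection-class mix.
    """

    n_genes: int = 30
    mean_cds_codons: int = 120
    n_individuals_per_pool: int = 10
    snp_density_per_kb: float = 4.0  # extra (intronic) segregating sites
    allele_freq_bounds: tuple[float, float] = (0.1, 0.9)
    depth_mean: float = 80.0
    depth_dispersion: float = 0.5  # variance = mean + disp * mean^2
    min_depth: int = 1
    base_error_rate: float = 0.005
    frac_low_quality: float = 0.05  # calls emitted below the Q20 filter
    fraction_dae_sites: float = 0.05
    dae_effect: float = 0.3
    class_mix: tuple[float, float, float] = (0.77, 0.21, 0.02)  # purifying/intermediate/positive
    plant_selection_classes: bool = True
    coding_snp_density_per_kb: float = 4.0  # used when classes are not planted
    dae_only_in_de_genes: bool = False
    n_libraries_per_treatment: int = 3
    fraction_de_genes: float = 0.2
    de_fold_change: float = 8.0
    count_mean: float = 200.0
    count_dispersion: float = 0.3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.base_error_rate,
            self.frac_low_quality,
            self.fraction_dae_sites,
            self.fraction_de_genes,
            *self.class_mix,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")
        lo, hi = self.allele_freq_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("allele_freq_bounds must satisfy 0 < lo < hi < 1")


@dataclass(frozen=True)
class SiteTruth:
    contig: str
    pos: int  # 1-based
    gene_id: str | None
    ref_allele: str
    alt_allele: str
    frac_s0: float  # expressed alt-allele fraction in pool S0
    frac_s1: float
    is_dae: bool
    region: str  # "coding" | "intronic"
    effect: str  # "synonymous" | "nonsynonymous" | "" for non-coding


@dataclass(frozen=True)
class GeneTruth:
    gene_id: str
    planted_nonsyn: int
    planted_syn: int
    selection_class: str  # intended class under the pseudocounted ratio
    is_de: bool
    fold_change: float  # S1 over C1 mean, 1.0 when not DE


@dataclass
class SimTruth:
    sites: list[SiteTruth] = field(default_factory=list)
    genes: list[GeneTruth] = field(default_factory=list)

    def dae_sites(self) -> list[SiteTruth]:
        return [s for s in self.sites if s.is_dae]


# ---------------------------------------------------------------------------
# reference + gene models


def _random_intergenic(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=length))


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(NON_STOP_CODONS, size=n_codons - 2)
    stop = rng.choice(sorted(STOPS))
    return "ATG" + "".join(body) + stop


def simulate_reference(config: SimConfig) -> tuple[GenomeRef, list[CdsModel]]:
    """One contig carrying ``n_genes`` non-overlapping gene models.

    At least 20% of genes are minus-strand and at least 20% multi-exon;
    every CDS starts with ATG, ends with a stop and has no internal stop.
    """
    rng = np.random.default_rng(config.rng_seed)
    if config.n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    parts: list[str] = []
    models: list[CdsModel] = []
    cursor = 0  # 0-based length laid down so far

    n_minus = max(1, math.ceil(0.25 * config.n_genes)) if config.n_genes > 1 else 0
    n_multi = max(1, math.ceil(0.30 * config.n_genes)) if config.n_genes > 1 else 0
    strands = ["-"] * n_minus + ["+"] * (config.n_genes - n_minus)
    multi = [True] * n_multi + [False] * (config.n_genes - n_multi)
    rng.shuffle(strands)
    rng.shuffle(multi)

    for gi in range(config.n_genes):
        gap = int(rng.integers(60, 160))
        parts.append(_random_intergenic(rng, gap))
        cursor += gap

        n_codons = max(20, int(rng.poisson(config.mean_cds_codons)))
        cds = _random_cds(rng, n_codons)
        assert "*" not in str(Seq(cds[:-3]).translate())

        if multi[gi]:
            n_exons = int(rng.integers(2, 4))
            cuts = sorted(
                rng.choice(np.arange(30, len(cds) - 30), size=n_exons - 1, replace=False)
            )
            exons = [cds[a:b] for a, b in zip([0, *cuts], [*cuts, len(cds)])]
        else:
            exons = [cds]
        introns = [
            _random_intergenic(rng, int(rng.integers(40, 90)))
            for _ in range(len(exons) - 1)
        ]

        # transcript-oriented gene region and exon offsets within it
        region_parts: list[str] = []
        offsets: list[tuple[int, int]] = []  # 0-based half-open within region
        off = 0
        for i, ex in enumerate(exons):
            offsets.append((off, off + len(ex)))
            region_parts.append(ex)
            off += len(ex)
            if i < len(introns):
                region_parts.append(introns[i])
                off += len(introns[i])
        region = "".join(region_parts)
        strand = strands[gi]
        if strand == "-":
            region = reverse_complement(region)
            offsets = [(len(region) - b, len(region) - a) for a, b in offsets]
            offsets.reverse()

        segments = tuple(
            (cursor + a + 1, cursor + b) for a, b in sorted(offsets)
        )
        models.append(
            CdsModel(
                gene_id=f"gene{gi + 1:04d}",
                contig="chr1",
                strand=strand,
                segments=segments,
                phase=0,
            )
        )
        parts.append(region)
        cursor += len(region)

    parts.append(_random_intergenic(rng, 80))
    ref = GenomeRef({"chr1": "".join(parts)})

    # self-check: every model translates cleanly
    for m in models:
        from .codon_sites import extract_cds, translate

        protein = translate(extract_cds(ref, m))
        if "*" in protein[:-1]:
            raise AssertionError(f"{m.gene_id}: internal stop in simulated CDS")
    return ref, models


# ---------------------------------------------------------------------------
# planting SNPs


def _kaks_targets_for_class(
    target: str, l_n: float, l_s: float, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick (nonsyn, syn) planted counts whose pseudocounted ratio lands
    comfortably inside the target class band given the gene's site lengths."""
    margins = {
        "purifying": (0.0, 0.38),
        "intermediate": (0.65, 1.35),
        "positive": (1.9, 6.0),
    }
    lo, hi = margins[target]
    candidates: list[tuple[int, int]] = []
    for s in range(0, 8):
        for n in range(0, 60):
            ratio = ((n + 1) / l_n) / ((s + 1) / l_s)
            if lo < ratio < hi and classify_selection(ratio) == target:
                candidates.append((n, s))
        if candidates:
            break
    if not candidates:
        raise ValueError(
            f"cannot plant class {target!r} for lengths L_N={l_n:.1f}, L_S={l_s:.1f}"
        )
    return candidates[int(rng.integers(len(candidates)))]


def _plantable_changes(codon: str) -> dict[str, list[tuple[int, str]]]:
    """Per effect, the (position, alt_base) single changes available in a codon."""
    out: dict[str, list[tuple[int, str]]] = {"synonymous": [], "nonsynonymous": []}
    aa = str(Seq(codon).translate())
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            alt_codon = codon[:pos] + alt + codon[pos + 1 :]
            alt_aa = str(Seq(alt_codon).translate())
            out["synonymous" if alt_aa == aa else "nonsynonymous"].append((pos, alt))
    return out


def _pool_fraction(rng: np.random.Generator, config: SimConfig) -> float:
    """Expressed-allele fraction: k/2N with k drawn inside the configured bounds."""
    two_n = 2 * config.n_individuals_per_pool
    lo, hi = config.allele_freq_bounds
    k_lo = max(1, math.ceil(lo * two_n))
    k_hi = min(two_n - 1, math.floor(hi * two_n))
    return int(rng.integers(k_lo, k_hi + 1)) / two_n


def _shift_fraction(p0: float, effect: float, rng: np.random.Generator) -> float:
    """Shift a fraction by ±effect, choosing a direction that stays in (0.02, 0.98)."""
    up, down = p0 + effect, p0 - effect
    feasible = [p for p in (up, down) if 0.02 <= p <= 0.98]
    if not feasible:
        return min(0.98, max(0.02, up))
    return feasible[int(rng.integers(len(feasible)))]


def plant_snps(
    config: SimConfig,
    ref: GenomeRef,
    models: list[CdsModel],
    rng: np.random.Generator,
    de_genes: set[str] | None = None,
) -> tuple[list[SiteTruth], list[tuple[str, int, int, str]]]:
    """Choose segregating sites and their true allele behaviour.

    Returns the site truth records and per-gene (gene_id, N, S, class)
    planted selection targets (class is "none" when planting is disabled).
    """
    from .codon_sites import extract_cds

    contig_seq = ref["chr1"]
    sites: list[SiteTruth] = []
    gene_plants: list[tuple[str, int, int, str]] = []
    class_names = ("purifying", "intermediate", "positive")

    for model in models:
        cds = extract_cds(ref, model)
        n_codons = len(cds) // 3 - 1  # exclude terminal stop
        # genomic position of each CDS offset
        cds_positions: list[int] = []
        if model.strand == "+":
            for s, e in model.segments:
                cds_positions.extend(range(s, e + 1))
        else:
            for s, e in reversed(model.segments):
                cds_positions.extend(range(e, s - 1, -1))

        if config.plant_selection_classes:
            lengths = gene_site_lengths(model, ref)
            target = class_names[
                int(rng.choice(3, p=np.asarray(config.class_mix)))
            ]
            n_plant, s_plant = _kaks_targets_for_class(
                target, lengths.nonsyn_length, lengths.syn_length, rng
            )
            gene_plants.append((model.gene_id, n_plant, s_plant, target))

            codon_order = rng.permutation(n_codons)
            needed = {"nonsynonymous": n_plant, "synonymous": s_plant}
            for ci in codon_order:
                if needed["nonsynonymous"] == 0 and needed["synonymous"] == 0:
                    break
                codon = cds[ci * 3 : ci * 3 + 3]
                options = _plantable_changes(codon)
                effect = None
                for eff in ("synonymous", "nonsynonymous"):
                    if needed[eff] > 0 and options[eff]:
                        effect = eff
                        break
                if effect is None:
                    continue
                pos_in_codon, alt = options[effect][
                    int(rng.integers(len(options[effect])))
                ]
                offset = ci * 3 + pos_in_codon
                genomic_pos = cds_positions[offset]
                ref_allele = contig_seq[genomic_pos - 1]
                alt_genomic = (
                    alt if model.strand == "+" else reverse_complement(alt)
                )
                p0 = _pool_fraction(rng, config)
                sites.append(
                    SiteTruth(
                        contig="chr1",
                        pos=genomic_pos,
                        gene_id=model.gene_id,
                        ref_allele=ref_allele,
                        alt_allele=alt_genomic,
                        frac_s0=p0,
                        frac_s1=p0,
                        is_dae=False,
                        region="coding",
                        effect=effect,
                    )
                )
                needed[effect] -= 1
            if needed["nonsynonymous"] or needed["synonymous"]:
                raise ValueError(
                    f"{model.gene_id}: could not place all planted SNPs"
                )
        else:
            gene_plants.append((model.gene_id, 0, 0, "none"))
            n_sites = rng.poisson(
                config.coding_snp_density_per_kb * len(cds) / 1000.0
            )
            chosen = rng.choice(
                len(cds) - 3, size=min(int(n_sites), len(cds) - 3), replace=False
            )
            for offset in sorted(int(o) for o in chosen):
                genomic_pos = cds_positions[offset]
                ref_allele = contig_seq[genomic_pos - 1]
                alt_genomic = rng.choice(
                    [b for b in "ACGT" if b != ref_allele]
                )
                p0 = _pool_fraction(rng, config)
                sites.append(
                    SiteTruth(
                        contig="chr1",
                        pos=genomic_pos,
                        gene_id=model.gene_id,
                        ref_allele=ref_allele,
                        alt_allele=str(alt_genomic),
                        frac_s0=p0,
                        frac_s1=p0,
                        is_dae=False,
                        region="coding",
                        effect="",
                    )
                )

        # intronic segregating sites at the configured density
        span_lo, span_hi = model.span
        intronic = [
            p
            for p in range(span_lo, span_hi + 1)
            if not model.contains(p)
        ]
        if intronic:
            n_intron = rng.poisson(config.snp_density_per_kb * len(intronic) / 1000.0)
            chosen = rng.choice(
                len(intronic), size=min(int(n_intron), len(intronic)), replace=False
            )
            for idx in sorted(int(i) for i in chosen):
                genomic_pos = intronic[idx]
                ref_allele = contig_seq[genomic_pos - 1]
                alt = str(rng.choice([b for b in "ACGT" if b != ref_allele]))
                p0 = _pool_fraction(rng, config)
                sites.append(
                    SiteTruth(
                        contig="chr1",
                        pos=genomic_pos,
                        gene_id=model.gene_id,
                        ref_allele=ref_allele,
                        alt_allele=alt,
                        frac_s0=p0,
                        frac_s1=p0,
                        is_dae=False,
                        region="intronic",
                        effect="",
                    )
                )

    # mark the DAE subset and shift its S1 fractions
    if config.fraction_dae_sites > 0 and sites:
        if config.dae_only_in_de_genes and de_genes is not None:
            eligible = [i for i, s in enumerate(sites) if s.gene_id in de_genes]
        else:
            eligible = list(range(len(sites)))
        n_dae = int(round(config.fraction_dae_sites * len(sites)))
        n_dae = min(n_dae, len(eligible))
        chosen = rng.choice(len(eligible), size=n_dae, replace=False)
        for idx in chosen:
            i = eligible[int(idx)]
            s = sites[i]
            p1 = _shift_fraction(s.frac_s0, config.dae_effect, rng)
            sites[i] = SiteTruth(
                **{**asdict(s), "frac_s1": p1, "is_dae": True}
            )
    return sites, gene_plants


# ---------------------------------------------------------------------------
# pileup emission


def _draw_depth(rng: np.random.Generator, config: SimConfig, size: int) -> np.ndarray:
    """Negative-binomial depths (variance = mean + disp * mean^2), floored
    at ``min_depth`` by redrawing."""
    mean, disp = config.depth_mean, config.depth_dispersion
    if disp <= 0:
        depths = rng.poisson(mean, size=size)
    else:
        r = 1.0 / disp
        p = r / (r + mean)
        depths = rng.negative_binomial(r, p, size=size)
    while True:
        low = depths < config.min_depth
        if not low.any():
            return depths
        if disp <= 0:
            depths[low] = rng.poisson(mean, size=int(low.sum()))
        else:
            depths[low] = rng.negative_binomial(r, p, size=int(low.sum()))


_OTHER = {b: [o for o in "ACGT" if o != b] for b in "ACGT"}


def _emit_column(
    rng: np.random.Generator,
    config: SimConfig,
    contig: str,
    pos: int,
    ref_base: str,
    alt: str | None,
    frac: float,
    depth: int,
) -> PileupColumn:
    n_alt = int(rng.binomial(depth, frac)) if alt is not None else 0
    calls = [alt] * n_alt + [ref_base] * (depth - n_alt)
    if config.base_error_rate > 0:
        errs = np.flatnonzero(rng.random(depth) < config.base_error_rate)
        for i in errs:
            calls[i] = _OTHER[calls[i]][int(rng.integers(3))]
    low = rng.random(depth) < config.frac_low_quality
    quals = np.where(
        low, rng.integers(5, 20, size=depth), rng.integers(25, 41, size=depth)
    )
    order = rng.permutation(depth)
    return PileupColumn(
        contig=contig,
        pos=pos,
        ref_base=ref_base,
        calls=tuple(calls[i] for i in order),
        quals=tuple(int(quals[i]) for i in order),
    )


def simulate_pools(
    config: SimConfig,
    ref: GenomeRef,
    models: list[CdsModel],
    rng: np.random.Generator | None = None,
    de_genes: set[str] | None = None,
    emit_monomorphic: bool = True,
) -> tuple[list[PileupColumn], list[PileupColumn], SimTruth]:
    """Two treatment pools' pileups over the gene regions, plus ground truth.

    Every truth site appears in both pools with depth > 0 (depths are
    redrawn above ``min_depth``).  With ``emit_monomorphic`` the pileups
    also cover every non-segregating position inside gene spans, exercising
    the monomorphic-rejection path of SNP calling.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 1)
    sites, gene_plants = plant_snps(config, ref, models, rng, de_genes=de_genes)
    truth = SimTruth(
        sites=sites,
        genes=[
            GeneTruth(
                gene_id=g,
                planted_nonsyn=n,
                planted_syn=s,
                selection_class=cls,
                is_de=False,
                fold_change=1.0,
            )
            for g, n, s, cls in gene_plants
        ],
    )
    by_pos = {s.pos: s for s in sites}
    positions: list[int] = []
    if emit_monomorphic:
        seen: set[int] = set()
        for m in models:
            lo, hi = m.span
            for p in range(lo, hi + 1):
                if p not in seen:
                    seen.add(p)
                    positions.append(p)
        positions.sort()
    else:
        positions = sorted(by_pos)

    contig_seq = ref["chr1"]
    cols_s0: list[PileupColumn] = []
    cols_s1: list[PileupColumn] = []
    depths0 = _draw_depth(rng, config, len(positions))
    depths1 = _draw_depth(rng, config, len(positions))
    for i, pos in enumerate(positions):
        ref_base = contig_seq[pos - 1]
        site = by_pos.get(pos)
        if site is None:
            cols_s0.append(
                _emit_column(rng, config, "chr1", pos, ref_base, None, 0.0, int(depths0[i]))
            )
            cols_s1.append(
                _emit_column(rng, config, "chr1", pos, ref_base, None, 0.0, int(depths1[i]))
            )
        else:
            cols_s0.append(
                _emit_column(
                    rng, config, "chr1", pos, ref_base, site.alt_allele,
                    site.frac_s0, int(depths0[i]),
                )
            )
            cols_s1.append(
                _emit_column(
                    rng, config, "chr1", pos, ref_base, site.alt_allele,
                    site.frac_s1, int(depths1[i]),
                )
            )
    return cols_s0, cols_s1, truth


# ---------------------------------------------------------------------------
# count matrices


def simulate_counts(
    config: SimConfig,
    models: list[CdsModel],
    rng: np.random.Generator | None = None,
    de_genes: dict[str, float] | None = None,
) -> tuple[CountMatrix, SimTruth]:
    """Per-gene counts for the two treatments' replicate libraries.

    Counts are negative-binomial around library-size-scaled means; truth-DE
    genes get the configured fold-change applied to the stress libraries.
    If ``de_genes`` (gene -> fold) is not supplied, a random
    ``fraction_de_genes`` subset is chosen, half up- and half down-regulated.
    """
    if rng is None:
        rng = np.random.default_rng(config.rng_seed + 2)
    gene_ids = [m.gene_id for m in models]
    if de_genes is None:
        n_de = int(round(config.fraction_de_genes * len(gene_ids)))
        chosen = rng.choice(len(gene_ids), size=n_de, replace=False)
        de_genes = {}
        for j, idx in enumerate(sorted(int(i) for i in chosen)):
            fc = config.de_fold_change if j % 2 == 0 else 1.0 / config.de_fold_change
            de_genes[gene_ids[idx]] = fc

    base_mean = config.count_mean * rng.lognormal(0.0, 0.8, size=len(gene_ids))
    n_lib = config.n_libraries_per_treatment
    libs = [f"C1_{i+1}" for i in range(n_lib)] + [f"S1_{i+1}" for i in range(n_lib)]
    size_factors = rng.uniform(0.8, 1.2, size=2 * n_lib)

    disp = config.count_dispersion
    r = 1.0 / disp if disp > 0 else None
    data = np.zeros((len(gene_ids), 2 * n_lib), dtype=int)
    for gi, gene in enumerate(gene_ids):
        fc = de_genes.get(gene, 1.0)
        for li, lib in enumerate(libs):
            mu = base_mean[gi] * size_factors[li]
            if lib.startswith("S1"):
                mu *= fc
            if r is None:
                data[gi, li] = rng.poisson(mu)
            else:
                p = r / (r + mu)
                data[gi, li] = rng.negative_binomial(r, p)

    matrix = CountMatrix(
        counts=pd.DataFrame(data, index=gene_ids, columns=libs),
        treatments={lib: ("C1" if lib.startswith("C1") else "S1") for lib in libs},
    )
    truth = SimTruth(
        genes=[
            GeneTruth(
                gene_id=g,
                planted_nonsyn=0,
                planted_syn=0,
                selection_class="none",
                is_de=g in de_genes,
                fold_change=de_genes.get(g, 1.0),
            )
            for g in gene_ids
        ]
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# full study + writers


def simulate_category_map(
    config: SimConfig,
    models: list[CdsModel],
    rng: np.random.Generator,
    n_categories: int = 8,
) -> dict[str, list[str]]:
    """Random many-to-many gene -> category assignments."""
    cats = [f"CAT:{i:04d}" for i in range(n_categories)]
    cmap: dict[str, list[str]] = {}
    for m in models:
        k = int(rng.integers(0, 3))
        if k:
            chosen = rng.choice(n_categories, size=k, replace=False)
            cmap[m.gene_id] = [cats[int(c)] for c in sorted(chosen)]
    return cmap


def write_truth(truth: SimTruth, sites_path, genes_path) -> None:
    pd.DataFrame([asdict(s) for s in truth.sites]).to_csv(
        sites_path, sep="\t", index=False
    )
    pd.DataFrame([asdict(g) for g in truth.genes]).to_csv(
        genes_path, sep="\t", index=False
    )


def read_truth(sites_path, genes_path) -> SimTruth:
    sites_df = pd.read_csv(sites_path, sep="\t")
    genes_df = pd.read_csv(genes_path, sep="\t")
    sites = [
        SiteTruth(
            contig=str(r.contig),
            pos=int(r.pos),
            gene_id=None if pd.isna(r.gene_id) else str(r.gene_id),
            ref_allele=str(r.ref_allele),
            alt_allele=str(r.alt_allele),
            frac_s0=float(r.frac_s0),
            frac_s1=float(r.frac_s1),
            is_dae=bool(r.is_dae),
            region=str(r.region),
            effect="" if pd.isna(r.effect) else str(r.effect),
        )
        for r in sites_df.itertuples()
    ]
    genes = [
        GeneTruth(
            gene_id=str(r.gene_id),
            planted_nonsyn=int(r.planted_nonsyn),
            planted_syn=int(r.planted_syn),
            selection_class=str(r.selection_class),
            is_de=bool(r.is_de),
            fold_change=float(r.fold_change),
        )
        for r in genes_df.itertuples()
    ]
    return SimTruth(sites=sites, genes=genes)


def simulate_study(config: SimConfig, outdir: str | Path) -> dict:
    """Generate a complete study on disk and return the manifest.

    Emits FASTA, GFF3, two pileups, a count matrix + treatment map, a
    category map, truth tables and a JSON manifest recording the config and
    seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.rng_seed)

    ref, models = simulate_reference(config)

    # decide DE truth first so DAE placement can honour dae_only_in_de_genes
    counts, counts_truth = simulate_counts(config, models, rng=rng)
    de_fold = {g.gene_id: g.fold_change for g in counts_truth.genes if g.is_de}
    cols_s0, cols_s1, pool_truth = simulate_pools(
        config, ref, models, rng=rng, de_genes=set(de_fold)
    )
    truth = SimTruth(
        sites=pool_truth.sites,
        genes=[
            GeneTruth(
                gene_id=pg.gene_id,
                planted_nonsyn=pg.planted_nonsyn,
                planted_syn=pg.planted_syn,
                selection_class=pg.selection_class,
                is_de=pg.gene_id in de_fold,
                fold_change=de_fold.get(pg.gene_id, 1.0),
            )
            for pg in pool_truth.genes
        ],
    )
    cmap = simulate_category_map(config, models, rng)

    files = {
        "reference": "reference.fasta",
        "annotation": "annotation.gff3",
        "pileup_s0": "pool_S0.pileup",
        "pileup_s1": "pool_S1.pileup",
        "counts": "counts.tsv",
        "treatments": "treatments.tsv",
        "category_map": "categories.tsv",
        "truth_sites": "truth_sites.tsv",
        "truth_genes": "truth_genes.tsv",
    }
    write_fasta(ref, outdir / files["reference"])
    write_gff3_cds(models, outdir / files["annotation"])
    write_pileup(cols_s0, outdir / files["pileup_s0"])
    write_pileup(cols_s1, outdir / files["pileup_s1"])
    write_count_matrix(counts, outdir / files["counts"], outdir / files["treatments"])
    from .enrichment import write_category_map

    write_category_map(cmap, outdir / files["category_map"])
    write_truth(truth, outdir / files["truth_sites"], outdir / files["truth_genes"])

    manifest = {
        "config": asdict(config),
        "rng_seed": config.rng_seed,
        "files": files,
        "n_sites": len(truth.sites),
        "n_dae_sites": len(truth.dae_sites()),
        "n_genes": len(models),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
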