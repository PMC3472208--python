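"""End-to-end orchestration: pileups in, per-stage TSVs and a manifest out.

Stages
------
snp     pool-wise SNP calling and cross-pool pairing (DAE profile)
dae     chi-squared differential allelic expression with BH-FDR
kaks    combined-pool SNP calling (selection profile), codon annotation,
        weighted site lengths and per-gene pseudocounted Ka/Ks
de      Fisher-exact differential expression over the count matrix
enrich  category over-representation for the standard gene-set contrasts
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import codon_sites, dae, de, pool_counts
from . import enrichment as enrich_mod
from .io_formats import CdsModel, GenomeRef, read_fasta, read_gff3_cds, read_pileup
from .selection import gene_kaks, round_half_up, summarize_kaks

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a pipeline run.

    Threshold defaults are the emulated study's: SNP calling at coverage 8,
    base quality 20, frequency 0.01, p 0.05; DAE pairing at depth 20 per
    pool with FDR 0.05; the selection branch at coverage 20–8000 with minor
    count 4; transversion penalty 6; selection classes split at 0.5/1.5
    with a 0.20 strong-purifying cutoff; DE at FDR 0.01.
    """

    ref_path: str = ""
    gff3_path: str = ""
    pileup_s0_path: str = ""
    pileup_s1_path: str = ""
    counts_path: str = ""
    treatments_path: str = ""
    category_map_path: str = ""
    out_dir: str = "poolstress_out"

    min_coverage: int = 8
    min_quality: int = 20
    min_freq: float = 0.01
    snp_alpha: float = 0.05
    snp_error_rate: float = 0.01
    dae_min_minor_count: int = 2
    dae_min_depth: int = 20
    dae_fdr: float = 0.05
    yates: bool = False
    kaks_min_coverage: int = 20
    kaks_max_coverage: int = 8000
    kaks_min_count: int = 4
    transversion_penalty: float = 6.0
    purifying_cutoff: float = 0.5
    positive_cutoff: float = 1.5
    strong_purifying_cutoff: float = 0.20
    de_fdr: float = 0.01
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_coverage", "min_quality", "min_freq", "snp_alpha",
            "dae_min_depth", "kaks_min_count", "kaks_max_coverage",
            "transversion_penalty", "purifying_cutoff", "positive_cutoff",
            "strong_purifying_cutoff", "de_fdr", "dae_fdr",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.purifying_cutoff >= self.positive_cutoff:
            raise ValueError("purifying_cutoff must be below positive_cutoff")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    snp_tables: list[pool_counts.AlleleTable2x2] = field(default_factory=list)
    dae_results: list[dae.DaeResult] = field(default_factory=list)
    kaks_results: list = field(default_factory=list)
    de_results: list[de.DeResult] = field(default_factory=list)
    enrichments: dict[str, list[enrich_mod.EnrichmentResult]] = field(default_factory=dict)
    concordance: dae.ConcordanceSummary | None = None
    manifest: dict = field(default_factory=dict)


def _count_pool(path: str, min_quality: int) -> dict[tuple[str, int], pool_counts.SiteAlleleCounts]:
    return {
        (col.contig, col.pos): pool_counts.count_alleles(col, min_quality)
        for col in read_pileup(path)
    }


def _assign_gene(models: list[CdsModel], contig: str, pos: int) -> tuple[str | None, str]:
    """Host gene and region label for a SNP (first containing model wins ties)."""
    for m in models:
        if m.contig != contig:
            continue
        label = codon_sites.locate_snp(m, pos)
        if label == "coding":
            return m.gene_id, "coding"
        if label == "intronic":
            return m.gene_id, "intronic"
    return None, "noncoding"


def run_snp_stage(
    config: PipelineConfig,
    sites_s0: dict,
    sites_s1: dict,
) -> list[pool_counts.AlleleTable2x2]:
    def _call(sites):
        out = []
        for site in sites.values():
            call = pool_counts.call_snp(
                site,
                min_coverage=config.min_coverage,
                min_freq=config.min_freq,
                min_minor_count=config.dae_min_minor_count,
                alpha=config.snp_alpha,
                error_rate=config.snp_error_rate,
            )
            if call is not None:
                out.append(call)
        return out

    calls_s0, calls_s1 = _call(sites_s0), _call(sites_s1)
    logger.info("SNP stage: %d calls in S0, %d in S1", len(calls_s0), len(calls_s1))
    return pool_counts.pair_pools(
        calls_s0, calls_s1, sites_s0, sites_s1,
        min_depth_per_pool=config.dae_min_depth,
    )


def run_dae_stage(
    config: PipelineConfig,
    tables: list[pool_counts.AlleleTable2x2],
    ref: GenomeRef,
    models: list[CdsModel],
) -> list[dae.DaeResult]:
    results = dae.test_dae(tables, alpha=config.dae_fdr, yates=config.yates)
    annotated = []
    by_model = {m.gene_id: m for m in models}
    for r in results:
        contig, pos = r.snp_id.split(":")
        gene_id, region = _assign_gene(models, contig, int(pos))
        effect = region
        sub_class = "unknown"
        if gene_id is not None and region == "coding":
            coding = codon_sites.annotate_snp(
                by_model[gene_id], ref, int(pos), r.allele_a, r.allele_b
            ) if ref[contig][int(pos) - 1] == r.allele_a else codon_sites.annotate_snp(
                by_model[gene_id], ref, int(pos), r.allele_b, r.allele_a
            )
            if coding is not None:
                effect = coding.effect
                sub_class = coding.substitution_class
        elif r.allele_a != r.allele_b:
            sub_class = codon_sites.classify_substitution(r.allele_a, r.allele_b)
        annotated.append(
            dataclasses.replace(r, gene_id=gene_id, effect=effect,
                                substitution_class=sub_class)
        )
    return annotated


def run_kaks_stage(
    config: PipelineConfig,
    sites_s0: dict,
    sites_s1: dict,
    ref: GenomeRef,
    models: list[CdsModel],
) -> list:
    """Selection branch: reads of both pools combined, stricter calling."""
    merged = pool_counts.merge_site_counts(sites_s0, sites_s1)
    by_gene_counts: dict[str, dict[str, int]] = {
        m.gene_id: {"nonsynonymous": 0, "synonymous": 0} for m in models
    }
    for (contig, pos), site in merged.items():
        call = pool_counts.call_snp(
            site,
            min_coverage=config.kaks_min_coverage,
            min_freq=config.min_freq,
            min_minor_count=config.kaks_min_count,
            alpha=config.snp_alpha,
            error_rate=config.snp_error_rate,
            max_coverage=config.kaks_max_coverage,
        )
        if call is None:
            continue
        ref_base = ref[contig][pos - 1]
        alleles = {call.major_allele, call.minor_allele}
        if ref_base not in alleles:
            continue  # neither allele matches the reference: unplaceable
        alt = next(a for a in alleles if a != ref_base) if len(alleles) == 2 else None
        if alt is None:
            continue
        for m in models:
            if m.contig == contig and m.contains(pos):
                coding = codon_sites.annotate_snp(m, ref, pos, ref_base, alt)
                if coding is not None:
                    by_gene_counts[m.gene_id][coding.effect] += 1
                break

    results = []
    for m in models:
        lengths = codon_sites.gene_site_lengths(m, ref, config.transversion_penalty)
        counts = by_gene_counts[m.gene_id]
        results.append(
            gene_kaks(
                m.gene_id,
                counts["nonsynonymous"],
                counts["synonymous"],
                lengths.nonsyn_length,
                lengths.syn_length,
                purifying_cutoff=config.purifying_cutoff,
                positive_cutoff=config.positive_cutoff,
            )
        )
    return results


def run_pipeline(config: PipelineConfig, stages: set[str] | None = None) -> PipelineResult:
    """Run the requested stages (all by default) and write their TSVs.

    Writes one TSV per stage to ``config.out_dir`` plus a JSON manifest
    recording the config hash, seed and per-table row counts.
    """
    all_stages = {"snp", "dae", "kaks", "de", "enrich"}
    stages = set(stages) if stages else all_stages
    unknown = stages - all_stages
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult()
    timers: dict[str, float] = {}

    need_pileups = stages & {"snp", "dae", "kaks"}
    ref = models = None
    sites_s0 = sites_s1 = None
    if need_pileups:
        ref = read_fasta(config.ref_path)
        models = read_gff3_cds(config.gff3_path, ref)
        t0 = time.perf_counter()
        sites_s0 = _count_pool(config.pileup_s0_path, config.min_quality)
        sites_s1 = _count_pool(config.pileup_s1_path, config.min_quality)
        timers["count"] = time.perf_counter() - t0

    if stages & {"snp", "dae"}:
        t0 = time.perf_counter()
        result.snp_tables = run_snp_stage(config, sites_s0, sites_s1)
        timers["snp"] = time.perf_counter() - t0
        pd.DataFrame(
            [
                {
                    "snp_id": t.snp_id, "allele_a": t.allele_a, "allele_b": t.allele_b,
                    "a_s0": t.a_s0, "b_s0": t.b_s0, "a_s1": t.a_s1, "b_s1": t.b_s1,
                }
                for t in result.snp_tables
            ]
        ).to_csv(outdir / "snp_tables.tsv", sep="\t", index=False)

    if "dae" in stages:
        t0 = time.perf_counter()
        result.dae_results = run_dae_stage(config, result.snp_tables, ref, models)
        timers["dae"] = time.perf_counter() - t0
        pd.DataFrame(
            [
                {
                    "snp_id": r.snp_id, "gene_id": r.gene_id,
                    "allele_a": r.allele_a, "allele_b": r.allele_b,
                    "a_s0": r.a_s0, "b_s0": r.b_s0,
                    "freq_s0": round_half_up(r.freq_s0, 2),
                    "a_s1": r.a_s1, "b_s1": r.b_s1,
                    "freq_s1": round_half_up(r.freq_s1, 2),
                    "chi2": r.chi2, "p_value": r.p_value, "q_value": r.q_value,
                    "significant": r.significant, "effect": r.effect,
                    "substitution_class": r.substitution_class,
                }
                for r in result.dae_results
            ]
        ).to_csv(outdir / "dae_results.tsv", sep="\t", index=False)

    if "kaks" in stages:
        t0 = time.perf_counter()
        result.kaks_results = run_kaks_stage(config, sites_s0, sites_s1, ref, models)
        timers["kaks"] = time.perf_counter() - t0
        pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "nonsyn_length": round_half_up(g.nonsyn_length, 1),
                    "syn_length": round_half_up(g.syn_length, 1),
                    "nonsyn": g.nonsyn, "syn": g.syn,
                    "kaks": g.ratio_1dp, "kaks_full": g.ratio,
                    "selection_class": g.selection_class,
                }
                for g in result.kaks_results
            ]
        ).to_csv(outdir / "kaks_results.tsv", sep="\t", index=False)

    if "de" in stages or "enrich" in stages:
        matrix = de.read_count_matrix(config.counts_path, config.treatments_path)
        matrix = de.filter_low_counts(matrix)
        t0 = time.perf_counter()
        result.de_results = de.de_test(matrix, "S1", "C1", fdr=config.de_fdr)
        timers["de"] = time.perf_counter() - t0
        pd.DataFrame([asdict(r) for r in result.de_results]).to_csv(
            outdir / "de_results.tsv", sep="\t", index=False
        )

    if "enrich" in stages:
        cmap = enrich_mod.read_category_map(config.category_map_path)
        background = {r.gene_id for r in result.de_results}
        gene_sets = enrich_mod.select_gene_sets(
            kaks_results=result.kaks_results,
            de_results=result.de_results,
            dae_results=result.dae_results,
            positive_cutoff=config.positive_cutoff,
            strong_purifying_cutoff=config.strong_purifying_cutoff,
        )
        rows = []
        for name, subset in gene_sets.items():
            subset = subset & background
            if not subset:
                continue
            for er in enrich_mod.enrich(subset, background, cmap):
                rows.append({"gene_set": name, **asdict(er)})
                result.enrichments.setdefault(name, []).append(er)
        pd.DataFrame(rows).to_csv(outdir / "enrichment.tsv", sep="\t", index=False)

    if "dae" in stages and result.de_results:
        de_sig = {r.gene_id: r.log_fc for r in result.de_results if r.significant}
        result.concordance = dae.dae_de_concordance(result.dae_results, de_sig)

    if "kaks" in stages and result.kaks_results:
        summary = summarize_kaks(result.kaks_results)
        with open(outdir / "kaks_summary.json", "w") as fh:
            json.dump(asdict(summary), fh, indent=2)

    result.manifest = {
        "config_hash": config.config_hash(),
        "rng_seed": config.rng_seed,
        "stages": sorted(stages),
        "timers_s": {k: round(v, 3) for k, v in timers.items()},
        "rows": {
            "snp_tables": len(result.snp_tables),
            "dae_results": len(result.dae_results),
            "kaks_results": len(result.kaks_results),
            "de_results": len(result.de_results),
        },
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2)
    return result
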