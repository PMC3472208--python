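import filecmp

import numpy as np
import pytest
from Bio.Seq import Seq

from poolstress.codon_sites import extract_cds
from poolstress.synthetic_data import (
    SimConfig,
    plant_snps,
    read_truth,
    simulate_counts,
    simulate_pools,
    simulate_reference,
    simulate_study,
)


class TestConfigValidation:
    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SimConfig(base_error_rate=1.5)

    def test_bad_class_mix(self):
        with pytest.raises(ValueError):
            SimConfig(class_mix=(0.5, 0.2, 0.2))

    def test_bad_freq_bounds(self):
        with pytest.raises(ValueError):
            SimConfig(allele_freq_bounds=(0.9, 0.1))


class TestSimulateReference:
    def test_single_small_gene(self):
        config = SimConfig(n_genes=1, mean_cds_codons=10, rng_seed=0)
        ref, models = simulate_reference(config)
        (m,) = models
        cds = extract_cds(ref, m)
        assert cds.startswith("ATG")
        assert len(cds) % 3 == 0

    def test_deterministic_under_seed(self):
        c = SimConfig(n_genes=8, rng_seed=42)
        ref1, m1 = simulate_reference(c)
        ref2, m2 = simulate_reference(c)
        assert ref1.contigs == ref2.contigs and m1 == m2

    def test_fifty_genes_valid_and_non_overlapping(self):
        config = SimConfig(n_genes=50, mean_cds_codons=60, rng_seed=1)
        ref, models = simulate_reference(config)
        assert len(models) == 50
        spans = sorted(m.span for m in models)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 < s2  # interval-overlap check
        strands = [m.strand for m in models]
        assert strands.count("-") >= 0.2 * len(models)
        assert sum(len(m.segments) > 1 for m in models) >= 0.2 * len(models)
        for m in models:
            protein = str(Seq(extract_cds(ref, m)).translate())
            assert "*" not in protein[:-1]  # no internal stops


class TestSimulatePools:
    def test_null_config_has_identical_fractions(self):
        config = SimConfig(n_genes=6, fraction_dae_sites=0.0, rng_seed=2)
        ref, models = simulate_reference(config)
        _s0, _s1, truth = simulate_pools(config, ref, models, emit_monomorphic=False)
        assert truth.sites
        for s in truth.sites:
            assert s.frac_s0 == s.frac_s1 and not s.is_dae

    def test_observed_shift_matches_dae_effect(self):
        """Monte-Carlo: at high depth the mean observed frequency shift at
        DAE sites approaches the configured effect."""
        config = SimConfig(
            n_genes=40,
            mean_cds_codons=120,
            plant_selection_classes=False,
            coding_snp_density_per_kb=80.0,
            snp_density_per_kb=0.0,
            fraction_dae_sites=1.0,
            dae_effect=0.3,
            depth_mean=500.0,
            min_depth=200,
            base_error_rate=0.0,
            frac_low_quality=0.0,
            rng_seed=3,
        )
        ref, models = simulate_reference(config)
        cols_s0, cols_s1, truth = simulate_pools(
            config, ref, models, emit_monomorphic=False
        )
        assert len(truth.sites) >= 1000
        by0 = {c.pos: c for c in cols_s0}
        by1 = {c.pos: c for c in cols_s1}
        shifts = []
        for s in truth.sites:
            f0 = by0[s.pos].calls.count(s.alt_allele) / len(by0[s.pos].calls)
            f1 = by1[s.pos].calls.count(s.alt_allele) / len(by1[s.pos].calls)
            shifts.append(abs(f1 - f0))
        assert np.mean(shifts) == pytest.approx(0.3, abs=0.01)

    def test_error_free_monomorphic_sites_pure(self):
        config = SimConfig(
            n_genes=3, base_error_rate=0.0, fraction_dae_sites=0.0, rng_seed=4
        )
        ref, models = simulate_reference(config)
        cols_s0, _s1, truth = simulate_pools(config, ref, models)
        seg = {s.pos for s in truth.sites}
        for col in cols_s0:
            if col.pos not in seg:
                assert set(col.calls) == {col.ref_base}

    def test_truth_sites_covered_in_both_pools(self):
        config = SimConfig(n_genes=6, depth_mean=2.0, min_depth=1, rng_seed=5)
        ref, models = simulate_reference(config)
        cols_s0, cols_s1, truth = simulate_pools(config, ref, models)
        pos0 = {c.pos: len(c.calls) for c in cols_s0}
        pos1 = {c.pos: len(c.calls) for c in cols_s1}
        for s in truth.sites:
            assert pos0[s.pos] > 0 and pos1[s.pos] > 0


class TestPlantedSelectionClasses:
    def test_planted_counts_give_target_class(self, rng):
        from poolstress.codon_sites import gene_site_lengths
        from poolstress.selection import gene_kaks

        config = SimConfig(n_genes=20, rng_seed=6)
        ref, models = simulate_reference(config)
        sites, plants = plant_snps(config, ref, models, rng)
        by_gene = {g: (n, s, cls) for g, n, s, cls in plants}
        for m in models:
            n, s, cls = by_gene[m.gene_id]
            lengths = gene_site_lengths(m, ref)
            g = gene_kaks(m.gene_id, n, s, lengths.nonsyn_length, lengths.syn_length)
            assert g.selection_class == cls
        # planted site effects match their labels, one SNP max per codon
        per_gene = {}
        for site in sites:
            if site.region == "coding":
                per_gene.setdefault(site.gene_id, []).append(site)
        for m in models:
            n, s, _cls = by_gene[m.gene_id]
            planted = per_gene.get(m.gene_id, [])
            assert sum(x.effect == "nonsynonymous" for x in planted) == n
            assert sum(x.effect == "synonymous" for x in planted) == s


class TestSimulateCounts:
    def test_no_de_truth_when_fold_one(self):
        config = SimConfig(n_genes=10, fraction_de_genes=0.0, rng_seed=7)
        _ref, models = simulate_reference(config)
        _m, truth = simulate_counts(config, models)
        assert not any(g.is_de for g in truth.genes)

    def test_three_libraries_per_treatment(self):
        config = SimConfig(n_genes=5, rng_seed=8)
        _ref, models = simulate_reference(config)
        matrix, _truth = simulate_counts(config, models)
        assert len(matrix.libraries("C1")) == 3
        assert len(matrix.libraries("S1")) == 3

    def test_fold_change_recovered_in_means(self):
        """Monte-Carlo over replicate draws of the same DE gene."""
        config = SimConfig(
            n_genes=200, fraction_de_genes=1.0, de_fold_change=8.0,
            count_dispersion=0.05, count_mean=2000.0, rng_seed=9,
        )
        _ref, models = simulate_reference(SimConfig(n_genes=200, rng_seed=9))
        matrix, truth = simulate_counts(
            config, models, de_genes={m.gene_id: 8.0 for m in models}
        )
        ratios = (
            matrix.counts[matrix.libraries("S1")].mean(axis=1)
            / matrix.counts[matrix.libraries("C1")].mean(axis=1)
        )
        assert np.median(ratios) == pytest.approx(8.0, rel=0.15)


class TestStudyDeterminism:
    def test_bit_identical_files_under_fixed_seed(self, tmp_path):
        config = SimConfig(n_genes=5, mean_cds_codons=40, rng_seed=10)
        man1 = simulate_study(config, tmp_path / "a")
        man2 = simulate_study(config, tmp_path / "b")
        assert man1["n_sites"] == man2["n_sites"]
        for name in man1["files"].values():
            assert filecmp.cmp(
                tmp_path / "a" / name, tmp_path / "b" / name, shallow=False
            ), name

    def test_truth_round_trip(self, sim_study):
        _config, outdir, manifest = sim_study
        truth = read_truth(outdir / "truth_sites.tsv", outdir / "truth_genes.tsv")
        assert len(truth.sites) == manifest["n_sites"]
        assert len(truth.genes) == manifest["n_genes"]

    def test_dae_restricted_to_de_genes_when_configured(self):
        config = SimConfig(
            n_genes=12, fraction_dae_sites=0.3, dae_only_in_de_genes=True,
            fraction_de_genes=0.3, rng_seed=12,
        )
        ref, models = simulate_reference(config)
        de_genes = {m.gene_id for m in models[:4]}
        _s0, _s1, truth = simulate_pools(
            config, ref, models, de_genes=de_genes, emit_monomorphic=False
        )
        dae_hosts = {s.gene_id for s in truth.dae_sites()}
        assert dae_hosts and dae_hosts <= de_genes
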