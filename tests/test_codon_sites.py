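"""Codon mapping, substitution classes and weighted site lengths.

The brute-force oracles here use Biopython's translation, independent of
the module's own genetic-code table.
"""

import itertools

import pytest
from Bio.Seq import Seq

from poolstress.codon_sites import (
    GENETIC_CODE,
    annotate_snp,
    classify_substitution,
    codon_site_lengths,
    extract_cds,
    gene_site_lengths,
    genomic_to_cds_offset,
    reverse_complement,
)
from poolstress.io_formats import CdsModel, GenomeRef

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]


def oracle_site_lengths(codon: str, penalty: float) -> float:
    """Independent enumeration of the weighted nonsynonymous length."""
    aa = str(Seq(codon).translate())
    total = 0.0
    for pos in range(3):
        w_non = w_all = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            transition = {codon[pos], alt} in ({"A", "G"}, {"C", "T"})
            w = 1.0 if transition else 1.0 / penalty
            w_all += w
            mutated = codon[:pos] + alt + codon[pos + 1 :]
            if str(Seq(mutated).translate()) != aa:
                w_non += w
        total += w_non / w_all
    return total


class TestGeneticCode:
    def test_matches_biopython_for_all_codons(self):
        for codon in ALL_CODONS:
            assert GENETIC_CODE[codon] == str(Seq(codon).translate())


class TestClassifySubstitution:
    def test_exhaustive_four_transitions_eight_transversions(self):
        pairs = [(a, b) for a in "ACGT" for b in "ACGT" if a != b]
        classes = [classify_substitution(a, b) for a, b in pairs]
        assert classes.count("transition") == 4
        assert classes.count("transversion") == 8
        assert classify_substitution("A", "G") == "transition"
        assert classify_substitution("A", "T") == "transversion"

    def test_identical_alleles_error(self):
        with pytest.raises(ValueError):
            classify_substitution("A", "A")


class TestExtractCds:
    def test_plus_strand_single_segment(self):
        ref = GenomeRef({"c": "ATGAAATTTCCC"})
        model = CdsModel("g", "c", "+", ((1, 6),), 0)
        assert extract_cds(ref, model) == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        ref = GenomeRef({"c": "ATGAAA"})
        model = CdsModel("g", "c", "-", ((1, 6),), 0)
        assert extract_cds(ref, model) == "TTTCAT"

    def test_phase_trims_five_prime_bases(self):
        ref = GenomeRef({"c": "GATGAAACC"})
        model = CdsModel("g", "c", "+", ((1, 7),), 1)
        assert extract_cds(ref, model) == "ATGAAA"

    def test_multi_segment_minus(self, small_ref):
        genome, models = small_ref
        gminus = next(m for m in models if m.gene_id == "gminus")
        assert extract_cds(genome, gminus) == "ATGCCTGAA"


class TestAnnotateSnp:
    def _single_gene(self):
        ref = GenomeRef({"c": "ATGTTTGGA"})
        return ref, CdsModel("g", "c", "+", ((1, 9),), 0)

    def test_synonymous_third_position(self):
        ref, model = self._single_gene()
        snp = annotate_snp(model, ref, 6, "T", "C")  # TTT -> TTC, Phe/Phe
        assert snp.effect == "synonymous"
        assert snp.codon_index == 1 and snp.codon_pos == 2
        assert snp.substitution_class == "transition"

    def test_nonsynonymous_first_position(self):
        ref, model = self._single_gene()
        snp = annotate_snp(model, ref, 4, "T", "G")  # TTT -> GTT, Phe->Val
        assert snp.effect == "nonsynonymous"

    def test_minus_strand_alleles_complemented(self, small_ref):
        genome, models = small_ref
        gminus = next(m for m in models if m.gene_id == "gminus")
        # genomic pos 31 is the 'A' of revcomp(exon1)="GGCAT"; CDS offset 1
        # (codon ATG pos 1): genomic A->G is CDS T->C, ATG->ACG, Met->Thr
        snp = annotate_snp(gminus, genome, 31, "A", "G")
        assert snp.cds_offset == 1
        assert (snp.ref_codon, snp.alt_codon) == ("ATG", "ACG")
        assert snp.effect == "nonsynonymous"

    def test_noncoding_returns_none(self, small_ref):
        genome, models = small_ref
        gminus = next(m for m in models if m.gene_id == "gminus")
        assert annotate_snp(gminus, genome, 25, "G", "A") is None  # intron

    def test_ref_mismatch_is_error(self):
        ref, model = self._single_gene()
        with pytest.raises(ValueError, match="does not match"):
            annotate_snp(model, ref, 4, "A", "G")

    def test_agrees_with_full_protein_comparison(self, sim_study):
        """Brute-force oracle: for simulated coding SNPs, mutate the whole
        genome, re-extract and translate both CDS versions with Biopython,
        and compare proteins."""
        from poolstress.io_formats import read_fasta, read_gff3_cds
        from poolstress.synthetic_data import read_truth

        _config, outdir, _manifest = sim_study
        ref = read_fasta(outdir / "reference.fasta")
        models = {m.gene_id: m for m in read_gff3_cds(outdir / "annotation.gff3")}
        truth = read_truth(outdir / "truth_sites.tsv", outdir / "truth_genes.tsv")
        coding = [s for s in truth.sites if s.region == "coding"]
        assert coding, "study should contain coding truth SNPs"
        for site in coding:
            model = models[site.gene_id]
            snp = annotate_snp(model, ref, site.pos, site.ref_allele, site.alt_allele)
            assert snp is not None
            mutated = dict(ref.contigs)
            seq = mutated[site.contig]
            mutated[site.contig] = (
                seq[: site.pos - 1] + site.alt_allele + seq[site.pos :]
            )
            alt_ref = GenomeRef(mutated)
            prot_ref = str(Seq(extract_cds(ref, model)).translate())
            prot_alt = str(Seq(extract_cds(alt_ref, model)).translate())
            oracle_effect = (
                "synonymous" if prot_ref == prot_alt else "nonsynonymous"
            )
            assert snp.effect == oracle_effect, site
            assert snp.effect == site.effect


class TestCodonSiteLengths:
    @pytest.mark.parametrize(
        "codon,nonsyn",
        [
            ("ATG", 3.0),  # Met: every change is nonsynonymous
            ("GGT", 2.0),  # fourfold-degenerate third position
            ("TTT", 2.25),  # third position: transition syn, transversions nonsyn
        ],
    )
    def test_worked_examples(self, codon, nonsyn):
        res = codon_site_lengths(codon, 6.0)
        assert res.nonsyn_length == pytest.approx(nonsyn)
        assert res.syn_length == pytest.approx(3.0 - nonsyn)

    @pytest.mark.parametrize("penalty", [1.0, 3.0, 6.0])
    def test_oracle_equivalence_all_codons(self, penalty):
        for codon in ALL_CODONS:
            res = codon_site_lengths(codon, penalty)
            assert res.nonsyn_length == pytest.approx(
                oracle_site_lengths(codon, penalty), abs=1e-12
            )
            assert res.nonsyn_length + res.syn_length == 3.0  # exact

    def test_penalty_one_is_unweighted_nei_gojobori(self):
        """With no transversion penalty the lengths are plain fractions of
        nonsynonymous changes: n/9 of the codon's 9 single-base changes,
        position by position."""
        for codon in ALL_CODONS:
            aa = str(Seq(codon).translate())
            frac = 0.0
            for pos in range(3):
                n_non = sum(
                    str(
                        Seq(codon[:pos] + alt + codon[pos + 1 :]).translate()
                    ) != aa
                    for alt in "ACGT"
                    if alt != codon[pos]
                )
                frac += n_non / 3
            assert codon_site_lengths(codon, 1.0).nonsyn_length == pytest.approx(frac)

    def test_rejects_n_and_bad_penalty(self):
        with pytest.raises(ValueError):
            codon_site_lengths("ATN")
        with pytest.raises(ValueError):
            codon_site_lengths("ATG", 0.0)


class TestGeneSiteLengths:
    def test_simple_gene(self):
        ref = GenomeRef({"c": "ATGATG"})
        model = CdsModel("g", "c", "+", ((1, 6),), 0)
        res = gene_site_lengths(model, ref)
        assert res.nonsyn_length == pytest.approx(6.0)
        assert res.syn_length == pytest.approx(0.0)

    def test_terminal_stop_excluded(self):
        ref = GenomeRef({"c": "ATGATGTAA"})
        model = CdsModel("g", "c", "+", ((1, 9),), 0)
        assert gene_site_lengths(model, ref).n_codons == 2

    def test_equals_sum_of_per_codon_oracle(self, rng):
        codons = [ALL_CODONS[i] for i in rng.integers(0, 64, size=100)]
        cds = "".join(codons)
        ref = GenomeRef({"c": cds})
        model = CdsModel("g", "c", "+", ((1, len(cds)),), 0)
        res = gene_site_lengths(model, ref, 6.0)
        analysed = codons[:-1] if codons[-1] in ("TAA", "TAG", "TGA") else codons
        expected = sum(oracle_site_lengths(c, 6.0) for c in analysed)
        assert res.nonsyn_length == pytest.approx(expected)
        assert res.nonsyn_length + res.syn_length == pytest.approx(
            3.0 * res.n_codons
        )


class TestOffsetMapping:
    def test_round_trip_all_positions(self, small_ref):
        genome, models = small_ref
        for model in models:
            cds = extract_cds(genome, model)
            seen = {}
            lo, hi = model.span
            for pos in range(lo, hi + 1):
                off = genomic_to_cds_offset(model, pos)
                if off is not None:
                    seen[off] = pos
            assert sorted(seen) == list(range(len(cds)))
            # the mapped base, strand-adjusted, equals the CDS base
            for off, pos in seen.items():
                base = genome[model.contig][pos - 1]
                if model.strand == "-":
                    base = reverse_complement(base)
                assert cds[off] == base
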