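"""Differential expression, gene-set enrichment and DAE/DE concordance.

Requires example_study/ from 01_simulate_study.py.  Runs every stage:
Fisher-exact DE on the count matrix (FDR 0.01), category enrichment of the
standard gene-set contrasts, and the fraction of significant DAE SNPs
hosted by DE-significant genes.
"""

from poolstress import PipelineConfig, run_pipeline

config = PipelineConfig(
    ref_path="example_study/reference.fasta",
    gff3_path="example_study/annotation.gff3",
    pileup_s0_path="example_study/pool_S0.pileup",
    pileup_s1_path="example_study/pool_S1.pileup",
    counts_path="example_study/counts.tsv",
    treatments_path="example_study/treatments.tsv",
    category_map_path="example_study/categories.tsv",
    out_dir="example_out",
)
result = run_pipeline(config)

n_de = sum(r.significant for r in result.de_results)
print(f"DE-significant genes (FDR < 0.01): {n_de} / {len(result.de_results)}")
for name, rows in result.enrichments.items():
    hits = [r for r in rows if r.q_value < 0.05]
    print(f"enrichment [{name}]: {len(hits)} categories at FDR < 0.05")
c = result.concordance
if c is not None and c.n_significant_dae:
    print(
        f"DAE/DE concordance: {c.fraction_concordant:.0%}"
        f" ({c.n_concordant}/{c.n_significant_dae} significant DAE SNPs"
        " sit in DE-significant genes)"
    )
# Concordant SNPs are candidate cis-acting regulatory variants: their
# allelic shift co-occurs with a change in the host gene's total expression.
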