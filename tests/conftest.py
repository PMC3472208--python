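import numpy as np
import pytest

from poolstress import SimConfig, simulate_reference
from poolstress.io_formats import CdsModel, GenomeRef


@pytest.fixture(scope="session")
def small_ref():
    """A tiny hand-built reference with one plus- and one minus-strand gene.

    chr1 layout (1-based):
      5..13  gplus   +  single CDS "ATGTTTGGA" (M F G)
      20..37 gminus  -  two CDS segments; spliced minus-strand CDS "ATGCCTGAA"
    """
    # gplus occupies 5..13
    seq = list("NNNN" + "ATGTTTGGA" + "NNNNNN")
    # gminus: transcript ATG CCT GAA split as ATGCC | TGAA between two exons
    # genomic plus-strand text is revcomp(exon2) + intron + revcomp(exon1)
    exon1, exon2 = "ATGCC", "TGAA"
    intron = "GGGG"
    region = "TTCA" + intron + "GGCAT"  # revcomp(TGAA)+GGGG+revcomp(ATGCC)
    seq += list(region + "NN")
    genome = GenomeRef({"chr1": "".join(seq)})
    gplus = CdsModel("gplus", "chr1", "+", ((5, 13),), 0)
    # region starts at 1-based 20: revcomp(exon2)=20..23, intron 24..27,
    # revcomp(exon1)=28..32
    gminus = CdsModel("gminus", "chr1", "-", ((20, 23), (28, 32)), 0)
    return genome, [gplus, gminus]


@pytest.fixture(scope="session")
def sim_study(tmp_path_factory):
    """One deterministic synthetic study on disk, shared across tests."""
    from poolstress import simulate_study

    outdir = tmp_path_factory.mktemp("study")
    config = SimConfig(n_genes=12, mean_cds_codons=80, rng_seed=11)
    manifest = simulate_study(config, outdir)
    return config, outdir, manifest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
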