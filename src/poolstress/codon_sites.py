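"""Codon-level SNP annotation and weighted synonymous/nonsynonymous site lengths.

A SNP inside a coding segment is mapped to its codon and classified as
synonymous or nonsynonymous under the standard genetic code (translation
table 1; plant nuclear genes).  Per-codon "site lengths" partition each
codon's 3 positions into an expected nonsynonymous and synonymous fraction,
with transversions down-weighted by a configurable penalty: a transition is
given weight 1 and each transversion weight 1/penalty, so with the default
penalty of 6 a transversion contributes one sixth as much as a transition.
At every position the three alternative bases always comprise exactly one
transition and two transversions, which makes the position's nonsynonymous
fraction depend only on the transition:transversion weight ratio.

Changes that create or destroy a stop codon count as nonsynonymous; the
terminal stop codon itself is excluded from gene totals.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from .io_formats import CdsModel, GenomeRef

# Standard genetic code, stop = "*"
GENETIC_CODE: dict[str, str] = {}
_BASES = "TCAG"
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            GENETIC_CODE[_b1 + _b2 + _b3] = _AAS[_i * 16 + _j * 4 + _k]

STOP_CODONS = frozenset(c for c, aa in GENETIC_CODE.items() if aa == "*")

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def translate(cds: str) -> str:
    """Translate an in-frame CDS; codons containing N become 'X'."""
    return "".join(
        GENETIC_CODE.get(cds[i : i + 3], "X") for i in range(0, len(cds) - 2, 3)
    )


def classify_substitution(a: str, b: str) -> str:
    """Classify a base change as ``transition`` (A<->G, C<->T) or ``transversion``."""
    a, b = a.upper(), b.upper()
    if a == b:
        raise ValueError(f"identical alleles {a!r}")
    if a not in "ACGT" or b not in "ACGT":
        raise ValueError(f"alleles must be A/C/G/T, got {a!r}, {b!r}")
    if {a, b} <= PURINES or {a, b} <= PYRIMIDINES:
        return "transition"
    return "transversion"


@dataclass(frozen=True)
class CodingSnp:
    """A SNP mapped into a codon, with its protein-level effect."""

    gene_id: str
    cds_offset: int  # 0-based within the spliced, phase-trimmed CDS
    codon_index: int
    codon_pos: int  # 0, 1 or 2
    ref_codon: str
    alt_codon: str
    effect: str  # "synonymous" | "nonsynonymous"
    substitution_class: str  # "transition" | "transversion"


@dataclass(frozen=True)
class CodonSiteLengths:
    codon: str
    nonsyn_length: float
    syn_length: float


@dataclass(frozen=True)
class GeneSiteLengths:
    gene_id: str
    nonsyn_length: float
    syn_length: float
    n_codons: int


def extract_cds(ref: GenomeRef, model: CdsModel) -> str:
    """Spliced coding sequence of ``model``, 5'->3', phase-trimmed.

    Minus-strand genes are reverse-complemented; the ``phase`` leading
    bases are dropped so the result starts on a complete codon and has
    length divisible by 3.
    """
    contig = ref[model.contig]
    if model.span[1] > len(contig):
        raise ValueError(
            f"gene {model.gene_id} extends past contig {model.contig}"
        )
    spliced = "".join(contig[s - 1 : e] for s, e in model.segments)
    if model.strand == "-":
        spliced = reverse_complement(spliced)
    spliced = spliced[model.phase :]
    if len(spliced) % 3 != 0:
        raise ValueError(
            f"gene {model.gene_id}: CDS length {len(spliced)} not divisible by 3"
        )
    return spliced


def genomic_to_cds_offset(model: CdsModel, pos: int) -> int | None:
    """Map a 1-based genomic position to a 0-based offset in the spliced,
    phase-trimmed CDS, honouring strand.  None if the position is not coding.
    """
    offset = 0
    if model.strand == "+":
        for s, e in model.segments:
            if s <= pos <= e:
                raw = offset + (pos - s)
                break
            offset += e - s + 1
        else:
            return None
    else:
        for s, e in reversed(model.segments):
            if s <= pos <= e:
                raw = offset + (e - pos)
                break
            offset += e - s + 1
        else:
            return None
    trimmed = raw - model.phase
    return trimmed if trimmed >= 0 else None


def locate_snp(model: CdsModel, pos: int) -> str:
    """Label a position relative to a gene model: coding, intronic or flanking."""
    if model.contains(pos):
        return "coding"
    lo, hi = model.span
    if lo <= pos <= hi:
        return "intronic"
    return "flanking"


def annotate_snp(
    model: CdsModel,
    ref: GenomeRef,
    pos: int,
    ref_allele: str,
    alt_allele: str,
) -> CodingSnp | None:
    """Annotate a biallelic SNP against one gene model.

    Returns None for non-coding positions.  For coding positions the
    alleles (given on the plus strand of the genome) are complemented on
    minus-strand genes, the reference and alternate codons are built, and
    the effect is classified under the standard genetic code.  A reference
    allele that disagrees with the genome sequence is a hard error.
    """
    genome_base = ref[model.contig][pos - 1]
    if genome_base != ref_allele.upper():
        raise ValueError(
            f"{model.contig}:{pos}: reference allele {ref_allele!r} does not "
            f"match genome base {genome_base!r}"
        )
    offset = genomic_to_cds_offset(model, pos)
    if offset is None:
        return None
    cds = extract_cds(ref, model)
    codon_index, codon_pos = divmod(offset, 3)
    ref_codon = cds[codon_index * 3 : codon_index * 3 + 3]
    a, b = ref_allele.upper(), alt_allele.upper()
    if model.strand == "-":
        a = a.translate(COMPLEMENT)
        b = b.translate(COMPLEMENT)
    if ref_codon[codon_pos] != a:
        raise ValueError(
            f"{model.gene_id} offset {offset}: codon base "
            f"{ref_codon[codon_pos]!r} != strand-adjusted ref allele {a!r}"
        )
    alt_codon = ref_codon[:codon_pos] + b + ref_codon[codon_pos + 1 :]
    if "N" in ref_codon or "N" in alt_codon:
        return None
    effect = (
        "synonymous"
        if GENETIC_CODE[ref_codon] == GENETIC_CODE[alt_codon]
        else "nonsynonymous"
    )
    return CodingSnp(
        gene_id=model.gene_id,
        cds_offset=offset,
        codon_index=codon_index,
        codon_pos=codon_pos,
        ref_codon=ref_codon,
        alt_codon=alt_codon,
        effect=effect,
        substitution_class=classify_substitution(ref_allele, alt_allele),
    )


@lru_cache(maxsize=512)
def codon_site_lengths(codon: str, transversion_penalty: float = 6.0) -> CodonSiteLengths:
    """Weighted nonsynonymous/synonymous site lengths of one codon.

    For each of the three positions, the three single-base changes are
    enumerated; the transition gets weight 1 and each transversion weight
    1/``transversion_penalty``.  The position's nonsynonymous fraction is
    the weighted share of changes that alter the amino acid (stop-affecting
    changes count as nonsynonymous), and the codon's nonsynonymous length
    is the sum of the three fractions.  ``syn_length`` is defined as
    3 - nonsyn_length, so the two always partition the codon exactly.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"codon must be 3 bases of A/C/G/T, got {codon!r}")
    if transversion_penalty <= 0:
        raise ValueError("transversion_penalty must be positive")
    aa = GENETIC_CODE[codon]
    nonsyn = 0.0
    for pos in range(3):
        w_nonsyn = 0.0
        w_total = 0.0
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            w = (
                1.0
                if classify_substitution(codon[pos], alt) == "transition"
                else 1.0 / transversion_penalty
            )
            w_total += w
            alt_codon = codon[:pos] + alt + codon[pos + 1 :]
            if GENETIC_CODE[alt_codon] != aa:
                w_nonsyn += w
        nonsyn += w_nonsyn / w_total
    return CodonSiteLengths(codon=codon, nonsyn_length=nonsyn, syn_length=3.0 - nonsyn)


def gene_site_lengths(
    model: CdsModel,
    ref: GenomeRef,
    transversion_penalty: float = 6.0,
) -> GeneSiteLengths:
    """Sum per-codon weighted site lengths over a gene's analysable codons.

    A terminal stop codon and any codon containing N are excluded.
    """
    cds = extract_cds(ref, model)
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    if codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    codons = [c for c in codons if "N" not in c]
    if not codons:
        raise ValueError(f"gene {model.gene_id}: no analysable codons")
    ln = 0.0
    for c in codons:
        ln += codon_site_lengths(c, transversion_penalty).nonsyn_length
    return GeneSiteLengths(
        gene_id=model.gene_id,
        nonsyn_length=ln,
        syn_length=3.0 * len(codons) - ln,
        n_codons=len(codons),
    )
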