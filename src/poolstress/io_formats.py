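"""Readers and writers for the external formats the pipeline touches.

Coordinate conventions: every external format (GFF3, pileup, output TSVs)
is 1-based inclusive; internal arithmetic is 0-based half-open, with the
conversion done here at the boundary.

The pileup dialect is the classic 6-column ``samtools mpileup`` text
(chrom, pos, ref, depth, read bases, base qualities) without the
mapping-quality column.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, TextIO

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")

_INDEL_RE = re.compile(r"[+-](\d+)")


@dataclass(frozen=True)
class GenomeRef:
    """A reference genome: contig id -> uppercase A/C/G/T/N sequence."""

    contigs: dict[str, str]

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} has an empty sequence")
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"contig {cid!r} contains invalid characters {sorted(bad)}"
                )

    def __getitem__(self, contig: str) -> str:
        return self.contigs[contig]

    def __contains__(self, contig: str) -> bool:
        return contig in self.contigs

    def __iter__(self) -> Iterator[str]:
        return iter(self.contigs)


@dataclass(frozen=True)
class CdsModel:
    """A gene's coding region: ordered genomic segments plus strand/phase.

    ``segments`` are 1-based inclusive (start, end) intervals sorted by
    genomic start and non-overlapping.  ``phase`` is the number of bases to
    trim from the 5' end of the spliced CDS before the first complete codon.
    """

    gene_id: str
    contig: str
    strand: str
    segments: tuple[tuple[int, int], ...]
    phase: int = 0

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if self.phase not in (0, 1, 2):
            raise ValueError(f"phase must be 0/1/2, got {self.phase!r}")
        if not self.segments:
            raise ValueError(f"gene {self.gene_id}: no CDS segments")
        prev_end = 0
        for start, end in self.segments:
            if start < 1 or end < start:
                raise ValueError(
                    f"gene {self.gene_id}: bad segment ({start}, {end})"
                )
            if start <= prev_end:
                raise ValueError(
                    f"gene {self.gene_id}: segments overlap or are unsorted"
                )
            prev_end = end

    @property
    def cds_length(self) -> int:
        """Spliced CDS length after phase trimming."""
        total = sum(e - s + 1 for s, e in self.segments)
        return total - self.phase

    @property
    def span(self) -> tuple[int, int]:
        """Genomic (start, end), 1-based inclusive, covering all segments."""
        return self.segments[0][0], self.segments[-1][1]

    def contains(self, pos: int) -> bool:
        """True if 1-based genomic ``pos`` falls inside a coding segment."""
        return any(s <= pos <= e for s, e in self.segments)


@dataclass(frozen=True)
class PileupColumn:
    """Decoded read bases with phred qualities at one reference position."""

    contig: str
    pos: int  # 1-based
    ref_base: str
    calls: tuple[str, ...]  # each in {A,C,G,T,N,*}
    quals: tuple[int, ...]  # phred, aligned with calls

    def __post_init__(self) -> None:
        if len(self.calls) != len(self.quals):
            raise ValueError(
                f"{self.contig}:{self.pos}: {len(self.calls)} calls vs "
                f"{len(self.quals)} qualities"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path) -> GenomeRef:
    """Read a FASTA file into a :class:`GenomeRef`.

    Sequences are uppercased; duplicate ids and empty sequences are hard
    errors.
    """
    contigs: dict[str, str] = {}
    current: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current is None:
            return
        seq = "".join(chunks).upper()
        if not seq:
            raise ValueError(f"empty sequence for {current!r} in {path}")
        contigs[current] = seq

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                current = line[1:].split()[0]
                if current in contigs:
                    raise ValueError(f"duplicate FASTA id {current!r} in {path}")
                chunks = []
            else:
                if current is None:
                    raise ValueError(f"sequence before header in {path}")
                chunks.append(line)
        _flush()
    if not contigs:
        raise ValueError(f"no FASTA records in {path}")
    return GenomeRef(contigs)


def write_fasta(ref: GenomeRef, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for cid, seq in ref.contigs.items():
            fh.write(f">{cid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 CDS models


def _gff3_attr(attrs: str, *keys: str) -> str | None:
    fields = dict(
        kv.split("=", 1) for kv in attrs.strip().split(";") if "=" in kv
    )
    for key in keys:
        if key in fields:
            return fields[key]
    return None


def read_gff3_cds(path: str | Path, ref: GenomeRef | None = None) -> list[CdsModel]:
    """Group GFF3 CDS features by parent gene into :class:`CdsModel` records.

    Records whose spliced length minus phase is not divisible by 3 are
    excluded with a logged warning rather than raising, so one malformed
    annotation does not abort a whole run.  If ``ref`` is given, models
    extending beyond their contig are excluded the same way.
    """
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns")
            contig, _src, ftype, start, end, _score, strand, phase, attrs = cols[:9]
            if ftype != "CDS":
                continue
            gene = _gff3_attr(attrs, "Parent", "gene_id", "ID")
            if gene is None:
                raise ValueError(f"{path}:{lineno}: CDS without Parent/ID attribute")
            rec = per_gene.setdefault(
                gene, {"contig": contig, "strand": strand, "segs": []}
            )
            rec["segs"].append((int(start), int(end), phase))

    models: list[CdsModel] = []
    for gene, rec in per_gene.items():
        segs = sorted(rec["segs"])
        strand = rec["strand"]
        # phase of the 5'-most segment: first on +, last on -
        phase_str = segs[0][2] if strand == "+" else segs[-1][2]
        phase = int(phase_str) if phase_str in "012" else 0
        try:
            model = CdsModel(
                gene_id=gene,
                contig=rec["contig"],
                strand=strand,
                segments=tuple((s, e) for s, e, _ in segs),
                phase=phase,
            )
        except ValueError as exc:
            logger.warning("excluding gene %s: %s", gene, exc)
            continue
        if model.cds_length % 3 != 0:
            logger.warning(
                "excluding gene %s: CDS length %d (after phase) not divisible by 3",
                gene,
                model.cds_length,
            )
            continue
        if ref is not None:
            if model.contig not in ref or model.span[1] > len(ref[model.contig]):
                logger.warning("excluding gene %s: outside contig bounds", gene)
                continue
        models.append(model)
    return models


def write_gff3_cds(models: Iterable[CdsModel], path: str | Path) -> None:
    """Write CDS features, one line per segment, grouped under gene parents."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            start, end = m.span
            fh.write(
                f"{m.contig}\tpoolstress\tgene\t{start}\t{end}\t.\t{m.strand}\t."
                f"\tID={m.gene_id}\n"
            )
            # GFF3 phase applies to the 5'-most segment of the reading frame
            segs = list(m.segments)
            phases = ["."] * len(segs)
            running = m.phase
            order = range(len(segs)) if m.strand == "+" else range(len(segs) - 1, -1, -1)
            for i in order:
                phases[i] = str(running)
                seg_len = segs[i][1] - segs[i][0] + 1
                running = (3 - (seg_len - running) % 3) % 3
            for (s, e), ph in zip(segs, phases):
                fh.write(
                    f"{m.contig}\tpoolstress\tCDS\t{s}\t{e}\t.\t{m.strand}\t{ph}"
                    f"\tParent={m.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# samtools 6-column pileup


def decode_pileup_bases(bases: str, ref_base: str) -> list[str]:
    """Decode a pileup read-base string into one call per read.

    ``.``/``,`` become the reference base; ACGT (either case) are calls;
    ``^X`` (read start + mapping quality) and ``$`` (read end) are stripped;
    ``+n``/``-n`` indel runs are skipped; ``*`` (deletion placeholder) is
    kept as a call so depth bookkeeping stays aligned with the quality
    string, but callers never treat it as an allele.
    """
    calls: list[str] = []
    i = 0
    n = len(bases)
    ref = ref_base.upper()
    while i < n:
        c = bases[i]
        if c == "^":
            i += 2  # caret plus mapping-quality char
        elif c == "$":
            i += 1
        elif c in "+-":
            m = _INDEL_RE.match(bases, i)
            if not m:
                raise ValueError(f"malformed indel at offset {i} in {bases!r}")
            length = int(m.group(1))
            i = m.end() + length
        elif c in ".,":
            calls.append(ref)
            i += 1
        elif c.upper() in "ACGTN":
            calls.append(c.upper())
            i += 1
        elif c == "*":
            calls.append("*")
            i += 1
        else:
            raise ValueError(f"unexpected pileup character {c!r} in {bases!r}")
    return calls


def read_pileup(path: str | Path) -> Iterator[PileupColumn]:
    """Stream 6-column samtools pileup text as decoded columns.

    A mismatch between the decoded call count and the quality-string length
    is a hard error naming the offending line.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 pileup columns, got {len(cols)}"
                )
            contig, pos, ref_base, depth, bases, quals = cols
            calls = decode_pileup_bases(bases, ref_base)
            if len(calls) != len(quals):
                raise ValueError(
                    f"{path}:{lineno}: decoded {len(calls)} calls but "
                    f"{len(quals)} quality characters"
                )
            if len(calls) != int(depth):
                raise ValueError(
                    f"{path}:{lineno}: decoded {len(calls)} calls but depth "
                    f"column says {depth}"
                )
            yield PileupColumn(
                contig=contig,
                pos=int(pos),
                ref_base=ref_base.upper(),
                calls=tuple(calls),
                quals=tuple(ord(q) - 33 for q in quals),
            )


def write_pileup(columns: Iterable[PileupColumn], path: str | Path) -> None:
    """Write columns back out as 6-column pileup text (ref matches as '.')."""
    with open(path, "w") as fh:
        for col in columns:
            bases = "".join(
                "." if c == col.ref_base else c for c in col.calls
            )
            quals = "".join(chr(q + 33) for q in col.quals)
            fh.write(
                f"{col.contig}\t{col.pos}\t{col.ref_base}\t{len(col.calls)}"
                f"\t{bases}\t{quals}\n"
            )
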