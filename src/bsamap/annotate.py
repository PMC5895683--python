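"""Strand-aware SNP effect annotation against gene models.

Each SNP is classified by its genomic context: inside a CDS (synonymous,
nonsynonymous, stop-gain or stop-loss by codon comparison), inside a gene
but outside the CDS (intronic; exonic-but-noncoding positions carry a
``utr`` note), within a configurable flank of a gene (upstream/downstream,
strand-aware), or intergenic. Gene models come from GFF3 (gene/mRNA/exon/
CDS features); the reference sequence from FASTA (via pyfaidx) or any
chromosome->string mapping.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

from Bio.Seq import Seq

from .pooled_variants import PooledSNP

log = logging.getLogger(__name__)

_BASES = frozenset("ACGT")


class Category(Enum):
    NONSYNONYMOUS = "NONSYNONYMOUS"
    SYNONYMOUS = "SYNONYMOUS"
    STOP_GAIN = "STOP_GAIN"
    STOP_LOSS = "STOP_LOSS"
    INTRONIC = "INTRONIC"
    UPSTREAM = "UPSTREAM"
    DOWNSTREAM = "DOWNSTREAM"
    INTERGENIC = "INTERGENIC"


#: Categories that change the encoded protein.
CODING_CHANGING = frozenset(
    {Category.NONSYNONYMOUS, Category.STOP_GAIN, Category.STOP_LOSS}
)

#: Exonic-CDS categories.
EXONIC = frozenset(
    {Category.NONSYNONYMOUS, Category.SYNONYMOUS, Category.STOP_GAIN,
     Category.STOP_LOSS}
)

# context rank used when several genes apply: exonic beats intronic beats
# flanking; intergenic only when nothing applies
_CONTEXT_RANK = {
    **{c: 0 for c in EXONIC},
    Category.INTRONIC: 1,
    Category.UPSTREAM: 2,
    Category.DOWNSTREAM: 2,
    Category.INTERGENIC: 3,
}

#: Ranking weight for candidate prioritisation (higher = more severe).
SEVERITY = {
    Category.STOP_GAIN: 3,
    Category.STOP_LOSS: 2,
    Category.NONSYNONYMOUS: 1,
}


class ReferenceMismatchError(ValueError):
    """Reference sequence disagrees with a record's ref base (coordinate bug
    guard)."""


class OutsideCDSError(ValueError):
    """Codon effect requested for a position not in the gene's CDS."""


@dataclass(frozen=True)
class GeneModel:
    """Strand-aware exon/CDS structure of one gene (first transcript).

    ``exons`` and ``cds`` are ordered, non-overlapping (start, end) pairs,
    1-based inclusive, sorted by start regardless of strand; the CDS length
    must be a multiple of three.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        for name, segs in (("exons", self.exons), ("cds", self.cds)):
            prev_end = 0
            for s, e in segs:
                if s > e or s <= prev_end:
                    raise ValueError(
                        f"{self.gene_id}: {name} segments must be sorted and "
                        f"non-overlapping, got {segs}"
                    )
                prev_end = e
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"{self.gene_id}: CDS length {self.cds_length} not a "
                "multiple of 3"
            )

    @property
    def span(self) -> tuple[int, int]:
        segs = self.exons or self.cds
        return (segs[0][0], segs[-1][1])

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)


@dataclass(frozen=True)
class AnnotationContext:
    """Result of classifying one SNP.

    ``gene_id`` is set for every category except INTERGENIC; the residue
    fields (ref_aa, alt_aa, residue_index 1-based) only for exonic-CDS
    categories.
    """

    category: Category
    gene_id: str | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None
    residue_index: int | None = None
    note: str | None = None


def translate(codon: str) -> str:
    """Translate one codon under the standard genetic code; stop is ``*``."""
    codon = codon.upper()
    if len(codon) != 3 or not set(codon) <= _BASES:
        raise ValueError(f"not an unambiguous DNA codon: {codon!r}")
    return str(Seq(codon).translate())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def fetch(reference: Mapping[str, object], chrom: str, start: int, end: int) -> str:
    """1-based inclusive slice of a chromosome from a dict of strings or a
    pyfaidx.Fasta."""
    return str(reference[chrom][start - 1:end]).upper()


def cds_position(gene: GeneModel, genomic_pos: int) -> int | None:
    """1-based coordinate of a genomic position within the spliced CDS.

    Counting starts at the translation start: the left-most CDS base for a
    plus-strand gene, the right-most for a minus-strand gene. Returns None
    for positions outside the CDS.
    """
    offset = 0  # bases in CDS segments left of the hit
    for s, e in gene.cds:
        if s <= genomic_pos <= e:
            plus_index = offset + (genomic_pos - s) + 1
            if gene.strand == "+":
                return plus_index
            return gene.cds_length - plus_index + 1
        offset += e - s + 1
    return None


def spliced_cds(gene: GeneModel, reference: Mapping[str, object]) -> str:
    """The gene's CDS sequence in reading orientation (reverse-complemented
    for minus-strand genes)."""
    seq = "".join(fetch(reference, gene.chrom, s, e) for s, e in gene.cds)
    return reverse_complement(seq) if gene.strand == "-" else seq


def codon_effect(
    gene: GeneModel,
    reference: Mapping[str, object],
    pos: int,
    ref_base: str,
    alt_base: str,
) -> AnnotationContext:
    """Codon-level effect of substituting ``ref_base`` -> ``alt_base`` at a
    CDS position.

    The reference sequence must carry ``ref_base`` at ``pos`` (a mismatch
    raises :class:`ReferenceMismatchError` — it means coordinates and
    sequence are out of register). ``residue_index`` is
    ``ceil(cds_pos / 3)``.
    """
    genomic_base = fetch(reference, gene.chrom, pos, pos)
    if genomic_base != ref_base.upper():
        raise ReferenceMismatchError(
            f"{gene.chrom}:{pos}: reference has {genomic_base}, record says "
            f"{ref_base}"
        )
    cds_pos = cds_position(gene, pos)
    if cds_pos is None:
        raise OutsideCDSError(f"{gene.chrom}:{pos} is not in CDS of {gene.gene_id}")
    cds_seq = spliced_cds(gene, reference)
    idx = cds_pos - 1
    codon_idx = idx // 3
    within = idx % 3
    ref_codon = cds_seq[codon_idx * 3: codon_idx * 3 + 3]
    sub = alt_base.upper() if gene.strand == "+" else reverse_complement(alt_base)
    alt_codon = ref_codon[:within] + sub + ref_codon[within + 1:]
    ref_aa = translate(ref_codon)
    alt_aa = translate(alt_codon)
    if ref_aa == alt_aa:
        category = Category.SYNONYMOUS
    elif alt_aa == "*":
        category = Category.STOP_GAIN
    elif ref_aa == "*":
        category = Category.STOP_LOSS
    else:
        category = Category.NONSYNONYMOUS
    return AnnotationContext(
        category=category,
        gene_id=gene.gene_id,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
        residue_index=codon_idx + 1,
    )


def _in_segments(pos: int, segs: Sequence[tuple[int, int]]) -> bool:
    return any(s <= pos <= e for s, e in segs)


def classify_snp(
    snp: PooledSNP,
    genes: Sequence[GeneModel],
    reference: Mapping[str, object] | None = None,
    flank_bp: int = 2000,
) -> AnnotationContext:
    """Classify a SNP against all gene models on its chromosome.

    When several genes apply, the most severe context wins (exonic >
    intronic > up/downstream); ties break by smaller distance to the gene
    span, then lexicographic gene id. ``reference`` is required only when
    the SNP can fall inside a CDS.
    """
    candidates: list[tuple[int, int, str, AnnotationContext]] = []
    for gene in genes:
        if gene.chrom != snp.chrom:
            continue
        g_start, g_end = gene.span
        if g_start <= snp.pos <= g_end:
            if cds_position(gene, snp.pos) is not None:
                if reference is None:
                    raise ValueError(
                        "reference sequence required to annotate CDS SNPs"
                    )
                ann = codon_effect(gene, reference, snp.pos,
                                   snp.ref_base, snp.alt_base)
            else:
                note = "utr" if _in_segments(snp.pos, gene.exons) else None
                ann = AnnotationContext(
                    category=Category.INTRONIC, gene_id=gene.gene_id, note=note
                )
            candidates.append((_CONTEXT_RANK[ann.category], 0, gene.gene_id, ann))
        else:
            dist = g_start - snp.pos if snp.pos < g_start else snp.pos - g_end
            if dist > flank_bp:
                continue
            before = snp.pos < g_start
            upstream = before if gene.strand == "+" else not before
            cat = Category.UPSTREAM if upstream else Category.DOWNSTREAM
            ann = AnnotationContext(category=cat, gene_id=gene.gene_id)
            candidates.append((_CONTEXT_RANK[cat], dist, gene.gene_id, ann))
    if not candidates:
        return AnnotationContext(category=Category.INTERGENIC)
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    return candidates[0][3]


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Load gene models from GFF3 (gene/mRNA/exon/CDS with ID/Parent).

    Only the first mRNA per gene is used (logged when a gene has several);
    genes without an mRNA take exon/CDS children of the gene feature.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if len(mrnas) > 1:
            log.info("%s: %d mRNAs, using first", gene.id, len(mrnas))
        parent = mrnas[0] if mrnas else gene
        exons = tuple(sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="exon")
        ))
        cds = tuple(sorted(
            (f.start, f.end) for f in db.children(parent, featuretype="CDS")
        ))
        genes.append(
            GeneModel(
                gene_id=gene.id, chrom=gene.seqid, strand=gene.strand,
                exons=exons or cds, cds=cds,
            )
        )
    return genes


def write_annotations_tsv(
    snps: Sequence[PooledSNP],
    annotations: Sequence[AnnotationContext],
    path: str | Path,
) -> None:
    import pandas as pd

    rows = [
        (s.chrom, s.pos, s.ref_base, s.alt_base, a.category.value,
         a.gene_id or ".", a.ref_aa or ".", a.alt_aa or ".",
         a.residue_index if a.residue_index is not None else ".",
         a.note or ".")
        for s, a in zip(snps, annotations)
    ]
    pd.DataFrame(
        rows,
        columns=["chrom", "pos", "ref", "alt", "effect", "gene",
                 "ref_aa", "alt_aa", "residue", "note"],
    ).to_csv(path, sep="\t", index=False)
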