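"""Packaged worked tables from the soybean *dw* dwarf (GmDW1) mapping study.

These small tab-separated tables — the nine SNPs of the chromosome-8
fine-mapping region with per-pool read depths and effects, the 36 annotated
genes of the 460-kb interval, linkage-marker positions, recessive-class
recombinant counts, F2 segregation counts, and the six genome-scan
intervals — are the published inputs against which the package's
statistics can be replayed end to end without raw sequencing data.
Chromosome ids are normalised to the Gm-style ("Gm08").
"""
from __future__ import annotations

from importlib import resources

import pandas as pd

from .annotate import AnnotationContext, Category
from .genetics import GenomicInterval, MarkerLinkage, SegregationCount
from .pooled_variants import PoolCounts, PooledSNP

TABLE_FILES = [
    "mapping_region_snps.tsv",
    "interval_genes.tsv",
    "linkage_markers.tsv",
    "fine_mapping_recombinants.tsv",
    "segregation_counts.tsv",
    "scan_intervals.tsv",
]

_EFFECTS = {
    "intergenic": Category.INTERGENIC,
    "upstream": Category.UPSTREAM,
    "downstream": Category.DOWNSTREAM,
    "nonsynonymous": Category.NONSYNONYMOUS,
    "intronic": Category.INTRONIC,
}


def raw_table(name: str) -> str:
    """Raw TSV text of a packaged table (see :data:`TABLE_FILES`)."""
    if name not in TABLE_FILES:
        raise KeyError(f"unknown table {name!r}; have {TABLE_FILES}")
    return (resources.files("bsamap") / "data" / name).read_text()


def _frame(name: str) -> pd.DataFrame:
    with resources.as_file(resources.files("bsamap") / "data" / name) as p:
        return pd.read_csv(p, sep="\t")


def mapping_region_snps() -> tuple[list[PooledSNP], list[AnnotationContext]]:
    """The nine SNPs of the ~500-kb fine-mapping region, with their
    published per-pool depths and effect annotations (aligned lists)."""
    df = _frame("mapping_region_snps.tsv")
    snps, anns = [], []
    for row in df.itertuples(index=False):
        snps.append(
            PooledSNP(
                chrom=row.chrom, pos=int(row.pos),
                ref_base=row.ref, alt_base=row.alt,
                wt=PoolCounts(int(row.wt_ref), int(row.wt_alt)),
                mut=PoolCounts(int(row.mut_ref), int(row.mut_alt)),
            )
        )
        gene = None if row.gene == "." else row.gene
        anns.append(
            AnnotationContext(category=_EFFECTS[row.effect], gene_id=gene)
        )
    return snps, anns


def interval_genes() -> list[str]:
    """The 36 annotated genes of the 460-kb fine-mapping interval."""
    return _frame("interval_genes.tsv")["gene_id"].tolist()


def linkage_marker_positions() -> dict[str, tuple[str, int]]:
    """Physical positions of the linkage markers, in bp (the published
    Mb values, printed at 2 decimals, treated as exact x 10^6)."""
    df = _frame("linkage_markers.tsv")
    return {
        row.marker_id: (row.chrom, int(round(row.position_mb * 1e6)))
        for row in df.itertuples(index=False)
    }


def fine_mapping_linkage() -> list[MarkerLinkage]:
    """Recessive-class recombinant counts at the fine-mapping markers."""
    df = _frame("fine_mapping_recombinants.tsv")
    return [
        MarkerLinkage(
            marker_id=row.marker_id, chrom=row.chrom,
            pos=int(round(row.position_mb * 1e6)),
            n_recombinant_plants=int(row.n_recombinant_plants),
        )
        for row in df.itertuples(index=False)
    ]


def segregation_counts() -> dict[str, SegregationCount]:
    """F2 wild/dwarf counts for the three mapping crosses."""
    df = _frame("segregation_counts.tsv")
    return {
        row.cross: SegregationCount(int(row.n_wild), int(row.n_mutant))
        for row in df.itertuples(index=False)
    }


def scan_intervals() -> dict[str, GenomicInterval]:
    """The six genome-scan candidate intervals (name -> interval)."""
    df = _frame("scan_intervals.tsv")
    return {
        row.name: GenomicInterval(
            chrom=row.chrom, start=int(row.start_bp), end=int(row.stop_bp)
        )
        for row in df.itertuples(index=False)
    }
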