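"""End-to-end orchestration: read pools -> ED scan -> linkage -> intersect ->
annotate -> candidate nomination -> report files.

The combined strategy is the study's own: a genome-wide pooled-frequency
scan proposes candidate intervals, recessive-class linkage mapping from an
independent F2 population proposes one interval, and only scan intervals
overlapping the linkage interval survive (the rest are flagged
EXCLUDED_BY_LINKAGE). Candidates are then nominated among protein-changing
SNPs of the intersected interval whose mutant pool is pure for the
alternate allele.
"""
from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import annotate as ann_mod
from . import ed_scan, genetics, pooled_variants

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r}: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: Path
    counts: Path | None = None
    vcf: Path | None = None
    gff3: Path | None = None
    fasta: Path | None = None
    markers: Path | None = None
    marker_positions: Path | None = None
    segregation: Path | None = None
    scan: ed_scan.ScanConfig = field(default_factory=ed_scan.ScanConfig)
    flank_bp: int = 2000
    purity_max_ref: float = 0
    wt_sample: str = "wt_pool"
    mut_sample: str = "mut_pool"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.counts is None and self.vcf is None:
            raise ValueError("one of counts/vcf is required")


@dataclass
class CandidateReport:
    scan_intervals: list[ed_scan.CandidateInterval]
    excluded_by_linkage: list[ed_scan.CandidateInterval]
    linkage_interval: genetics.GenomicInterval | None
    intersected: genetics.GenomicInterval | None
    linkage: list[genetics.LinkageResult]
    segregation: dict[str, genetics.SegregationTestResult]
    scores: list[ed_scan.EdScore]
    annotations: list[ann_mod.AnnotationContext]
    annotated_snps: list[pooled_variants.PooledSNP]
    candidates: list[genetics.Candidate]

    def to_json_dict(self) -> dict:
        def iv(x):
            return None if x is None else {
                "chrom": x.chrom, "start": x.start, "end": x.end,
            }

        return {
            "scan_intervals": [
                {**iv(i), "n_snps": i.n_snps, "max_ed": round(i.max_ed, 6),
                 "length_kb": i.length_kb}
                for i in self.scan_intervals
            ],
            "excluded_by_linkage": [
                {**iv(i), "n_snps": i.n_snps, "max_ed": round(i.max_ed, 6)}
                for i in self.excluded_by_linkage
            ],
            "linkage_interval": iv(self.linkage_interval),
            "intersected_interval": iv(self.intersected),
            "linkage": [
                {"marker_id": r.marker_id, "n_plants": r.n_plants,
                 "n_recombinant_plants": r.n_recombinant_plants,
                 "n_recombinant_chromosomes": r.n_recombinant_chromosomes,
                 "recomb_fraction": round(r.recomb_fraction, 6),
                 "cosegregating": r.cosegregating}
                for r in self.linkage
            ],
            "segregation": {
                name: {"chi2": round(r.chi2, 4), "df": r.df, "p": round(r.p, 4)}
                for name, r in self.segregation.items()
            },
            "candidates": [
                {"chrom": c.snp.chrom, "pos": c.snp.pos,
                 "ref": c.snp.ref_base, "alt": c.snp.alt_base,
                 "gene": c.annotation.gene_id,
                 "category": c.annotation.category.value,
                 "ref_aa": c.annotation.ref_aa, "alt_aa": c.annotation.alt_aa,
                 "residue": c.annotation.residue_index,
                 "purity": round(c.purity, 6), "ed": round(c.ed, 6)}
                for c in self.candidates
            ],
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
            log.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("read")
def _read_snps(config: PipelineConfig) -> list[pooled_variants.PooledSNP]:
    if config.counts is not None:
        snps = pooled_variants.read_counts_tsv(config.counts)
    else:
        snps = pooled_variants.read_pooled_vcf(
            config.vcf, config.wt_sample, config.mut_sample
        )
    log.info("read %d pooled SNP records", len(snps))
    return snps


@_stage("scan")
def _scan(config, snps):
    scores = ed_scan.scan(snps, config.scan)
    intervals = ed_scan.call_intervals(scores, config.scan)
    log.info("%d scored SNPs, %d candidate interval(s)", len(scores), len(intervals))
    return scores, intervals


@_stage("segregation")
def _segregation(config) -> dict[str, genetics.SegregationTestResult]:
    if config.segregation is None:
        return {}
    import pandas as pd

    df = pd.read_csv(config.segregation, sep="\t")
    return {
        row.cross: genetics.chi_square_segregation(
            genetics.SegregationCount(int(row.n_wild), int(row.n_mutant))
        )
        for row in df.itertuples(index=False)
    }


@_stage("linkage")
def _linkage(config):
    if config.markers is None or config.marker_positions is None:
        return [], None
    import pandas as pd

    genotypes = genetics.read_marker_tsv(config.markers)
    pos_df = pd.read_csv(config.marker_positions, sep="\t")
    positions = {
        row.marker_id: (row.chrom, int(row.pos))
        for row in pos_df.itertuples(index=False)
    }
    results = []
    marker_links = []
    for marker_id, (chrom, pos) in sorted(positions.items(), key=lambda kv: kv[1]):
        res = genetics.count_recombinants(genotypes, marker_id)
        results.append(res)
        marker_links.append(
            genetics.MarkerLinkage(
                marker_id=marker_id, chrom=chrom, pos=pos,
                n_recombinant_plants=res.n_recombinant_plants,
            )
        )
    interval = genetics.refine_interval(marker_links)
    log.info(
        "linkage interval %s:%d-%d from %d markers",
        interval.chrom, interval.start, interval.end, len(marker_links),
    )
    return results, interval


@_stage("annotate")
def _annotate(config, snps):
    if config.gff3 is None or config.fasta is None:
        raise FileNotFoundError("annotation requires --gff3 and --fasta")
    if not Path(config.gff3).exists():
        raise FileNotFoundError(f"GFF3 not found: {config.gff3}")
    if not Path(config.fasta).exists():
        raise FileNotFoundError(f"FASTA not found: {config.fasta}")
    import pyfaidx

    genes = ann_mod.read_gff3(config.gff3)
    reference = pyfaidx.Fasta(str(config.fasta))
    anns = [
        ann_mod.classify_snp(s, genes, reference, config.flank_bp) for s in snps
    ]
    return genes, anns


@_stage("candidates")
def _candidates(config, snps, anns, genes, interval):
    gene_ids = [
        g.gene_id for g in genes
        if interval is None
        or (g.chrom == interval.chrom
            and not (g.span[1] < interval.start or g.span[0] > interval.end))
    ]
    return genetics.mutmap_candidate_filter(
        snps, anns, gene_ids,
        purity_max_ref=config.purity_max_ref, power_k=config.scan.power_k,
    )


def run_pipeline(config: PipelineConfig) -> CandidateReport:
    """Execute every stage and write the report files into
    ``config.outdir`` (intervals.bed, scores.tsv, annotations.tsv,
    linkage.tsv, candidates.tsv, report.json). Deterministic for a fixed
    configuration: reruns produce byte-identical reports."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    snps = _read_snps(config)
    scores, intervals = _scan(config, snps)
    segregation = _segregation(config)
    linkage_results, linkage_interval = _linkage(config)

    kept, excluded = intervals, []
    intersected = None
    if linkage_interval is not None:
        kept, excluded = [], []
        for iv in intervals:
            gi = genetics.GenomicInterval(iv.chrom, iv.start, iv.end)
            if genetics.intersect_intervals(gi, linkage_interval) is None:
                excluded.append(iv)
            else:
                kept.append(iv)
        if kept:
            best = max(kept, key=lambda iv: iv.max_ed)
            intersected = genetics.intersect_intervals(
                genetics.GenomicInterval(best.chrom, best.start, best.end),
                linkage_interval,
            )
    elif intervals:
        best = max(intervals, key=lambda iv: iv.max_ed)
        intersected = genetics.GenomicInterval(best.chrom, best.start, best.end)

    # restrict annotation + candidate nomination to the mapped interval
    scored_snps = [sc.snp for sc in scores]
    if intersected is not None:
        region_snps = [
            s for s in scored_snps
            if s.chrom == intersected.chrom
            and intersected.start <= s.pos <= intersected.end
        ]
    else:
        region_snps = []
        log.warning("no mapped interval; candidate nomination skipped")

    genes, anns = ([], [])
    candidates: list[genetics.Candidate] = []
    if region_snps:
        genes, anns = _annotate(config, region_snps)
        candidates = _candidates(config, region_snps, anns, genes, intersected)
    if not candidates:
        log.warning("no candidate SNP survived filtering")

    report = CandidateReport(
        scan_intervals=kept,
        excluded_by_linkage=excluded,
        linkage_interval=linkage_interval,
        intersected=intersected,
        linkage=linkage_results,
        segregation=segregation,
        scores=scores,
        annotations=anns,
        annotated_snps=region_snps,
        candidates=candidates,
    )
    _write_report(report, outdir)
    return report


def _write_report(report: CandidateReport, outdir: Path) -> None:
    ed_scan.write_scores_tsv(report.scores, outdir / "scores.tsv")
    ed_scan.write_intervals_bed(
        report.scan_intervals + report.excluded_by_linkage,
        outdir / "intervals.bed",
    )
    if report.annotated_snps:
        ann_mod.write_annotations_tsv(
            report.annotated_snps, report.annotations, outdir / "annotations.tsv"
        )
    with open(outdir / "linkage.tsv", "w") as fh:
        fh.write(
            "marker_id\tn_plants\tn_recombinant_plants\t"
            "n_recombinant_chromosomes\trecomb_fraction\tcosegregating\n"
        )
        for r in report.linkage:
            fh.write(
                f"{r.marker_id}\t{r.n_plants}\t{r.n_recombinant_plants}\t"
                f"{r.n_recombinant_chromosomes}\t{r.recomb_fraction:.6f}\t"
                f"{int(r.cosegregating)}\n"
            )
    with open(outdir / "candidates.tsv", "w") as fh:
        fh.write("rank\tchrom\tpos\tref\talt\tgene\tcategory\tpurity\ted\n")
        for rank, c in enumerate(report.candidates, start=1):
            fh.write(
                f"{rank}\t{c.snp.chrom}\t{c.snp.pos}\t{c.snp.ref_base}\t"
                f"{c.snp.alt_base}\t{c.annotation.gene_id}\t"
                f"{c.annotation.category.value}\t{c.purity:.6f}\t{c.ed:.6f}\n"
            )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
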