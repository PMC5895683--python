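"""Segregation tests, recessive-class linkage mapping, interval arithmetic,
MutMap+-style candidate filtering, and summary phenotype statistics.

The linkage estimator here is the recessive-class design: only plants with
the recessive (mutant) phenotype are genotyped, so at a marker fully linked
to the causal locus every plant is homozygous for the mutant-parent allele
(call ``A``). Any heterozygous (``H``, one recombinant chromosome) or
other-parent homozygous (``B``, two recombinant chromosomes) call reveals
recombination between marker and causal locus.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Sequence

from scipy import stats

from . import ed_scan
from .annotate import CODING_CHANGING, SEVERITY, AnnotationContext
from .pooled_variants import Genotype, PooledSNP, call_genotype

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# segregation testing

@dataclass(frozen=True)
class SegregationCount:
    n_wild: int
    n_mutant: int

    def __post_init__(self) -> None:
        if self.n_wild < 0 or self.n_mutant < 0:
            raise ValueError("counts must be non-negative")
        if self.n_wild + self.n_mutant == 0:
            raise ValueError("total count must be > 0")

    @property
    def total(self) -> int:
        return self.n_wild + self.n_mutant


@dataclass(frozen=True)
class SegregationTestResult:
    chi2: float
    df: int
    p: float


def chi_square_segregation(
    counts: SegregationCount,
    expected_ratio: tuple[float, float] = (3.0, 1.0),
) -> SegregationTestResult:
    """Goodness-of-fit chi-square against a phenotypic ratio (default 3:1,
    the F2 expectation for a monogenic recessive trait).

    No continuity correction is applied: chi2 = sum (O - E)^2 / E with
    df = 1, p from the upper tail.
    """
    rw, rm = expected_ratio
    if rw <= 0 or rm <= 0:
        raise ValueError("expected ratio classes must be positive")
    total = counts.total
    e_wild = total * rw / (rw + rm)
    e_mut = total * rm / (rw + rm)
    chi2 = (counts.n_wild - e_wild) ** 2 / e_wild + (counts.n_mutant - e_mut) ** 2 / e_mut
    p = float(stats.chi2.sf(chi2, df=1))
    return SegregationTestResult(chi2=float(chi2), df=1, p=p)


# ---------------------------------------------------------------------------
# recessive-class linkage mapping

class MarkerCall(Enum):
    A = "A"        # homozygous mutant-parent allele
    H = "H"        # heterozygous
    B = "B"        # homozygous other-parent allele
    MISSING = "-"


@dataclass(frozen=True)
class MarkerGenotype:
    plant_id: str
    marker_id: str
    call: MarkerCall


@dataclass(frozen=True)
class LinkageResult:
    marker_id: str
    n_plants: int
    n_recombinant_plants: int
    n_recombinant_chromosomes: int
    recomb_fraction: float
    cosegregating: bool


def count_recombinants(
    genotypes: Sequence[MarkerGenotype], marker_id: str
) -> LinkageResult:
    """Count recombinants at one marker over phenotypically recessive plants.

    Recombinants are reported both as plants (any non-``A`` call) and as
    chromosomes (``H`` = 1, ``B`` = 2); the recombination-fraction estimate
    is chromosomes / (2 * plants). MISSING calls are excluded.
    """
    calls = [
        g.call for g in genotypes
        if g.marker_id == marker_id and g.call is not MarkerCall.MISSING
    ]
    if not calls:
        raise ValueError(f"no scored genotypes for marker {marker_id!r}")
    n_plants = len(calls)
    rec_plants = sum(1 for c in calls if c is not MarkerCall.A)
    rec_chroms = sum({MarkerCall.A: 0, MarkerCall.H: 1, MarkerCall.B: 2}[c]
                     for c in calls)
    return LinkageResult(
        marker_id=marker_id,
        n_plants=n_plants,
        n_recombinant_plants=rec_plants,
        n_recombinant_chromosomes=rec_chroms,
        recomb_fraction=rec_chroms / (2 * n_plants),
        cosegregating=rec_plants == 0,
    )


def read_marker_tsv(path: str | Path) -> list[MarkerGenotype]:
    """Read ``plant_id  marker_id  call`` (tab-separated, header row)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("plant_id", "marker_id", "call"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        call = MarkerCall(row.call) if row.call in ("A", "H", "B") else MarkerCall.MISSING
        out.append(MarkerGenotype(str(row.plant_id), str(row.marker_id), call))
    return out


# ---------------------------------------------------------------------------
# interval arithmetic

@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} > end {self.end}")

    @property
    def length_bp(self) -> int:
        """Span between the bounding coordinates (end - start), the
        convention used when a mapping interval's size is quoted from its
        flanking positions."""
        return self.end - self.start

    @property
    def length_kb(self) -> int:
        return self.length_bp // 1000

    @property
    def length_mb(self) -> float:
        return round(self.length_bp / 1e6, 1)


@dataclass(frozen=True)
class MarkerLinkage:
    """A mapped marker with its recombinant count in the recessive class."""

    marker_id: str
    chrom: str
    pos: int
    n_recombinant_plants: int


def refine_interval(markers: Sequence[MarkerLinkage]) -> GenomicInterval:
    """Bound the causal locus by the nearest flanking recombinant markers.

    The markers (any order; one chromosome) must contain at least one
    cosegregating marker with a recombinant-bearing marker on each side,
    and every marker strictly between the flanks must itself cosegregate —
    a recombinant marker inside the cosegregating span is a data
    inconsistency and raises ValueError.
    """
    if not markers:
        raise ValueError("no markers supplied")
    chroms = {m.chrom for m in markers}
    if len(chroms) != 1:
        raise ValueError(f"markers span several chromosomes: {sorted(chroms)}")
    ms = sorted(markers, key=lambda m: m.pos)
    coseg = [i for i, m in enumerate(ms) if m.n_recombinant_plants == 0]
    if not coseg:
        raise ValueError("no cosegregating marker")
    lo, hi = coseg[0], coseg[-1]
    inner = [ms[i] for i in range(lo, hi + 1) if ms[i].n_recombinant_plants > 0]
    if inner:
        raise ValueError(
            "recombinant marker(s) interior to the cosegregating span: "
            + ", ".join(m.marker_id for m in inner)
        )
    if lo == 0 or hi == len(ms) - 1:
        raise ValueError(
            "cosegregating span not flanked by recombinant markers on both sides"
        )
    return GenomicInterval(chrom=ms[0].chrom, start=ms[lo - 1].pos, end=ms[hi + 1].pos)


def intersect_intervals(
    a: GenomicInterval, b: GenomicInterval
) -> GenomicInterval | None:
    """Overlap of two intervals, or None when disjoint / different
    chromosomes. Commutative and idempotent."""
    if a.chrom != b.chrom:
        return None
    start = max(a.start, b.start)
    end = min(a.end, b.end)
    if start > end:
        return None
    return GenomicInterval(chrom=a.chrom, start=start, end=end)


# ---------------------------------------------------------------------------
# candidate filtering

@dataclass(frozen=True)
class Candidate:
    snp: PooledSNP
    annotation: AnnotationContext
    ed: float
    purity: float


def mutmap_candidate_filter(
    snps: Sequence[PooledSNP],
    annotations: Sequence[AnnotationContext],
    interval_genes: Sequence[str],
    *,
    purity_max_ref: float = 0,
    power_k: int = 1,
) -> list[Candidate]:
    """Nominate causal candidates among annotated SNPs of a mapped interval.

    Stage 1 keeps SNPs whose annotated gene belongs to ``interval_genes``
    and whose effect changes the protein (nonsynonymous / stop gain / stop
    loss). Stage 2 applies the mutant-pool homozygosity expectation of a
    recessive causal allele: at most ``purity_max_ref`` reference reads in
    the mutant pool (0 by default; ``math.inf`` disables the check) and a
    wild-type pool not homozygous-alternate. Survivors are ranked by
    (category severity, mutant-pool purity alt/(alt+ref), ED) descending,
    ties by position.

    An empty ``interval_genes`` list logs a warning and skips the gene-
    membership test (the coding-change requirement is kept, since ranking
    by effect severity is meaningless for non-coding SNPs).
    """
    if len(snps) != len(annotations):
        raise ValueError("snps and annotations must align")
    gene_set = set(interval_genes)
    if not gene_set:
        log.warning("empty interval gene list; gene-membership filter skipped")
    out: list[Candidate] = []
    for snp, ann in zip(snps, annotations):
        if ann.category not in CODING_CHANGING:
            continue
        if gene_set and ann.gene_id not in gene_set:
            continue
        # stage 2: mutant-pool purity and wild-type pool not fixed
        if snp.mut.ref_depth > purity_max_ref:
            continue
        if call_genotype(snp.wt) is Genotype.HOM_ALT:
            continue
        purity = snp.mut.alt_depth / snp.mut.total if snp.mut.total else 0.0
        ed = ed_scan.ed_score(snp, power_k).ed if snp.wt.total and snp.mut.total else 0.0
        out.append(Candidate(snp=snp, annotation=ann, ed=ed, purity=purity))
    out.sort(
        key=lambda c: (
            -SEVERITY.get(c.annotation.category, 0),
            -c.purity,
            -c.ed,
            c.snp.chrom,
            c.snp.pos,
        )
    )
    return out


# ---------------------------------------------------------------------------
# summary statistics

@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def t_test_from_summary(
    a: SummaryStats, b: SummaryStats, variant: str = "welch"
) -> tuple[float, float, float]:
    """Two-sample t test from summary statistics (mean, SD, n).

    ``variant='welch'`` (default) uses unequal variances with
    Welch–Satterthwaite degrees of freedom; ``'pooled'`` the classical
    equal-variance test. Returns (t, df, two-sided p).
    """
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown variant {variant!r}")
    equal_var = variant == "pooled"
    t, p = stats.ttest_ind_from_stats(
        a.mean, a.sd, a.n, b.mean, b.sd, b.n, equal_var=equal_var
    )
    if equal_var:
        df = a.n + b.n - 2.0
    else:
        va, vb = a.sd ** 2 / a.n, b.sd ** 2 / b.n
        df = (va + vb) ** 2 / (va ** 2 / (a.n - 1) + vb ** 2 / (b.n - 1))
    return float(t), float(df), float(p)


@dataclass(frozen=True)
class ExpressionMeasure:
    """Relative qPCR quantification inputs (quantification cycles)."""

    ct_target_sample: float
    ct_reference_sample: float
    ct_target_calibrator: float
    ct_reference_calibrator: float

    def __post_init__(self) -> None:
        for v in (self.ct_target_sample, self.ct_reference_sample,
                  self.ct_target_calibrator, self.ct_reference_calibrator):
            if not math.isfinite(v):
                raise ValueError("all Ct values must be finite")

    @property
    def ddct(self) -> float:
        return (self.ct_target_sample - self.ct_reference_sample) - (
            self.ct_target_calibrator - self.ct_reference_calibrator
        )

    @property
    def fold_change(self) -> float:
        return 2.0 ** (-self.ddct)


def delta_delta_ct(measure: ExpressionMeasure) -> float:
    """Fold change by the 2^-ddCt method."""
    return measure.fold_change
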