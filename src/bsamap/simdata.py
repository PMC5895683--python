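"""Forward simulator of an EMS bulked-segregant mapping experiment.

The simulated design mirrors a MutMap+-style study: an EMS-mutagenised
line, isogenic except for one residual heterozygous window, is selfed; the
progeny segregate 3:1 for a recessive causal SNP inside that window.
Phenotype-selected pools (mutant and wild-type siblings) are "sequenced"
by depth-limited read sampling, yielding the pooled per-SNP allele depths
the rest of the package consumes. Ground truth (every SNP, the causal
locus, true pool allele frequencies, per-plant genotypes) is retained so
downstream statistics can be verified against it.

Model summary
-------------
* Mutagenesis plants ``ems_snp_count`` SNPs at distinct uniform positions,
  with ref>alt pairs drawn from an EMS substitution spectrum (default 85%
  G:C>A:T transitions, the canonical EMS signature, remainder uniform over
  the other substitutions). One SNP is the designated causal site.
* SNPs within ``linked_window_bp`` of the causal locus on its chromosome
  segregate (the selfed parent is heterozygous there); all others are
  homozygous in both pools (alternate-allele frequency 1 relative to the
  reference genome).
* Meiosis follows Haldane's model: per gamete, crossover count is
  Poisson(recomb_rate x window length) with uniform breakpoints, no
  interference. Phenotype is recessive: mutant iff homozygous alternate at
  the causal SNP; the expected mutant fraction is 1/4.
* Pooling takes exactly ``n_per_pool`` plants of each phenotype class
  without replacement. Per SNP and pool, total depth ~ Poisson(mean_depth)
  and alternate depth ~ Binomial(depth, f), where f is the pool's true
  alternate frequency, optionally perturbed by a per-read error rate that
  flips each read's allele.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .pooled_variants import PoolCounts, PooledSNP, write_counts_tsv

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
_ALL_SUBS = [(r, a) for r in "ACGT" for a in "ACGT" if r != a]

#: Canonical EMS signature: mostly G:C>A:T transitions.
DEFAULT_EMS_SPECTRUM: dict[str, float] = {"G:C>A:T": 0.85, "other": 0.15}


class Population(Enum):
    SELFED_HET = "SELFED_HET"   # M3 heterozygote selfed -> isogenic M4
    F2_CROSS = "F2_CROSS"       # F1 heterozygote selfed -> F2


class SNPClass(Enum):
    BACKGROUND_HOM = "BACKGROUND_HOM"
    SEGREGATING = "SEGREGATING"


class Phenotype(Enum):
    WILD = "WILD"
    DWARF = "DWARF"


@dataclass
class SimConfig:
    """Experimental-design parameters.

    Defaults follow the study design this package re-implements: pools of
    45 plants each at 50x expected depth from an M4 population of 214
    selfed progeny, a soybean-like recombination rate of 2.5e-8 M/bp, and
    a ±10-Mb residual-heterozygosity window around the causal locus.
    """

    chrom_lengths: list[tuple[str, int]]
    ems_snp_count: int
    causal: tuple[str, int]
    n_per_pool: int = 45
    mean_depth: float = 50.0
    population: Population = Population.SELFED_HET
    recomb_rate: float = 2.5e-8
    ems_spectrum: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EMS_SPECTRUM)
    )
    linked_window_bp: int = 10_000_000
    n_plants: int = 214
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lens = dict(self.chrom_lengths)
        if any(n <= 0 for n in lens.values()):
            raise ValueError("zero- or negative-length chromosome")
        chrom, pos = self.causal
        if chrom not in lens:
            raise ValueError(f"causal chromosome {chrom!r} not in chrom_lengths")
        if not 1 <= pos <= lens[chrom]:
            raise ValueError(f"causal position {pos} outside {chrom}")
        if self.n_per_pool < 1:
            raise ValueError("n_per_pool must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")
        if self.ems_snp_count < 1:
            raise ValueError("ems_snp_count must be >= 1")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        total = sum(self.ems_spectrum.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"ems_spectrum probabilities sum to {total}, not 1")

    @property
    def genome_size(self) -> int:
        return sum(n for _, n in self.chrom_lengths)

    def window(self) -> tuple[str, int, int]:
        """(chrom, start, end) of the segregating window, clipped to the
        causal chromosome."""
        chrom, pos = self.causal
        length = dict(self.chrom_lengths)[chrom]
        return (
            chrom,
            max(1, pos - self.linked_window_bp),
            min(length, pos + self.linked_window_bp),
        )


@dataclass
class SimSNP:
    chrom: str
    pos: int
    ref_base: str
    alt_base: str
    snp_class: SNPClass
    true_f_wt_alt: float | None = None
    true_f_mut_alt: float | None = None


@dataclass
class SimTruth:
    """Ground truth emitted by the simulator.

    ``individuals`` is an (n_plants, n_segregating) alternate-allele dosage
    matrix over the SNPs indexed by ``seg_indices``; background-homozygous
    SNPs have dosage 2 in every plant and are not stored per plant.
    """

    snps: list[SimSNP]
    causal_index: int
    seg_indices: np.ndarray | None = None
    individuals: np.ndarray | None = None
    phenotypes: list[Phenotype] | None = None
    wt_pool: np.ndarray | None = None
    mut_pool: np.ndarray | None = None

    @property
    def causal(self) -> SimSNP:
        return self.snps[self.causal_index]


def _expand_spectrum(
    spectrum: Mapping[str, float]
) -> tuple[list[str], np.ndarray, dict[str, list[tuple[str, str]]]]:
    """Expand mutation-class labels into (ref, alt) substitution lists.

    ``"G:C>A:T"`` names a complementary transition pair (G>A and C>T),
    ``"T>A"`` a single substitution together with its complement (A>T),
    and ``"other"`` covers every substitution not claimed by another class,
    uniformly.
    """
    classes: dict[str, list[tuple[str, str]]] = {}
    claimed: set[tuple[str, str]] = set()
    for label in spectrum:
        if label == "other":
            continue
        if ":" in label:
            refs, alts = label.split(">")
            r1, r2 = refs.split(":")
            a1, a2 = alts.split(":")
            pairs = [(r1, a1), (r2, a2)]
        else:
            r, a = label.split(">")
            pairs = [(r, a), (_COMPLEMENT[r], _COMPLEMENT[a])]
            pairs = list(dict.fromkeys(pairs))
        for p in pairs:
            if p[0] == p[1] or p[0] not in "ACGT" or p[1] not in "ACGT":
                raise ValueError(f"bad substitution {p} in class {label!r}")
        classes[label] = pairs
        claimed.update(pairs)
    if "other" in spectrum:
        classes["other"] = [p for p in _ALL_SUBS if p not in claimed]
    labels = list(classes)
    probs = np.array([spectrum[l] for l in labels], dtype=float)
    return labels, probs, classes


def _rng(config: SimConfig, stage: int) -> np.random.Generator:
    # independent, reproducible stream per stage
    return np.random.default_rng([stage, config.seed])


def simulate_mutagenesis(config: SimConfig) -> SimTruth:
    """Plant EMS SNPs across the genome and designate the causal site.

    ``ems_snp_count`` distinct positions are drawn uniformly (chromosomes
    weighted by length); the configured causal position is always one of
    them — a background draw colliding with it is reassigned
    deterministically to the nearest free base. SNPs inside the linked
    window are SEGREGATING, all others BACKGROUND_HOM with true alternate
    frequency 1 in both pools.
    """
    rng = _rng(config, 0)
    labels, probs, classes = _expand_spectrum(config.ems_spectrum)
    chroms = [c for c, _ in config.chrom_lengths]
    lengths = np.array([n for _, n in config.chrom_lengths], dtype=float)
    weights = lengths / lengths.sum()
    causal_chrom, causal_pos = config.causal

    taken: set[tuple[str, int]] = {(causal_chrom, causal_pos)}
    sites: list[tuple[str, int]] = []
    n_background = config.ems_snp_count - 1
    while len(sites) < n_background:
        k = n_background - len(sites)
        idx = rng.choice(len(chroms), size=k, p=weights)
        for i in range(k):
            c = chroms[int(idx[i])]
            clen = dict(config.chrom_lengths)[c]
            p = int(rng.integers(1, clen + 1))
            site = (c, p)
            if site in taken:
                # collision (incl. with the causal site): nearest free base,
                # lower coordinate preferred
                for d in range(1, clen):
                    for q in (p - d, p + d):
                        if 1 <= q <= clen and (c, q) not in taken:
                            site = (c, q)
                            break
                    if site != (c, p):
                        break
            taken.add(site)
            sites.append(site)
    sites.append((causal_chrom, causal_pos))
    sites.sort()

    _, win_start, win_end = config.window()
    snps: list[SimSNP] = []
    for chrom, pos in sites:
        lab = labels[int(rng.choice(len(labels), p=probs))]
        ref, alt = classes[lab][int(rng.integers(len(classes[lab])))]
        segregating = chrom == causal_chrom and win_start <= pos <= win_end
        cls = SNPClass.SEGREGATING if segregating else SNPClass.BACKGROUND_HOM
        snp = SimSNP(chrom=chrom, pos=pos, ref_base=ref, alt_base=alt, snp_class=cls)
        if cls is SNPClass.BACKGROUND_HOM:
            snp.true_f_wt_alt = snp.true_f_mut_alt = 1.0
        snps.append(snp)
    causal_index = sites.index((causal_chrom, causal_pos))
    truth = SimTruth(snps=snps, causal_index=causal_index)
    truth.seg_indices = np.array(
        [i for i, s in enumerate(snps) if s.snp_class is SNPClass.SEGREGATING],
        dtype=int,
    )
    return truth


def simulate_population(truth: SimTruth, config: SimConfig) -> SimTruth:
    """Self the heterozygous parent and genotype/phenotype each plant.

    Each of ``config.n_plants`` progeny receives two independent gametes;
    a gamete is a mosaic of the two parental haplotypes over the
    segregating window (haplotype 1 carries every alternate allele), with
    Poisson crossover counts and uniform breakpoints (Haldane, no
    interference). Both population designs (selfed M3 heterozygote and F2
    from a cross) reduce to one selfing of a heterozygote and share this
    implementation. A plant is DWARF iff homozygous alternate at the
    causal SNP.
    """
    if truth.seg_indices is None:
        raise ValueError("run simulate_mutagenesis first")
    rng = _rng(config, 1)
    seg = truth.seg_indices
    positions = np.array([truth.snps[i].pos for i in seg], dtype=float)
    causal_col = int(np.where(seg == truth.causal_index)[0][0])
    _, win_start, win_end = config.window()
    win_len = float(win_end - win_start)
    mean_x = config.recomb_rate * win_len

    n = config.n_plants
    dosage = np.zeros((n, len(seg)), dtype=np.int8)
    for i in range(n):
        geno = np.zeros(len(seg), dtype=np.int8)
        for _gamete in range(2):
            n_x = rng.poisson(mean_x)
            start_hap = int(rng.integers(2))
            if n_x == 0:
                hap = np.full(len(seg), start_hap, dtype=np.int8)
            else:
                breaks = np.sort(rng.uniform(win_start, win_end, size=n_x))
                hap = (start_hap + np.searchsorted(breaks, positions)) % 2
            geno += hap.astype(np.int8)
        dosage[i] = geno
    truth.individuals = dosage
    truth.phenotypes = [
        Phenotype.DWARF if dosage[i, causal_col] == 2 else Phenotype.WILD
        for i in range(n)
    ]
    return truth


class InsufficientPlantsError(RuntimeError):
    pass


def pool_and_sample(truth: SimTruth, config: SimConfig) -> list[PooledSNP]:
    """Form the phenotype pools and sample pooled read depths.

    Exactly ``n_per_pool`` DWARF and ``n_per_pool`` WILD plants are drawn
    without replacement (an explicit error names the deficient class).
    True pool allele frequencies (mean dosage / 2 over pooled plants) are
    written back onto ``truth.snps``; read depths are then sampled per SNP
    and pool.
    """
    if truth.individuals is None or truth.phenotypes is None:
        raise ValueError("run simulate_population first")
    rng = _rng(config, 2)
    phen = np.array([p is Phenotype.DWARF for p in truth.phenotypes])
    dwarf_idx = np.flatnonzero(phen)
    wild_idx = np.flatnonzero(~phen)
    for name, idx in (("DWARF", dwarf_idx), ("WILD", wild_idx)):
        if len(idx) < config.n_per_pool:
            raise InsufficientPlantsError(
                f"need {config.n_per_pool} {name} plants, population has "
                f"{len(idx)}"
            )
    mut_pool = np.sort(rng.choice(dwarf_idx, size=config.n_per_pool, replace=False))
    wt_pool = np.sort(rng.choice(wild_idx, size=config.n_per_pool, replace=False))
    truth.mut_pool, truth.wt_pool = mut_pool, wt_pool

    seg = truth.seg_indices
    f_mut_seg = truth.individuals[mut_pool][:, :].mean(axis=0) / 2.0
    f_wt_seg = truth.individuals[wt_pool][:, :].mean(axis=0) / 2.0
    seg_col = {int(s): j for j, s in enumerate(seg)}

    eps = config.error_rate
    out: list[PooledSNP] = []
    for i, snp in enumerate(truth.snps):
        if snp.snp_class is SNPClass.SEGREGATING:
            snp.true_f_wt_alt = float(f_wt_seg[seg_col[i]])
            snp.true_f_mut_alt = float(f_mut_seg[seg_col[i]])
        counts = []
        for f in (snp.true_f_wt_alt, snp.true_f_mut_alt):
            depth = int(rng.poisson(config.mean_depth))
            f_eff = f * (1 - eps) + (1 - f) * eps
            alt = int(rng.binomial(depth, f_eff)) if depth > 0 else 0
            counts.append(PoolCounts(ref_depth=depth - alt, alt_depth=alt))
        out.append(
            PooledSNP(
                chrom=snp.chrom, pos=snp.pos, ref_base=snp.ref_base,
                alt_base=snp.alt_base, wt=counts[0], mut=counts[1],
            )
        )
    return out


# ---------------------------------------------------------------------------
# fixture emission: toy reference, gene models, and serialised records

def toy_config(seed: int = 0, **overrides) -> SimConfig:
    """A scaled-down genome preserving the study's pooling design.

    Four 200-kb chromosomes; the causal SNP mid-chromosome-2 with a ±50-kb
    segregating window; recomb_rate 5e-6 M/bp so the window's genetic
    length (~0.5 M) matches the full-size design; SNP density raised so the
    window holds ~50 segregating SNPs. Pools stay at 45 + 45 plants and
    50x depth; the population is 400 plants so both phenotype classes are
    always large enough to pool.
    """
    params = dict(
        chrom_lengths=[("chr1", 200_000), ("chr2", 200_000),
                       ("chr3", 200_000), ("chr4", 200_000)],
        ems_snp_count=400,
        causal=("chr2", 100_000),
        n_per_pool=45,
        mean_depth=50.0,
        recomb_rate=5e-6,
        linked_window_bp=50_000,
        n_plants=400,
        seed=seed,
    )
    params.update(overrides)
    return SimConfig(**params)


def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    return {
        chrom: rng.integers(0, 4, size=length).astype(np.uint8)
        for chrom, length in config.chrom_lengths
    }


_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE2IDX = {b: i for i, b in enumerate("ACGT")}


def _genome_to_str(genome: dict[str, np.ndarray]) -> dict[str, str]:
    return {c: _IDX2BASE[a].tobytes().decode() for c, a in genome.items()}


def _place_genes(
    truth: SimTruth, config: SimConfig
) -> list[dict]:
    """Lay out toy gene models over the simulated genome.

    One two-exon plus-strand gene contains the causal SNP; single-exon
    plus-strand genes cover every second segregating SNP outside an
    exclusion zone of 0.4 x window half-width around the causal locus (so
    candidate filtering faces coding competitors, but at genetic distances
    where recombination in the mapping population can separate them from
    the causal allele — competitors inside the zone would be effectively
    inseparable at any realistic pool depth); one two-exon minus-strand
    gene sits on chr1 clear of any SNP. Returns dicts with gene_id/chrom/
    strand/exons/cds, coordinates 1-based inclusive.
    """
    causal = truth.causal
    p = causal.pos
    genes = [
        {
            "gene_id": "toyg0001",
            "chrom": causal.chrom,
            "strand": "+",
            # CDS 30 + 33 bp; the causal base sits mid-codon at
            # genomic (p-1, p, p+1)
            "cds": [(p - 50, p - 21), (p - 10, p + 22)],
            "exons": [(p - 55, p - 21), (p - 10, p + 30)],
        }
    ]
    occupied = [(p - 55, p + 30)]
    snp_positions = {(s.chrom, s.pos) for s in truth.snps}

    # minus-strand two-exon gene on chr1, shifted off any SNP
    start = 5_000
    while any((("chr1", q) in snp_positions) for q in range(start - 5, start + 100)):
        start += 137
    genes.append(
        {
            "gene_id": "toyg0002",
            "chrom": "chr1",
            "strand": "-",
            "cds": [(start, start + 29), (start + 50, start + 82)],
            "exons": [(start, start + 29), (start + 50, start + 90)],
        }
    )

    n = 3
    exclusion = int(0.4 * config.linked_window_bp)
    kept = 0
    for i in truth.seg_indices:
        s = truth.snps[int(i)]
        if int(i) == truth.causal_index or abs(s.pos - p) < exclusion:
            continue
        kept += 1
        if kept % 2:
            continue
        q = s.pos
        lo, hi = q - 30, q + 32  # 63-bp single-exon CDS
        clen = dict(config.chrom_lengths)[s.chrom]
        if lo < 1 or hi > clen:
            continue
        if any(not (hi < a or lo > b) for a, b in occupied):
            continue
        genes.append(
            {
                "gene_id": f"toyg{n:04d}",
                "chrom": s.chrom,
                "strand": "+",
                "cds": [(lo, hi)],
                "exons": [(lo, hi)],
            }
        )
        occupied.append((lo, hi))
        n += 1
    return genes


def _force_nonsynonymous_causal(
    genome: dict[str, np.ndarray], truth: SimTruth
) -> None:
    """Adjust the two codon neighbours of the causal base so its ref>alt
    substitution is nonsynonymous (never touching other SNP positions)."""
    from .annotate import translate

    causal = truth.causal
    arr = genome[causal.chrom]
    p = causal.pos
    snp_positions = {s.pos for s in truth.snps if s.chrom == causal.chrom}
    free = [q for q in (p - 1, p + 1) if q not in snp_positions]

    def codon(b_prev: str, b_next: str) -> tuple[str, str]:
        ref = b_prev + causal.ref_base + b_next
        alt = b_prev + causal.alt_base + b_next
        return ref, alt

    cur_prev = "ACGT"[int(arr[p - 2])]
    cur_next = "ACGT"[int(arr[p])]
    choices = []
    prev_opts = "ACGT" if (p - 1) in free else [cur_prev]
    next_opts = "ACGT" if (p + 1) in free else [cur_next]
    for bp in prev_opts:
        for bn in next_opts:
            ref_c, alt_c = codon(bp, bn)
            ra, aa = translate(ref_c), translate(alt_c)
            if ra != "*" and aa != "*" and ra != aa:
                choices.append((bp, bn))
    if not choices:  # pragma: no cover - requires both neighbours to be SNPs
        log.warning("could not force a nonsynonymous causal codon")
        return
    bp, bn = choices[0]
    arr[p - 2] = _BASE2IDX[bp]
    arr[p] = _BASE2IDX[bn]


def annotation_track(
    truth: SimTruth, config: SimConfig
) -> tuple[dict[str, str], list[dict]]:
    """Build a reference genome and toy gene models consistent with the
    simulated SNPs.

    The genome carries every SNP's ref base; the causal SNP sits mid-codon
    in a two-exon plus-strand gene and its substitution is guaranteed
    protein-changing. Returns (chrom -> sequence, gene dicts); convert the
    dicts with :func:`gene_models` for use with the annotation module.
    """
    rng = _rng(config, 3)
    genome = _random_genome(config, rng)
    for s in truth.snps:
        genome[s.chrom][s.pos - 1] = _BASE2IDX[s.ref_base]
    genes = _place_genes(truth, config)
    _force_nonsynonymous_causal(genome, truth)
    return _genome_to_str(genome), genes


def gene_models(gene_dicts: Sequence[dict]) -> list:
    from .annotate import GeneModel

    return [
        GeneModel(
            gene_id=g["gene_id"], chrom=g["chrom"], strand=g["strand"],
            exons=tuple(g["exons"]), cds=tuple(g["cds"]),
        )
        for g in gene_dicts
    ]


def _write_fasta(genome: dict[str, str], path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def _write_gff3(genes: list[dict], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gid = g["gene_id"]
            span = (min(s for s, _ in g["exons"]), max(e for _, e in g["exons"]))
            base = f"{g['chrom']}\ttoy\t"
            tail = f"\t.\t{g['strand']}\t"
            fh.write(f"{base}gene\t{span[0]}\t{span[1]}{tail}.\tID={gid}\n")
            fh.write(
                f"{base}mRNA\t{span[0]}\t{span[1]}{tail}.\t"
                f"ID={gid}.t1;Parent={gid}\n"
            )
            for s, e in g["exons"]:
                fh.write(f"{base}exon\t{s}\t{e}{tail}.\tParent={gid}.t1\n")
            segs = g["cds"] if g["strand"] == "+" else list(reversed(g["cds"]))
            done = 0
            for s, e in segs:
                phase = (3 - done % 3) % 3
                fh.write(f"{base}CDS\t{s}\t{e}{tail}{phase}\tParent={gid}.t1\n")
                done += e - s + 1


def _write_vcf(
    snps: Sequence[PooledSNP], config: SimConfig, path: Path
) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in config.chrom_lengths:
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description='
            '"Allelic depths for the ref and alt alleles">\n'
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            "wt_pool\tmut_pool\n"
        )
        for s in snps:
            fh.write(
                f"{s.chrom}\t{s.pos}\t.\t{s.ref_base}\t{s.alt_base}\t.\tPASS"
                f"\t.\tAD:DP\t{s.wt.ref_depth},{s.wt.alt_depth}:{s.wt.total}"
                f"\t{s.mut.ref_depth},{s.mut.alt_depth}:{s.mut.total}\n"
            )


def _write_truth_tsv(truth: SimTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tclass\ttrue_f_wt_alt\ttrue_f_mut_alt\tcausal\n")
        for i, s in enumerate(truth.snps):
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.ref_base}\t{s.alt_base}\t"
                f"{s.snp_class.value}\t{s.true_f_wt_alt:.6f}\t"
                f"{s.true_f_mut_alt:.6f}\t{int(i == truth.causal_index)}\n"
            )


def _marker_fixture(
    truth: SimTruth, config: SimConfig, n_markers: int = 7, max_plants: int = 140
) -> tuple[list[tuple[str, str, int]], list[tuple[str, str, str]]]:
    """Pick marker SNPs across the window (the causal SNP is always one of
    them, mirroring markers developed from the identified SNPs) and
    genotype the recessive-class plants at them."""
    seg = truth.seg_indices
    causal_col = int(np.where(seg == truth.causal_index)[0][0])
    cols = sorted(set(
        np.linspace(0, len(seg) - 1, n_markers).astype(int).tolist() + [causal_col]
    ))
    positions = [
        ("M%02d" % (k + 1), truth.snps[int(seg[c])].chrom, truth.snps[int(seg[c])].pos)
        for k, c in enumerate(cols)
    ]
    dwarf = [i for i, p in enumerate(truth.phenotypes) if p is Phenotype.DWARF]
    dwarf = dwarf[:max_plants]
    call_map = {2: "A", 1: "H", 0: "B"}
    genos = []
    for i in dwarf:
        for k, c in enumerate(cols):
            genos.append(
                (f"plant{i:04d}", "M%02d" % (k + 1),
                 call_map[int(truth.individuals[i, c])])
            )
    return positions, genos


def emit_fixtures(
    outdir: str | Path, config: SimConfig | None = None
) -> dict[str, Path]:
    """Run the full simulation and write every artifact the pipeline reads.

    Writes into ``outdir``: ``reference.fa`` (toy genome consistent with
    every SNP's ref base; the causal codon is guaranteed protein-changing),
    ``genes.gff3``, ``pooled_counts.tsv``, ``pooled.vcf``, ``truth.tsv``,
    ``markers.tsv`` + ``marker_positions.tsv`` (recessive-class genotypes),
    ``segregation.tsv`` (population phenotype counts), and, under
    ``study/``, the packaged worked tables from the soybean dwarf mapping
    study. Fixed seed => byte-identical outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config = config or toy_config()

    truth = simulate_mutagenesis(config)
    simulate_population(truth, config)
    snps = pool_and_sample(truth, config)

    genome_str, genes = annotation_track(truth, config)

    paths = {
        "reference": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "counts": outdir / "pooled_counts.tsv",
        "vcf": outdir / "pooled.vcf",
        "truth": outdir / "truth.tsv",
        "markers": outdir / "markers.tsv",
        "marker_positions": outdir / "marker_positions.tsv",
        "segregation": outdir / "segregation.tsv",
    }
    _write_fasta(genome_str, paths["reference"])
    _write_gff3(genes, paths["gff3"])
    write_counts_tsv(snps, paths["counts"])
    _write_vcf(snps, config, paths["vcf"])
    _write_truth_tsv(truth, paths["truth"])

    positions, genos = _marker_fixture(truth, config)
    with open(paths["marker_positions"], "w") as fh:
        fh.write("marker_id\tchrom\tpos\n")
        for mid, chrom, pos in positions:
            fh.write(f"{mid}\t{chrom}\t{pos}\n")
    with open(paths["markers"], "w") as fh:
        fh.write("plant_id\tmarker_id\tcall\n")
        for pid, mid, call in genos:
            fh.write(f"{pid}\t{mid}\t{call}\n")
    n_dwarf = sum(1 for p in truth.phenotypes if p is Phenotype.DWARF)
    with open(paths["segregation"], "w") as fh:
        fh.write("cross\tn_wild\tn_mutant\n")
        fh.write(f"simulated\t{len(truth.phenotypes) - n_dwarf}\t{n_dwarf}\n")

    from . import study

    study_dir = outdir / "study"
    study_dir.mkdir(exist_ok=True)
    for name in study.TABLE_FILES:
        (study_dir / name).write_text(study.raw_table(name))
        paths[f"study/{name}"] = study_dir / name
    return paths
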