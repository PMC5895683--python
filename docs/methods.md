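# Methods

This note documents the statistical model, the simulator, the default
parameters and the numerical choices behind `bsamap`. It states no result
that the test suite or `scripts/acceptance.py` does not itself compute.

## The mapping model

The package targets the classic mapping-by-sequencing design for a
monogenic recessive mutant from an EMS-mutagenised, otherwise isogenic
line (a MutMap+-style setup):

1. A plant heterozygous at the causal locus is selfed; progeny segregate
   3:1 wild : mutant. A χ² goodness-of-fit against the 3:1 expectation
   (df = 1, upper tail, **no continuity correction**) confirms
   monogenic recessive inheritance. The correction is deliberately
   omitted: with it, observed counts such as 97:31 give χ² ≈ 0.01
   rather than the conventional 0.04 reported for this design.
2. Phenotype-selected pools (n plants each) are sequenced. Per SNP the
   alternate-allele frequencies `f_mut`, `f_wt` are read-count ratios,
   and the ED statistic `sqrt(2)·|f_mut − f_wt|` measures pool
   divergence. At a recessive causal SNP the mutant pool is fixed
   (`f_mut = 1`) while selected wild-type siblings are a 1:2 mixture of
   homozygous-reference and heterozygous plants, so `E[f_wt] = 1/3` and
   `E[ED] → sqrt(2)·2/3 ≈ 0.9428` as depth and pool size grow.
3. SNPs with ED above a threshold seed candidate intervals; consecutive
   seeds within `max_gap_bp` merge, and intervals with fewer than
   `min_snps` seeds are dropped. Interval bounds are the outermost seed
   SNP positions (no padding), and lengths in kb are **truncated**, not
   rounded (a 92,994-bp span is 92 kb) — matching how such interval
   tables are conventionally printed.
4. Recessive-class linkage mapping: only phenotypically mutant F2 plants
   are genotyped. Calls are `A` (homozygous mutant-parent allele), `H`,
   `B`; recombinants are counted both as plants (any non-`A` call, the
   number a mapping paper quotes) and as chromosomes (`H` = 1, `B` = 2),
   the latter giving the recombination-fraction estimator
   `chromosomes / (2·plants)`. The refined interval is bounded by the
   nearest flanking markers showing ≥ 1 recombinant; a recombinant
   marker strictly inside the cosegregating span is rejected as a data
   inconsistency.
5. Scan intervals that do not overlap the linkage interval are flagged
   `EXCLUDED_BY_LINKAGE` (the false-positive exclusion that motivates
   combining the two maps); the surviving interval is intersected with
   the linkage interval.
6. Candidate nomination inside the mapped interval: keep
   protein-changing SNPs (nonsynonymous / stop-gain / stop-loss) in
   interval genes; require the mutant pool to be pure for the alternate
   allele (reference reads ≤ `purity_max_ref`, default 0) and the
   wild-type pool not homozygous-alternate; rank by category severity,
   then mutant-pool purity, then ED, ties by position.

## Key defaults

| parameter | default | rationale |
|---|---|---|
| ED threshold | 0.259 | the cutoff used in the soybean dwarf study this package replays; its derivation is not published, so `threshold_from_null` offers fixed / quantile (q = 0.995) / median + 3·SD alternatives |
| ED power k | 1 | raw ED matches the 0.259 cutoff's scale; k > 1 (e.g. ED⁴) is common elsewhere and configurable |
| interval merge gap | 1 Mb | no merge rule is published; 1 Mb keeps sparse isolated seeds from forming intervals |
| min seeds / interval | 2 | a single noisy SNP should not found an interval |
| per-pool depth filter | 10 | the published "high-quality SNP" criterion is unstated; 10 reads per pool is surfaced in config |
| genotype call: min depth | 5 | below 5 reads a pool call is NO_CALL |
| genotype call: het reads / fraction | 2 / 0.10 | chosen so every published pool-genotype call of the nine-SNP fine-mapping table is reproduced; the minor-fraction bound must lie in (3/40, 6/56] ≈ (0.075, 0.107] for that, hence 0.10 |
| up/downstream flank | 2 kb | tabulated "up-/downstream" effects come without a stated distance; 2 kb is the common promoter-proximal convention |
| t test | Welch | only "Student's t test" is stated for the summary-statistics comparisons; Welch is the safer default, pooled variance available |

Marker positions printed in Mb at two decimals are treated as exact
bp × 10⁶ for interval arithmetic, with Mb results reported at one decimal
(so 10.19–16.91 Mb spans 6.7 Mb, and its intersection with the
chromosome-8 scan interval spans 4.3 Mb).

## The forward simulator

`simdata` generates the full experiment with known ground truth:

* **Mutagenesis** — `ems_snp_count` SNPs at distinct uniform positions
  (chromosomes weighted by length). Substitutions follow an EMS spectrum,
  default 85 % G:C→A:T transitions with the remaining 15 % uniform over
  other substitutions; the spectrum is configurable (the real causal
  change here was a T>A transversion). One SNP is the designated causal
  site.
* **Isogenic-background model** — only SNPs within `linked_window_bp`
  (default ±10 Mb) of the causal locus segregate; all others are
  homozygous in both pools (alternate frequency 1 against the reference
  genome). The window width is a modelling choice: the physical extent of
  residual heterozygosity in the selfed parent is not published; ±10 Mb
  comfortably covers the observed chromosome-8 interval.
* **Meiosis** — Haldane model: per gamete, crossovers ~
  Poisson(`recomb_rate` × window length) with uniform breakpoints, no
  interference; one exchange process per gamete. Default rate
  2.5 × 10⁻⁸ M/bp (a soybean-like genome-wide average). Both supported
  population designs (selfed M3 heterozygote; F2 from a cross) reduce to
  one selfing of a heterozygote over the segregating window.
* **Phenotype** — strictly recessive: mutant iff homozygous alternate at
  the causal SNP; expected mutant fraction 1/4.
* **Pooling and sequencing** — exactly `n_per_pool` plants per phenotype
  class (default 45), sampled without replacement from a population of
  `n_plants` (default 214, the M4 population size of the modelled study);
  per SNP and pool, total depth ~ Poisson(`mean_depth`, default 50) and
  alternate depth ~ Binomial(depth, f), with an optional per-read error
  rate ε that flips each read's allele (default 0). All outputs are
  byte-identical under a fixed seed; each stage draws from its own
  seeded stream.
* **Annotation track** — a toy reference genome (consistent with every
  SNP's reference base) and gene models: the causal SNP sits mid-codon in
  a two-exon plus-strand gene and its substitution is forced to be
  protein-changing (codon neighbours adjusted, never touching other SNP
  positions); a two-exon minus-strand gene exercises strand-aware
  annotation; single-exon "competitor" genes cover every second
  segregating SNP outside an exclusion zone of 0.4 × the window
  half-width around the causal locus. The zone exists because a coding
  SNP genetically closer than ~1/(pool depth) Morgans is inseparable from
  the causal allele by read purity at any realistic depth — competitors
  are placed where the recessive-class design can, in principle,
  distinguish them, which is the property worth testing.

### Scaled problem sizes

Tests and the acceptance script run a scaled genome chosen for
desk-speed: four 200-kb chromosomes, a ±50-kb segregating window, and
recombination rate 5 × 10⁻⁶ M/bp so the window's genetic length (~0.5 M)
matches the full-scale design; SNP density is raised to ~0.5/kb so the
window holds ~50 segregating SNPs. Pool sizes (45 + 45) and depth (50×)
are kept at the study's values. Simulated populations for the recovery
properties use 400 plants so both phenotype classes essentially always
hold 45 plants (at the historical 214, roughly one seed in eleven would
legitimately lack 45 mutants and pooling would error).

### What the simulator does and does not emulate

It reproduces the segregation structure, pooled allele-frequency signal,
depth noise, and recombination geometry of the design. It does **not**
model read-level artefacts (base-calling error beyond the scalar ε,
mapping bias, paralog collapse), variant-calling error, indels, or
multi-generation pedigrees. Passing tests therefore demonstrate the
statistical machinery is correct under the idealised design, not that a
real experiment's noisier variant calls would behave as cleanly — notably
the real study's rejected competitor SNP showed a mutant-pool frequency
far from the tight-linkage expectation, a pattern (likely a calling or
residual-heterozygosity artefact) the simulator does not generate.

## Numerical and degenerate-input choices

* Allele frequency at zero depth is an explicit error
  (`ZeroDepthError`); depth filters must run first.
* Genotype calls with equal ref/alt depths below the het thresholds
  report HET rather than picking an allele arbitrarily.
* `codon_effect` validates the reference base at the SNP position against
  the record (a mismatch raises, guarding coordinate bugs) and computes
  `residue_index = ceil(cds_pos / 3)`; minus-strand CDS coordinates count
  from the 3′-most genomic base.
* Exonic-but-noncoding (UTR) positions are reported INTRONIC with a
  `utr` note, keeping the published category set intact.
* When several genes apply to a SNP the most severe context wins
  (exonic > intronic > flanking), ties broken by distance then gene id.
* Interval calling on unsorted input sorts with a logged notice;
  interval equality in tests is exact, not approximate.
* The empirical threshold methods refuse fewer than 100 scores.
* With an empty interval gene list the candidate filter warns and skips
  only the gene-membership test; the coding-change requirement stays
  (severity ranking is meaningless for non-coding SNPs).

## Known limitations

* SNP-only: indels are skipped on input (counted in the log). The
  modelled study likewise found no indels in its final interval.
* One transcript per gene (the first mRNA; logged when more exist); no
  splice-site disruption calls.
* No smoothing/sliding window over ED and no SNP-index-style confidence
  bands; the interval caller works on raw per-SNP scores.
* The genome-wide SNP totals and the derivation of the 0.259 threshold
  in the original experiment depend on raw reads that are not public;
  they are out of scope here and replaced by the simulator-based
  properties the acceptance script reports.
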