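"""Forward simulator: mutagenesis, inheritance, pooling, and emission."""
import hashlib
from collections import Counter

import numpy as np
import pytest

from bsamap import simdata
from bsamap.simdata import (
    InsufficientPlantsError,
    Phenotype,
    SimConfig,
    SNPClass,
    pool_and_sample,
    simulate_mutagenesis,
    simulate_population,
)

from conftest import tiny_config


class TestSimulateMutagenesis:
    def test_count_and_single_causal(self):
        cfg = tiny_config(seed=7, ems_snp_count=100)
        truth = simulate_mutagenesis(cfg)
        assert len(truth.snps) == 100
        assert len({(s.chrom, s.pos) for s in truth.snps}) == 100
        assert truth.causal.pos == 25_000 and truth.causal.chrom == "c2"

    def test_degenerate_spectrum(self):
        cfg = tiny_config(seed=2, ems_spectrum={"G:C>A:T": 1.0})
        truth = simulate_mutagenesis(cfg)
        assert all(
            (s.ref_base, s.alt_base) in {("G", "A"), ("C", "T")}
            for s in truth.snps
        )

    def test_default_spectrum_fraction(self):
        cfg = tiny_config(
            seed=1, ems_snp_count=10_000,
            chrom_lengths=[("c1", 500_000), ("c2", 500_000)],
            causal=("c2", 250_000),
        )
        truth = simulate_mutagenesis(cfg)
        gc_at = sum(
            (s.ref_base, s.alt_base) in {("G", "A"), ("C", "T")}
            for s in truth.snps
        )
        assert abs(gc_at / len(truth.snps) - 0.85) < 0.02

    def test_window_partitions_classes(self):
        cfg = tiny_config(seed=3)
        truth = simulate_mutagenesis(cfg)
        for s in truth.snps:
            in_window = s.chrom == "c2" and 15_000 <= s.pos <= 35_000
            expected = (
                SNPClass.SEGREGATING if in_window else SNPClass.BACKGROUND_HOM
            )
            assert s.snp_class is expected
        for s in truth.snps:
            if s.snp_class is SNPClass.BACKGROUND_HOM:
                assert s.true_f_wt_alt == s.true_f_mut_alt == 1.0

    def test_zero_length_chromosome_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(
                chrom_lengths=[("c1", 0)], ems_snp_count=5, causal=("c1", 1)
            )

    def test_bad_spectrum_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            tiny_config(ems_spectrum={"G:C>A:T": 0.5})


class TestSimulatePopulation:
    def test_dwarf_fraction_near_one_quarter(self):
        cfg = tiny_config(seed=3, n_plants=10_000)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        frac = sum(p is Phenotype.DWARF for p in truth.phenotypes) / 10_000
        assert 0.235 <= frac <= 0.265

    def test_no_recombination_gives_intact_haplotypes(self):
        cfg = tiny_config(seed=5, recomb_rate=0.0)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        causal_col = int(
            np.where(truth.seg_indices == truth.causal_index)[0][0]
        )
        for row in truth.individuals:
            assert np.all(row == row[causal_col])

    def test_dwarf_iff_homozygous_alternate_at_causal(self):
        cfg = tiny_config(seed=6)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        causal_col = int(
            np.where(truth.seg_indices == truth.causal_index)[0][0]
        )
        for i, phen in enumerate(truth.phenotypes):
            assert (phen is Phenotype.DWARF) == (
                truth.individuals[i, causal_col] == 2
            )

    def test_segregation_consistent_with_three_to_one(self):
        """3:1 goodness-of-fit is non-significant at alpha=0.01 in almost
        every simulated population of the study's size."""
        from bsamap.genetics import SegregationCount, chi_square_segregation

        failures = 0
        for seed in range(50):
            cfg = tiny_config(seed=seed, n_plants=214, ems_snp_count=20)
            truth = simulate_mutagenesis(cfg)
            simulate_population(truth, cfg)
            n_dwarf = sum(p is Phenotype.DWARF for p in truth.phenotypes)
            res = chi_square_segregation(
                SegregationCount(214 - n_dwarf, n_dwarf)
            )
            failures += res.p <= 0.01
        assert failures <= 2


class TestPoolAndSample:
    def test_background_sites_have_zero_reference_depth(self):
        cfg = tiny_config(seed=8)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        snps = pool_and_sample(truth, cfg)
        for sim_snp, pooled in zip(truth.snps, snps):
            if sim_snp.snp_class is SNPClass.BACKGROUND_HOM:
                assert pooled.wt.ref_depth == 0
                assert pooled.mut.ref_depth == 0

    def test_causal_mutant_pool_frequency_is_one(self):
        cfg = tiny_config(seed=9)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        pool_and_sample(truth, cfg)
        assert truth.causal.true_f_mut_alt == 1.0

    def test_wild_pool_causal_frequency_near_one_third(self):
        """Selected wild siblings are a 1:2 mix of hom-ref and het, so the
        causal alternate frequency averages 1/3 (mean over 200 seeds)."""
        freqs = []
        for seed in range(200):
            cfg = tiny_config(seed=seed, ems_snp_count=20)
            truth = simulate_mutagenesis(cfg)
            simulate_population(truth, cfg)
            pool_and_sample(truth, cfg)
            freqs.append(truth.causal.true_f_wt_alt)
        assert abs(float(np.mean(freqs)) - 1 / 3) < 0.02

    def test_insufficient_plants_names_class(self):
        cfg = tiny_config(seed=10, n_plants=50, n_per_pool=45)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        with pytest.raises(InsufficientPlantsError, match="DWARF"):
            pool_and_sample(truth, cfg)

    def test_error_rate_perturbs_background_sites(self):
        cfg = tiny_config(seed=4, error_rate=0.05, mean_depth=100)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        snps = pool_and_sample(truth, cfg)
        ref_reads = sum(
            pooled.wt.ref_depth
            for sim_snp, pooled in zip(truth.snps, snps)
            if sim_snp.snp_class is SNPClass.BACKGROUND_HOM
        )
        assert ref_reads > 0


def test_causal_codon_forcing_with_adjacent_snp():
    """When another SNP occupies a causal-codon neighbour base, the codon
    adjustment must leave it untouched and still produce a protein-changing
    causal substitution (toy seed 317 has such an adjacency)."""
    from bsamap.annotate import CODING_CHANGING, classify_snp
    from bsamap.pooled_variants import PoolCounts, PooledSNP

    cfg = simdata.toy_config(seed=317)
    truth = simulate_mutagenesis(cfg)
    causal = truth.causal
    neighbours = {
        (s.chrom, s.pos) for s in truth.snps
    } & {(causal.chrom, causal.pos - 1), (causal.chrom, causal.pos + 1)}
    assert neighbours  # the seed exercises the adjacency path
    genome, gene_dicts = simdata.annotation_track(truth, cfg)
    models = simdata.gene_models(gene_dicts)
    snp = PooledSNP(causal.chrom, causal.pos, causal.ref_base,
                    causal.alt_base, PoolCounts(10, 5), PoolCounts(0, 15))
    assert classify_snp(snp, models, genome).category in CODING_CHANGING
    # the neighbour SNP's planted ref base survived the codon adjustment
    for chrom, pos in neighbours:
        ref_base = next(
            s.ref_base for s in truth.snps if (s.chrom, s.pos) == (chrom, pos)
        )
        assert genome[chrom][pos - 1] == ref_base


def _hash_tree(root):
    out = {}
    for p in sorted(root.rglob("*")):
        if p.is_file():
            out[p.relative_to(root)] = hashlib.sha256(p.read_bytes()).hexdigest()
    return out


class TestEmitFixtures:
    def test_fixed_seed_reproduces_byte_identical_outputs(self, tmp_path):
        cfg_a = simdata.toy_config(seed=42)
        cfg_b = simdata.toy_config(seed=42)
        simdata.emit_fixtures(tmp_path / "a", cfg_a)
        simdata.emit_fixtures(tmp_path / "b", cfg_b)
        assert _hash_tree(tmp_path / "a") == _hash_tree(tmp_path / "b")

    def test_counts_round_trip_matches_sampled_records(self, tmp_path):
        from bsamap.pooled_variants import read_counts_tsv

        cfg = simdata.toy_config(seed=13)
        truth = simulate_mutagenesis(cfg)
        simulate_population(truth, cfg)
        snps = pool_and_sample(truth, cfg)
        simdata.emit_fixtures(tmp_path, simdata.toy_config(seed=13))
        assert read_counts_tsv(tmp_path / "pooled_counts.tsv") == sorted(
            snps, key=lambda s: (s.chrom, s.pos)
        )

    def test_study_tables_included_with_nine_snps(self, sim_dir):
        table = (sim_dir / "study" / "mapping_region_snps.tsv").read_text()
        assert len(table.strip().splitlines()) == 10  # header + 9 records

    def test_reference_carries_every_ref_base(self, sim_dir):
        import pyfaidx

        from bsamap.pooled_variants import read_counts_tsv

        ref = pyfaidx.Fasta(str(sim_dir / "reference.fa"))
        for s in read_counts_tsv(sim_dir / "pooled_counts.tsv"):
            assert str(ref[s.chrom][s.pos - 1]).upper() == s.ref_base

    def test_causal_annotates_protein_changing(self, sim_dir):
        """The planted causal SNP must be a coding, protein-changing variant
        of its toy gene."""
        import pandas as pd

        from bsamap.annotate import CODING_CHANGING, classify_snp, read_gff3
        from bsamap.pooled_variants import read_counts_tsv

        truth = pd.read_csv(sim_dir / "truth.tsv", sep="\t")
        causal = truth[truth.causal == 1].iloc[0]
        genes = read_gff3(sim_dir / "genes.gff3")
        import pyfaidx

        ref = pyfaidx.Fasta(str(sim_dir / "reference.fa"))
        snp = next(
            s for s in read_counts_tsv(sim_dir / "pooled_counts.tsv")
            if s.chrom == causal.chrom and s.pos == causal.pos
        )
        ann = classify_snp(snp, genes, ref)
        assert ann.category in CODING_CHANGING
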