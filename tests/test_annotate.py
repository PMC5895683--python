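"""Codon translation, CDS coordinates, effect calls, and context classes."""
import pytest

from bsamap.annotate import (
    AnnotationContext,
    Category,
    GeneModel,
    OutsideCDSError,
    ReferenceMismatchError,
    cds_position,
    classify_snp,
    codon_effect,
    read_gff3,
    reverse_complement,
    spliced_cds,
    translate,
)
from bsamap.pooled_variants import PoolCounts, PooledSNP


def _seq_with(planted: dict[int, str], length: int = 5000) -> str:
    seq = ["A"] * length
    for pos, frag in planted.items():
        seq[pos - 1: pos - 1 + len(frag)] = list(frag)
    return "".join(seq)


@pytest.fixture()
def plus_gene():
    # two-exon gene with 5' UTR bases in exon 1 and 3' UTR in exon 2
    gene = GeneModel(
        gene_id="gA", chrom="t1", strand="+",
        exons=((1095, 1103), (1201, 1210)),
        cds=((1101, 1103), (1201, 1203)),
    )
    ref = {"t1": _seq_with({1101: "ATG", 1201: "TGG"})}
    return gene, ref


class TestTranslate:
    @pytest.mark.parametrize(
        "codon,aa", [("TGG", "W"), ("AGG", "R"), ("TGA", "*"), ("ATG", "M")]
    )
    def test_standard_code(self, codon, aa):
        assert translate(codon) == aa

    @pytest.mark.parametrize("bad", ["TGN", "TG", "TGGA", "U GG"])
    def test_ambiguous_rejected(self, bad):
        with pytest.raises(ValueError):
            translate(bad)


class TestCdsPosition:
    def test_plus_strand_cumulative(self, plus_gene):
        gene, _ = plus_gene
        assert cds_position(gene, 1101) == 1
        assert cds_position(gene, 1201) == 4
        assert cds_position(gene, 1203) == 6

    def test_intronic_is_none(self, plus_gene):
        gene, _ = plus_gene
        assert cds_position(gene, 1150) is None

    def test_minus_strand_counts_from_three_prime_end(self):
        gene = GeneModel(
            gene_id="gM", chrom="t1", strand="-",
            exons=((101, 103), (201, 203)), cds=((101, 103), (201, 203)),
        )
        assert cds_position(gene, 203) == 1
        assert cds_position(gene, 101) == 6


def _one_codon_gene(codon: str, chrom: str = "t1"):
    gene = GeneModel(
        gene_id="g1", chrom=chrom, strand="+",
        exons=((11, 13),), cds=((11, 13),),
    )
    ref = {chrom: _seq_with({11: codon}, length=30)}
    return gene, ref


class TestCodonEffect:
    def test_trp_to_arg_missense(self):
        # the causal substitution class of the dwarf allele: TGG (Trp)
        # with T>A at codon position 1 gives AGG (Arg)
        gene, ref = _one_codon_gene("TGG")
        ann = codon_effect(gene, ref, 11, "T", "A")
        assert ann.category is Category.NONSYNONYMOUS
        assert (ann.ref_aa, ann.alt_aa, ann.residue_index) == ("W", "R", 1)

    def test_synonymous_wobble(self):
        gene, ref = _one_codon_gene("GCT")
        ann = codon_effect(gene, ref, 13, "T", "C")
        assert ann.category is Category.SYNONYMOUS
        assert ann.ref_aa == ann.alt_aa == "A"

    def test_stop_gain(self):
        gene, ref = _one_codon_gene("TGG")
        ann = codon_effect(gene, ref, 12, "G", "A")
        assert ann.category is Category.STOP_GAIN
        assert ann.alt_aa == "*"

    def test_reference_mismatch_guard(self):
        gene, ref = _one_codon_gene("TGG")
        with pytest.raises(ReferenceMismatchError):
            codon_effect(gene, ref, 11, "C", "A")

    def test_outside_cds_rejected(self):
        gene, ref = _one_codon_gene("TGG")
        with pytest.raises(OutsideCDSError):
            codon_effect(gene, ref, 5, "A", "G")

    def test_residue_index_spans_exons(self, plus_gene):
        gene, ref = plus_gene
        ann = codon_effect(gene, ref, 1202, "G", "A")
        assert ann.residue_index == 2  # cds position 5 -> codon 2


def _snp(chrom, pos, ref="A", alt="G"):
    return PooledSNP(chrom, pos, ref, alt, PoolCounts(10, 0), PoolCounts(0, 10))


class TestClassifySnp:
    def test_intergenic_beyond_flank(self, plus_gene):
        gene, ref = plus_gene
        ann = classify_snp(_snp("t1", 4000), [gene], ref)
        assert ann.category is Category.INTERGENIC
        assert ann.gene_id is None

    def test_upstream_500bp_of_plus_gene(self, plus_gene):
        gene, ref = plus_gene
        ann = classify_snp(_snp("t1", 595), [gene], ref)
        assert ann.category is Category.UPSTREAM
        assert ann.gene_id == "gA"

    def test_downstream_of_plus_gene(self, plus_gene):
        gene, ref = plus_gene
        ann = classify_snp(_snp("t1", 1250), [gene], ref)
        assert ann.category is Category.DOWNSTREAM

    def test_intronic(self, plus_gene):
        gene, ref = plus_gene
        ann = classify_snp(_snp("t1", 1150), [gene], ref)
        assert ann.category is Category.INTRONIC
        assert ann.note is None

    def test_utr_reported_intronic_with_note(self, plus_gene):
        gene, ref = plus_gene
        ann = classify_snp(_snp("t1", 1097), [gene], ref)
        assert ann.category is Category.INTRONIC
        assert ann.note == "utr"

    def test_exonic_wins_over_overlapping_noncoding_context(self):
        coding = GeneModel(
            gene_id="gC", chrom="t1", strand="+",
            exons=((2001, 2063),), cds=((2001, 2063),),
        )
        other = GeneModel(
            gene_id="gD", chrom="t1", strand="+",
            exons=((1990, 2010), (2070, 2100)), cds=((2070, 2096),),
        )
        ref = {"t1": _seq_with({2001: "ATG"})}
        ann = classify_snp(_snp("t1", 2002, ref="T", alt="C"),
                           [other, coding], ref)
        assert ann.gene_id == "gC"
        assert ann.category in {Category.SYNONYMOUS, Category.NONSYNONYMOUS,
                                Category.STOP_GAIN, Category.STOP_LOSS}

    def test_no_residue_fields_for_non_exonic(self, plus_gene):
        gene, ref = plus_gene
        for pos in (595, 1150, 1250, 4000, 1097):
            ann = classify_snp(_snp("t1", pos), [gene], ref)
            assert ann.ref_aa is None and ann.alt_aa is None
            assert ann.residue_index is None


def _flip_gene(gene: GeneModel, length: int) -> GeneModel:
    flip = lambda seg: (length - seg[1] + 1, length - seg[0] + 1)
    return GeneModel(
        gene_id=gene.gene_id, chrom=gene.chrom,
        strand="+" if gene.strand == "-" else "-",
        exons=tuple(sorted(flip(s) for s in gene.exons)),
        cds=tuple(sorted(flip(s) for s in gene.cds)),
    )


class TestStrandDuality:
    """A minus-strand gene must behave exactly like the plus-strand gene of
    the reverse-complemented genome."""

    def _fixture(self):
        seq = _seq_with({101: "CATTGGCCA", 201: "GCTAGCTAA"}, length=400)
        gene = GeneModel(
            gene_id="gM", chrom="t2", strand="-",
            exons=((101, 109), (201, 209)), cds=((101, 109), (201, 209)),
        )
        return gene, {"t2": seq}

    def test_spliced_protein_matches_revcomp(self):
        gene, ref = self._fixture()
        flipped_ref = {"t2": reverse_complement(ref["t2"])}
        flipped = _flip_gene(gene, len(ref["t2"]))
        minus_cds = spliced_cds(gene, ref)
        plus_cds = spliced_cds(flipped, flipped_ref)
        assert minus_cds == plus_cds

    def test_effect_calls_match_under_flip(self):
        gene, ref = self._fixture()
        length = len(ref["t2"])
        flipped_ref = {"t2": reverse_complement(ref["t2"])}
        flipped = _flip_gene(gene, length)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for s, e in gene.cds:
            for pos in range(s, e + 1):
                base = ref["t2"][pos - 1]
                for alt in "ACGT":
                    if alt == base:
                        continue
                    a1 = codon_effect(gene, ref, pos, base, alt)
                    a2 = codon_effect(
                        flipped, flipped_ref, length - pos + 1,
                        comp[base], comp[alt],
                    )
                    assert (a1.category, a1.ref_aa, a1.alt_aa,
                            a1.residue_index) == (
                        a2.category, a2.ref_aa, a2.alt_aa, a2.residue_index)


def test_identity_substitution_is_synonymous_everywhere(plus_gene):
    """Substituting every CDS base by itself is exhaustively synonymous."""
    gene, ref = plus_gene
    for s, e in gene.cds:
        for pos in range(s, e + 1):
            base = ref["t1"][pos - 1]
            ann = codon_effect(gene, ref, pos, base, base)
            assert ann.category is Category.SYNONYMOUS
            assert ann.ref_aa == ann.alt_aa


class TestGff3Reader:
    def test_emitted_models_parse_and_validate(self, sim_dir):
        genes = read_gff3(sim_dir / "genes.gff3")
        assert len(genes) > 2
        by_id = {g.gene_id: g for g in genes}
        assert by_id["toyg0001"].strand == "+"
        assert len(by_id["toyg0001"].cds) == 2
        assert by_id["toyg0002"].strand == "-"

    def test_minus_strand_fixture_gene_protein_matches_revcomp(self, sim_dir):
        import pyfaidx

        genes = {g.gene_id: g for g in read_gff3(sim_dir / "genes.gff3")}
        gene = genes["toyg0002"]
        ref = pyfaidx.Fasta(str(sim_dir / "reference.fa"))
        chrom_seq = str(ref[gene.chrom][:])
        flipped = _flip_gene(gene, len(chrom_seq))
        flipped_ref = {gene.chrom: reverse_complement(chrom_seq)}
        assert spliced_cds(gene, {gene.chrom: chrom_seq}) == spliced_cds(
            flipped, flipped_ref
        )
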