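import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from caseinhap import consequence as cq, tables
from caseinhap.models import (
    GeneModel,
    ReferenceSequence,
    VariantRecord,
    revcomp,
)


def model(bundle, gene):
    return bundle.gene_model(gene)


class TestClassifyCoreSnps:
    def test_csn2_minus_strand_his_to_pro(self, default_bundle):
        v = VariantRecord("6", 87181619, "T", "G")
        c = cq.classify(v, model(default_bundle, "CSN2"),
                        default_bundle.reference)
        assert c.category == "missense"
        assert (c.ref_aa, c.alt_aa) == ("H", "P")
        assert (c.precursor_pos, c.mature_pos) == (82, 67)

    def test_csn3_ile_to_thr(self, default_bundle):
        v = VariantRecord("6", 87390576, "T", "C")
        c = cq.classify(v, model(default_bundle, "CSN3"),
                        default_bundle.reference)
        assert c.category == "missense"
        assert (c.ref_aa, c.alt_aa) == ("I", "T")

    def test_csn1s1_positions(self, default_bundle):
        v = VariantRecord("6", 87157262, "A", "G")
        _, _, ppos, mpos = cq.amino_acid_change(
            v, model(default_bundle, "CSN1S1"), default_bundle.reference)
        assert (ppos, mpos) == (207, 192)

    def test_csn3_mature_offset(self, default_bundle):
        v = VariantRecord("6", 87390632, "A", "G")
        _, _, ppos, mpos = cq.amino_acid_change(
            v, model(default_bundle, "CSN3"), default_bundle.reference)
        assert (ppos, mpos) == (176, 155)

    def test_signal_peptide_constant_within_gene(self, default_bundle):
        diffs = {}
        for snp in tables.CORE_SNPS:
            v = VariantRecord("6", snp.pos, snp.ref, snp.alt)
            _, _, ppos, mpos = cq.amino_acid_change(
                v, model(default_bundle, snp.gene), default_bundle.reference)
            diffs.setdefault(snp.gene, set()).add(ppos - mpos)
        assert all(len(d) == 1 for d in diffs.values())
        assert diffs["CSN3"] == {21}


class TestFixtureCategories:
    def test_placed_categories_reproduced(self, default_bundle, default_matrix):
        classified = cq.classify_all(default_matrix.variants,
                                     default_bundle.gene_models,
                                     default_bundle.reference)
        merged = classified.merge(default_bundle.placements,
                                  on="pos", suffixes=("", "_truth"))
        assert (merged.category == merged.category_truth).all()
        assert (merged.gene == merged.gene_truth).all()

    def test_partition_counts_sum_to_total(self, default_bundle, default_matrix):
        classified = cq.classify_all(default_matrix.variants,
                                     default_bundle.gene_models,
                                     default_bundle.reference)
        counts = cq.category_counts(classified)
        assert counts.sum() == default_matrix.n_variants
        assert set(classified.category) <= set(cq.CATEGORIES)

    def test_intron_snp(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        a, b = gm.introns[0]
        pos = a + 50
        v = VariantRecord("6", pos, default_bundle.reference.base(pos),
                          "A" if default_bundle.reference.base(pos) != "A" else "C")
        assert cq.classify(v, gm, default_bundle.reference).category == "intron"

    def test_engineered_synonymous_verified_by_translation(
            self, default_bundle, default_matrix):
        ref = default_bundle.reference
        syn = default_bundle.placements.query("category == 'synonymous'")
        assert len(syn) > 0
        for rec in syn.itertuples():
            gm = default_bundle.gene_model(rec.gene)
            codon_no, codon_pos = gm.codon_number(rec.pos)
            codon = [ref.base(gm.genomic_position((codon_no - 1) * 3 + k))
                     for k in (1, 2, 3)]
            alt_codon = list(codon)
            alt_codon[codon_pos - 1] = rec.alt
            codon, alt_codon = "".join(codon), "".join(alt_codon)
            if gm.strand == "-":
                codon = str(Seq(codon).complement())
                alt_codon = str(Seq(alt_codon).complement())
            assert (str(Seq(codon).translate())
                    == str(Seq(alt_codon).translate()))


class TestSpliceRegion:
    def test_five_bases_into_intron(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        a, _ = gm.introns[0]
        assert cq.splice_region_test(a + 4, gm) is True

    def test_twenty_bases_into_intron(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        a, _ = gm.introns[0]
        assert cq.splice_region_test(a + 19, gm) is False

    def test_junction_adjacent_exon_base(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        a, _ = gm.introns[0]
        assert cq.splice_region_test(a - 1, gm) is True

    def test_splice_precedence_over_coding(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        a, _ = gm.introns[0]
        pos = a - 1  # last CDS base of exon 1
        assert gm.in_cds(pos)
        ref = default_bundle.reference
        alt = "A" if ref.base(pos) != "A" else "C"
        c = cq.classify(VariantRecord("6", pos, ref.base(pos), alt), gm, ref)
        assert c.category == "splice_region"


class TestErrors:
    def test_out_of_scope(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        pos = gm.span[1] + 10_000
        v = VariantRecord("6", pos, "A", "G")
        with pytest.raises(cq.OutOfScopeError):
            cq.classify(v, gm, default_bundle.reference)

    def test_reference_mismatch(self, default_bundle):
        gm = model(default_bundle, "CSN1S1")
        pos = gm.introns[0][0] + 50
        base = default_bundle.reference.base(pos)
        wrong = "A" if base != "A" else "C"
        other = "G" if wrong != "G" else "T"
        with pytest.raises(cq.ReferenceMismatchError):
            cq.classify(VariantRecord("6", pos, wrong, other), gm,
                        default_bundle.reference)


class TestStrandProperty:
    def test_mirrored_fixture_identical_amino_acid_calls(self, default_bundle):
        """Reverse-complementing the whole window and flipping strands must
        leave every coding call unchanged."""
        ref = default_bundle.reference
        T = ref.start + ref.end  # p' = T - p maps the window onto itself

        mirror_ref = ReferenceSequence(ref.name, ref.offset, revcomp(ref.seq))

        def flip_ivs(ivs):
            return sorted((T - b, T - a) for a, b in ivs)

        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for snp in tables.CORE_SNPS:
            gm = default_bundle.gene_model(snp.gene)
            mgm = GeneModel(
                gene_id=gm.gene_id, chrom=gm.chrom,
                strand="-" if gm.strand == "+" else "+",
                exons=flip_ivs(gm.exons), cds=flip_ivs(gm.cds),
                utr5=flip_ivs(gm.utr5), utr3=flip_ivs(gm.utr3),
                upstream_length=gm.upstream_length,
                signal_peptide=gm.signal_peptide)
            v = VariantRecord("6", snp.pos, snp.ref, snp.alt)
            mv = VariantRecord("6", T - snp.pos, comp[snp.ref], comp[snp.alt])
            orig = cq.amino_acid_change(v, gm, ref)
            mirrored = cq.amino_acid_change(mv, mgm, mirror_ref)
            assert orig == mirrored


class TestDensity:
    def test_hand_computed_density(self):
        df = cq.snp_density({"G": {"intron": 15}},
                            {"G": {"upstream": 1000, "intron": 10296,
                                   "exon": 500, "missense": 500,
                                   "synonymous": 500}})
        assert df.loc["G", "intron"] == 14.6  # 15 / 10296 * 1e4 by hand

    def test_zero_snps(self):
        df = cq.snp_density({"G": {}},
                            {"G": {r: 1000 for r in cq.DENSITY_REGIONS}})
        assert (df.loc["G"] == 0.0).all()

    def test_nonpositive_length_error(self):
        with pytest.raises(Exception):
            cq.snp_density({"G": {"intron": 1}},
                           {"G": {r: 0 for r in cq.DENSITY_REGIONS}})

    def test_fixture_density_matches_hand_computation(
            self, default_bundle, default_matrix):
        classified = cq.classify_all(default_matrix.variants,
                                     default_bundle.gene_models,
                                     default_bundle.reference)
        df = cq.density_table(classified, default_bundle.gene_models)
        lengths = cq.region_lengths(default_bundle.gene_models)
        for gm in default_bundle.gene_models:
            sub = classified[(classified.gene == gm.gene_id)
                             & (classified.category == "intron")]
            expect = round(len(sub) / lengths[gm.gene_id]["intron"] * 1e4, 1)
            assert df.loc[gm.gene_id, "intron"] == expect
        # exon column = coding SNPs (missense + synonymous)
        for gm in default_bundle.gene_models:
            row = df.loc[gm.gene_id]
            sub = classified[classified.gene == gm.gene_id]
            n_cod = (sub.category.isin(["missense", "synonymous"])).sum()
            assert row["exon"] == round(n_cod / lengths[gm.gene_id]["exon"] * 1e4, 1)
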