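"""Codon translation and strand-aware amino-acid effect annotation."""

import pytest

from bsaseq import annotate as ann
from bsaseq.synthetic import GeneModel, GenomeAssembly, PolymorphicSite, _revcomp


@pytest.mark.parametrize(
    "codon,aa",
    [("GCA", "Ala"), ("GGA", "Gly"), ("CCC", "Pro"), ("AAC", "Asn"),
     ("TAA", "Ter"), ("ATG", "Met"), ("TTT", "Phe"), ("AAA", "Lys")],
)
def test_translate_standard_code(codon, aa):
    assert ann.translate(codon) == aa


def test_translate_rejects_non_acgt():
    with pytest.raises(ann.AnnotationError):
        ann.translate("ANG")
    with pytest.raises(ann.AnnotationError):
        ann.translate("AT")


def _plus_gene(cds: str, flank: int = 30):
    seq = "A" * flank + cds + "T" * flank
    asm = GenomeAssembly({"c": seq})
    gene = GeneModel("g", "c", "+", ((flank, flank + len(cds)),))
    return asm, gene, flank


def _minus_gene(cds: str, flank: int = 30):
    seq = "C" * flank + _revcomp(cds) + "G" * flank
    asm = GenomeAssembly({"c": seq})
    gene = GeneModel("g", "c", "-", ((flank, flank + len(cds)),))
    return asm, gene, flank


CDS = "ATG" + "GGT" * 177 + "CCC" + "GGT" * 10 + "GCT" + "AAA" + "TCA"  # no stop, Ala/Lys near end


class TestSubstitutions:
    def test_mnv_in_one_codon_is_single_change(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 178 * 3  # codon 179 = CCC
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, "CC", "AA", "MNV", "g"), gene, asm
        )
        assert (e.effect, e.notation) == ("missense", "Pro179Asn")
        assert (e.coding_codon_before, e.coding_codon_after) == ("CCC", "AAC")
        assert e.aa_position == 179

    def test_minus_strand_reverse_complement(self):
        """Plus-strand TTT>GTT on a minus-strand gene is coding AAA>AAC."""
        cds = "ATG" + "GGT" * 5 + "AAA" + "GGT" * 5
        asm, gene, _ = _minus_gene(cds)
        gp = gene.genomic_positions()
        codon_pos = sorted(gp[18:21])  # codon 7 = AAA
        assert asm["c"][codon_pos[0] : codon_pos[-1] + 1] == "TTT"
        e = ann.annotate_effect(
            PolymorphicSite("c", codon_pos[0], "T", "G", "SNV", "g"), gene, asm
        )
        assert e.effect == "missense"
        assert (e.aa_before, e.aa_after) == ("Lys", "Asn")
        assert (e.genomic_triplet_before, e.genomic_triplet_after) == ("TTT", "GTT")
        assert (e.coding_codon_before, e.coding_codon_after) == ("AAA", "AAC")

    def test_wobble_substitution_is_synonymous(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + len(CDS) - 9 + 2  # third base of GCT (Ala)
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, "T", "C", "SNV", "g"), gene, asm
        )
        assert e.effect == "synonymous"
        assert e.aa_before == e.aa_after == "Ala"
        assert e not in ann.filter_nonsynonymous([e])

    def test_stop_gained(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + len(CDS) - 6  # AAA codon -> TAA
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, "A", "T", "SNV", "g"), gene, asm
        )
        assert e.effect == "stop_gained"
        assert e.aa_after == "Ter"

    def test_reference_identical_allele_is_synonymous_with_same_codons(self):
        class Stub:
            chrom, pos, ref_allele, alt_allele = "c", 33, "G", "G"

        asm, gene, _ = _plus_gene(CDS)
        e = ann.annotate_effect(Stub(), gene, asm)
        assert e.effect == "synonymous"
        assert e.coding_codon_before == e.coding_codon_after

    def test_intergenic_variant_marked_non_coding(self):
        asm, gene, _ = _plus_gene(CDS)
        e = ann.annotate_effect(
            PolymorphicSite("c", 3, "A", "G", "SNV", None), gene, asm
        )
        assert e.effect == "non_coding"
        assert not e.is_nonsynonymous


class TestIndels:
    def test_inframe_insertion_at_codon_boundary(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 3 * 19 - 1  # anchored on the last base of codon 19
        ref = asm["c"][pos]
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, ref, ref + "CCG", "INS", "g"), gene, asm
        )
        assert (e.effect, e.notation) == ("inframe_insertion", "19insPro")
        assert ann.position_label(e.pos, e.ref_allele, e.alt_allele) == f"{pos + 1}^{pos + 2}"

    def test_frameshift_insertion(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 10
        ref = asm["c"][pos]
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, ref, ref + "CG", "INS", "g"), gene, asm
        )
        assert e.effect == "frameshift"

    def test_inframe_deletion_of_whole_codons(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 3 * 6 - 1  # delete codons 7-8 (GGT GGT)
        ref = asm["c"][pos : pos + 7]
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, ref, ref[0], "DEL", "g"), gene, asm
        )
        assert e.effect == "inframe_deletion"
        assert e.notation == "Gly*2 7-8del"

    def test_frameshift_deletion(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 9
        ref = asm["c"][pos : pos + 2]
        e = ann.annotate_effect(
            PolymorphicSite("c", pos, ref, ref[0], "DEL", "g"), gene, asm
        )
        assert e.effect == "frameshift"

    def test_minus_strand_insertion_reverse_complemented(self):
        cds = "ATG" + "GGT" * 8
        asm, gene, _ = _minus_gene(cds)
        gp = gene.genomic_positions()
        # insert after coding position 11 (codon boundary at index 12)
        p_right = gp[12]  # genomic position of coding index 12 (minus strand)
        anchor = p_right  # genomic anchor: base whose coding index is 12
        ref = asm["c"][anchor]
        # plus-strand CGG inserted after anchor = coding CCG before index 12
        e = ann.annotate_effect(
            PolymorphicSite("c", anchor, ref, ref + "CGG", "INS", "g"), gene, asm
        )
        assert e.effect == "inframe_insertion"
        assert "Pro" in e.notation


class TestStructural:
    def test_exon_spanning_variant_unsupported(self):
        cds = "ATG" + "GGT" * 9
        seq = "A" * 20 + cds[:15] + "T" * 40 + cds[15:] + "A" * 20
        asm = GenomeAssembly({"c": seq})
        gene = GeneModel("g", "c", "+", ((20, 35), (75, 75 + len(cds) - 15)))
        e = ann.annotate_effect(
            PolymorphicSite("c", 34, seq[34 : 36], "AA" if seq[34:36] != "AA" else "CC", "MNV", "g"),
            gene, asm,
        )
        assert e.effect == "unsupported"

    def test_exon_junction_codon_annotated_across_intron(self):
        """A codon split by an intron still translates correctly."""
        cds = "ATG" + "CCA" * 9  # Pro codons
        # split inside codon 3 (coding indices 6..8): exon1 = 0..7, exon2 = 8..
        seq = "A" * 20 + cds[:7] + "G" * 30 + cds[7:] + "A" * 20
        asm = GenomeAssembly({"c": seq})
        gene = GeneModel("g", "c", "+", ((20, 27), (57, 57 + len(cds) - 7)))
        assert gene.coding_sequence(asm) == cds
        e = ann.annotate_effect(
            PolymorphicSite("c", 57, "C", "A", "SNV", "g"), gene, asm
        )  # coding index 7: codon 3 CCA -> CAA? index 7 is middle base of codon 3
        assert e.effect == "missense"
        assert e.aa_before == "Pro"
        assert e.exon_index == 2

    def test_reference_mismatch_rejected(self):
        asm, gene, _ = _plus_gene(CDS)
        with pytest.raises(ann.AnnotationError):
            ann.annotate_effect(
                PolymorphicSite("c", 35, "Z" if False else ("G" if asm["c"][35] != "G" else "C"), "T", "SNV", "g"),
                gene, asm,
            )


class TestRoundTripOnPlantedSites:
    def test_coding_codons_reproduce_reference_bases(self, parents):
        """For every planted coding SNV, the reported genomic triplet must
        equal the reference bases of that codon, and the coding codon its
        strand-corrected counterpart."""
        by_id = {g.gene_id: g for g in parents.genes}
        n_checked = 0
        for site in parents.sites:
            if not site.in_gene:
                continue
            gene = by_id[site.in_gene]
            e = ann.annotate_effect(site, gene, parents.recurrent)
            assert e.effect in ("synonymous", "missense", "stop_gained")
            assert e.genomic_triplet_before is not None
            expected = (
                e.coding_codon_before
                if gene.strand == "+"
                else _revcomp(e.coding_codon_before)
            )
            assert e.genomic_triplet_before == expected
            assert site.recurrent_allele in e.genomic_triplet_before
            n_checked += 1
        assert n_checked >= 10


def test_strand_duality_random_substitutions():
    """Annotating on a minus-strand gene equals annotating the reverse
    complement construction on the plus strand."""
    import numpy as np

    rng = np.random.default_rng(5)
    cds = "ATG" + "".join(
        rng.choice(["GGT", "CCA", "TTC", "AAA", "GCG"], size=30)
    )
    asm_p, gene_p, flank = _plus_gene(cds)
    asm_m, gene_m, _ = _minus_gene(cds)
    gp_m = gene_m.genomic_positions()
    for cds_idx in rng.integers(3, len(cds), size=25):
        cds_idx = int(cds_idx)
        ref_coding = cds[cds_idx]
        alt_coding = {"A": "G", "C": "T", "G": "A", "T": "C"}[ref_coding]
        e_plus = ann.annotate_effect(
            PolymorphicSite("c", flank + cds_idx, ref_coding, alt_coding, "SNV", "g"),
            gene_p, asm_p,
        )
        pos_m = gp_m[cds_idx]
        e_minus = ann.annotate_effect(
            PolymorphicSite(
                "c", pos_m,
                ref_coding.translate(str.maketrans("ACGT", "TGCA")),
                alt_coding.translate(str.maketrans("ACGT", "TGCA")),
                "SNV", "g",
            ),
            gene_m, asm_m,
        )
        assert (e_plus.effect, e_plus.notation) == (e_minus.effect, e_minus.notation)
        assert e_plus.coding_codon_before == e_minus.coding_codon_before


class TestMerging:
    def test_adjacent_snvs_in_one_codon_merge_to_mnv(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 178 * 3
        sites = [
            PolymorphicSite("c", pos, "C", "A", "SNV", "g"),
            PolymorphicSite("c", pos + 1, "C", "A", "SNV", "g"),
        ]
        merged = ann.merge_adjacent_substitutions(sites, [gene])
        assert len(merged) == 1
        assert merged[0].site_type == "MNV"
        e = ann.annotate_effect(merged[0], gene, asm)
        assert e.notation == "Pro179Asn"

    def test_substitutions_in_different_codons_not_merged(self):
        asm, gene, flank = _plus_gene(CDS)
        pos = flank + 178 * 3 + 2  # last base of codon 179, first of 180
        sites = [
            PolymorphicSite("c", pos, "C", "A", "SNV", "g"),
            PolymorphicSite("c", pos + 1, "G", "A", "SNV", "g"),
        ]
        merged = ann.merge_adjacent_substitutions(sites, [gene])
        assert len(merged) == 2
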