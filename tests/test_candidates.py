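"""Consensus extraction, three-way gene comparison, and TAV verification."""

import numpy as np
import pytest

from bsaseq import candidates as cand
from bsaseq.calling import SiteCounts
from bsaseq.synthetic import GeneModel, GenomeAssembly, _revcomp


@pytest.fixture()
def simple_gene():
    cds = "ATG" + "GCA" * 10 + "CCC" + "GCA" * 5  # 51 bp
    seq = "A" * 25 + cds + "T" * 25
    asm = GenomeAssembly({"c": seq})
    gene = GeneModel("g", "c", "+", ((25, 25 + len(cds)),))
    return asm, gene, cds


def _site(pos, ref, alt, depth, alt_count, label="HdL"):
    return SiteCounts("c", pos, ref, alt, depth, alt_count, label)


class TestConsensus:
    def test_identity_at_uniform_depth(self, simple_gene):
        asm, gene, cds = simple_gene
        cons = cand.extract_consensus(gene, asm, [], "HdL", 5, 50)
        assert cons.sequence == cds
        assert cons.masked_fraction == 0.0

    def test_low_depth_masks_with_n(self, simple_gene):
        asm, gene, cds = simple_gene
        counts = [_site(30, cds[5], "T" if cds[5] != "T" else "G", 4, 0)]
        cons = cand.extract_consensus(gene, asm, counts, "HdL", 5, 50)
        assert cons.sequence[5] == "N"
        assert cons.masked_fraction == pytest.approx(1 / len(cds))

    def test_majority_alt_enters_consensus(self, simple_gene):
        asm, gene, cds = simple_gene
        counts = [_site(28, cds[3], "T", 40, 24)]  # 60% alternate
        cons = cand.extract_consensus(gene, asm, counts, "HdL", 5, 50)
        assert cons.sequence[3] == "T"

    def test_tie_resolves_to_reference(self, simple_gene):
        asm, gene, cds = simple_gene
        counts = [_site(28, cds[3], "T", 40, 20)]  # exactly 50%
        cons = cand.extract_consensus(gene, asm, counts, "HdL", 5, 50)
        assert cons.sequence[3] == cds[3]

    def test_uncovered_gene_is_all_n(self, simple_gene, caplog):
        asm, gene, cds = simple_gene
        with caplog.at_level("WARNING"):
            cons = cand.extract_consensus(gene, asm, [], "HdL", 5, 0)
        assert set(cons.sequence) == {"N"}
        assert cons.masked_fraction == 1.0

    def test_matches_bruteforce_majority_oracle(self, simple_gene):
        """Random per-site count matrices against a per-position tally."""
        asm, gene, cds = simple_gene
        rng = np.random.default_rng(9)
        for _ in range(20):
            pos = int(rng.integers(3, len(cds)))
            depth = int(rng.integers(0, 60))
            alt_count = int(rng.integers(0, depth + 1)) if depth else 0
            alt_base = "T" if cds[pos] != "T" else "G"
            counts = [_site(25 + pos, cds[pos], alt_base, depth, alt_count)]
            cons = cand.extract_consensus(gene, asm, counts, "HdL", 5, 50)
            if depth < 5:
                expected = "N"
            elif alt_count > depth - alt_count:
                expected = alt_base
            else:
                expected = cds[pos]
            assert cons.sequence[pos] == expected

    def test_minus_strand_consensus_is_coding_strand(self):
        cds = "ATG" + "GCA" * 6
        seq = "C" * 20 + _revcomp(cds) + "G" * 20
        asm = GenomeAssembly({"c": seq})
        gene = GeneModel("g", "c", "-", ((20, 20 + len(cds)),))
        gp = gene.genomic_positions()
        # alternate on the plus strand at coding index 4
        p = gp[4]
        plus_ref = seq[p]
        plus_alt = "A" if plus_ref != "A" else "G"
        cons = cand.extract_consensus(
            gene, asm, [_site(p, plus_ref, plus_alt, 40, 30)], "HdL", 5, 50
        )
        assert cons.sequence[4] == plus_alt.translate(str.maketrans("ACGT", "TGCA"))


class TestCompareGene:
    def test_identical_triple_gives_empty(self, simple_gene):
        _, _, cds = simple_gene
        low = cand.GeneConsensus("g", "HdL", cds, 0.0)
        high = cand.GeneConsensus("g", "HdH", cds, 0.0)
        assert cand.compare_gene("g", cds, low, high) == []

    def test_shared_nonref_classification(self, simple_gene):
        _, _, cds = simple_gene
        mutant = cds[:4] + "A" + cds[5:]
        low = cand.GeneConsensus("g", "HdL", mutant, 0.0)
        high = cand.GeneConsensus("g", "HdH", mutant, 0.0)
        (v,) = cand.compare_gene("g", cds, low, high)
        assert v.classification == "shared_nonref"
        assert v.low_allele == v.high_allele == "A"

    def test_segregating_missense(self, simple_gene):
        _, _, cds = simple_gene
        # GCA -> GGA at codon 2: Ala -> Gly, only in the high bulk
        mutant = cds[:4] + "G" + cds[5:]
        low = cand.GeneConsensus("g", "HdL", cds, 0.0)
        high = cand.GeneConsensus("g", "HdH", mutant, 0.0)
        (v,) = cand.compare_gene("g", cds, low, high)
        assert v.classification == "segregating"
        assert v.effect == "missense"
        assert v.notation == "Ala2Gly"

    def test_n_positions_skipped(self, simple_gene):
        _, _, cds = simple_gene
        low = cand.GeneConsensus("g", "HdL", "N" + cds[1:], 0.0)
        high = cand.GeneConsensus("g", "HdH", cds, 0.0)
        assert cand.compare_gene("g", cds, low, high) == []

    def test_length_changing_insertion_aligned(self, simple_gene):
        _, _, cds = simple_gene
        at = 33  # codon boundary
        mutant = cds[:at] + "GGG" + cds[at:]
        low = cand.GeneConsensus("g", "HdL", cds, 0.0)
        high = cand.GeneConsensus("g", "HdH", mutant, 0.0)
        variants = cand.compare_gene("g", cds, low, high)
        assert len(variants) == 1
        assert variants[0].kind == "INS"
        assert variants[0].classification == "segregating"
        assert variants[0].effect == "inframe_insertion"

    def test_fully_masked_inputs_warn_and_return_empty(self, simple_gene, caplog):
        _, _, cds = simple_gene
        low = cand.GeneConsensus("g", "HdL", "N" * len(cds), 1.0)
        high = cand.GeneConsensus("g", "HdH", "N" * len(cds), 1.0)
        with caplog.at_level("WARNING"):
            assert cand.compare_gene("g", cds, low, high) == []


class TestVerification:
    def test_verified_at_12_80(self):
        assert cand.verify_frequency_rule(12, 80, 40, 28, True)

    def test_not_verified_at_23_50(self):
        assert not cand.verify_frequency_rule(23, 50, 39, 39, True)

    def test_synonymous_never_eligible(self):
        assert not cand.verify_frequency_rule(5, 95, 40, 40, False)

    def test_hom_het_by_category(self):
        assert cand.verify_frequency_rule(100, 21, 39, 39, True)

    def test_missing_coverage_stays_unverified(self):
        assert not cand.verify_frequency_rule(10, 90, None, None, True)

    def test_shared_nonref_never_in_tav_output(self, simple_gene):
        _, _, cds = simple_gene
        mutant = cds[:4] + "G" + cds[5:]
        low = cand.GeneConsensus("g", "HdL", mutant, 0.0)
        high = cand.GeneConsensus("g", "HdH", mutant, 0.0)
        (v,) = cand.compare_gene("g", cds, low, high)
        v.low_freq, v.high_freq, v.low_cov, v.high_cov = 95.0, 95.0, 40, 40
        (out,) = cand.verify_candidate_tavs([v])
        assert out.classification == "shared_nonref"
        assert not out.verified_tav


class TestPanel:
    def test_empty_panel_rows(self):
        rows, missing = cand.run_candidate_panel(["g1", "g2"], {"g1": [], "g2": []})
        assert all(r["total_variants"] == 0 for r in rows)
        assert missing == []

    def test_missing_gene_listed_and_run_continues(self, caplog):
        with caplog.at_level("WARNING"):
            rows, missing = cand.run_candidate_panel(["g1", "ghost"], {"g1": []})
        assert missing == ["ghost"]
        assert len(rows) == 1


def test_agreement_with_association_path(simple_gene):
    """A segregating candidate SNV receives the same category and TAV
    status as the genome-wide association route."""
    from bsaseq import association as assoc
    from bsaseq.calling import BulkComparison, SiteCounts

    _, _, cds = simple_gene
    low_freq, high_freq, low_cov, high_cov = 12.0, 80.0, 50, 40
    verified = cand.verify_frequency_rule(low_freq, high_freq, low_cov, high_cov, True)

    alt_l = assoc.reconstruct_alt_count(low_freq, low_cov)
    alt_h = assoc.reconstruct_alt_count(high_freq, high_cov)
    pair = BulkComparison(
        "c", 1, "A", "G",
        SiteCounts("c", 1, "A", "G", low_cov, alt_l, "HdL"),
        SiteCounts("c", 1, "A", "G", high_cov, alt_h, "HdH"),
    )
    (rec,) = assoc.select_tavs(assoc.build_records([pair]))
    assert rec.is_tav == verified
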