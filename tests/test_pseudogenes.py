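import numpy as np
import pytest

from degenome import simulate
from degenome.orthologs import OrthologPair, find_orthologs
from degenome.pseudogenes import (InvalidOrfError, Thresholds, classify_cds,
                                  classify_genome, detect_mutations)

from conftest import random_dna, random_orf


class TestDetectMutations:
    def test_identical_sequences_yield_no_mutations(self, rng):
        orf = random_orf(100, rng)
        scan = detect_mutations(orf, orf)
        assert scan.mutations == []
        assert scan.span == 1.0

    def test_single_deletion_reported_at_affected_codon(self, rng):
        orf = random_orf(100, rng)
        der = orf[: 3 * 49] + orf[3 * 49 + 1 :]  # delete 1 nt in codon 50
        scan = detect_mutations(der, orf)
        kinds = [(m.type, m.position_codon) for m in scan.mutations]
        assert kinds == [("frameshift_indel", 50)]

    def test_single_insertion_reported(self, rng):
        orf = random_orf(100, rng)
        der = orf[: 3 * 29] + "G" + orf[3 * 29 :]
        scan = detect_mutations(der, orf)
        assert [(m.type, m.position_codon) for m in scan.mutations] == [
            ("frameshift_indel", 30)]

    def test_premature_stop_caa_to_taa(self, rng):
        orf = random_orf(100, rng)
        orf = orf[: 3 * 29] + "CAA" + orf[3 * 30 :]
        der = orf[: 3 * 29] + "TAA" + orf[3 * 30 :]
        scan = detect_mutations(der, orf)
        assert [(m.type, m.position_codon) for m in scan.mutations] == [
            ("premature_stop", 30)]

    def test_stop_adjacent_substitution_is_ignored(self, rng):
        """A stop arising within the final three sense codons is treated as
        stop-adjacent noise, not an inactivating mutation."""
        orf = random_orf(100, rng)
        orf = orf[: 3 * 97] + "CAA" + orf[3 * 98 :]  # codon 98 of 100
        der = orf[: 3 * 97] + "TAA" + orf[3 * 98 :]
        assert detect_mutations(der, orf).mutations == []

    def test_scrambled_tail_typed_as_truncation(self, rng):
        orf = random_orf(120, rng)
        cut = 3 * 60
        der = orf[:cut] + random_dna(len(orf) - cut, rng)
        scan = detect_mutations(der, orf)
        types = {m.type for m in scan.mutations}
        assert "truncation" in types
        trunc = [m for m in scan.mutations if m.type == "truncation"][0]
        assert abs(trunc.position_codon - 61) <= 3
        assert scan.span < 0.99

    def test_is_insertion_typed_when_library_given(self, rng):
        orf = random_orf(150, rng)
        lib = {c.name: c.seq for c in simulate.make_is_library(3)}
        ins = lib["ISync2"]
        der = orf[: 3 * 70] + ins + orf[3 * 70 :]
        scan = detect_mutations(der, orf, is_library=lib)
        assert [(m.type, m.position_codon) for m in scan.mutations] == [
            ("is_interruption", 71)]

    def test_invalid_reference_orf_rejected(self, rng):
        with pytest.raises(InvalidOrfError):
            detect_mutations("ATGAAATAA", "CCCAAATAA")  # no start codon
        with pytest.raises(InvalidOrfError):
            detect_mutations("ATGAAATAA", "ATGAAACCC")  # no stop codon

    def test_context_does_not_create_false_calls(self, rng):
        orf = random_orf(150, rng)
        der = random_dna(2500, rng) + orf + random_dna(2500, rng)
        scan = detect_mutations(der, orf)
        assert scan.mutations == [] and scan.span == 1.0


class TestSpanRules:
    def _pair(self, identity=1.0, coverage=1.0):
        return OrthologPair("r", "d", identity, coverage, True)

    def test_long_orf_truncated_to_two_thirds_is_pseudogene(self, rng):
        """300-nt reference spanning only 200 nt fails both the 99% and the
        short-ORF 90% branches."""
        orf = random_orf(100, rng)  # 300 nt
        scan = detect_mutations(orf[:200] + random_dna(2500, rng), orf)
        assert scan.span < 0.90
        assert any(m.type == "truncation" for m in scan.mutations)

    def test_short_orf_rule_accepts_92_percent_span(self, rng):
        """240-nt reference (<300 nt) spanning 220 nt with no inactivating
        mutation is intact under the 90% short-ORF branch."""
        orf = random_orf(80, rng)  # 240 nt
        scan = detect_mutations(orf[:220] + random_dna(2500, rng), orf)
        assert scan.mutations == []
        assert 0.90 < scan.span <= 220 / 240 + 0.01


class TestClassifyGenome:
    def test_identical_genomes_have_zero_pseudogenes(self, rng):
        cfg = simulate.AncestorConfig(genome_length=40_000, n_genes=25,
                                      seed=5, n_rrna_operons=1)
        anc, _ = simulate.generate_ancestor(cfg)
        pairs = find_orthologs(anc, anc, 0.0, 0.0)
        report = classify_genome(anc, anc, pairs)
        assert report.n_pseudo == 0
        assert report.fraction_pseudo == 0.0
        assert all(not c.mutations for c in report.classifications)

    def test_ledger_counts_recovered(self, small_pair):
        pairs = find_orthologs(small_pair["ancestor"],
                               small_pair["derived"], 0.0, 0.0)
        lib = {c.name: c.seq for c in small_pair["library"]}
        report = classify_genome(small_pair["derived"],
                                 small_pair["ancestor"], pairs,
                                 is_library=lib)
        rec, prec, n_truth, n_pred = simulate.score_classification(
            report, small_pair["ledger"])
        assert rec == 1.0
        assert prec == 1.0
        assert n_pred == n_truth
        # totals are column sums
        assert report.n_intact + report.n_pseudo + report.n_unresolved == \
            report.n_cds

    def test_verdict_invariant_no_intact_with_mutations(self, small_pair):
        pairs = find_orthologs(small_pair["ancestor"],
                               small_pair["derived"], 0.0, 0.0)
        report = classify_genome(small_pair["derived"],
                                 small_pair["ancestor"], pairs)
        for c in report.classifications:
            if c.verdict == "intact":
                assert not c.mutations
            if c.verdict == "pseudogene":
                assert c.mutations or c.span <= 0.99

    def test_missing_ortholog_is_unresolved(self, rng):
        cfg = simulate.AncestorConfig(genome_length=30_000, n_genes=18,
                                      seed=9, n_rrna_operons=1)
        anc, _ = simulate.generate_ancestor(cfg)
        report = classify_genome(anc, anc, pairs=[])
        assert all(c.verdict == "unresolved"
                   for c in report.classifications)


def test_threshold_monotonicity(rng):
    """Raising the fast-path identity/length thresholds never converts a
    pseudogene verdict to intact."""
    orf = random_orf(120, rng)
    der = orf[: 3 * 50] + orf[3 * 50 + 1 :]  # frameshifted derived gene
    from degenome.genome_io import AnnotatedGenome, Feature

    ref_g = AnnotatedGenome("r", random_dna(100, rng) + orf +
                            random_dna(100, rng), True,
                            [Feature("CDS", 100, 100 + len(orf), "+", "g")])
    der_g = AnnotatedGenome("d", random_dna(100, rng) + der +
                            random_dna(100, rng), True,
                            [Feature("CDS", 100, 100 + len(der), "+", "g")])
    pair = OrthologPair("g", "g", 0.95, 1.0, True)
    base = classify_cds(pair, der_g, ref_g, Thresholds())
    assert base.verdict == "pseudogene"
    for fi, fl in [(0.95, 0.9), (0.99, 0.99)]:
        harder = classify_cds(pair, der_g, ref_g,
                              Thresholds(fast_identity=fi, fast_length=fl))
        assert harder.verdict == "pseudogene"
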