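import numpy as np
import pytest

from degenome import simulate
from degenome.genome_io import AnnotatedGenome, Feature, revcomp
from degenome.mobile import (annotate_is, detect_duplications,
                             genic_intervals, intergenic_clustering_test)

from conftest import random_dna


@pytest.fixture(scope="module")
def library():
    return simulate.make_is_library(17)


def _genome_with_inserts(library, positions, rng, L=30_000, disrupted=()):
    seq = random_dna(L, rng)
    out = seq
    offset = 0
    for i, pos in enumerate(sorted(positions)):
        cons = library[i % len(library)]
        ins = cons.seq
        if i in disrupted:
            cut = cons.orf_start + 200
            ins = ins[:cut] + ins[cut + 1 :]
        p = pos + offset
        out = out[:p] + ins + out[p:]
        offset += len(ins)
    return AnnotatedGenome("t", out, True, [])


class TestAnnotateIs:
    def test_exact_insertions_found_intact(self, library, rng):
        g = _genome_with_inserts(library, [5000, 15000, 25000], rng)
        anns = annotate_is(g, library)
        assert len(anns) == 3
        assert all(a.transposase_state == "intact" for a in anns)
        assert all(a.identity_to_family_consensus == 1.0 for a in anns)

    def test_frameshifted_transposase_is_disrupted(self, library, rng):
        g = _genome_with_inserts(library, [8000, 20000], rng, disrupted={1})
        anns = annotate_is(g, library)
        states = sorted(a.transposase_state for a in anns)
        assert states == ["disrupted", "intact"]

    def test_minus_strand_insertion_found(self, library, rng):
        cons = library[0]
        seq = random_dna(10_000, rng)
        seq = seq[:4000] + revcomp(cons.seq) + seq[4000:]
        anns = annotate_is(AnnotatedGenome("t", seq, True, []), library)
        assert len(anns) == 1
        assert anns[0].strand == "-"
        assert anns[0].start == 4000

    def test_identity_threshold_excludes_degraded_copy(self, library, rng):
        cons = library[0]
        degraded = list(cons.seq)
        n_mut = int(len(degraded) * 0.08)  # ~92% identity
        for i in rng.choice(len(degraded), size=n_mut, replace=False):
            degraded[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[degraded[i]]
        seq = random_dna(5000, rng) + "".join(degraded) + random_dna(5000, rng)
        g = AnnotatedGenome("t", seq, True, [])
        assert annotate_is(g, library, min_identity=0.94) == []
        assert len(annotate_is(g, library, min_identity=0.85)) == 1

    def test_empty_library_rejected(self, rng):
        g = AnnotatedGenome("t", random_dna(1000, rng), True, [])
        with pytest.raises(ValueError):
            annotate_is(g, [])

    def test_annotation_invariant_under_reverse_complement(self, library,
                                                           rng):
        g = _genome_with_inserts(library, [6000, 18000], rng)
        rc = AnnotatedGenome("rc", revcomp(g.sequence), True, [])
        a1 = annotate_is(g, library)
        a2 = annotate_is(rc, library)
        assert len(a1) == len(a2) == 2
        L = len(g)
        assert sorted((L - a.end, L - a.start) for a in a1) == \
            sorted((a.start, a.end) for a in a2)


def _toy_gene_genome(L=100_000, period=1000, genic=800):
    feats = []
    pos = 0
    i = 0
    while pos + period <= L:
        i += 1
        feats.append(Feature("CDS", pos + (period - genic), pos + period,
                             "+", f"g{i:04d}"))
        pos += period
    return AnnotatedGenome("toy", "A" * L, True, feats)


class TestClusteringTest:
    def test_fully_intergenic_genome_gives_p_one(self, rng):
        g = AnnotatedGenome("t", random_dna(10_000, rng), True, [])
        res = intergenic_clustering_test([100, 5000, 9000], g,
                                         n_perm=1000, seed=0)
        assert res.observed_intergenic_fraction == 1.0
        assert res.expected_fraction == 1.0
        assert res.p_value == 1.0

    def test_matches_closed_form_binomial(self):
        """10 IS all intergenic on a 20%-intergenic genome: exceedance
        probability 0.2^10; the raw Monte-Carlo estimate must sit within
        3 MC standard errors of it."""
        g = _toy_gene_genome()
        mids = [i * 1000 + 100 for i in range(10)]  # all in the gaps
        res = intergenic_clustering_test(mids, g, n_perm=100_000, seed=5)
        assert res.observed_intergenic_fraction == 1.0
        p0 = 0.2 ** 10
        se = np.sqrt(p0 * (1 - p0) / 100_000)
        assert abs(res.null_exceedance - p0) <= 3 * se

    def test_p_value_reproducible_given_seed(self):
        g = _toy_gene_genome(L=20_000)
        mids = [500, 1500, 2500, 10_100]
        a = intergenic_clustering_test(mids, g, n_perm=2000, seed=42)
        b = intergenic_clustering_test(mids, g, n_perm=2000, seed=42)
        assert a.p_value == b.p_value
        assert a.null_exceedance == b.null_exceedance

    def test_zero_sites_rejected(self):
        with pytest.raises(ValueError):
            intergenic_clustering_test([], _toy_gene_genome(), 1000, 0)

    def test_genic_intervals_merge_overlaps(self, rng):
        g = AnnotatedGenome("t", random_dna(1000, rng), True, [
            Feature("CDS", 10, 300, "+", "a"),
            Feature("tRNA", 250, 400, "+", "b"),
            Feature("rRNA_16S", 600, 900, "+", "c"),
        ])
        merged = genic_intervals(g)
        assert merged.tolist() == [[10, 400], [600, 900]]


class TestDuplications:
    def test_random_genome_has_no_duplications(self, rng):
        g = AnnotatedGenome("t", random_dna(60_000, rng), True, [])
        assert detect_duplications(g, min_len=2500) == []

    def test_engineered_duplication_counts(self, small_pair):
        lib = small_pair["library"]
        der = small_pair["derived"]
        anns = annotate_is(der, lib)
        dups = detect_duplications(der, is_annotations=anns)
        assert len(dups) == 1
        d = dups[0]
        assert d.length_nt == 13_476
        assert d.n_substitutions == 13
        assert d.n_indels == 4
        assert d.bounded_by_is
        assert d.bounding_family == "IS256"
        assert d.identity > 0.99

    def test_identity_threshold_excludes_diverged_pair(self, rng):
        unit = random_dna(4000, rng)
        mutated = list(unit)
        for i in rng.choice(len(unit), size=200, replace=False):  # ~95%
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        seq = (random_dna(3000, rng) + unit + random_dna(2000, rng)
               + "".join(mutated) + random_dna(3000, rng))
        g = AnnotatedGenome("t", seq, True, [])
        assert detect_duplications(g, min_len=2500, min_identity=0.99) == []
        found = detect_duplications(g, min_len=2500, min_identity=0.90)
        assert len(found) == 1

    def test_min_len_validated(self, rng):
        g = AnnotatedGenome("t", random_dna(5000, rng), True, [])
        with pytest.raises(ValueError):
            detect_duplications(g, min_len=100)
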