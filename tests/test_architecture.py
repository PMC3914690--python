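import numpy as np
import pytest

from degenome import simulate
from degenome.architecture import (DIF_HS, KopsSites, cumulative_skew_extrema,
                                   find_dif, find_kops, gc_skew, kops_polarity,
                                   skew_polarization_index)
from degenome.genome_io import revcomp, rotate

from conftest import random_dna


def test_skew_formula_on_homopolymers():
    g = gc_skew("G" * 200, window=100, step=100)
    assert np.allclose(g.values, 1.0)
    c = gc_skew("C" * 200, window=100, step=100)
    assert np.allclose(c.values, -1.0)
    at = gc_skew("AT" * 100, window=100, step=100)
    assert np.allclose(at.values, 0.0)
    assert at.flagged.all()


def test_skew_direct_small_window():
    t = gc_skew("GGC" + "A" * 197, window=100, step=100)
    # first window holds 2 G and 1 C: (2-1)/(2+1)
    assert t.values[0] == pytest.approx(1 / 3)


def test_skew_antisymmetry_under_reverse_complement(rng):
    seq = random_dna(5000, rng)
    fwd = gc_skew(seq, 500, 500).values
    rev = gc_skew(revcomp(seq), 500, 500).values
    assert np.allclose(fwd, -rev[::-1])


def test_ori_ter_recovered_on_biased_genome():
    """Leading-strand G bias of 0.05 on a 200-kb genome localizes ori and
    ter within two windows of the construction."""
    for seed in (0, 1, 2):
        cfg = simulate.AncestorConfig(genome_length=200_000, n_genes=140,
                                      seed=seed)
        anc, meta = simulate.generate_ancestor(cfg)
        rot = rotate(anc, 137_000)
        track = gc_skew(rot.sequence, 10_000, 5_000)
        ori, ter = cumulative_skew_extrema(track)
        true_ori = (meta.ori - 137_000) % len(anc)
        true_ter = (meta.ter - 137_000) % len(anc)
        assert abs(ori - true_ori) <= 2 * track.window
        assert abs(ter - true_ter) <= 2 * track.window


def test_polarization_index_extremes(rng):
    cfg = simulate.AncestorConfig(genome_length=200_000, n_genes=140, seed=4)
    anc, meta = simulate.generate_ancestor(cfg)
    track = gc_skew(anc.sequence, 10_000, 5_000)
    assert skew_polarization_index(track, meta.ori, meta.ter) >= 0.95
    # unbiased random sequence: index near 1/2
    null = gc_skew(random_dna(200_000, rng), 10_000, 5_000)
    assert skew_polarization_index(null, 0, 100_000) < 0.75


def test_unbiased_ancestor_has_no_polarization():
    cfg = simulate.AncestorConfig(genome_length=100_000, n_genes=70,
                                  skew_bias=0.0, seed=6)
    anc, meta = simulate.generate_ancestor(cfg)
    track = gc_skew(anc.sequence, 10_000, 5_000)
    assert skew_polarization_index(track, meta.ori, meta.ter) < 0.8


def test_kops_motif_scan_both_strands():
    seq = "TTGGGAAGGGTT"
    sites = find_kops(seq)
    assert sites.sites == [(2, "+")]
    sites_rc = find_kops(revcomp(seq))
    assert sites_rc.sites == [(2, "-")]


def test_kops_count_invariant_under_rotation(rng):
    cfg = simulate.AncestorConfig(genome_length=60_000, n_genes=40,
                                  n_kops=30, seed=8, n_rrna_operons=1)
    anc, _ = simulate.generate_ancestor(cfg)
    n0 = len(find_kops(anc.sequence).sites)
    # rotate at a point clear of any motif instance
    n1 = len(find_kops(rotate(anc, 33).sequence).sites)
    assert n0 == n1 == 30


def test_kops_polarity_fully_polarized_then_degraded():
    cfg = simulate.AncestorConfig(genome_length=100_000, n_genes=70,
                                  n_kops=40, kops_polarity=1.0, seed=12,
                                  n_rrna_operons=1)
    anc, meta = simulate.generate_ancestor(cfg)
    sites = find_kops(anc.sequence)
    assert len(sites.sites) == 40
    assert kops_polarity(sites, meta.ori, meta.ter, len(anc)) == 1.0
    params = simulate.DegenerationParams(p_pseudo=0.0, n_inversions=8,
                                         inversion_length=(3000, 15000),
                                         seed=12)
    der, ledger = simulate.degenerate(anc, params,
                                      simulate.make_is_library(12), meta)
    pol = kops_polarity(find_kops(der.sequence), ledger.final_ori,
                        ledger.final_ter, len(der))
    assert pol < 1.0


def test_polarity_complements_under_ori_ter_relabel():
    """Relabeling ori as ter reverses the expected orientation of every
    site, so polarity maps to its complement."""
    sites = KopsSites("GGGNAGGG", [(10, "+"), (60, "-"), (80, "-")])
    a = kops_polarity(sites, 0, 50, 100)
    b = kops_polarity(sites, 50, 0, 100)
    assert a + b == pytest.approx(1.0)


class TestDif:
    def test_embedded_dif_found_exactly(self, rng):
        seq = random_dna(4000, rng) + DIF_HS + random_dna(6000 - len(DIF_HS),
                                                          rng)
        hit = find_dif(seq)
        assert hit == (4000, "+", 0)

    def test_reverse_strand_hit(self, rng):
        seq = random_dna(3000, rng) + revcomp(DIF_HS) + random_dna(1000, rng)
        pos, strand, mm = find_dif(seq)
        assert (pos, strand, mm) == (3000, "-", 0)

    def test_boundary_mismatch_count(self, rng):
        mutated = list(DIF_HS)
        for i in (3, 9, 15, 21):
            mutated[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[mutated[i]]
        seq = random_dna(2000, rng) + "".join(mutated) + random_dna(500, rng)
        hit = find_dif(seq, max_mismatch=4)
        assert hit is not None and hit[2] == 4

    def test_absent_when_over_mismatch_budget(self, rng):
        assert find_dif(random_dna(20_000, rng), max_mismatch=4) is None

    def test_agrees_with_brute_force(self, rng):
        def brute(seq, query, max_mm):
            best = None
            for rank, q in enumerate((query, revcomp(query))):
                for p in range(len(seq) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(seq[p : p + len(q)], q))
                    cand = (mm, p, rank)
                    if best is None or cand < best:
                        best = cand
            if best is None or best[0] > max_mm:
                return None
            return best[1], "+-"[best[2]], best[0]

        for seed in range(3):
            r = np.random.default_rng(seed)
            seq = random_dna(5000, r)
            # embed a partially-degraded dif
            deg = list(DIF_HS)
            for i in list(r.choice(len(deg), size=int(r.integers(0, 5)),
                                   replace=False)):
                deg[i] = "ACGT"[int(r.integers(4))]
            pos = int(r.integers(0, 4000))
            seq = seq[:pos] + "".join(deg) + seq[pos + len(deg):]
            assert find_dif(seq) == brute(seq, DIF_HS, 4)

    def test_validation(self, rng):
        with pytest.raises(ValueError):
            find_dif("ACGT" * 100, dif_query="")
        with pytest.raises(ValueError):
            find_dif("ACGT" * 100, max_mismatch=10)
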