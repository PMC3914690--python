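"""One-to-one CDS orthology between a reference and a derived genome.

Orthology is established by reciprocal best hits (RBH).  Because the two
genomes are assumed closely related (a few percent nucleotide divergence),
the best-hit search runs on nucleotide CDS sequences — shared 12-mer seeding
to shortlist candidates, then global edit distance — which stays reliable
even when a coding sequence has been frameshifted or partially scrambled and
its translation is uninformative.  Protein identity and coverage for each
reciprocal pair are then computed from a BLOSUM62 global protein alignment
and used for the ``min_identity`` / ``min_coverage`` filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

from . import _align
from .genome_io import AnnotatedGenome, Feature

_SEED_K = 12
_MIN_SHARED_SEEDS = 2


@dataclass(frozen=True)
class OrthologPair:
    ref_locus: str
    der_locus: str
    protein_identity: float
    coverage_ref: float
    reciprocal: bool


def translate_cds(nt: str) -> str:
    """Translate, trimming the terminal stop; internal stops become '*'."""
    trimmed = nt[: len(nt) - len(nt) % 3]
    aa = str(Seq(trimmed).translate())
    return aa[:-1] if aa.endswith("*") else aa


def _candidate_features(genome: AnnotatedGenome) -> list[Feature]:
    # Mobile elements and phage are never orthology candidates.
    return genome.features_of_kind("CDS", "pseudogene")


def _seed_index(seqs: dict[str, str]) -> dict[str, set[str]]:
    index: dict[str, set[str]] = {}
    for tag, seq in seqs.items():
        for i in range(0, len(seq) - _SEED_K + 1, 4):
            index.setdefault(seq[i : i + _SEED_K], set()).add(tag)
    return index


def _best_hits(query_seqs: dict[str, str],
               subject_seqs: dict[str, str]) -> dict[str, str]:
    """Best subject per query by normalized global edit distance."""
    index = _seed_index(subject_seqs)
    best: dict[str, str] = {}
    for tag in sorted(query_seqs):
        seq = query_seqs[tag]
        counts: dict[str, int] = {}
        for i in range(len(seq) - _SEED_K + 1):
            for hit in index.get(seq[i : i + _SEED_K], ()):
                counts[hit] = counts.get(hit, 0) + 1
        if counts:
            # Rank by edit distance only among strong-seed candidates: a
            # large mobile-element insertion inflates global distance but
            # barely dents the shared-seed count.
            top = max(counts.values())
            candidates = [t for t, c in counts.items()
                          if c >= max(_MIN_SHARED_SEEDS, 0.3 * top)]
        else:
            candidates = []
        if not candidates:
            candidates = list(subject_seqs)
        scored = []
        for cand in sorted(candidates):
            d = _align.edit_distance(seq, subject_seqs[cand])
            scored.append((d / max(len(seq), len(subject_seqs[cand])), cand))
        scored.sort()
        best[tag] = scored[0][1]
    return best


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "global"
    return aligner


def protein_stats(ref_aa: str, der_aa: str) -> tuple[float, float]:
    """(identity over alignment columns, fraction of reference aligned)."""
    aligner = _protein_aligner()
    aln = aligner.align(ref_aa, der_aa)[0]
    ref_rows, der_rows = aln[0], aln[1]
    matches = sum(a == b and a != "-" for a, b in zip(ref_rows, der_rows))
    aligned_ref = sum(
        a != "-" and b != "-" for a, b in zip(ref_rows, der_rows)
    )
    return matches / len(ref_rows), aligned_ref / len(ref_aa)


def find_orthologs(ref: AnnotatedGenome, der: AnnotatedGenome,
                   min_identity: float = 0.9,
                   min_coverage: float = 0.8) -> list[OrthologPair]:
    """Reciprocal best hits between reference and derived CDSs.

    Deterministic: candidate ties are broken by smaller normalized distance,
    then lexicographic locus tag (the sort inside ``_best_hits``).
    """
    ref_feats = _candidate_features(ref)
    der_feats = _candidate_features(der)
    if not ref_feats or not der_feats:
        warnings.warn("empty CDS set; no orthologs", stacklevel=2)
        return []
    ref_nt = {f.locus_tag: ref.feature_seq(f) for f in ref_feats}
    der_nt = {f.locus_tag: der.feature_seq(f) for f in der_feats}
    fwd = _best_hits(ref_nt, der_nt)
    rev = _best_hits(der_nt, ref_nt)
    pairs = []
    for ref_tag in sorted(fwd):
        der_tag = fwd[ref_tag]
        if rev.get(der_tag) != ref_tag:
            continue
        ref_aa = translate_cds(ref_nt[ref_tag])
        der_aa = translate_cds(der_nt[der_tag])
        if not ref_aa or not der_aa:
            continue
        identity, coverage = protein_stats(ref_aa, der_aa)
        if identity >= min_identity and coverage >= min_coverage:
            pairs.append(OrthologPair(ref_tag, der_tag, round(identity, 6),
                                      round(coverage, 6), True))
    return pairs


def pairs_to_table(pairs: list[OrthologPair]):
    import pandas as pd

    return pd.DataFrame(
        [vars(p) for p in pairs],
        columns=["ref_locus", "der_locus", "protein_identity",
                 "coverage_ref", "reciprocal"],
    )
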