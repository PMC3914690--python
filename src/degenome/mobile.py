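"""IS element annotation, the intergenic-clustering permutation test and
IS-bounded duplication detection.

IS discovery is library-driven: consensus sequences (with the transposase
ORF coordinates) are located in the genome by exact 16-mer seeding followed
by edit-distance refinement; each accepted hit's transposase is classified
intact or disrupted with the pseudogene mutation scanner.  The clustering
test compares the observed fraction of IS midpoints in intergenic space
with a uniform-placement null by seeded permutation.  Duplications are
found as maximal non-IS repeat pairs via twice-occurring k-mers, chained,
extended to the bounding (masked) IS elements and aligned to count
substitutions and indel events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _align, pseudogenes
from .genome_io import AnnotatedGenome, revcomp

_SEED_K = 16


@dataclass
class IsConsensus:
    name: str
    family: str
    seq: str
    orf_start: int  # transposase ORF, 0-based within consensus
    orf_end: int


@dataclass
class IsAnnotation:
    family: str
    name: str
    start: int
    end: int
    strand: str
    transposase_state: str  # intact | disrupted
    identity_to_family_consensus: float


@dataclass
class DuplicationPair:
    start_a: int
    end_a: int
    start_b: int
    end_b: int
    length_nt: int
    identity: float
    n_substitutions: int
    n_indels: int  # indel events (gap runs)
    bounded_by_is: bool
    bounding_family: str | None


def annotate_is(genome: AnnotatedGenome, is_library: list[IsConsensus],
                min_identity: float = 0.94,
                min_coverage: float = 0.8) -> list[IsAnnotation]:
    if not is_library:
        raise ValueError("empty IS library")
    seq = genome.sequence
    out: list[IsAnnotation] = []
    for cons in sorted(is_library, key=lambda c: c.name):
        for strand, probe in (("+", cons.seq), ("-", revcomp(cons.seq))):
            for lo, hi in _seed_clusters(seq, probe):
                ann = _refine_hit(seq, probe, cons, strand, lo, hi,
                                  min_identity, min_coverage)
                if ann is not None:
                    out.append(ann)
    out.sort(key=lambda a: (a.start, a.name))
    # Drop duplicate/contained calls at the same locus.
    dedup: list[IsAnnotation] = []
    for a in out:
        if dedup and a.start < dedup[-1].end - len(a.family):
            if a.identity_to_family_consensus <= dedup[-1].identity_to_family_consensus:
                continue
            dedup.pop()
        dedup.append(a)
    return dedup


def _seed_clusters(seq: str, probe: str) -> list[tuple[int, int]]:
    """Candidate genome windows sharing exact 16-mers with the probe."""
    seeds = {probe[i : i + _SEED_K] for i in range(0, len(probe) - _SEED_K + 1, 8)}
    hits = []
    index: dict[str, list[int]] = {}
    for s in seeds:
        index[s] = []
    for i in range(len(seq) - _SEED_K + 1):
        sub = seq[i : i + _SEED_K]
        if sub in index:
            hits.append(i)
    hits.sort()
    clusters = []
    for pos in hits:
        if clusters and pos - clusters[-1][1] <= len(probe):
            clusters[-1][1] = pos + _SEED_K
        else:
            clusters.append([pos, pos + _SEED_K])
    pad = len(probe) // 2 + 50
    return [(max(0, a - pad), min(len(seq), b + pad)) for a, b in clusters]


def _refine_hit(seq: str, probe: str, cons: IsConsensus, strand: str,
                lo: int, hi: int, min_identity: float,
                min_coverage: float) -> IsAnnotation | None:
    window = seq[lo:hi]
    d, (t0, t1), ops = _align.align_path(probe, window, mode="HW")
    if d < 0:
        return None
    identity = 1.0 - d / len(probe)
    if identity < min_identity or (t1 - t0) < min_coverage * len(probe):
        return None
    start, end = lo + t0, lo + t1
    state = _transposase_state(seq[start:end], cons, strand)
    return IsAnnotation(cons.family, cons.name, start, end, strand,
                        state, round(identity, 4))


def _transposase_state(hit_seq: str, cons: IsConsensus, strand: str) -> str:
    oriented = revcomp(hit_seq) if strand == "-" else hit_seq
    cons_orf = cons.seq[cons.orf_start : cons.orf_end]
    try:
        scan = pseudogenes.detect_mutations(oriented, cons_orf)
    except pseudogenes.InvalidOrfError:
        return "disrupted"
    return "intact" if not scan.mutations else "disrupted"


# ---------------------------------------------------------------------------
# Intergenic clustering
# ---------------------------------------------------------------------------

@dataclass
class ClusteringTestResult:
    observed_intergenic_fraction: float
    expected_fraction: float  # intergenic fraction of the genome
    p_value: float  # add-one permutation p-value
    null_exceedance: float  # raw exceedance proportion count/n_perm
    n_is: int
    n_perm: int
    seed: int


def genic_intervals(genome: AnnotatedGenome) -> np.ndarray:
    """Merged forward-strand intervals of CDS/rRNA/tRNA features (n, 2).

    Intergenic space is the complement of these intervals.
    """
    kinds = ("CDS", "pseudogene", "rRNA_16S", "rRNA_23S", "rRNA_5S", "tRNA")
    length = len(genome)
    ivals = []
    for f in genome.features_of_kind(*kinds):
        if f.wraps_origin:
            ivals.append((f.start, length))
            ivals.append((0, f.end))
        else:
            ivals.append((f.start, f.end))
    if not ivals:
        return np.empty((0, 2), dtype=int)
    ivals.sort()
    merged = [list(ivals[0])]
    for a, b in ivals[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return np.asarray(merged, dtype=int)


def _is_genic(positions: np.ndarray, merged: np.ndarray) -> np.ndarray:
    if merged.size == 0:
        return np.zeros(positions.shape, dtype=bool)
    edges = merged.ravel()
    idx = np.searchsorted(edges, positions, side="right")
    return idx % 2 == 1


def intergenic_clustering_test(is_midpoints: list[int] | np.ndarray,
                               genome: AnnotatedGenome,
                               n_perm: int = 10_000,
                               seed: int = 0) -> ClusteringTestResult:
    mids = np.asarray(is_midpoints, dtype=int)
    if mids.size == 0:
        raise ValueError("no IS sites")
    if n_perm < 1000:
        raise ValueError("n_perm must be >= 1000")
    length = len(genome)
    merged = genic_intervals(genome)
    genic_nt = int((merged[:, 1] - merged[:, 0]).sum()) if merged.size else 0
    expected = 1.0 - genic_nt / length

    observed = float(np.mean(~_is_genic(mids, merged)))
    rng = np.random.default_rng(seed)
    null_pos = rng.integers(0, length, size=(n_perm, mids.size))
    null_frac = np.mean(~_is_genic(null_pos, merged), axis=1)
    count = int(np.sum(null_frac >= observed))
    return ClusteringTestResult(
        observed_intergenic_fraction=observed,
        expected_fraction=expected,
        p_value=(count + 1) / (n_perm + 1),
        null_exceedance=count / n_perm,
        n_is=int(mids.size),
        n_perm=n_perm,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Duplications
# ---------------------------------------------------------------------------

def detect_duplications(genome: AnnotatedGenome, min_len: int = 2500,
                        min_identity: float = 0.98, k: int = 20,
                        is_annotations: list[IsAnnotation] | None = None,
                        max_gap: int = 2000, diag_tol: int = 40
                        ) -> list[DuplicationPair]:
    """Find non-IS repeat pairs >= min_len by chaining twice-occurring
    k-mers on a consistent diagonal.

    ``max_gap`` must bridge interior multi-copy sequence (rRNA operons,
    masked IS) inside a duplicated segment, where k-mers occur more than
    twice and contribute no seeds.
    """
    if min_len < 500:
        raise ValueError("min_len must be >= 500")
    seq = genome.sequence
    length = len(seq)
    masked = np.zeros(length, dtype=bool)
    for f in genome.features_of_kind("IS_element"):
        masked[f.positions(length)] = True
    for a in is_annotations or []:
        masked[a.start : a.end] = True

    occ: dict[str, list[int]] = {}
    for i in range(length - k + 1):
        if masked[i : i + k].any():
            continue
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        occ.setdefault(kmer, []).append(i)
    pair_pos = sorted(
        (p[0], p[1]) for p in occ.values() if len(p) == 2
    )

    # Chain twice-occurring k-mers on a consistent diagonal.  Pairs from
    # unrelated repeats interleave in position order, so every open chain
    # is a candidate, not just the most recent one.
    chains: list[list[tuple[int, int]]] = []
    for a, b in pair_pos:
        placed = False
        for chain in reversed(chains):
            pa, pb = chain[-1]
            if a - pa > max_gap:
                break  # chains sorted by tail; earlier ones are further away
            if abs((b - a) - (pb - pa)) <= diag_tol and a > pa:
                chain.append((a, b))
                placed = True
                break
        if not placed:
            chains.append([(a, b)])
        chains.sort(key=lambda c: c[-1][0])

    out: list[DuplicationPair] = []
    for chain in chains:
        a0, b0 = chain[0]
        a1, b1 = chain[-1][0] + k, chain[-1][1] + k
        if a1 - a0 < min_len * 0.8:
            continue
        a0, a1, b0, b1 = _extend_pair(seq, masked, a0, a1, b0, b1)
        if a1 > b0:  # overlapping copies: not a duplication pair
            continue
        d, _, ops = _align.align_path(seq[a0:a1], seq[b0:b1], mode="NW")
        identity = _align.alignment_identity(ops)
        if (a1 - a0) < min_len or identity < min_identity:
            continue
        n_sub = sum(n for op, n in ops if op == "X")
        n_indel = sum(1 for op, _ in ops if op in "ID")
        bounded, family = _is_bounded(genome, is_annotations or [],
                                      (a0, a1), (b0, b1))
        out.append(DuplicationPair(a0, a1, b0, b1, a1 - a0,
                                   round(identity, 6), n_sub, n_indel,
                                   bounded, family))
    return out


def _extend_pair(seq: str, masked: np.ndarray, a0: int, a1: int,
                 b0: int, b1: int) -> tuple[int, int, int, int]:
    """Greedily extend both copies outward over matching unmasked bases."""
    while (a0 > 0 and b0 > 0 and not masked[a0 - 1] and not masked[b0 - 1]
           and seq[a0 - 1] == seq[b0 - 1] and a1 <= b0 - 1):
        a0 -= 1
        b0 -= 1
    n = len(seq)
    while (a1 < n and b1 < n and not masked[a1] and not masked[b1]
           and seq[a1] == seq[b1] and a1 < b0):
        a1 += 1
        b1 += 1
    return a0, a1, b0, b1


def _is_bounded(genome: AnnotatedGenome, annotations: list[IsAnnotation],
                ival_a: tuple[int, int], ival_b: tuple[int, int],
                flank: int = 2000) -> tuple[bool, str | None]:
    anns = list(annotations)
    for f in genome.features_of_kind("IS_element"):
        anns.append(IsAnnotation(f.family or "IS", f.locus_tag, f.start,
                                 f.end, f.strand, "intact", 1.0))
    families: list[set[str]] = []
    for start, end in (ival_a, ival_b):
        for lo, hi in ((start - flank, start), (end, end + flank)):
            fams = {a.family for a in anns if a.start < hi and a.end > lo}
            families.append(fams)
    common = set.intersection(*families) if families else set()
    if common:
        return True, sorted(common)[0]
    return False, None


def is_annotations_to_gff3(annotations: list[IsAnnotation],
                           genome_id: str) -> str:
    lines = ["##gff-version 3"]
    for i, a in enumerate(annotations, 1):
        attrs = (f"ID=is{i:04d};family={a.family};consensus={a.name};"
                 f"transposase={a.transposase_state};"
                 f"identity={a.identity_to_family_consensus}")
        lines.append("\t".join([
            genome_id, "degenome", "mobile_genetic_element",
            str(a.start + 1), str(a.end), ".", a.strand, ".", attrs,
        ]))
    return "\n".join(lines) + "\n"
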