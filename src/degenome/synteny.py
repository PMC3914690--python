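"""Whole-genome k-mer match search, synteny block chaining and
replichore-symmetry classification.

Exact k-mers (default k=20, after masking repetitive features) that occur
exactly once in each genome — counting both strands — anchor the comparison.
Matches collinear on a consistent diagonal are chained into strand-aware
blocks.  Against supplied ori/ter positions each block is classed as
replichore-symmetric (same strand and same replichore, or inverted strand
and switched replichore), violating, or indeterminate when it straddles
ori/ter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .genome_io import revcomp


@dataclass(frozen=True)
class KmerMatch:
    ref_pos: int
    der_pos: int
    strand: str  # '+' same strand, '-' opposite


@dataclass
class SyntenyBlock:
    ref_start: int
    ref_end: int  # half-open
    der_start: int
    der_end: int
    orientation: str  # same_strand | opposite_strand
    n_kmers: int
    symmetry_class: str = "indeterminate"


def _unique_kmers(seq: str, k: int) -> dict[str, tuple[int, str]]:
    """Canonical k-mer -> (position, orientation) for k-mers unique on both
    strands combined; k-mers containing N excluded."""
    counts: dict[str, int] = {}
    first: dict[str, tuple[int, str]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        rc = revcomp(kmer)
        canon, orient = (kmer, "+") if kmer <= rc else (rc, "-")
        n = 2 if kmer == rc else 1  # palindromes occupy both strands
        counts[canon] = counts.get(canon, 0) + n
        if canon not in first:
            first[canon] = (i, orient)
    return {c: first[c] for c, n in counts.items() if n == 1}


def kmer_matches(ref_masked: str, der_masked: str, k: int = 20
                 ) -> list[KmerMatch]:
    if k > len(ref_masked) or k > len(der_masked):
        raise ValueError("k exceeds sequence length")
    if k < 8:
        raise ValueError("k must be >= 8")
    ref_idx = _unique_kmers(ref_masked, k)
    der_idx = _unique_kmers(der_masked, k)
    matches = []
    for canon, (rpos, rorient) in ref_idx.items():
        hit = der_idx.get(canon)
        if hit is None:
            continue
        dpos, dorient = hit
        matches.append(KmerMatch(rpos, dpos,
                                 "+" if rorient == dorient else "-"))
    matches.sort(key=lambda m: m.ref_pos)
    return matches


def chain_blocks(matches: list[KmerMatch], k: int = 20, max_gap: int = 1000,
                 diag_tol: int = 20) -> list[SyntenyBlock]:
    """Merge collinear same-strand matches into maximal blocks.

    Matches are scanned in reference order; a match extends the current
    block when the strand agrees, the reference gap is at most ``max_gap``
    and the diagonal (der - ref for same strand, der + ref for opposite)
    drifts by at most ``diag_tol``.
    """
    blocks: list[SyntenyBlock] = []
    current: list[KmerMatch] = []

    def diag(m: KmerMatch) -> int:
        return m.der_pos - m.ref_pos if m.strand == "+" else m.der_pos + m.ref_pos

    def flush() -> None:
        if not current:
            return
        ders = [m.der_pos for m in current]
        blocks.append(SyntenyBlock(
            current[0].ref_pos, current[-1].ref_pos + k,
            min(ders), max(ders) + k,
            "same_strand" if current[0].strand == "+" else "opposite_strand",
            len(current)))

    for m in sorted(matches, key=lambda x: x.ref_pos):
        if current:
            prev = current[-1]
            if (m.strand == prev.strand
                    and m.ref_pos - prev.ref_pos <= max_gap
                    and abs(diag(m) - diag(prev)) <= diag_tol):
                current.append(m)
                continue
            flush()
            current = []
        current = [m]
    flush()
    blocks.sort(key=lambda b: b.ref_start)
    return blocks


def _replichore(pos: int, ori: int, ter: int, length: int) -> int:
    """1 for the ori->ter arc in ascending coordinates, 2 for the other."""
    if ori < ter:
        return 1 if ori <= pos < ter else 2
    return 2 if ter <= pos < ori else 1


def _straddles(start: int, end: int, boundary: int) -> bool:
    return start < boundary < end


def classify_symmetry(blocks: list[SyntenyBlock], ref_ori: int, ref_ter: int,
                      der_ori: int, der_ter: int, ref_len: int, der_len: int
                      ) -> tuple[list[SyntenyBlock], float]:
    """Set each block's symmetry class; return genome-level violation
    fraction (violating / (violating + symmetric))."""
    if ref_ori == ref_ter or der_ori == der_ter:
        raise ValueError("ori and ter must differ")
    out = []
    n_sym = n_vio = 0
    for b in blocks:
        if (_straddles(b.ref_start, b.ref_end, ref_ori)
                or _straddles(b.ref_start, b.ref_end, ref_ter)
                or _straddles(b.der_start, b.der_end, der_ori)
                or _straddles(b.der_start, b.der_end, der_ter)):
            out.append(replace(b, symmetry_class="indeterminate"))
            continue
        r = _replichore((b.ref_start + b.ref_end) // 2, ref_ori, ref_ter, ref_len)
        d = _replichore((b.der_start + b.der_end) // 2, der_ori, der_ter, der_len)
        same_repl = r == d
        symmetric = (same_repl and b.orientation == "same_strand") or (
            not same_repl and b.orientation == "opposite_strand")
        if symmetric:
            n_sym += 1
        else:
            n_vio += 1
        out.append(replace(b, symmetry_class="symmetric" if symmetric
                           else "violating"))
    frac = n_vio / (n_sym + n_vio) if (n_sym + n_vio) else float("nan")
    return out, frac


def blocks_to_frame(blocks: list[SyntenyBlock]):
    import pandas as pd

    return pd.DataFrame([vars(b) for b in blocks])


def matches_to_frame(matches: list[KmerMatch]):
    import pandas as pd

    return pd.DataFrame([vars(m) for m in matches])
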