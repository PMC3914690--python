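"""Pairwise dN/dS estimation (Nei–Gojobori counting) and the relaxed-
selection screen for cryptic pseudogenes.

Synonymous/nonsynonymous *sites* are counted per codon by enumerating all
nine single-nucleotide changes; at each codon position the site value is the
fraction of changes that are synonymous among those that do not create a
stop codon, and sites are averaged over the two sequences.  *Differences*
between a codon pair are averaged over all minimal mutational pathways
(orderings of the differing positions), excluding pathways that pass
through a stop codon; if every pathway does, all are used.  Proportions are
corrected for multiple hits with the Jukes–Cantor formula
``d = -(3/4) ln(1 - (4/3) p)``, undefined for ``p >= 3/4``.

omega (dN/dS) is +inf when dS = 0 with dN > 0 and NaN when both are zero;
infinite and undefined values are excluded from means.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

import numpy as np

from . import _align

_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = {}


def _build_table() -> None:
    from Bio.Seq import Seq

    for a in _BASES:
        for b in _BASES:
            for c in _BASES:
                codon = a + b + c
                _CODON_TABLE[codon] = str(Seq(codon).translate())


_build_table()
STOPS = frozenset(c for c, aa in _CODON_TABLE.items() if aa == "*")


class CodonAlignmentError(ValueError):
    pass


@dataclass
class CodonAlignment:
    ref_codons: list[str]
    der_codons: list[str]

    def __post_init__(self) -> None:
        if len(self.ref_codons) != len(self.der_codons):
            raise CodonAlignmentError("codon lists of unequal length")
        for codons in (self.ref_codons, self.der_codons):
            for c in codons:
                if c in STOPS:
                    raise CodonAlignmentError(f"internal stop codon {c}")
                if len(c) != 3 or any(b not in _BASES for b in c):
                    raise CodonAlignmentError(f"invalid codon {c!r}")

    @property
    def n_codons(self) -> int:
        return len(self.ref_codons)

    def swapped(self) -> "CodonAlignment":
        return CodonAlignment(list(self.der_codons), list(self.ref_codons))


@dataclass
class SelectionEstimate:
    ref_locus: str
    der_locus: str
    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float  # NaN when the JC correction is undefined
    dN: float
    omega: float  # dN/dS; +inf if dS=0<dN; NaN if both 0 or undefined
    orf_len_nt: int


@lru_cache(maxsize=None)
def syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (0..3)."""
    if codon in STOPS:
        raise CodonAlignmentError(f"stop codon {codon}")
    aa = _CODON_TABLE[codon]
    total = 0.0
    for pos in range(3):
        syn = viable = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt in STOPS:
                continue
            viable += 1
            if _CODON_TABLE[alt] == aa:
                syn += 1
        if viable:
            total += syn / viable
    return total


@lru_cache(maxsize=None)
def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(Sd, Nd) between two sense codons, averaged over minimal pathways."""
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    all_paths: list[tuple[int, int]] = []
    for order in permutations(diff):
        cur = c1
        sd = nd = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                through_stop = True
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        all_paths.append((sd, nd))
        if not through_stop:
            valid.append((sd, nd))
    paths = valid if valid else all_paths
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def jukes_cantor(p: float) -> float:
    if p < 0:
        raise ValueError("negative proportion")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def estimate_dnds(aln: CodonAlignment, ref_locus: str = "ref",
                  der_locus: str = "der") -> SelectionEstimate:
    if aln.n_codons < 1:
        raise CodonAlignmentError("empty alignment")
    s_ref = sum(syn_sites(c) for c in aln.ref_codons)
    s_der = sum(syn_sites(c) for c in aln.der_codons)
    S = (s_ref + s_der) / 2.0
    N = 3.0 * aln.n_codons - S
    Sd = Nd = 0.0
    for c1, c2 in zip(aln.ref_codons, aln.der_codons):
        sd, nd = pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    dS = jukes_cantor(pS)
    dN = jukes_cantor(pN)
    if math.isnan(dS) or math.isnan(dN):
        omega = float("nan")
    elif dS > 0:
        omega = dN / dS
    elif dN > 0:
        omega = float("inf")
    else:
        omega = float("nan")
    return SelectionEstimate(ref_locus, der_locus, S, N, Sd, Nd, pS, pN,
                             dS, dN, omega, 3 * aln.n_codons)


def codon_alignment_from_nt(ref_nt: str, der_nt: str) -> CodonAlignment:
    """Codon alignment from two CDS nucleotide sequences.

    The sequences are globally aligned; in-frame gap runs are dropped in
    codon units, and a frameshifting indel raises ``CodonAlignmentError``
    (frameshifted pairs are excluded from selection analysis upstream).
    Terminal stop codons are trimmed.
    """
    ref_nt, der_nt = _trim_stop(ref_nt), _trim_stop(der_nt)
    _, _, ops = _align.align_path(ref_nt, der_nt, mode="NW")
    ops = _align.normalize_paired_indels(ref_nt, der_nt, ops)
    for op, n in ops:
        if op in "ID" and n % 3 != 0:
            raise CodonAlignmentError("frameshifting indel in alignment")
    ref_cols: list[str] = []
    der_cols: list[str] = []
    qi = ti = 0
    for op, n in ops:
        if op in "=XM":
            ref_cols.extend(ref_nt[qi : qi + n])
            der_cols.extend(der_nt[ti : ti + n])
            qi += n
            ti += n
        elif op == "I":
            ref_cols.extend(ref_nt[qi : qi + n])
            der_cols.extend("-" * n)
            qi += n
        elif op == "D":
            ref_cols.extend("-" * n)
            der_cols.extend(der_nt[ti : ti + n])
            ti += n
    ref_codons, der_codons = [], []
    for i in range(0, len(ref_cols) - len(ref_cols) % 3, 3):
        rc = "".join(ref_cols[i : i + 3])
        dc = "".join(der_cols[i : i + 3])
        if "-" in rc or "-" in dc:
            continue
        if rc in STOPS or dc in STOPS:
            continue  # stop-adjacent noise; terminal stops already trimmed
        ref_codons.append(rc)
        der_codons.append(dc)
    return CodonAlignment(ref_codons, der_codons)


def _trim_stop(nt: str) -> str:
    nt = nt[: len(nt) - len(nt) % 3]
    return nt[:-3] if nt[-3:] in STOPS else nt


def bootstrap_se(aln: CodonAlignment, n_boot: int = 1000,
                 seed: int = 0) -> tuple[float, float]:
    """Codon-bootstrap standard errors of (dS, dN)."""
    rng = np.random.default_rng(seed)
    n = aln.n_codons
    ds_vals, dn_vals = [], []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sub = CodonAlignment([aln.ref_codons[i] for i in idx],
                             [aln.der_codons[i] for i in idx])
        est = estimate_dnds(sub)
        ds_vals.append(est.dS)
        dn_vals.append(est.dN)
    return (float(np.nanstd(ds_vals, ddof=1)),
            float(np.nanstd(dn_vals, ddof=1)))


@dataclass
class CrypticScreenReport:
    flagged: list[str]  # omega >= threshold_flag
    unflagged: list[str]
    labeled: list[tuple[str, str | None]]  # omega >= threshold_label, product
    mean_omega: float
    mean_len_flagged: float
    mean_len_unflagged: float
    length_ratio: float  # flagged / unflagged mean ORF length
    n_undefined: int


def screen_cryptic(estimates: list[SelectionEstimate],
                   threshold_flag: float = 0.3,
                   threshold_label: float = 0.4,
                   products: dict[str, str] | None = None
                   ) -> CrypticScreenReport:
    defined = [e for e in estimates if not math.isnan(e.omega)]
    if not defined:
        raise ValueError("no gene has a defined omega")
    flagged = [e for e in defined if e.omega >= threshold_flag]
    unflagged = [e for e in defined if e.omega < threshold_flag]
    labeled = [(e.der_locus, (products or {}).get(e.der_locus))
               for e in defined if e.omega >= threshold_label]
    finite = [e.omega for e in defined if math.isfinite(e.omega)]
    mean_len_f = (float(np.mean([e.orf_len_nt for e in flagged]))
                  if flagged else float("nan"))
    mean_len_u = (float(np.mean([e.orf_len_nt for e in unflagged]))
                  if unflagged else float("nan"))
    return CrypticScreenReport(
        flagged=[e.der_locus for e in flagged],
        unflagged=[e.der_locus for e in unflagged],
        labeled=labeled,
        mean_omega=float(np.mean(finite)) if finite else float("nan"),
        mean_len_flagged=mean_len_f,
        mean_len_unflagged=mean_len_u,
        length_ratio=mean_len_f / mean_len_u if unflagged and flagged else float("nan"),
        n_undefined=len(estimates) - len(defined),
    )


def estimates_to_frame(estimates: list[SelectionEstimate],
                       threshold_flag: float = 0.3):
    import pandas as pd

    rows = []
    for e in estimates:
        d = vars(e).copy()
        d["flag"] = (not math.isnan(e.omega)) and e.omega >= threshold_flag
        rows.append(d)
    return pd.DataFrame(rows)
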