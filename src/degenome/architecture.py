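"""Chromosome architecture: GC skew, ori/ter inference, skew polarization,
KOPS motif mapping and the dif site search.

In an unrearranged circular chromosome replicated bidirectionally, the
leading strand is G-enriched, so windowed (G-C)/(G+C) skew is positive on
one replichore and negative on the other; the cumulative skew curve then
attains its global minimum at the replication origin and its maximum at the
terminus.  KOPS motifs (consensus GGGNAGGG) read ori->ter on each leading
strand, and the 28-nt dif site sits at the terminus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome_io import revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

KOPS_MOTIF = "GGGNAGGG"
DIF_HS = "AGTACGCATAATACATATTATGTTAAAT"


@dataclass
class SkewTrack:
    window: int
    step: int
    positions: np.ndarray  # window midpoints
    values: np.ndarray  # (G-C)/(G+C) per window
    flagged: np.ndarray  # windows with G+C == 0


def gc_skew(seq: str, window: int = 10_000, step: int = 5_000) -> SkewTrack:
    length = len(seq)
    if window > length:
        raise ValueError("window exceeds genome length")
    if not (100 <= window) or step > window or step < 1:
        raise ValueError("require window >= 100 and 1 <= step <= window")
    arr = np.frombuffer(seq.encode(), dtype="S1")
    g = np.concatenate([[0], np.cumsum(arr == b"G")])
    c = np.concatenate([[0], np.cumsum(arr == b"C")])
    starts = np.arange(0, length - window + 1, step)
    ng = g[starts + window] - g[starts]
    nc = c[starts + window] - c[starts]
    tot = ng + nc
    flagged = tot == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(flagged, 0.0, (ng - nc) / np.where(tot == 0, 1, tot))
    return SkewTrack(window, step, starts + window // 2, values, flagged)


def cumulative_skew_extrema(track: SkewTrack) -> tuple[int, int]:
    """(ori, ter): cumulative-skew global minimum and maximum midpoints."""
    cum = np.cumsum(track.values)
    ori = int(track.positions[int(np.argmin(cum))])
    ter = int(track.positions[int(np.argmax(cum))])
    return ori, ter


def skew_polarization_index(track: SkewTrack, ori: int, ter: int) -> float:
    """Fraction of windows whose skew sign follows the two-replichore model,
    with the sign orientation chosen to maximize agreement (so 0.5 means no
    polarization and 1.0 perfect polarization)."""
    if ori == ter:
        raise ValueError("ori and ter must differ")
    use = ~track.flagged & (track.values != 0)
    if not use.any():
        raise ValueError("all windows flagged")
    pos = track.positions[use]
    sign = np.sign(track.values[use])
    lo, hi = min(ori, ter), max(ori, ter)
    in_arc = (pos >= lo) & (pos < hi)
    expected = np.where(in_arc, 1.0, -1.0)
    agree = float(np.mean(sign == expected))
    return max(agree, 1.0 - agree)


@dataclass
class KopsSites:
    motif: str
    sites: list[tuple[int, str]]  # (forward-strand position, strand)


def _iupac_regex(motif: str) -> "re.Pattern[str]":
    import re

    pattern = "".join(
        f"[{IUPAC[ch]}]" if len(IUPAC[ch]) > 1 else IUPAC[ch]
        for ch in motif.upper()
    )
    return re.compile(f"(?=({pattern}))")


def find_kops(seq: str, motif: str = KOPS_MOTIF) -> KopsSites:
    bad = set(motif.upper()) - set(IUPAC)
    if bad:
        raise ValueError(f"invalid IUPAC symbols {sorted(bad)}")
    fwd = _iupac_regex(motif)
    rev = _iupac_regex(revcomp(motif))
    sites = [(m.start(), "+") for m in fwd.finditer(seq)]
    sites += [(m.start(), "-") for m in rev.finditer(seq)]
    sites.sort()
    return KopsSites(motif, sites)


def kops_polarity(sites: KopsSites, ori: int, ter: int, length: int) -> float:
    """Fraction of sites oriented ori->ter on their replichore's leading
    strand (+ on the ascending ori->ter arc, - on the other)."""
    if not sites.sites:
        return float("nan")
    lo, hi = min(ori, ter), max(ori, ter)
    asc_is_oriter = ori < ter
    ok = 0
    for pos, strand in sites.sites:
        on_asc = lo <= pos < hi
        expected = "+" if (on_asc == asc_is_oriter) else "-"
        ok += strand == expected
    return ok / len(sites.sites)


def find_dif(seq: str, dif_query: str = DIF_HS, max_mismatch: int = 4
             ) -> tuple[int, str, int] | None:
    """Best ungapped placement (position, strand, mismatches) of the dif
    query on either strand, or None if none has <= max_mismatch mismatches.
    Ties resolve to the leftmost position, + strand first."""
    if not dif_query:
        raise ValueError("empty dif query")
    if max_mismatch > len(dif_query) // 4:
        raise ValueError("max_mismatch too large for query length")
    m = len(dif_query)
    if m > len(seq):
        return None
    arr = np.frombuffer(seq.encode(), dtype="S1")
    windows = np.lib.stride_tricks.sliding_window_view(arr, m)
    best: tuple[int, int, int] | None = None  # (mismatches, pos, strand_rank)
    for rank, query in enumerate((dif_query, revcomp(dif_query))):
        q = np.frombuffer(query.encode(), dtype="S1")
        mism = (windows != q).sum(axis=1)
        pos = int(np.argmin(mism))
        cand = (int(mism[pos]), pos, rank)
        if best is None or cand < best:
            best = cand
    assert best is not None
    if best[0] > max_mismatch:
        return None
    return best[1], "+-"[best[2]], best[0]


def track_to_frame(track: SkewTrack):
    import pandas as pd

    return pd.DataFrame({
        "position": track.positions,
        "skew": track.values,
        "flagged": track.flagged,
    })


def kops_to_bed(sites: KopsSites, genome_id: str) -> str:
    lines = []
    for pos, strand in sites.sites:
        lines.append("\t".join([
            genome_id, str(pos), str(pos + len(sites.motif)),
            "KOPS", "0", strand,
        ]))
    return "\n".join(lines) + ("\n" if lines else "")
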