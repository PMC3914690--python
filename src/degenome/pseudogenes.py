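"""Reference-anchored pseudogene classification.

Each derived CDS is compared with its reference ortholog.  A fast path
accepts genes with high protein identity and length that carry no
inactivating mutation; everything else is re-examined with flanking genomic
context (default 2,500 nt each side) so that truncations and frameshifts
that displace the annotated ORF boundary are still recovered.  Finally a
span rule applies: a gene is intact only if the aligned derived sequence
spans more than 99% of the reference ORF (90% for reference ORFs shorter
than 300 nt) and carries no inactivating mutation.

Mutation typing works on the nucleotide alignment projected into the
reference reading frame: indels of length not divisible by three are
frameshifts; reference-frame stop codons ahead of the reference stop are
premature stops (calls within the final three sense codons are suppressed
as stop-adjacent noise); a long terminal run of codons with collapsed
identity is a truncation (individual calls inside it are folded into the
truncation record); a large insertion matching an IS consensus is an IS
interruption.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _align
from .genome_io import AnnotatedGenome, Feature, revcomp
from .orthologs import OrthologPair

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODONS = frozenset({"ATG", "GTG", "TTG"})


@dataclass(frozen=True)
class InactivatingMutation:
    type: str  # frameshift_indel | premature_stop | truncation | is_interruption
    position_codon: int  # 1-based, reference frame
    detail: str = ""


@dataclass
class Thresholds:
    fast_identity: float = 0.90
    fast_length: float = 0.80
    span_long: float = 0.99
    span_short: float = 0.90
    short_orf_nt: int = 300
    context_nt: int = 2500
    stop_tail_codons: int = 3  # suppress stop calls this close to the end
    diverged_identity: float = 0.75  # per-codon identity drift threshold
    min_truncation_codons: int = 10
    is_insert_identity: float = 0.8


@dataclass
class CdsClassification:
    der_locus: str
    ref_locus: str | None
    verdict: str  # intact | pseudogene | unresolved
    mutations: list[InactivatingMutation] = field(default_factory=list)
    protein_identity: float = float("nan")
    length_fraction: float = float("nan")
    span: float = float("nan")
    rule_fired: str = "fast_path"


@dataclass
class MutationScan:
    mutations: list[InactivatingMutation]
    span: float  # fraction of reference covered by non-diverged alignment
    nt_identity: float


class InvalidOrfError(ValueError):
    pass


def _check_ref_orf(ref_cds: str) -> None:
    if len(ref_cds) % 3 != 0 or len(ref_cds) < 6:
        raise InvalidOrfError("reference CDS length not a codon multiple")
    if ref_cds[:3] not in START_CODONS:
        raise InvalidOrfError(f"reference CDS lacks a start codon: {ref_cds[:3]}")
    if ref_cds[-3:] not in STOP_CODONS:
        raise InvalidOrfError(f"reference CDS lacks a stop codon: {ref_cds[-3:]}")


def detect_mutations(der_seq: str, ref_cds: str,
                     is_library: dict[str, str] | None = None,
                     thresholds: Thresholds | None = None) -> MutationScan:
    """Scan a derived sequence (CDS with optional flanking context) against
    a valid reference ORF and return typed inactivating mutations."""
    th = thresholds or Thresholds()
    _check_ref_orf(ref_cds)
    n_codons = len(ref_cds) // 3

    # A mobile-element insertion is removed before alignment: an edit-
    # distance aligner would rather thread the reference through the
    # element as noise than pay for a kilobase-scale gap.
    excised: list[int] = []  # positions in the cleaned target
    if is_library:
        der_seq, excised_raw = _excise_is_segments(der_seq, is_library, th)
        excised = excised_raw

    _, (t0, t1), ops = _align.align_path(ref_cds, der_seq, mode="HW")
    t0, t1, ops = _align.absorb_terminal_query_gaps(ref_cds, der_seq, t0, t1,
                                                    ops)
    ops = _align.normalize_paired_indels(ref_cds, der_seq, ops, t_start=t0)
    proj, insertions = _align.project_target_onto_query(
        ref_cds, der_seq, ops, target_start=t0)

    # Per-codon identity in the reference frame; '-' counts as a mismatch.
    codon_ident = np.fromiter(
        (sum(proj[3 * i + k] == ref_cds[3 * i + k] for k in range(3)) / 3.0
         for i in range(n_codons)),
        dtype=float, count=n_codons,
    )
    # Changepoint where the alignment degenerates: the prefix score drifts
    # up while per-codon identity beats the divergence threshold and down
    # inside scrambled/unrelated sequence, so its argmax is the boundary.
    score = np.concatenate(
        [[0.0], np.cumsum(codon_ident - th.diverged_identity)])
    trunc_start = int(np.argmax(score))
    truncated = (n_codons - trunc_start) >= th.min_truncation_codons
    limit = trunc_start if truncated else n_codons

    mutations: list[InactivatingMutation] = []
    # Indels within the final stop-adjacent codons are alignment noise at
    # the ORF boundary, suppressed like stop-adjacent premature stops.
    fs_limit = min(limit, n_codons - 1 - th.stop_tail_codons)

    t_end = t0 + sum(n for op, n in ops if op in "=XMD")
    for pos in excised:
        if not t0 < pos < t_end:
            continue  # element sits in the flanking context, not the ORF
        codon = _query_pos_at(ops, t0, pos) // 3 + 1
        if codon <= limit:
            mutations.append(InactivatingMutation(
                "is_interruption", codon, "IS-library match excised"))

    for qpos, ins in insertions:
        codon = qpos // 3 + 1
        if codon > limit:
            continue
        if len(ins) % 3 != 0 and codon <= fs_limit:
            mutations.append(InactivatingMutation(
                "frameshift_indel", codon, f"+{len(ins)}nt"))

    # Deletion runs (gaps in the projection) within the conserved region.
    i = 0
    while i < 3 * limit:
        if proj[i] == "-":
            j = i
            while j < len(proj) and proj[j] == "-":
                j += 1
            run = j - i
            # Terminal gap runs are coverage loss, not internal indels.
            if (run % 3 != 0 and run < 3 * th.min_truncation_codons
                    and i > 0 and j < len(proj)
                    and i // 3 + 1 <= fs_limit):
                mutations.append(InactivatingMutation(
                    "frameshift_indel", i // 3 + 1, f"-{run}nt"))
            i = j
        else:
            i += 1

    # Reference-frame premature stops in the conserved region.
    stop_limit = min(limit, n_codons - 1 - th.stop_tail_codons)
    for ci in range(stop_limit):
        triplet = "".join(proj[3 * ci : 3 * ci + 3])
        if "-" in triplet:
            continue
        if triplet in STOP_CODONS and ref_cds[3 * ci : 3 * ci + 3] not in STOP_CODONS:
            mutations.append(InactivatingMutation(
                "premature_stop", ci + 1, triplet))

    if truncated:
        mutations.append(InactivatingMutation(
            "truncation", trunc_start + 1,
            f"{n_codons - trunc_start} codons lost"))

    # Span: reference positions aligned to well-matching derived sequence
    # (the diverged tail beyond the changepoint does not count).
    covered = sum(
        1 for p in range(3 * trunc_start) if proj[p] != "-"
    )
    span = covered / len(ref_cds)
    ident = float(np.mean([proj[p] == ref_cds[p] for p in range(len(ref_cds))]))
    mutations.sort(key=lambda m: (m.position_codon, m.type))
    return MutationScan(mutations, span, ident)


def _excise_is_segments(der_seq: str, is_library: dict[str, str],
                        th: Thresholds) -> tuple[str, list[int]]:
    """Remove IS-consensus matches from the derived sequence; returns the
    cleaned sequence and the excision positions within it."""
    positions: list[int] = []
    for _ in range(8):  # several elements may be nested/adjacent
        changed = False
        for name in sorted(is_library):
            cons = is_library[name]
            for probe in (cons, revcomp(cons)):
                if len(probe) > len(der_seq):
                    continue
                d, (s, e), _ = _align.align_path(probe, der_seq, mode="HW")
                if d < 0:
                    continue
                identity = 1.0 - d / len(probe)
                if (identity >= th.is_insert_identity
                        and (e - s) >= 0.8 * len(probe)):
                    der_seq = der_seq[:s] + der_seq[e:]
                    positions = [p if p <= s else p - (e - s)
                                 for p in positions]
                    positions.append(s)
                    changed = True
        if not changed:
            break
    return der_seq, positions


def _query_pos_at(ops: list[tuple[str, int]], t0: int, tpos: int) -> int:
    """Query position aligned at target position ``tpos``."""
    qi, ti = 0, t0
    for op, n in ops:
        if op in "=XM":
            if ti + n > tpos:
                return qi + (tpos - ti)
            qi += n
            ti += n
        elif op == "I":
            qi += n
        else:
            if ti + n > tpos:
                return qi
            ti += n
    return qi


def _extended_der_seq(genome: AnnotatedGenome, feature: Feature,
                      context_nt: int) -> str:
    length = len(genome)
    fstart, span = feature.start, feature.length(length)
    if genome.is_circular and context_nt > 0:
        lo = fstart - context_nt
        hi = fstart + span + context_nt
        if hi - lo >= length:
            lo, hi = 0, length
        seq2 = genome.sequence * 2
        nt = seq2[lo % length : lo % length + (hi - lo)]
    else:
        lo = max(0, fstart - context_nt)
        hi = min(length, fstart + span + context_nt)
        nt = genome.sequence[lo:hi]
    return revcomp(nt) if feature.strand == "-" else nt


def classify_cds(pair: OrthologPair | None, der_genome: AnnotatedGenome,
                 ref_genome: AnnotatedGenome,
                 thresholds: Thresholds | None = None,
                 is_library: dict[str, str] | None = None,
                 der_locus: str | None = None) -> CdsClassification:
    th = thresholds or Thresholds()
    if pair is None:
        return CdsClassification(der_locus or "?", None, "unresolved",
                                 rule_fired="extended_search")
    ref_f = ref_genome.get_feature(pair.ref_locus)
    der_f = der_genome.get_feature(pair.der_locus)
    ref_nt = ref_genome.feature_seq(ref_f)
    der_nt = der_genome.feature_seq(der_f)

    # Fast path: high-identity, near-full-length and mutation-free.
    if (pair.protein_identity > th.fast_identity
            and pair.coverage_ref > th.fast_length):
        scan = detect_mutations(der_nt, ref_nt, is_library, th)
        if not scan.mutations:
            return CdsClassification(
                pair.der_locus, pair.ref_locus, "intact", [],
                pair.protein_identity, pair.coverage_ref, scan.span,
                "fast_path")

    # Extended search with flanking context.
    der_ext = _extended_der_seq(der_genome, der_f, th.context_nt)
    scan = detect_mutations(der_ext, ref_nt, is_library, th)

    short = len(ref_nt) < th.short_orf_nt
    span_threshold = th.span_short if short else th.span_long
    rule = "short_orf_rule" if short else "span_rule"
    if not scan.mutations and scan.span > span_threshold:
        verdict = "intact"
    else:
        verdict = "pseudogene"
        if scan.mutations:
            rule = "extended_search"
    return CdsClassification(
        pair.der_locus, pair.ref_locus, verdict, scan.mutations,
        pair.protein_identity, pair.coverage_ref, scan.span, rule)


@dataclass
class ClassificationReport:
    classifications: list[CdsClassification]
    n_cds: int = 0
    n_intact: int = 0
    n_pseudo: int = 0
    n_unresolved: int = 0
    fraction_pseudo: float = float("nan")

    def __post_init__(self) -> None:
        self.n_cds = len(self.classifications)
        self.n_intact = sum(c.verdict == "intact" for c in self.classifications)
        self.n_pseudo = sum(c.verdict == "pseudogene" for c in self.classifications)
        self.n_unresolved = self.n_cds - self.n_intact - self.n_pseudo
        denom = self.n_intact + self.n_pseudo
        self.fraction_pseudo = self.n_pseudo / denom if denom else float("nan")

    def to_frame(self):
        import pandas as pd

        rows = []
        for c in self.classifications:
            rows.append({
                "der_locus": c.der_locus,
                "ref_locus": c.ref_locus,
                "verdict": c.verdict,
                "rule_fired": c.rule_fired,
                "protein_identity": c.protein_identity,
                "length_fraction": c.length_fraction,
                "span": c.span,
                "n_mutations": len(c.mutations),
                "mutations": ";".join(
                    f"{m.type}@{m.position_codon}({m.detail})"
                    for m in c.mutations),
            })
        return pd.DataFrame(rows)


def classify_genome(der_genome: AnnotatedGenome, ref_genome: AnnotatedGenome,
                    pairs: list[OrthologPair],
                    thresholds: Thresholds | None = None,
                    is_library: dict[str, str] | None = None
                    ) -> ClassificationReport:
    by_der = {p.der_locus: p for p in pairs}
    out = []
    for f in der_genome.features_of_kind("CDS", "pseudogene"):
        pair = by_der.get(f.locus_tag)
        out.append(classify_cds(pair, der_genome, ref_genome, thresholds,
                                is_library, der_locus=f.locus_tag))
    return ClassificationReport(out)
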