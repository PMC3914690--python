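"""Synthetic ancestor genomes, a parameterized degeneration process, and a
ground-truth ledger for recovery scoring.

``generate_ancestor`` builds a gene-dense circular chromosome with
bidirectional replichores (leading strands G-enriched by a stated bias, so
GC skew is polarized and cumulative skew recovers ori/ter), polarized KOPS
motifs, a dif site at the terminus, and rRNA operons with a consistent toy
stem pairing map and per-position variability map.

``degenerate`` applies a recorded sequence of events — background
substitutions, per-gene inactivations (frameshift / premature stop /
truncation), IS-bounded tandem duplications, IS insertions with an
intergenic bias, inversions, translocations and deletions — in a fixed
order, and returns the derived genome together with a ``TruthLedger`` whose
primitive-event list replays to the derived sequence byte-exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace as dc_replace
from pathlib import Path

import numpy as np

from . import architecture
from .dnds import _CODON_TABLE, STOPS
from .genome_io import AnnotatedGenome, Feature, revcomp
from .mobile import IsConsensus
from .rrna import PairingMap, VariabilityMap

SENSE_CODONS = sorted(c for c in _CODON_TABLE if c not in STOPS)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class AncestorConfig:
    genome_length: int = 200_000
    n_genes: int = 150
    gene_length_mean: int = 900
    gene_length_sd: int = 200
    gene_length_min: int = 150
    skew_bias: float = 0.05  # G excess over C on the leading strand
    gc_content: float = 0.54
    p_co_oriented: float = 0.7  # genes on the leading strand
    n_kops: int = 60
    kops_polarity: float = 1.0
    n_rrna_operons: int = 2
    rrna_length: int = 1200
    min_gap: int = 40
    seed: int = 0


@dataclass
class DegenerationParams:
    p_pseudo: float = 0.4
    mutation_weights: tuple[float, float, float] = (0.4, 0.3, 0.3)
    # frameshift : premature_stop : truncation
    n_is_insertions: int = 0
    is_intergenic_bias: float = 0.85
    p_is_disrupted: float = 0.25
    n_inversions: int = 0
    inversion_length: tuple[int, int] = (5_000, 50_000)
    n_translocations: int = 0
    translocation_length: tuple[int, int] = (2_000, 10_000)
    n_duplications: int = 0
    duplication_length: int = 13_476
    duplication_subs: int = 13
    duplication_indels: int = 4
    duplication_family: str = "IS256"
    n_deletions: int = 0
    deletion_length: tuple[int, int] = (500, 3_000)
    mu: float = 0.0  # background substitution rate per site
    background_omega: float = 0.2  # acceptance prob. of nonsyn background subs
    rrna_n_subs: int = 0  # substitutions per 16S copy
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.mutation_weights) - 1.0) > 1e-9:
            raise ValueError("mutation weights must sum to 1")
        for p in (self.p_pseudo, self.is_intergenic_bias, self.mu):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")


@dataclass
class AncestorMeta:
    ori: int
    ter: int
    dif_pos: int
    kops: list[tuple[int, str]]
    gene_strands: dict[str, str]
    rrna_ref: str
    pairing: PairingMap
    vmap: VariabilityMap
    residual_kops: int
    config: AncestorConfig


@dataclass
class TruthLedger:
    seed: int
    ancestor_id: str
    events: list[dict] = field(default_factory=list)
    inactivated: dict[str, list[dict]] = field(default_factory=dict)
    n_background_subs: int = 0
    is_insertions: list[dict] = field(default_factory=list)
    duplications: list[dict] = field(default_factory=list)
    inversions: list[dict] = field(default_factory=list)
    translocations: list[dict] = field(default_factory=list)
    deletions: list[dict] = field(default_factory=list)
    deleted_loci: list[str] = field(default_factory=list)
    rrna_subs: dict[str, list[int]] = field(default_factory=dict)
    final_ori: int | None = None  # ancestor ori/ter mapped through all events
    final_ter: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        return cls(**json.loads(Path(path).read_text()))


class SimulationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Ancestor generation
# ---------------------------------------------------------------------------

def _base_probs(gc: float, bias: float, leading_forward: bool
                ) -> dict[str, float]:
    s = 1.0 if leading_forward else -1.0
    return {"G": gc / 2 + s * bias / 2, "C": gc / 2 - s * bias / 2,
            "A": (1 - gc) / 2, "T": (1 - gc) / 2}


def _codon_weights(probs: dict[str, float], strand: str) -> np.ndarray:
    w = np.empty(len(SENSE_CODONS))
    for i, codon in enumerate(SENSE_CODONS):
        p = 1.0
        for b in codon:
            p *= probs[b] if strand == "+" else probs[_COMP[b]]
        w[i] = p
    return w / w.sum()


def _random_bases(rng: np.random.Generator, n: int,
                  probs: dict[str, float]) -> str:
    bases = np.array(list("ACGT"))
    p = np.array([probs[b] for b in "ACGT"])
    return "".join(rng.choice(bases, size=n, p=p / p.sum()))


def _make_gene(rng: np.random.Generator, n_codons: int,
               probs: dict[str, float], strand: str) -> str:
    """Coding-strand sequence: ATG + sense codons + TAA."""
    w = _codon_weights(probs, strand)
    body = rng.choice(SENSE_CODONS, size=n_codons - 2, p=w)
    return "ATG" + "".join(body) + "TAA"


def make_16s(rng: np.random.Generator, length: int = 1200,
             gc: float = 0.54) -> tuple[str, PairingMap, VariabilityMap]:
    """Toy 16S with helices forced Watson-Crick and a variability map
    (stems low-variability, loops increasingly variable)."""
    seq = list(_random_bases(rng, length, _base_probs(gc, 0.0, True)))
    pairs = []
    helix_span = 140
    n_helices = max(1, (length - 20) // helix_span)
    for h in range(n_helices):
        base = h * helix_span + 10
        for t in range(15):
            i, j = base + t, base + 125 - t
            if j >= length:
                continue
            seq[j - 1] = _COMP[seq[i - 1]]
            pairs.append((i, j))
    pairing = PairingMap(pairs)
    paired = set(pairing.partner())
    classes = []
    for pos in range(1, length + 1):
        if pos in paired:
            classes.append(int(rng.integers(1, 3)))  # 1-2: conserved stems
        else:
            classes.append(int(rng.integers(3, 7)))  # 3-6: loops
    return "".join(seq), pairing, VariabilityMap(classes)


def _scrub_kops(seq: list[str], features: list[Feature],
                motif: str = architecture.KOPS_MOTIF,
                max_rounds: int = 20) -> int:
    """Remove chance KOPS motif occurrences; returns count left unfixable."""
    by_pos: list[tuple[int, int]] = []  # (start, end) of containing CDS
    cds = sorted((f.start, f.end, f.strand) for f in features
                 if f.kind == "CDS")

    def containing(pos: int):
        for s, e, st in cds:
            if s <= pos < e:
                return s, e, st
        return None

    for _ in range(max_rounds):
        text = "".join(seq)
        sites = architecture.find_kops(text, motif).sites
        if not sites:
            return 0
        fixed_any = False
        for pos, strand in sites:
            if _fix_motif_site(seq, pos, len(motif), containing):
                fixed_any = True
        if not fixed_any:
            break
    text = "".join(seq)
    return len(architecture.find_kops(text, motif).sites)


def _fix_motif_site(seq: list[str], pos: int, mlen: int, containing) -> bool:
    for off in range(mlen):
        p = pos + off
        if p >= len(seq):
            break
        hit = containing(p)
        if hit is None:
            old = seq[p]
            seq[p] = "A" if old != "A" else "C"
            if _motif_free_window(seq, pos, mlen):
                return True
            seq[p] = old
            continue
        s, e, strand = hit
        if strand == "+":
            cstart = s + ((p - s) // 3) * 3
            codon = "".join(seq[cstart : cstart + 3])
        else:
            cstart = e - (((e - p - 1) // 3) + 1) * 3
            codon = revcomp("".join(seq[cstart : cstart + 3]))
        aa = _CODON_TABLE.get(codon)
        if aa is None or codon in STOPS:
            continue
        for alt in SENSE_CODONS:
            if alt == codon or _CODON_TABLE[alt] != aa:
                continue
            fwd = alt if strand == "+" else revcomp(alt)
            old3 = seq[cstart : cstart + 3]
            seq[cstart : cstart + 3] = list(fwd)
            if _motif_free_window(seq, pos, mlen):
                return True
            seq[cstart : cstart + 3] = old3
    return False


def _motif_free_window(seq: list[str], pos: int, mlen: int) -> bool:
    lo, hi = max(0, pos - mlen), min(len(seq), pos + 2 * mlen)
    window = "".join(seq[lo:hi])
    return not architecture.find_kops(window).sites


def generate_ancestor(cfg: AncestorConfig
                      ) -> tuple[AnnotatedGenome, AncestorMeta]:
    rng = np.random.default_rng(cfg.seed)
    length = cfg.genome_length
    ori, ter = 0, length // 2

    # Gene lengths in codons (including start and stop codons).
    n_cod = np.maximum(
        cfg.gene_length_min // 3,
        np.rint(rng.normal(cfg.gene_length_mean, cfg.gene_length_sd,
                           cfg.n_genes) / 3).astype(int),
    )
    rrna_ref, pairing, vmap = make_16s(rng, cfg.rrna_length, cfg.gc_content)

    slots: list[tuple[str, int]] = [("gene", int(c) * 3) for c in n_cod]
    for r in range(cfg.n_rrna_operons):
        slots.append(("rrna16", cfg.rrna_length))
        slots.append(("rrna5", 120))
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    genic_nt = sum(s[1] for s in slots)
    spare = length - genic_nt - (len(slots) + 1) * cfg.min_gap
    if spare < 0:
        raise SimulationError("genes exceed genome length; infeasible packing")
    extra = rng.multinomial(spare, np.full(len(slots) + 1, 1 / (len(slots) + 1)))
    gaps = extra + cfg.min_gap

    seq_parts: list[str] = []
    features: list[Feature] = []
    gene_strands: dict[str, str] = {}
    cursor = 0
    gi = ri = fi = 0
    for idx, (kind, size) in enumerate(slots):
        gap = int(gaps[idx])
        mid = cursor + gap + size // 2
        leading_fwd = mid < ter  # replichore 1 = [ori, ter)
        probs = _base_probs(cfg.gc_content, cfg.skew_bias, leading_fwd)
        seq_parts.append(_random_bases(rng, gap, probs))
        cursor += gap
        if kind == "gene":
            gi += 1
            tag = f"g{gi:04d}"
            co = rng.random() < cfg.p_co_oriented
            strand = ("+" if leading_fwd else "-") if co else \
                     ("-" if leading_fwd else "+")
            coding = _make_gene(rng, size // 3, probs, strand)
            seq_parts.append(revcomp(coding) if strand == "-" else coding)
            features.append(Feature("CDS", cursor, cursor + size, strand, tag))
            gene_strands[tag] = strand
        elif kind == "rrna16":
            ri += 1
            tag = f"rrs{ri:02d}"
            features.append(Feature("rRNA_16S", cursor, cursor + size, "+",
                                    tag, product="16S ribosomal RNA"))
            seq_parts.append(rrna_ref)
        else:
            fi += 1
            features.append(Feature("rRNA_5S", cursor, cursor + size, "+",
                                    f"rrf{fi:02d}", product="5S ribosomal RNA"))
            seq_parts.append(_random_bases(rng, size, probs))
        cursor += size
    seq_parts.append(_random_bases(
        rng, length - cursor, _base_probs(cfg.gc_content, cfg.skew_bias, False)))
    seq = list("".join(seq_parts))
    assert len(seq) == length

    residual = _scrub_kops(seq, features)

    # Place dif at the terminus, then polarized KOPS in intergenic space.
    used: list[tuple[int, int]] = []
    free = _feature_free_mask(length, features)
    dif = architecture.DIF_HS
    dif_pos = _nearest_free_slot(free, ter, len(dif))
    seq[dif_pos : dif_pos + len(dif)] = list(dif)
    used.append((dif_pos, dif_pos + len(dif)))

    kops_sites: list[tuple[int, str]] = []
    attempts = 0
    while len(kops_sites) < cfg.n_kops and attempts < cfg.n_kops * 200:
        attempts += 1
        pos = int(rng.integers(0, length - 8))
        if not free[pos : pos + 8].all():
            continue
        if any(pos < e + 2 and pos + 8 > s - 2 for s, e in used):
            continue
        leading_fwd = pos < ter
        expected = "+" if leading_fwd else "-"
        polarized = rng.random() < cfg.kops_polarity
        strand = expected if polarized else ("-" if expected == "+" else "+")
        motif = architecture.KOPS_MOTIF.replace("N", rng.choice(list("ACGT")))
        inst = motif if strand == "+" else revcomp(motif)
        seq[pos : pos + 8] = list(inst)
        used.append((pos, pos + 8))
        kops_sites.append((pos, strand))
    if len(kops_sites) < cfg.n_kops:
        raise SimulationError("could not place all KOPS sites")
    kops_sites.sort()

    genome = AnnotatedGenome(f"ancestor_seed{cfg.seed}", "".join(seq),
                             True, features)
    meta = AncestorMeta(ori, ter, dif_pos, kops_sites, gene_strands,
                        rrna_ref, pairing, vmap, residual, cfg)
    return genome, meta


def _feature_free_mask(length: int, features: list[Feature],
                       margin: int = 5) -> np.ndarray:
    free = np.ones(length, dtype=bool)
    for f in features:
        lo = max(0, f.start - margin)
        hi = min(length, (f.start + f.length(length)) + margin)
        free[lo:hi] = False
    return free


def _nearest_free_slot(free: np.ndarray, target: int, size: int) -> int:
    ok = np.convolve(free.astype(int), np.ones(size, dtype=int),
                     mode="valid") == size
    candidates = np.nonzero(ok)[0]
    if candidates.size == 0:
        raise SimulationError("no free slot")
    return int(candidates[np.argmin(np.abs(candidates - target))])


# ---------------------------------------------------------------------------
# IS library
# ---------------------------------------------------------------------------

def make_is_library(seed: int = 0, families: tuple[str, ...] =
                    ("IS5", "IS256", "IS21", "ISL3")) -> list[IsConsensus]:
    """Synthetic IS consensus set: each element carries a transposase ORF."""
    rng = np.random.default_rng(seed + 777)
    lib = []
    for i, fam in enumerate(families):
        orf_codons = int(rng.integers(280, 380))
        body = rng.choice(SENSE_CODONS, size=orf_codons - 2)
        orf = "ATG" + "".join(body) + "TAA"
        left = _random_bases(rng, 60, _base_probs(0.5, 0.0, True))
        right = _random_bases(rng, 60, _base_probs(0.5, 0.0, True))
        seq = left + orf + right
        lib.append(IsConsensus(f"ISync{i + 1}", fam, seq, 60, 60 + len(orf)))
    return lib


# ---------------------------------------------------------------------------
# Genome editor with tracked intervals
# ---------------------------------------------------------------------------

class _Editor:
    def __init__(self, genome: AnnotatedGenome):
        for f in genome.features:
            if f.wraps_origin:
                raise SimulationError("editor requires unwrapped features")
        self.seq = list(genome.sequence)
        self.features = [dc_replace(f) for f in genome.features]
        self.events: list[dict] = []
        self.tracked: dict[str, list] = {}  # name -> [start, end, valid]
        self.removed_features: list[Feature] = []

    def track(self, name: str, start: int, end: int) -> None:
        self.tracked[name] = [start, end, True]

    # -- primitive ops -----------------------------------------------------
    def substitute(self, pos: int, new: str) -> None:
        self.events.append({"op": "sub", "pos": pos, "new": new})
        self.seq[pos] = new

    def replace_range(self, start: int, end: int, new: str) -> None:
        assert end - start == len(new)
        self.events.append({"op": "replace", "start": start, "end": end,
                            "new": new})
        self.seq[start:end] = list(new)

    def insert(self, pos: int, s: str, feature: Feature | None = None) -> None:
        self.events.append({"op": "ins", "pos": pos, "seq": s})
        self.seq[pos:pos] = list(s)
        n = len(s)
        for f in self.features:
            if f.start >= pos:
                f.start += n
                f.end += n
            elif f.end > pos:
                f.end += n
        for t in self.tracked.values():
            if t[0] >= pos:
                t[0] += n
                t[1] += n
            elif t[1] > pos:
                t[1] += n
        if feature is not None:
            self.features.append(dc_replace(feature, start=pos, end=pos + n))

    def delete(self, start: int, end: int) -> list[str]:
        self.events.append({"op": "del", "start": start, "end": end})
        del self.seq[start:end]
        n = end - start
        kept, lost = [], []
        for f in self.features:
            if f.end <= start:
                kept.append(f)
            elif f.start >= end:
                f.start -= n
                f.end -= n
                kept.append(f)
            elif f.start >= start and f.end <= end:
                lost.append(f.locus_tag)
                self.removed_features.append(f)
            else:  # partial overlap: trim
                f.start = min(f.start, start) if f.start < start else start
                f.end = start if f.end <= end else f.end - n
                if f.end > f.start:
                    kept.append(f)
                else:
                    lost.append(f.locus_tag)
        self.features = kept
        for t in self.tracked.values():
            if t[0] >= end:
                t[0] -= n
                t[1] -= n
            elif t[1] > start:
                t[2] = False
        return lost

    def invert(self, start: int, end: int) -> None:
        self.events.append({"op": "inv", "start": start, "end": end})
        self.seq[start:end] = list(revcomp("".join(self.seq[start:end])))
        for f in self.features:
            if f.start >= start and f.end <= end:
                f.start, f.end = start + end - f.end, start + end - f.start
                f.strand = "-" if f.strand == "+" else "+"
            elif f.start < end and f.end > start:
                raise SimulationError("inversion breakpoint inside a feature")
        for t in self.tracked.values():
            if t[0] >= start and t[1] <= end:
                t[0], t[1] = start + end - t[1], start + end - t[0]
            elif t[0] < end and t[1] > start:
                t[2] = False

    def move(self, start: int, end: int, dest: int) -> None:
        """Cut [start,end) and reinsert so it begins at post-cut ``dest``."""
        assert dest <= start or dest >= end
        seg = "".join(self.seq[start:end])
        seg_feats = [f for f in self.features
                     if f.start >= start and f.end <= end]
        for f in seg_feats:
            self.features.remove(f)
        n = end - start
        adj = dest if dest <= start else dest - n
        self.events.append({"op": "mov", "start": start, "end": end,
                            "dest": adj})
        del self.seq[start:end]
        for f in self.features:
            if f.start >= end:
                f.start -= n
                f.end -= n
            elif f.end > start and f.start < start:
                raise SimulationError("translocation breakpoint inside feature")
        for t in self.tracked.values():
            if t[0] >= end:
                t[0] -= n
                t[1] -= n
            elif t[1] > start and t[0] < end:
                t[2] = False
        self.seq[adj:adj] = list(seg)
        for f in self.features:
            if f.start >= adj:
                f.start += n
                f.end += n
            elif f.end > adj:
                f.end += n
        for t in self.tracked.values():
            if t[0] >= adj:
                t[0] += n
                t[1] += n
            elif t[1] > adj:
                t[1] += n
        for f in seg_feats:
            off = adj - start
            self.features.append(dc_replace(f, start=f.start + off,
                                            end=f.end + off))

    # -- helpers -----------------------------------------------------------
    def free_mask(self, margin: int = 5) -> np.ndarray:
        return _feature_free_mask(len(self.seq), self.features, margin)

    def get_feature(self, tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == tag:
                return f
        raise KeyError(tag)

    def to_genome(self, gid: str) -> AnnotatedGenome:
        feats = sorted(self.features, key=lambda f: (f.start, f.locus_tag))
        return AnnotatedGenome(gid, "".join(self.seq), True, feats)


def replay(ancestor: AnnotatedGenome, events: list[dict]) -> str:
    """Apply a ledger's primitive events; returns the derived sequence."""
    seq = list(ancestor.sequence)
    for ev in events:
        op = ev["op"]
        if op == "sub":
            seq[ev["pos"]] = ev["new"]
        elif op == "replace":
            seq[ev["start"] : ev["end"]] = list(ev["new"])
        elif op == "ins":
            seq[ev["pos"] : ev["pos"]] = list(ev["seq"])
        elif op == "del":
            del seq[ev["start"] : ev["end"]]
        elif op == "inv":
            seq[ev["start"] : ev["end"]] = list(
                revcomp("".join(seq[ev["start"] : ev["end"]])))
        elif op == "mov":
            seg = seq[ev["start"] : ev["end"]]
            del seq[ev["start"] : ev["end"]]
            seq[ev["dest"] : ev["dest"]] = seg
        else:
            raise ValueError(f"unknown op {op}")
    return "".join(seq)


# ---------------------------------------------------------------------------
# Degeneration
# ---------------------------------------------------------------------------

def _codon_fwd_interval(f: Feature, codon: int) -> tuple[int, int]:
    """Forward-strand interval of 1-based coding codon ``codon``."""
    if f.strand == "+":
        s = f.start + 3 * (codon - 1)
    else:
        s = f.end - 3 * codon
    return s, s + 3


def _write_codon(ed: _Editor, f: Feature, codon: int, coding_codon: str,
                 record: bool = True) -> None:
    s, e = _codon_fwd_interval(f, codon)
    fwd = coding_codon if f.strand == "+" else revcomp(coding_codon)
    for off, b in enumerate(fwd):
        if ed.seq[s + off] != b:
            ed.substitute(s + off, b)


def degenerate(ancestor: AnnotatedGenome, params: DegenerationParams,
               is_library: list[IsConsensus] | None = None,
               meta: AncestorMeta | None = None
               ) -> tuple[AnnotatedGenome, TruthLedger]:
    rng = np.random.default_rng(params.seed)
    if is_library is None:
        is_library = make_is_library(params.seed)
    ed = _Editor(ancestor)
    ledger = TruthLedger(params.seed, ancestor.id)
    length = len(ed.seq)
    if meta is not None:
        ed.track("ori", meta.ori, meta.ori + 1)
        ed.track("ter", meta.ter, meta.ter + 1)

    # Phase 1: background substitutions (never stop-creating, never in rRNA).
    if params.mu > 0:
        n_subs = rng.binomial(length, params.mu)
        positions = np.sort(rng.choice(length, size=n_subs, replace=False))
        rrna = [(f.start, f.end) for f in ed.features
                if f.kind.startswith("rRNA")]
        cds = sorted((f.start, f.end, f.strand) for f in ed.features
                     if f.kind == "CDS")
        applied = 0
        for pos in positions:
            pos = int(pos)
            if any(s <= pos < e for s, e in rrna):
                continue
            old = ed.seq[pos]
            if old == "N":
                continue
            new = str(rng.choice([b for b in "ACGT" if b != old]))
            change = _codon_change(ed, cds, pos, new)
            if change is not None:
                old_codon, new_codon = change
                if new_codon in STOPS:
                    continue
                if (_CODON_TABLE[old_codon] != _CODON_TABLE[new_codon]
                        and rng.random() >= params.background_omega):
                    continue  # nonsynonymous change purged by selection
            ed.substitute(pos, new)
            applied += 1
        ledger.n_background_subs = applied

    # Phase 2: gene inactivations.
    tags = sorted(meta.gene_strands) if meta else sorted(
        f.locus_tag for f in ed.features if f.kind == "CDS")
    draw = rng.random(len(tags))
    types = rng.choice(["frameshift_indel", "premature_stop", "truncation"],
                       size=len(tags), p=list(params.mutation_weights))
    for tag, u, mtype in zip(tags, draw, types):
        if u >= params.p_pseudo:
            continue
        f = ed.get_feature(tag)
        n_cod = (f.end - f.start) // 3
        recs = _inactivate_gene(ed, rng, f, n_cod, str(mtype))
        ledger.inactivated.setdefault(tag, []).extend(recs)

    # Phase 3: IS-bounded tandem duplications.
    lib_by_family = {c.family: c for c in is_library}
    for di in range(params.n_duplications):
        _apply_duplication(ed, rng, params, lib_by_family, ledger, di)

    # Phase 4: IS insertions.
    for ii in range(params.n_is_insertions):
        _apply_is_insertion(ed, rng, params, is_library, ledger, ii)

    # Phase 5: inversions (sampled disjoint, so each maps to one block).
    inverted: list[tuple[int, int]] = []
    for _ in range(params.n_inversions):
        ival = _sample_free_segment(ed, rng, params.inversion_length,
                                    blocked=inverted)
        ed.invert(*ival)
        inverted.append(ival)
        ledger.inversions.append({"start": ival[0], "end": ival[1]})

    # Phase 6: translocations.
    for _ in range(params.n_translocations):
        a, b = _sample_free_segment(ed, rng, params.translocation_length)
        free = ed.free_mask()
        for t in ed.tracked.values():
            if t[2]:
                free[max(0, t[0] - 5) : t[1] + 5] = False
        free[max(0, a - 1) : b + 1] = False
        dest_opts = np.nonzero(free)[0]
        if dest_opts.size == 0:
            raise SimulationError("no translocation destination")
        dest = int(rng.choice(dest_opts))
        ed.move(a, b, dest)
        ledger.translocations.append({"start": a, "end": b, "dest": dest})

    # Phase 7: deletions.
    for _ in range(params.n_deletions):
        a, b = _sample_free_segment(ed, rng, params.deletion_length)
        lost = ed.delete(a, b)
        ledger.deletions.append({"start": a, "end": b, "loci": lost})
        ledger.deleted_loci.extend(lost)

    # rRNA substitutions (variability-weighted), per 16S copy.
    if params.rrna_n_subs > 0 and meta is not None:
        for f in [f for f in ed.features if f.kind == "rRNA_16S"]:
            positions = sample_variability_positions(
                meta.vmap, params.rrna_n_subs, rng)
            ledger.rrna_subs[f.locus_tag] = [int(p) for p in positions]
            for p in positions:
                p = int(p)  # 1-based on the coding strand
                gpos = f.start + p - 1 if f.strand == "+" else f.end - p
                old = ed.seq[gpos]
                new = str(rng.choice([b for b in "ACGT" if b != old]))
                ed.substitute(gpos, new)

    ledger.events = ed.events
    for name in ("ori", "ter"):
        t = ed.tracked.get(name)
        if t is not None and t[2]:
            setattr(ledger, f"final_{name}", t[0])
    # Final coordinates for tracked duplication intervals.
    for rec in ledger.duplications:
        for key in ("a", "b"):
            t = ed.tracked[f"dup{rec['index']}_{key}"]
            rec[f"interval_{key}"] = [t[0], t[1]] if t[2] else None
    derived = ed.to_genome(f"derived_seed{params.seed}")
    return derived, ledger


def _codon_change(ed: _Editor, cds: list[tuple[int, int, str]], pos: int,
                  new: str) -> tuple[str, str] | None:
    """(old codon, new codon) on the coding strand if ``pos`` lies in a CDS,
    else None."""
    for s, e, strand in cds:
        if s <= pos < e:
            if strand == "+":
                cstart = s + ((pos - s) // 3) * 3
            else:
                k = (e - pos - 1) // 3
                cstart = e - 3 * (k + 1)
            fwd = "".join(ed.seq[cstart : cstart + 3])
            fwd_new = fwd[: pos - cstart] + new + fwd[pos - cstart + 1 :]
            if strand == "-":
                return revcomp(fwd), revcomp(fwd_new)
            return fwd, fwd_new
    return None


def _inactivate_gene(ed: _Editor, rng: np.random.Generator, f: Feature,
                     n_cod: int, mtype: str) -> list[dict]:
    lo, hi = 4, n_cod - 5  # >= 9 nt from both ORF ends, clear of stop tail
    if hi <= lo:
        lo, hi = 2, max(3, n_cod - 3)
    if mtype == "frameshift_indel":
        codon = int(rng.integers(lo, hi + 1))
        s, _ = _codon_fwd_interval(f, codon)
        if rng.random() < 0.5:
            ed.delete(s, s + 1)
            detail = "-1nt"
        else:
            ed.insert(s, str(rng.choice(list("ACGT"))))
            detail = "+1nt"
        return [{"type": "frameshift_indel", "codon": codon,
                 "detail": detail}]
    if mtype == "premature_stop":
        codon = int(rng.integers(lo, hi + 1))
        _write_codon(ed, f, codon, "TAA")
        return [{"type": "premature_stop", "codon": codon, "detail": "TAA"}]
    # Truncation: premature stop then downstream scramble.
    codon = int(rng.integers(max(lo, int(n_cod * 0.35)),
                             max(lo + 1, int(n_cod * 0.7))))
    _write_codon(ed, f, codon, "TAA")
    if f.strand == "+":
        lo_nt, hi_nt = f.start + 3 * codon, f.end - 3
    else:
        lo_nt, hi_nt = f.start + 3, f.end - 3 * codon
    scramble = "".join(rng.choice(list("ACGT"), size=hi_nt - lo_nt))
    ed.replace_range(lo_nt, hi_nt, scramble)
    return [{"type": "truncation", "codon": codon,
             "detail": f"scrambled_from_codon_{codon}"}]


def _sample_free_segment(ed: _Editor, rng: np.random.Generator,
                         length_range: tuple[int, int],
                         max_tries: int = 400,
                         blocked: list[tuple[int, int]] | None = None
                         ) -> tuple[int, int]:
    """Segment with both breakpoints in feature-free space, avoiding
    tracked (duplication) intervals and any explicitly blocked intervals."""
    free = ed.free_mask()
    for t in ed.tracked.values():
        if t[2]:
            free[max(0, t[0] - 5) : t[1] + 5] = False
    candidates = np.nonzero(free)[0]
    if candidates.size == 0:
        raise SimulationError("no feature-free breakpoints available")
    for _ in range(max_tries):
        size = int(rng.integers(length_range[0], length_range[1] + 1))
        a = int(rng.choice(candidates))
        b = a + size
        if b >= len(ed.seq) - 1:
            continue
        if not free[b]:
            continue
        if blocked and any(a < hi and b > lo for lo, hi in blocked):
            continue
        return a, b
    raise SimulationError("could not sample a feature-free segment; "
                          "event collision retries exhausted")


def _apply_duplication(ed: _Editor, rng: np.random.Generator,
                       params: DegenerationParams,
                       lib_by_family: dict[str, IsConsensus],
                       ledger: TruthLedger, index: int) -> None:
    cons = lib_by_family.get(params.duplication_family)
    if cons is None:
        raise SimulationError(
            f"family {params.duplication_family} not in IS library")
    L = params.duplication_length
    free = ed.free_mask()
    candidates = np.nonzero(free[: max(1, len(ed.seq) - L - 1)])[0]
    src = None
    for _ in range(400):
        s = int(rng.choice(candidates))
        if free[s + L]:
            src = s
            break
    if src is None:
        raise SimulationError("no duplication source interval found")
    li = len(cons.seq)
    ed.insert(src, cons.seq, Feature("IS_element", 0, 0, "+",
                                     f"dup{index}_isL", family=cons.family))
    a0 = src + li  # unit now starts here
    unit = "".join(ed.seq[a0 : a0 + L])
    ed.insert(a0 + L, cons.seq, Feature("IS_element", 0, 0, "+",
                                        f"dup{index}_isM", family=cons.family))
    copy_b = _mutate_copy(unit, params.duplication_subs,
                          params.duplication_indels, rng)
    b0 = a0 + L + li
    ed.insert(b0, copy_b)
    ed.insert(b0 + len(copy_b), cons.seq,
              Feature("IS_element", 0, 0, "+", f"dup{index}_isR",
                      family=cons.family))
    ed.track(f"dup{index}_a", a0, a0 + L)
    ed.track(f"dup{index}_b", b0, b0 + len(copy_b))
    ledger.duplications.append({
        "index": index, "length": L,
        "n_subs": params.duplication_subs,
        "n_indels": params.duplication_indels,
        "family": cons.family,
    })


def _mutate_copy(unit: str, n_subs: int, n_indels: int,
                 rng: np.random.Generator) -> str:
    """Copy with n_subs substitutions and n_indels single-base indels at
    well-separated interior positions."""
    n = len(unit)
    k = n_subs + n_indels
    positions = np.sort(rng.choice(np.arange(100, n - 100), size=k,
                                   replace=False))
    while np.any(np.diff(positions) < 50):
        positions = np.sort(rng.choice(np.arange(100, n - 100), size=k,
                                       replace=False))
    roles = rng.permutation(["sub"] * n_subs + ["indel"] * n_indels)
    out = []
    prev = 0
    for pos, role in zip(positions, roles):
        pos = int(pos)
        out.append(unit[prev:pos])
        if role == "sub":
            old = unit[pos]
            out.append(str(rng.choice([b for b in "ACGT" if b != old])))
            prev = pos + 1
        elif rng.random() < 0.5:  # deletion of one base
            prev = pos + 1
        else:  # insertion of one base
            out.append(str(rng.choice(list("ACGT"))))
            out.append(unit[pos])
            prev = pos + 1
    out.append(unit[prev:])
    return "".join(out)


def _apply_is_insertion(ed: _Editor, rng: np.random.Generator,
                        params: DegenerationParams,
                        is_library: list[IsConsensus],
                        ledger: TruthLedger, index: int) -> None:
    cons = is_library[int(rng.integers(0, len(is_library)))]
    strand = "+" if rng.random() < 0.5 else "-"
    disrupted = rng.random() < params.p_is_disrupted
    seq = cons.seq
    if disrupted:
        cut = cons.orf_start + (cons.orf_end - cons.orf_start) // 2
        seq = seq[:cut] + seq[cut + 1 :]  # frameshift in the transposase
    if strand == "-":
        seq = revcomp(seq)
    intergenic = rng.random() < params.is_intergenic_bias
    locus = None
    if intergenic:
        free = ed.free_mask()
        for t in ed.tracked.values():
            if t[2]:
                free[max(0, t[0] - 5) : t[1] + 5] = False
        opts = np.nonzero(free)[0]
        if opts.size == 0:
            raise SimulationError("no intergenic IS target")
        pos = int(rng.choice(opts))
    else:
        blocked = [(t[0], t[1]) for t in ed.tracked.values() if t[2]]
        genes = [f for f in ed.features if f.kind == "CDS"
                 and f.end - f.start > 120
                 and not any(f.start < hi and f.end > lo
                             for lo, hi in blocked)]
        if not genes:
            raise SimulationError("no genic IS target")
        weights = np.array([f.end - f.start - 60 for f in genes], dtype=float)
        g = genes[int(rng.choice(len(genes), p=weights / weights.sum()))]
        pos = int(rng.integers(g.start + 30, g.end - 30))
        locus = g.locus_tag
    tag = f"ins{index:03d}_{cons.name}"
    ed.insert(pos, seq, Feature("IS_element", 0, 0, strand, tag,
                                family=cons.family))
    ed.track(f"is_{index}", pos, pos + len(seq))
    if locus is not None:
        ledger.inactivated.setdefault(locus, []).append(
            {"type": "is_interruption", "codon": None,
             "detail": f"{cons.name}"})
    ledger.is_insertions.append({
        "index": index, "family": cons.family, "name": cons.name,
        "strand": strand, "disrupted": bool(disrupted),
        "target": "genic" if locus else "intergenic", "locus": locus,
    })


def sample_variability_positions(vmap: VariabilityMap, n: int,
                                 rng: np.random.Generator) -> np.ndarray:
    """Substitution positions (1-based) drawn with probability proportional
    to the variability class value."""
    w = np.asarray(vmap.classes, dtype=float)
    return 1 + rng.choice(len(w), size=n, replace=False, p=w / w.sum())


# ---------------------------------------------------------------------------
# Codon-pair evolution for selection analyses
# ---------------------------------------------------------------------------

def simulate_codon_pair(n_codons: int, omega: float, n_proposals: int,
                        rng: np.random.Generator
                        ) -> tuple[list[str], list[str]]:
    """Ancestor/derived codon lists evolved under a syn/nonsyn rate dial.

    Proposals are single-nucleotide changes at uniform positions; a
    synonymous proposal is always accepted, a nonsynonymous one with
    probability ``omega``; stop-creating proposals are rejected.
    """
    ref = list(rng.choice(SENSE_CODONS, size=n_codons))
    der = list(ref)
    for _ in range(n_proposals):
        ci = int(rng.integers(0, n_codons))
        pos = int(rng.integers(0, 3))
        codon = der[ci]
        new_base = str(rng.choice([b for b in "ACGT" if b != codon[pos]]))
        alt = codon[:pos] + new_base + codon[pos + 1 :]
        if alt in STOPS:
            continue
        if _CODON_TABLE[alt] == _CODON_TABLE[codon] or rng.random() < omega:
            der[ci] = alt
    return ref, der


# ---------------------------------------------------------------------------
# Scoring and emission
# ---------------------------------------------------------------------------

def score_classification(report, ledger: TruthLedger
                         ) -> tuple[float, float, int, int]:
    """(recall, precision, n_truth, n_predicted) of pseudogene calls
    against the ledger, over genes still present in the derived genome."""
    present = {c.der_locus for c in report.classifications}
    truth = (set(ledger.inactivated) - set(ledger.deleted_loci)) & present
    pred = {c.der_locus for c in report.classifications
            if c.verdict == "pseudogene"}
    tp = len(pred & truth)
    recall = tp / len(truth) if truth else float("nan")
    precision = tp / len(pred) if pred else float("nan")
    return recall, precision, len(truth), len(pred)


def emit_bundle(outdir: str | Path, ancestor: AnnotatedGenome,
                derived: AnnotatedGenome, ledger: TruthLedger,
                meta: AncestorMeta,
                is_library: list[IsConsensus]) -> None:
    from .genome_io import write_genome

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_genome(ancestor, outdir / "ancestor.fasta", "fasta+gff3")
    write_genome(derived, outdir / "derived.fasta", "fasta+gff3")
    ledger.to_json(outdir / "ledger.json")
    meta.pairing.to_tsv(outdir / "rrna_pairing.tsv")
    meta.vmap.to_tsv(outdir / "rrna_variability.tsv")
    lines = []
    for c in is_library:
        lines.append(f">{c.name} family={c.family} "
                     f"orf={c.orf_start}..{c.orf_end}")
        lines.append(c.seq)
    (outdir / "is_library.fasta").write_text("\n".join(lines) + "\n")
    info = {"ori": meta.ori, "ter": meta.ter, "dif": meta.dif_pos,
            "kops": meta.kops, "residual_kops": meta.residual_kops}
    (outdir / "ancestor_meta.json").write_text(json.dumps(info, indent=1))


def load_is_library(path: str | Path) -> list[IsConsensus]:
    lib = []
    name = family = None
    orf = (0, 0)
    seq_lines: list[str] = []

    def flush():
        if name is not None:
            lib.append(IsConsensus(name, family or "IS", "".join(seq_lines),
                                   orf[0], orf[1]))

    for line in Path(path).read_text().splitlines():
        if line.startswith(">"):
            flush()
            parts = line[1:].split()
            name = parts[0]
            family = None
            orf = (0, 0)
            seq_lines = []
            for p in parts[1:]:
                if p.startswith("family="):
                    family = p.split("=", 1)[1]
                elif p.startswith("orf="):
                    a, b = p.split("=", 1)[1].split("..")
                    orf = (int(a), int(b))
        else:
            seq_lines.append(line.strip())
    flush()
    return lib
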