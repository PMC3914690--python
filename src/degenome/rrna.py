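"""16S rRNA mutation classification.

Substitutions relative to a reference 16S gene are classified two ways:

* against a stem pairing map — a substituted paired position is
  *conservative* when the resulting base pair in the query molecule (using
  the partner's query state, i.e. the realized molecule) is Watson-Crick or
  G·U wobble (G·T in DNA representation), *disruptive* otherwise;
  substitutions at unpaired positions are *loop*;
* against a per-position variability map (ordinal classes 1 = invariant ..
  6 = hypervariable) — substitutions are binned as rare-site (classes 1-2
  by default) versus common-site.

Gapped positions are excluded from both classifications and counted
separately; indels are therefore reported but never typed as substitutions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from . import _align

_GOOD_PAIRS = frozenset({
    "AT", "TA", "GC", "CG",  # Watson-Crick
    "GT", "TG",  # G.U wobble in DNA representation
})


@dataclass
class PairingMap:
    pairs: list[tuple[int, int]]  # 1-based reference positions, i < j

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for i, j in self.pairs:
            if not i < j:
                raise ValueError(f"pair ({i},{j}) must have i < j")
            if i in seen or j in seen:
                raise ValueError(f"position in more than one pair: ({i},{j})")
            seen.update((i, j))

    def partner(self) -> dict[int, int]:
        d: dict[int, int] = {}
        for i, j in self.pairs:
            d[i] = j
            d[j] = i
        return d

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PairingMap":
        pairs = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            i, j = line.split("\t")[:2]
            pairs.append((int(i), int(j)))
        return cls(pairs)

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{i}\t{j}\n" for i, j in self.pairs))


@dataclass
class VariabilityMap:
    classes: list[int]  # index 0 = reference position 1

    def __post_init__(self) -> None:
        if any(not 1 <= c <= 6 for c in self.classes):
            raise ValueError("variability classes must be in 1..6")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "VariabilityMap":
        rows = []
        for line in Path(path).read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            pos, cl = line.split("\t")[:2]
            rows.append((int(pos), int(cl)))
        rows.sort()
        return cls([c for _, c in rows])

    def to_tsv(self, path: str | Path) -> None:
        Path(path).write_text(
            "".join(f"{p}\t{c}\n" for p, c in enumerate(self.classes, 1)))


@dataclass
class StemMutationReport:
    conservative: int
    disruptive: int
    loop: int
    gapped: int  # ref positions involved in indels, excluded from the above
    per_site: list[tuple[int, str, str, str]]  # (pos, ref, query, verdict)

    @property
    def total_substitutions(self) -> int:
        return self.conservative + self.disruptive + self.loop

    @property
    def disruptive_to_conservative(self) -> float:
        if self.conservative == 0:
            return float("inf") if self.disruptive else float("nan")
        return self.disruptive / self.conservative


def _project(ref: str, query: str) -> list[str]:
    _, _, ops = _align.align_path(ref, query, mode="NW")
    ops = _align.normalize_paired_indels(ref, query, ops)
    proj, _ = _align.project_target_onto_query(ref, query, ops)
    return proj


def classify_stem_mutations(ref_16s: str, query_16s: str,
                            pairing: PairingMap) -> StemMutationReport:
    ref = ref_16s.upper()
    proj = _project(ref, query_16s.upper())
    partner = pairing.partner()
    for i, j in pairing.pairs:
        if j > len(ref):
            raise ValueError(f"pairing index {j} outside reference")
    conservative = disruptive = loop = gapped = 0
    per_site = []
    for pos1 in range(1, len(ref) + 1):
        r, q = ref[pos1 - 1], proj[pos1 - 1]
        if q == "-":
            gapped += 1
            continue
        if q == r:
            continue
        mate = partner.get(pos1)
        if mate is None:
            loop += 1
            per_site.append((pos1, r, q, "loop"))
            continue
        mate_q = proj[mate - 1]
        if mate_q == "-":
            gapped += 1
            per_site.append((pos1, r, q, "gapped_partner"))
            continue
        # Evaluate the realized query pair, 5' member first.
        duo = q + mate_q if pos1 < mate else mate_q + q
        verdict = "conservative" if duo in _GOOD_PAIRS else "disruptive"
        if verdict == "conservative":
            conservative += 1
        else:
            disruptive += 1
        per_site.append((pos1, r, q, verdict))
    return StemMutationReport(conservative, disruptive, loop, gapped, per_site)


@dataclass
class VariabilityReport:
    rare_site_subs: int
    common_site_subs: int
    gapped: int
    by_class: dict[int, int]

    @property
    def rare_fraction(self) -> float:
        total = self.rare_site_subs + self.common_site_subs
        return self.rare_site_subs / total if total else float("nan")


def classify_variability(ref_16s: str, query_16s: str, vmap: VariabilityMap,
                         rare_classes: frozenset[int] = frozenset({1, 2})
                         ) -> VariabilityReport:
    ref = ref_16s.upper()
    if len(vmap.classes) < len(ref):
        raise ValueError("variability map does not cover reference length")
    proj = _project(ref, query_16s.upper())
    rare = common = gapped = 0
    by_class: dict[int, int] = {c: 0 for c in range(1, 7)}
    for pos0, (r, q) in enumerate(zip(ref, proj)):
        if q == "-":
            gapped += 1
            continue
        if q == r:
            continue
        cl = vmap.classes[pos0]
        by_class[cl] += 1
        if cl in rare_classes:
            rare += 1
        else:
            common += 1
    return VariabilityReport(rare, common, gapped, by_class)
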