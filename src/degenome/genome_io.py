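"""Genome and annotation I/O plus coordinate/masking services.

Internal convention is 0-based half-open intervals on the forward strand;
GenBank and GFF3 round-trip through the standard 1-based inclusive
coordinates.  Circular genomes keep a single record; a feature crossing the
origin is stored with ``wraps_origin=True`` and ``end`` reduced modulo the
genome length (so ``end <= start`` only for wrapped features).
"""

from __future__ import annotations

import urllib.parse
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

FEATURE_KINDS = (
    "CDS",
    "pseudogene",
    "rRNA_16S",
    "rRNA_23S",
    "rRNA_5S",
    "tRNA",
    "IS_element",
    "phage",
    "other",
)

_VALID_BASES = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGTN string."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeParseError(ValueError):
    """Raised when an input file cannot be parsed or validated."""


@dataclass
class Feature:
    kind: str
    start: int  # 0-based
    end: int  # half-open; end <= start only when wraps_origin
    strand: str  # '+' or '-'
    locus_tag: str
    product: str | None = None
    family: str | None = None
    wraps_origin: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome_length required for wrapped feature")
            return genome_length - self.start + self.end
        return self.end - self.start

    def positions(self, genome_length: int) -> np.ndarray:
        """All forward-strand positions covered, in 5'->3' forward order."""
        if self.wraps_origin:
            return np.concatenate(
                [np.arange(self.start, genome_length), np.arange(0, self.end)]
            )
        return np.arange(self.start, self.end)

    def midpoint(self, genome_length: int) -> int:
        return int(
            (self.start + self.length(genome_length) // 2) % genome_length
        )


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    is_circular: bool = True
    features: list[Feature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise GenomeParseError(
                f"genome {self.id}: invalid characters {sorted(bad)}"
            )
        if len(self.sequence) < 1:
            raise GenomeParseError(f"genome {self.id}: empty sequence")
        self.validate_features()

    def __len__(self) -> int:
        return len(self.sequence)

    def validate_features(self) -> None:
        length = len(self.sequence)
        seen: set[str] = set()
        for f in self.features:
            if f.kind not in FEATURE_KINDS:
                raise GenomeParseError(f"{f.locus_tag}: unknown kind {f.kind}")
            if f.strand not in "+-":
                raise GenomeParseError(f"{f.locus_tag}: bad strand {f.strand}")
            if not (0 <= f.start < length) or not (0 < f.end <= length):
                raise GenomeParseError(
                    f"{f.locus_tag}: interval [{f.start},{f.end}) outside "
                    f"[0,{length})"
                )
            if f.wraps_origin:
                if not self.is_circular:
                    raise GenomeParseError(
                        f"{f.locus_tag}: wrapped feature on linear genome"
                    )
            elif f.start >= f.end:
                raise GenomeParseError(
                    f"{f.locus_tag}: start >= end without wraps_origin"
                )
            if f.locus_tag in seen:
                raise GenomeParseError(f"duplicate locus_tag {f.locus_tag}")
            seen.add(f.locus_tag)

    def features_of_kind(self, *kinds: str) -> list[Feature]:
        return [f for f in self.features if f.kind in kinds]

    def get_feature(self, locus_tag: str) -> Feature:
        for f in self.features:
            if f.locus_tag == locus_tag:
                return f
        raise KeyError(locus_tag)

    def feature_seq(self, feature: Feature) -> str:
        """Feature sequence on its coding strand (5'->3')."""
        if feature.wraps_origin:
            nt = self.sequence[feature.start :] + self.sequence[: feature.end]
        else:
            nt = self.sequence[feature.start : feature.end]
        return revcomp(nt) if feature.strand == "-" else nt


def rotate(genome: AnnotatedGenome, offset: int) -> AnnotatedGenome:
    """Linearized copy rotated so original position ``offset`` becomes 0.

    Features that end up crossing the new origin are flagged wraps_origin.
    """
    length = len(genome)
    offset %= length
    seq = genome.sequence[offset:] + genome.sequence[:offset]
    feats = []
    for f in genome.features:
        start = (f.start - offset) % length
        end_excl = (f.start + f.length(length) - offset - 1) % length + 1
        wraps = end_excl <= start
        feats.append(
            replace(f, start=start, end=end_excl % length if wraps else end_excl,
                    wraps_origin=wraps)
        )
    return AnnotatedGenome(genome.id, seq, genome.is_circular, feats)


def mask_features(genome: AnnotatedGenome, kinds: set[str]) -> str:
    """Sequence with positions of the selected feature kinds replaced by N."""
    unknown = set(kinds) - set(FEATURE_KINDS)
    if unknown:
        raise ValueError(f"unknown feature kinds: {sorted(unknown)}")
    if not kinds:
        return genome.sequence
    arr = np.frombuffer(genome.sequence.encode(), dtype="S1").copy()
    for f in genome.features:
        if f.kind in kinds:
            arr[f.positions(len(genome))] = b"N"
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GENBANK_KIND = {
    "CDS": "CDS",
    "pseudogene": "CDS",
    "tRNA": "tRNA",
    "rRNA_16S": "rRNA",
    "rRNA_23S": "rRNA",
    "rRNA_5S": "rRNA",
    "IS_element": "mobile_element",
    "phage": "misc_feature",
    "other": "misc_feature",
}


def _kind_from_genbank(feat: SeqFeature) -> str | None:
    q = feat.qualifiers
    if feat.type == "CDS":
        return "pseudogene" if ("pseudo" in q or "pseudogene" in q) else "CDS"
    if feat.type == "tRNA":
        return "tRNA"
    if feat.type == "rRNA":
        product = (q.get("product") or [""])[0].lower()
        for tag, kind in (("16s", "rRNA_16S"), ("23s", "rRNA_23S"),
                          ("5s", "rRNA_5S")):
            if tag in product:
                return kind
        return "other"
    if feat.type in ("mobile_element", "repeat_region"):
        return "IS_element"
    if feat.type == "misc_feature":
        note = (q.get("note") or [""])[0].lower()
        if "phage" in note or "prophage" in note:
            return "phage"
        return "other"
    return None


def _read_genbank(path: Path) -> AnnotatedGenome:
    try:
        record = next(SeqIO.parse(str(path), "genbank"))
    except (StopIteration, ValueError) as exc:
        raise GenomeParseError(f"{path}: not a parseable GenBank record: {exc}")
    is_circular = record.annotations.get("topology", "linear") == "circular"
    length = len(record.seq)
    feats = []
    counter = 0
    for feat in record.features:
        kind = _kind_from_genbank(feat)
        if kind is None:
            continue
        counter += 1
        q = feat.qualifiers
        tag = (q.get("locus_tag") or [f"feat{counter:05d}"])[0]
        product = (q.get("product") or [None])[0]
        family = (q.get("mobile_element_type") or q.get("rpt_family") or [None])[0]
        loc = feat.location
        start = int(loc.start)
        end = int(loc.end)
        wraps = False
        if isinstance(loc, CompoundLocation) and is_circular:
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            if len(parts) == 2 and int(parts[0].start) == 0 and int(parts[1].end) == length:
                start, end, wraps = int(parts[1].start), int(parts[0].end), True
        strand = "-" if loc.strand == -1 else "+"
        feats.append(Feature(kind, start, end, strand, tag, product, family, wraps))
    return AnnotatedGenome(record.id or path.stem, str(record.seq),
                           is_circular, feats)


def _write_genbank(genome: AnnotatedGenome, path: Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, name=genome.id[:16],
                       description="")
    record.annotations["molecule_type"] = "DNA"
    record.annotations["topology"] = (
        "circular" if genome.is_circular else "linear"
    )
    length = len(genome)
    for f in genome.features:
        strand = -1 if f.strand == "-" else 1
        if f.wraps_origin:
            loc = CompoundLocation(
                [SimpleLocation(f.start, length, strand),
                 SimpleLocation(0, f.end, strand)]
                if strand == 1
                else [SimpleLocation(0, f.end, strand),
                      SimpleLocation(f.start, length, strand)]
            )
        else:
            loc = SimpleLocation(f.start, f.end, strand)
        quals: dict[str, list[str]] = {"locus_tag": [f.locus_tag]}
        if f.kind == "pseudogene":
            quals["pseudo"] = [""]
        if f.product:
            quals["product"] = [f.product]
        if f.kind == "IS_element" and f.family:
            quals["mobile_element_type"] = [f.family]
        if f.kind.startswith("rRNA_") and not f.product:
            quals["product"] = [f.kind.split("_")[1] + " ribosomal RNA"]
        if f.kind == "phage":
            quals["note"] = ["prophage region"]
        record.features.append(
            SeqFeature(loc, type=_GENBANK_KIND[f.kind], qualifiers=quals)
        )
    SeqIO.write(record, str(path), "genbank")


# ---------------------------------------------------------------------------
# FASTA + GFF3
# ---------------------------------------------------------------------------

def _gff3_escape(value: str) -> str:
    return urllib.parse.quote(value, safe=" ")


def _read_fasta_gff3(fasta_path: Path, gff3_path: Path,
                     is_circular: bool) -> AnnotatedGenome:
    import gffutils

    try:
        record = next(SeqIO.parse(str(fasta_path), "fasta"))
    except StopIteration:
        raise GenomeParseError(f"{fasta_path}: no FASTA record")
    length = len(record.seq)
    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    feats = []
    counter = 0
    for gf in db.all_features():
        if gf.featuretype == "region":
            continue
        counter += 1
        kind = gf.featuretype if gf.featuretype in FEATURE_KINDS else None
        if kind is None:
            if gf.featuretype == "rRNA":
                prod = (gf.attributes.get("product") or [""])[0].lower()
                kind = ("rRNA_16S" if "16s" in prod else
                        "rRNA_23S" if "23s" in prod else
                        "rRNA_5S" if "5s" in prod else "other")
            elif gf.featuretype in ("mobile_genetic_element", "mobile_element"):
                kind = "IS_element"
            else:
                kind = "other"
        start = gf.start - 1  # GFF3 is 1-based inclusive
        end = gf.end
        wraps = False
        if end > length:
            if not is_circular:
                raise GenomeParseError(
                    f"{gff3_path}: feature at {gf.start}..{gf.end} exceeds "
                    f"linear sequence of length {length}"
                )
            end, wraps = end % length, True
        tag = (gf.attributes.get("locus_tag") or gf.attributes.get("ID")
               or [f"feat{counter:05d}"])[0]
        feats.append(Feature(
            kind, start, end, "-" if gf.strand == "-" else "+", tag,
            (gf.attributes.get("product") or [None])[0],
            (gf.attributes.get("family") or [None])[0],
            wraps,
        ))
    return AnnotatedGenome(record.id, str(record.seq), is_circular, feats)


def _write_fasta_gff3(genome: AnnotatedGenome, fasta_path: Path,
                      gff3_path: Path) -> None:
    record = SeqRecord(Seq(genome.sequence), id=genome.id, description="")
    SeqIO.write(record, str(fasta_path), "fasta")
    length = len(genome)
    lines = ["##gff-version 3",
             f"##sequence-region {genome.id} 1 {length}"]
    for f in genome.features:
        end = f.end + length if f.wraps_origin else f.end
        attrs = [f"ID={_gff3_escape(f.locus_tag)}",
                 f"locus_tag={_gff3_escape(f.locus_tag)}"]
        if f.product:
            attrs.append(f"product={_gff3_escape(f.product)}")
        if f.family:
            attrs.append(f"family={_gff3_escape(f.family)}")
        lines.append("\t".join([
            genome.id, "degenome", f.kind, str(f.start + 1), str(end),
            ".", f.strand, ".", ";".join(attrs),
        ]))
    gff3_path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Public entry points
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, format: str = "genbank",
                gff3_path: str | Path | None = None,
                is_circular: bool = True) -> AnnotatedGenome:
    """Read a genome in ``genbank`` or ``fasta+gff3`` format.

    For ``fasta+gff3``, ``path`` is the FASTA file; the annotation defaults
    to the same stem with a ``.gff3`` suffix unless ``gff3_path`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise GenomeParseError(f"no such file: {path}")
    if format == "genbank":
        return _read_genbank(path)
    if format == "fasta+gff3":
        gff3 = Path(gff3_path) if gff3_path else path.with_suffix(".gff3")
        if not gff3.exists():
            raise GenomeParseError(f"no such file: {gff3}")
        return _read_fasta_gff3(path, gff3, is_circular)
    raise ValueError(f"unknown format {format!r}")


def write_genome(genome: AnnotatedGenome, path: str | Path,
                 format: str = "genbank",
                 gff3_path: str | Path | None = None) -> None:
    path = Path(path)
    if format == "genbank":
        _write_genbank(genome, path)
    elif format == "fasta+gff3":
        gff3 = Path(gff3_path) if gff3_path else path.with_suffix(".gff3")
        _write_fasta_gff3(genome, path, gff3)
    else:
        raise ValueError(f"unknown format {format!r}")


def write_masked_fasta(genome: AnnotatedGenome, kinds: set[str],
                       path: str | Path) -> None:
    masked = mask_features(genome, kinds)
    record = SeqRecord(Seq(masked), id=genome.id,
                       description="masked:" + ",".join(sorted(kinds)))
    SeqIO.write(record, str(path), "fasta")
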