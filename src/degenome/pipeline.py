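"""End-to-end orchestration: simulate (or load) a reference/derived genome
pair and run every analysis stage, writing per-stage tables and a summary
JSON with the headline statistics."""

from __future__ import annotations

import json
import logging
import math
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import architecture, dnds, mobile, orthologs, pseudogenes, rrna, simulate, synteny
from .genome_io import mask_features, read_genome

log = logging.getLogger("degenome")


@dataclass
class RunConfig:
    outdir: str = "degenome_out"
    seed: int = 0
    # Simulation mode (used when ref_path is None).
    ancestor: simulate.AncestorConfig = field(
        default_factory=simulate.AncestorConfig)
    degeneration: simulate.DegenerationParams = field(
        default_factory=simulate.DegenerationParams)
    # Analysis of user genomes.
    ref_path: str | None = None
    der_path: str | None = None
    input_format: str = "fasta+gff3"
    is_library_path: str | None = None
    pairing_path: str | None = None
    vmap_path: str | None = None
    # Stage parameters.
    min_identity: float = 0.9
    min_coverage: float = 0.8
    anchor_identity: float = 0.0
    anchor_coverage: float = 0.0
    k: int = 20
    max_gap: int = 1000
    window: int = 10_000
    step: int = 5_000
    dnds_flag: float = 0.3
    dnds_label: float = 0.4
    n_perm: int = 10_000
    ref_ori: int | None = None
    ref_ter: int | None = None
    der_ori: int | None = None
    der_ter: int | None = None

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        raw = json.loads(Path(path).read_text())
        raw["ancestor"] = simulate.AncestorConfig(**raw.get("ancestor", {}))
        deg = raw.get("degeneration", {})
        for key in ("mutation_weights", "inversion_length",
                    "translocation_length", "deletion_length"):
            if key in deg:
                deg[key] = tuple(deg[key])
        raw["degeneration"] = simulate.DegenerationParams(**deg)
        return cls(**raw)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage} failed: {cause}")
        self.stage = stage
        self.cause = cause


_MASK_KINDS = {"IS_element", "phage", "rRNA_16S", "rRNA_23S", "rRNA_5S"}


def run_pipeline(config: RunConfig) -> dict:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed}
    stage = "io"
    t0 = time.time()
    try:
        ref, der, meta, ledger, is_library, pairing, vmap = _stage_io(config, out)
        log.info("stage io done in %.1fs", time.time() - t0)

        stage = "orthologs"
        pairs = orthologs.find_orthologs(
            ref, der, config.anchor_identity, config.anchor_coverage)
        orthologs.pairs_to_table(pairs).to_csv(
            out / "orthologs.tsv", sep="\t", index=False)
        summary["n_ortholog_pairs"] = len(pairs)

        stage = "classify"
        lib_seqs = {c.name: c.seq for c in is_library} if is_library else None
        report = pseudogenes.classify_genome(der, ref, pairs,
                                             is_library=lib_seqs)
        report.to_frame().to_csv(out / "classification.tsv", sep="\t",
                                 index=False)
        summary.update({
            "n_cds": report.n_cds, "n_intact": report.n_intact,
            "n_pseudo": report.n_pseudo,
            "n_unresolved": report.n_unresolved,
            "fraction_pseudo": report.fraction_pseudo,
        })
        if ledger is not None:
            rec, prec, n_truth, n_pred = simulate.score_classification(
                report, ledger)
            summary.update({"pseudogene_recall": rec,
                            "pseudogene_precision": prec,
                            "n_truth_inactivated": n_truth})

        stage = "dnds"
        intact = {c.der_locus for c in report.classifications
                  if c.verdict == "intact"}
        estimates = []
        for p in pairs:
            if p.der_locus not in intact:
                continue
            if (p.protein_identity < config.min_identity
                    or p.coverage_ref < config.min_coverage):
                continue
            try:
                aln = dnds.codon_alignment_from_nt(
                    ref.feature_seq(ref.get_feature(p.ref_locus)),
                    der.feature_seq(der.get_feature(p.der_locus)))
                estimates.append(dnds.estimate_dnds(aln, p.ref_locus,
                                                    p.der_locus))
            except dnds.CodonAlignmentError:
                continue
        if estimates:
            dnds.estimates_to_frame(estimates, config.dnds_flag).to_csv(
                out / "dnds.tsv", sep="\t", index=False)
            summary["n_dnds_genes"] = len(estimates)
            if any(not math.isnan(e.omega) for e in estimates):
                screen = dnds.screen_cryptic(estimates, config.dnds_flag,
                                             config.dnds_label)
                summary.update({
                    "mean_omega": screen.mean_omega,
                    "n_flagged": len(screen.flagged),
                    "mean_len_flagged": screen.mean_len_flagged,
                    "mean_len_unflagged": screen.mean_len_unflagged,
                })
            else:  # identical genomes: no divergence to estimate from
                summary.update({"mean_omega": None, "n_flagged": 0})

        stage = "synteny"
        ref_masked = mask_features(ref, _MASK_KINDS)
        der_masked = mask_features(der, _MASK_KINDS)
        matches = synteny.kmer_matches(ref_masked, der_masked, config.k)
        blocks = synteny.chain_blocks(matches, config.k, config.max_gap)

        stage = "architecture"
        arch = {}
        tracks = {}
        for name, g in (("ref", ref), ("der", der)):
            track = architecture.gc_skew(g.sequence, config.window, config.step)
            tracks[name] = track
            ori, ter = architecture.cumulative_skew_extrema(track)
            ori = getattr(config, f"{name}_ori") or ori
            ter = getattr(config, f"{name}_ter") or ter
            pol = architecture.skew_polarization_index(track, ori, ter)
            sites = architecture.find_kops(g.sequence)
            kp = architecture.kops_polarity(sites, ori, ter, len(g))
            dif = architecture.find_dif(g.sequence)
            arch[name] = {"ori": ori, "ter": ter, "polarization_index": pol,
                          "n_kops": len(sites.sites), "kops_polarity": kp,
                          "dif": None if dif is None else
                          {"pos": dif[0], "strand": dif[1],
                           "mismatches": dif[2]}}
            architecture.track_to_frame(track).to_csv(
                out / f"gc_skew_{name}.tsv", sep="\t", index=False)
            (out / f"kops_{name}.bed").write_text(
                architecture.kops_to_bed(sites, g.id))
        summary["architecture"] = arch

        blocks, violation = synteny.classify_symmetry(
            blocks, arch["ref"]["ori"], arch["ref"]["ter"],
            arch["der"]["ori"], arch["der"]["ter"], len(ref), len(der))
        synteny.blocks_to_frame(blocks).to_csv(out / "synteny_blocks.tsv",
                                               sep="\t", index=False)
        summary.update({"n_synteny_blocks": len(blocks),
                        "n_kmer_matches": len(matches),
                        "violation_fraction": violation})

        stage = "mobile"
        if is_library:
            annotations = mobile.annotate_is(der, is_library)
            (out / "is_annotations.gff3").write_text(
                mobile.is_annotations_to_gff3(annotations, der.id))
            summary["n_is_elements"] = len(annotations)
            summary["n_is_intact"] = sum(
                a.transposase_state == "intact" for a in annotations)
            if annotations:
                mids = [(a.start + a.end) // 2 for a in annotations]
                ct = mobile.intergenic_clustering_test(
                    mids, der, config.n_perm, config.seed)
                summary["is_clustering"] = {
                    "observed_intergenic_fraction":
                        ct.observed_intergenic_fraction,
                    "expected_fraction": ct.expected_fraction,
                    "p_value": ct.p_value,
                }
            dups = mobile.detect_duplications(der, is_annotations=annotations)
            summary["n_duplications"] = len(dups)
            summary["duplications"] = [asdict(d) for d in dups]
            import pandas as pd

            pd.DataFrame([asdict(d) for d in dups]).to_csv(
                out / "duplications.tsv", sep="\t", index=False)

        stage = "rrna"
        ref_16s = ref.features_of_kind("rRNA_16S")
        der_16s = der.features_of_kind("rRNA_16S")
        if ref_16s and der_16s and pairing is not None:
            r_seq = ref.feature_seq(ref_16s[0])
            q_seq = der.feature_seq(der_16s[0])
            stems = rrna.classify_stem_mutations(r_seq, q_seq, pairing)
            rep = {"conservative": stems.conservative,
                   "disruptive": stems.disruptive, "loop": stems.loop,
                   "disruptive_to_conservative":
                       _jsonable(stems.disruptive_to_conservative)}
            if vmap is not None:
                var = rrna.classify_variability(r_seq, q_seq, vmap)
                rep.update({"rare_site_subs": var.rare_site_subs,
                            "common_site_subs": var.common_site_subs,
                            "rare_fraction": _jsonable(var.rare_fraction)})
            summary["rrna"] = rep

    except Exception as exc:  # noqa: BLE001 - stage name is the diagnostic
        log.error("stage %s failed: %s", stage, exc)
        raise StageError(stage, exc) from exc

    (out / "summary.json").write_text(
        json.dumps(_jsonable(summary), indent=1, sort_keys=True))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) or math.isinf(f) else f
    return obj


def _stage_io(config: RunConfig, out: Path):
    if config.ref_path is None:
        cfg = simulate.AncestorConfig(
            **{**asdict(config.ancestor), "seed": config.seed})
        deg_kwargs = asdict(config.degeneration)
        deg_kwargs["seed"] = config.seed
        deg_kwargs["mutation_weights"] = tuple(deg_kwargs["mutation_weights"])
        for key in ("inversion_length", "translocation_length",
                    "deletion_length"):
            deg_kwargs[key] = tuple(deg_kwargs[key])
        deg = simulate.DegenerationParams(**deg_kwargs)
        ancestor, meta = simulate.generate_ancestor(cfg)
        library = simulate.make_is_library(config.seed)
        derived, ledger = simulate.degenerate(ancestor, deg, library, meta)
        simulate.emit_bundle(out / "simulated", ancestor, derived, ledger,
                             meta, library)
        return (ancestor, derived, meta, ledger, library,
                meta.pairing, meta.vmap)
    ref = read_genome(config.ref_path, config.input_format)
    if config.der_path is None:
        raise ValueError("der_path required when ref_path is given")
    der = read_genome(config.der_path, config.input_format)
    library = (simulate.load_is_library(config.is_library_path)
               if config.is_library_path else None)
    pairing = (rrna.PairingMap.from_tsv(config.pairing_path)
               if config.pairing_path else None)
    vmap = (rrna.VariabilityMap.from_tsv(config.vmap_path)
            if config.vmap_path else None)
    return ref, der, None, None, library, pairing, vmap
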