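"""End-to-end orchestration: inputs → MAPs → features → model → analyses.

Stages always run in dependency order. Every stage is deterministic given
the input files and the seed, so running a prefix of stages writes exactly
the files the full run would write for those stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import coincidence as coin
from . import hotspots as hot
from . import io as pio
from . import models
from . import structure as struct
from .maps import MAP, build_family_maps, feature_matrix, maps_to_frame, write_map_table
from .types import FamilyAlignment, ProteinEntry, StructureChain

log = logging.getLogger(__name__)

STAGES = ["build-maps", "features", "train", "score", "hotspots", "coincidence", "variants"]


@dataclass
class PipelineConfig:
    input_dir: str
    out_dir: str
    seed: int = 0
    neighbor_window: int = 2
    probe_radius: float = struct.DEFAULT_PROBE_RADIUS
    n_sphere_points: int = struct.DEFAULT_N_SPHERE_POINTS
    contact_cutoff: float = struct.DEFAULT_CONTACT_CUTOFF
    holdback: float = 0.33
    l2_penalty: float = models.DEFAULT_L2_PENALTY
    thresholds: tuple[float, ...] = hot.DEFAULT_THRESHOLDS
    hotspot_threshold: float | None = None  # None: derive from KFSC >= 11
    hotspot_kfsc_min: int = 11
    hotspot_coverage: float = 0.90

    def config_hash(self) -> str:
        """Fingerprint of the scientific parameters (paths excluded)."""
        d = {k: v for k, v in asdict(self).items() if k not in ("input_dir", "out_dir")}
        blob = json.dumps(d, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


@dataclass
class Inputs:
    entries: dict[str, ProteinEntry]
    alignments: dict[str, FamilyAlignment]
    ptms: list
    disorder: dict
    structures: dict[str, list[StructureChain]]
    chain_map: dict[tuple[str, str], str]
    variants: list
    counters: dict = field(default_factory=dict)


def load_inputs(input_dir: str | Path) -> Inputs:
    d = Path(input_dir)
    entries = pio.read_protein_table(d / "proteins.tsv")
    alignments = {}
    for f in sorted((d / "families").glob("*.fasta")):
        aln = pio.read_alignment(f)
        aln.validate_against(entries)
        alignments[aln.family_id] = aln
    ptms, ptm_report = pio.read_ptm_table(d / "ptms.tsv", entries)
    disorder = (
        pio.read_disorder_table(d / "disorder.tsv") if (d / "disorder.tsv").exists() else {}
    )
    structures: dict[str, list[StructureChain]] = {}
    if (d / "structures").is_dir():
        for f in sorted((d / "structures").glob("*.pdb")):
            chains = pio.read_structure(f)
            if chains:
                structures[chains[0].structure_id] = chains
    chain_map = (
        pio.read_chain_map(d / "chain_map.tsv") if (d / "chain_map.tsv").exists() else {}
    )
    variants, var_report = (
        pio.read_variant_table(d / "variants.tsv", entries)
        if (d / "variants.tsv").exists()
        else ([], None)
    )
    counters = {
        "families": len(alignments),
        "proteins": len(entries),
        "ptms_accepted": len(ptms),
        "ptms_rejected": len(ptm_report),
        "structures": len(structures),
        "variants": len(variants),
        "variants_rejected": len(var_report) if var_report is not None else 0,
    }
    return Inputs(entries, alignments, ptms, disorder, structures, chain_map, variants, counters)


@dataclass
class PipelineResult:
    maps: list[MAP]
    counters: dict
    model: models.NNModel | None = None
    roc_train: models.ROCResult | None = None
    roc_val: models.ROCResult | None = None
    roc_full: models.ROCResult | None = None
    single_feature_aucs: dict[str, float] | None = None
    threshold: float | None = None
    calls: list | None = None
    enrichment_known: pd.DataFrame | None = None
    network: coin.CoincidenceNetwork | None = None
    variant_records: list | None = None
    variant_summary: pd.DataFrame | None = None
    enrichment_variants: pd.DataFrame | None = None


def run_pipeline(config: PipelineConfig, until: str = "variants") -> PipelineResult:
    """Run stages in order up to ``until`` and write outputs under out_dir."""
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; one of {STAGES}")
    last = STAGES.index(until)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    inputs = load_inputs(config.input_dir)

    # --- build-maps: alignment-derived features and labels
    maps: list[MAP] = []
    ptms_by_family: dict[str, list] = {}
    for p in inputs.ptms:
        ptms_by_family.setdefault(inputs.entries[p.uid].family_id, []).append(p)
    for fid in sorted(inputs.alignments):
        fam_ptms = ptms_by_family.get(fid, [])
        if fam_ptms:
            maps.extend(
                build_family_maps(inputs.alignments[fid], fam_ptms, window=config.neighbor_window)
            )
    counters = dict(inputs.counters, maps=len(maps))
    result = PipelineResult(maps=maps, counters=counters)
    write_map_table(maps, out / "map_table.tsv")
    if last == STAGES.index("build-maps"):
        _write_run_info(config, counters, out)
        return result

    # --- features: structure-derived SASA / PPI
    if inputs.structures:
        _structure_stage(config, inputs, maps, counters)
    else:
        warnings.warn(
            "no structure inputs: running in alignment-only mode (sasa missing, ppi 0)"
        )
    write_map_table(maps, out / "map_table.tsv")
    if last <= STAGES.index("features"):
        _write_run_info(config, counters, out)
        return result

    # --- train
    X, y = feature_matrix(maps)
    model, roc_train, roc_val = models.train_nn(
        X, y, holdback=config.holdback, seed=config.seed, l2=config.l2_penalty
    )
    result.model, result.roc_train, result.roc_val = model, roc_train, roc_val
    single = {}
    for j, name in enumerate(models.FEATURE_NAMES):
        try:
            _, roc = models.fit_single_feature_logistic(X[:, j], y)
            single[name] = roc.auc
        except ValueError:
            single[name] = float("nan")
    result.single_feature_aucs = single
    (out / "model.json").write_text(model.to_json())
    pd.DataFrame(
        [{"model": k, "auc": v} for k, v in single.items()]
        + [
            {"model": "nn_train", "auc": roc_train.auc},
            {"model": "nn_validation", "auc": roc_val.auc},
        ]
    ).to_csv(out / "model_aucs.tsv", sep="\t", index=False)
    if last <= STAGES.index("train"):
        _write_run_info(config, counters, out)
        return result

    # --- score
    scores = model.forward(X)
    for m, s in zip(maps, scores):
        m.score = float(s)
    result.roc_full = models.roc_auc(scores, y)
    write_map_table(maps, out / "map_table.tsv")
    if last <= STAGES.index("score"):
        _write_run_info(config, counters, out)
        return result

    # --- hotspots
    try:
        threshold = (
            config.hotspot_threshold
            if config.hotspot_threshold is not None
            else hot.derive_hotspot_threshold(
                maps, kfsc_min=config.hotspot_kfsc_min, coverage=config.hotspot_coverage
            )
        )
    except ValueError as exc:
        warnings.warn(f"threshold derivation failed ({exc}); using 0.196 default")
        threshold = 0.196
    result.threshold = threshold
    result.calls = hot.call_hotspots(maps, threshold)
    hot.hotspot_summary(result.calls).to_csv(out / "hotspot_summary.tsv", sep="\t", index=False)
    frame = maps_to_frame(maps)
    frame["is_hotspot"] = [c.is_hotspot for c in result.calls]
    frame.to_csv(out / "hotspot_report.tsv", sep="\t", index=False)
    known_mask = np.array([m.known_function for m in maps])
    if known_mask.any():
        result.enrichment_known = hot.enrichment_vs_random(
            scores, known_mask, config.thresholds
        )
        result.enrichment_known.to_csv(out / "enrichment_known.tsv", sep="\t", index=False)
    (out / "threshold.json").write_text(
        json.dumps({"threshold": threshold, "derived": config.hotspot_threshold is None})
    )
    if last <= STAGES.index("hotspots"):
        _write_run_info(config, counters, out)
        return result

    # --- coincidence
    network = coin.build_coincidence_network(maps)
    if network.graph.number_of_edges():
        coin.relative_edge_count(network)
        coin.classify_edges_typical(network)
    result.network = network
    coin.export_network(network, out / "coincidence_nodes.tsv", out / "coincidence_edges.tsv")
    if inputs.disorder:
        coin.coincident_disorder_distribution(maps, inputs.disorder).to_csv(
            out / "coincident_disorder.tsv", sep="\t", index=False
        )
    if last <= STAGES.index("coincidence"):
        _write_run_info(config, counters, out)
        return result

    # --- variants
    if inputs.variants:
        records, drop_report = hot.join_variants(maps, inputs.variants, inputs.alignments)
        result.variant_records = records
        counters["variant_records"] = len(records)
        result.variant_summary = hot.pathogenic_benign_summary(records, threshold)
        result.variant_summary.to_csv(out / "variant_summary.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "uid": r.variant.uid,
                    "position": r.variant.native_position,
                    "significance": r.variant.significance,
                    "family_id": r.map.family_id,
                    "column": r.map.column,
                    "type": r.type,
                    "score": r.score,
                    "is_hotspot": r.score is not None and r.score >= threshold,
                }
                for r in records
            ]
        ).to_csv(out / "variant_records.tsv", sep="\t", index=False)
        coincident = {(r.map.family_id, r.map.column) for r in records}
        mask = np.array([(m.family_id, m.column) in coincident for m in maps])
        if mask.any():
            result.enrichment_variants = hot.enrichment_vs_random(
                scores, mask, config.thresholds
            )
            result.enrichment_variants.to_csv(
                out / "enrichment_variants.tsv", sep="\t", index=False
            )
        if drop_report is not None and len(drop_report):
            drop_report.to_csv(out / "variant_drops.tsv", sep="\t", index=False)
    _write_run_info(config, counters, out)
    return result


def _structure_stage(config: PipelineConfig, inputs: Inputs, maps, counters) -> None:
    """Map chains to proteins, filter, compute SASA/PPI, aggregate to MAPs."""
    chains_by_uid: dict[str, list[StructureChain]] = {}
    n_rejected = 0
    all_chains = [c for chains in inputs.structures.values() for c in chains]
    interface_flags = struct.detect_interface_residues(all_chains, config.contact_cutoff)
    for (sid, cid), uid in inputs.chain_map.items():
        chain = next(
            (c for c in inputs.structures.get(sid, []) if c.chain_id == cid), None
        )
        if chain is None or uid not in inputs.entries:
            continue
        pio.map_resolved_to_canonical(chain, inputs.entries[uid])
        kept, report = pio.filter_structures([chain])
        if kept:
            chains_by_uid.setdefault(uid, []).append(chain)
        else:
            n_rejected += 1
            log.info("chain %s/%s rejected: %s", sid, cid, report.rejected[0][1])
    counters["chains_rejected"] = n_rejected
    counters["chains_qualifying"] = sum(len(v) for v in chains_by_uid.values())
    annotations: dict[tuple[str, int], struct.ResidueStructureAnnotation] = {}
    needed_uids = {o.uid for m in maps for o in m.observations}
    for uid in sorted(needed_uids & set(chains_by_uid)):
        ann = struct.annotate_protein(
            inputs.entries[uid],
            chains_by_uid[uid],
            inputs.disorder.get(uid),
            probe_radius=config.probe_radius,
            n_sphere_points=config.n_sphere_points,
            contact_cutoff=config.contact_cutoff,
            interface_flags=interface_flags,
        )
        for pos, a in ann.items():
            annotations[(uid, pos)] = a
    for m in maps:
        struct.aggregate_map_structure_features(m, annotations)


def _write_run_info(config: PipelineConfig, counters: dict, out: Path) -> None:
    (out / "run_info.json").write_text(
        json.dumps(
            {"config_hash": config.config_hash(), "seed": config.seed, "counters": counters},
            indent=1,
        )
    )
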