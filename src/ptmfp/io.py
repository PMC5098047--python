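"""Readers and writers for the external formats the pipeline touches.

Formats: aligned multi-FASTA families, TSV tables for proteins / PTMs /
disorder / variants / chain maps, and PDB coordinate files (ATOM records,
first model only). Everything is UTF-8 text.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.PDB import PDBParser
from Bio.PDB.Polypeptide import is_aa
from Bio.SeqUtils import seq1

from .types import (
    Atom,
    DisorderTrack,
    FamilyAlignment,
    FormatError,
    ProteinEntry,
    PTMObservation,
    StructureChain,
    VariantRecord,
)

log = logging.getLogger(__name__)

PTM_COLUMNS = ["uid", "position", "residue", "ptm_type", "known_function", "source_count"]
VARIANT_COLUMNS = ["uid", "position", "ref", "alt", "significance"]


@dataclass
class RejectionReport:
    """Per-row / per-chain rejections with reasons, for audit logs."""

    rejected: list[tuple[str, str]] = field(default_factory=list)  # (item, reason)

    def add(self, item: str, reason: str) -> None:
        self.rejected.append((item, reason))

    def __len__(self) -> int:
        return len(self.rejected)


# ---------------------------------------------------------------------------
# alignments and sequence tables
# ---------------------------------------------------------------------------

def read_alignment(path: str | Path, family_id: str | None = None) -> FamilyAlignment:
    """Read one family alignment from an aligned multi-FASTA file."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) < 2:
        raise FormatError(f"{path}: alignment needs >= 2 records, got {len(records)}")
    members = [(r.id, str(r.seq).upper()) for r in records]
    return FamilyAlignment(family_id or path.stem, members)


def write_alignment(alignment: FamilyAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for uid, row in alignment.members:
            fh.write(f">{uid}\n{row}\n")


def read_protein_table(path: str | Path) -> dict[str, ProteinEntry]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    entries: dict[str, ProteinEntry] = {}
    for rec in df.itertuples(index=False):
        if rec.uid in entries:
            raise FormatError(f"duplicate uid {rec.uid}")
        organism = getattr(rec, "organism", None)
        if isinstance(organism, float):  # NaN from pandas
            organism = None
        entries[rec.uid] = ProteinEntry(rec.uid, rec.sequence, rec.family_id, organism)
    return entries


def write_protein_table(entries: dict[str, ProteinEntry], path: str | Path) -> None:
    rows = [
        {"uid": e.uid, "sequence": e.sequence, "family_id": e.family_id,
         "organism": e.organism or ""}
        for e in entries.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PTM, disorder and variant tables
# ---------------------------------------------------------------------------

def read_ptm_table(
    path: str | Path,
    entries: dict[str, ProteinEntry] | None = None,
) -> tuple[list[PTMObservation], RejectionReport]:
    """Read a PTM annotation TSV, validating rows against canonical sequences.

    Rows whose residue disagrees with the canonical sequence, whose position
    falls outside it, or that are flagged putative (optional ``putative``
    column) are rejected and reported, never silently kept.
    """
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        warnings.warn(f"{path}: empty PTM table")
        return [], RejectionReport()
    missing = [c for c in PTM_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    report = RejectionReport()
    out: list[PTMObservation] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        tag = f"{path}:{i + 2}"
        if bool(getattr(rec, "putative", False)):
            report.add(tag, "putative")
            continue
        try:
            pos = int(rec.position)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{tag}: malformed position {rec.position!r}") from exc
        if entries is not None:
            entry = entries.get(rec.uid)
            if entry is None:
                report.add(tag, f"unknown uid {rec.uid}")
                continue
            if not (1 <= pos <= len(entry)):
                report.add(tag, f"position {pos} outside sequence")
                continue
            if entry.sequence[pos - 1] != rec.residue:
                report.add(
                    tag,
                    f"residue mismatch: table {rec.residue}, "
                    f"canonical {entry.sequence[pos - 1]} at {pos}",
                )
                continue
        out.append(
            PTMObservation(
                uid=rec.uid,
                native_position=pos,
                residue=str(rec.residue),
                ptm_type=str(rec.ptm_type),
                known_function=_parse_bool(rec.known_function),
                source_count=int(rec.source_count),
            )
        )
    for item, reason in report.rejected:
        log.info("rejected PTM row %s: %s", item, reason)
    return out, report


def write_ptm_table(ptms: list[PTMObservation], path: str | Path) -> None:
    rows = [
        {"uid": p.uid, "position": p.native_position, "residue": p.residue,
         "ptm_type": p.ptm_type, "known_function": p.known_function,
         "source_count": p.source_count}
        for p in ptms
    ]
    pd.DataFrame(rows, columns=PTM_COLUMNS).to_csv(path, sep="\t", index=False)


def read_disorder_table(path: str | Path) -> dict[str, DisorderTrack]:
    """Read per-residue disorder tendencies (uid, position, tendency)."""
    df = pd.read_csv(path, sep="\t")
    tracks: dict[str, DisorderTrack] = {}
    for uid, grp in df.groupby("uid", sort=False):
        grp = grp.sort_values("position")
        positions = grp["position"].to_numpy()
        if positions[0] != 1 or (positions[1:] - positions[:-1] != 1).any():
            raise FormatError(f"{path}: disorder track for {uid} has position gaps")
        tracks[str(uid)] = DisorderTrack(str(uid), grp["tendency"].tolist())
    return tracks


def write_disorder_table(tracks: dict[str, DisorderTrack], path: str | Path) -> None:
    rows = [
        {"uid": t.uid, "position": i + 1, "tendency": v}
        for t in tracks.values()
        for i, v in enumerate(t.tendencies)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_variant_table(
    path: str | Path, entries: dict[str, ProteinEntry] | None = None
) -> tuple[list[VariantRecord], RejectionReport]:
    df = pd.read_csv(path, sep="\t")
    report = RejectionReport()
    out: list[VariantRecord] = []
    for i, rec in enumerate(df.itertuples(index=False)):
        tag = f"{path}:{i + 2}"
        pos = int(rec.position)
        if entries is not None:
            entry = entries.get(rec.uid)
            if entry is None:
                report.add(tag, f"unknown uid {rec.uid}")
                continue
            if not (1 <= pos <= len(entry)):
                report.add(tag, "position outside sequence")
                continue
        out.append(VariantRecord(rec.uid, pos, rec.ref, rec.alt, rec.significance))
    return out, report


def write_variant_table(variants: list[VariantRecord], path: str | Path) -> None:
    rows = [
        {"uid": v.uid, "position": v.native_position, "ref": v.ref_aa,
         "alt": v.alt_aa, "significance": v.significance}
        for v in variants
    ]
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_chain_map(path: str | Path) -> dict[tuple[str, str], str]:
    """Read the (structure_id, chain_id) -> uid mapping TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return {
        (rec.structure_id, rec.chain_id): rec.uid for rec in df.itertuples(index=False)
    }


def write_chain_map(mapping: dict[tuple[str, str], str], path: str | Path) -> None:
    rows = [
        {"structure_id": s, "chain_id": c, "uid": u}
        for (s, c), u in mapping.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _parse_bool(v) -> bool:
    if isinstance(v, str):
        return v.strip().lower() in {"true", "1", "yes", "t"}
    return bool(v)


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

def read_structure(path: str | Path, structure_id: str | None = None) -> list[StructureChain]:
    """Parse a PDB coordinate file into per-chain residue/atom lists.

    Only ATOM records of the 20 standard residues in the first model are
    kept; alternate locations are resolved to the highest-occupancy atom
    (ties broken alphabetically by altloc identifier).
    """
    path = Path(path)
    sid = structure_id or path.stem
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # PDBConstructionWarning noise
        structure = PDBParser(QUIET=True).get_structure(sid, str(path))
    models = list(structure.get_models())
    if not models:
        warnings.warn(f"{path}: no ATOM records")
        return []
    chains: list[StructureChain] = []
    for chain in models[0]:
        atoms: list[Atom] = []
        residues: list[tuple[int, str]] = []
        for res in chain:
            if not is_aa(res, standard=True):
                continue
            res_index = res.id[1]
            residues.append((res_index, seq1(res.get_resname())))
            for atom in res.get_unpacked_list():
                if atom.is_disordered() and atom.get_altloc() not in _best_altloc(res, atom.get_name()):
                    continue
                elem = (atom.element or atom.get_name()[0]).upper()
                x, y, z = atom.coord
                atoms.append(Atom(res_index, atom.get_name(), elem, float(x), float(y), float(z)))
        if residues:
            residues.sort(key=lambda t: t[0])
            chains.append(StructureChain(sid, chain.id, atoms, residues))
    if not chains:
        warnings.warn(f"{path}: no standard-residue ATOM records")
    return chains


def _best_altloc(res, atom_name: str) -> str:
    """Altloc of the highest-occupancy copy, ties alphabetical."""
    best = None
    for atom in res.get_unpacked_list():
        if atom.get_name() != atom_name:
            continue
        key = (-(atom.get_occupancy() or 0.0), atom.get_altloc())
        if best is None or key < best[0]:
            best = (key, atom.get_altloc())
    return best[1] if best else ""


def map_resolved_to_canonical(
    chain: StructureChain, entry: ProteinEntry
) -> dict[int, int] | None:
    """Map resolved residue indices onto canonical positions, or reject.

    The resolved sequence is split into contiguous segments (runs of
    consecutive residue numbers) and each segment must occur verbatim in the
    canonical sequence, left to right and non-overlapping. Any internal
    insertion or substitution relative to the canonical sequence — the
    chimera signature — rejects the whole chain. Mutates ``chain.residue_map``
    / ``chain.rejection_reason`` and returns the map (or None).
    """
    if not chain.residues or not entry.sequence:
        chain.rejection_reason = "empty"
        return None
    segments: list[list[tuple[int, str]]] = [[chain.residues[0]]]
    for prev, cur in zip(chain.residues, chain.residues[1:]):
        if cur[0] == prev[0] + 1:
            segments[-1].append(cur)
        else:
            segments.append([cur])
    mapping: dict[int, int] = {}
    cursor = 0  # 0-based canonical search start
    for seg in segments:
        seq = "".join(aa for _, aa in seg)
        hit = entry.sequence.find(seq, cursor)
        if hit < 0:
            chain.rejection_reason = "noncanonical"
            chain.residue_map = None
            return None
        for offset, (res_index, _) in enumerate(seg):
            mapping[res_index] = hit + offset + 1  # 1-based
        cursor = hit + len(seq)
    chain.residue_map = mapping
    chain.rejection_reason = None
    return mapping


MIN_RESOLVED_RESIDUES = 50  # chains must resolve strictly more than this


def filter_structures(
    chains: list[StructureChain],
) -> tuple[list[StructureChain], RejectionReport]:
    """Keep chains with > 50 resolved residues and an accepted residue map."""
    report = RejectionReport()
    kept: list[StructureChain] = []
    for chain in chains:
        tag = f"{chain.structure_id}/{chain.chain_id}"
        if chain.resolved_residue_count <= MIN_RESOLVED_RESIDUES:
            report.add(tag, f"only {chain.resolved_residue_count} resolved residues")
        elif chain.residue_map is None:
            report.add(tag, chain.rejection_reason or "noncanonical")
        else:
            kept.append(chain)
    return kept, report
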