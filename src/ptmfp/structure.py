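"""Structure-derived residue features: SASA, disorder fallback, interfaces.

SASA is computed with the Shrake–Rupley rolling-probe algorithm (probe
1.4 Å, 960 test points per atom on a deterministic golden-spiral lattice).
Residues never resolved in any qualifying chain borrow the protein's maximal
observed per-residue SASA when predicted disordered (tendency > 0.5), and
stay missing when predicted ordered. Interface residence is a geometric
criterion: any heavy atom within 5.0 Å of a heavy atom of a different chain
in the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .maps import MAP
from .types import DisorderTrack, ProteinEntry, StructureChain

# Bondi-style van der Waals radii (Å) for elements common in protein chains
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "P": 1.80,
    "SE": 1.90,
}
DEFAULT_FALLBACK_RADIUS = 1.70  # unknown elements are treated as carbon

DEFAULT_PROBE_RADIUS = 1.4  # Å, water probe
DEFAULT_N_SPHERE_POINTS = 960
DEFAULT_CONTACT_CUTOFF = 5.0  # Å, inter-chain heavy-atom contact
DISORDER_CUTOFF = 0.5


def sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere lattice (golden spiral)."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    theta = i * np.pi * (3.0 - np.sqrt(5.0))
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley_sasa(
    chain: StructureChain,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    radii: dict[str, float] | None = None,
    fallback_radius: float = DEFAULT_FALLBACK_RADIUS,
) -> dict[int, float]:
    """Per-residue solvent accessible surface area for one chain (Å²).

    Each atom's accessible area is (exposed points / total points) ·
    4π(r_vdw + probe)²; atom areas are summed per residue index.
    """
    if not chain.atoms:
        raise ValueError("chain has no atoms")
    table = dict(VDW_RADII if radii is None else radii)
    coords = np.array([[a.x, a.y, a.z] for a in chain.atoms])
    atom_radii = np.array(
        [table.get(a.element, fallback_radius) + probe_radius for a in chain.atoms]
    )
    res_idx = np.array([a.res_index for a in chain.atoms])
    unit = sphere_points(n_sphere_points)
    area = _per_atom_sasa(_canonical_frame(coords), atom_radii, unit)
    out: dict[int, float] = {}
    for ri in np.unique(res_idx):
        out[int(ri)] = float(area[res_idx == ri].sum())
    return out


def _canonical_frame(coords: np.ndarray) -> np.ndarray:
    """Rotate/translate coordinates into a molecule-intrinsic frame.

    The test-point lattice is fixed in space, so sampling in the principal-axes
    frame (signs fixed by third moments) makes the result invariant under
    rigid motion of the input to machine precision.
    """
    x = coords - coords.mean(axis=0)
    if len(x) < 3:
        return x
    _, _, vt = np.linalg.svd(x, full_matrices=False)
    proj = x @ vt.T
    for k in range(proj.shape[1]):
        s3 = (proj[:, k] ** 3).sum()
        if s3 < 0 or (s3 == 0 and proj[np.argmax(np.abs(proj[:, k])), k] < 0):
            proj[:, k] *= -1
    return proj


def _per_atom_sasa(coords: np.ndarray, radii: np.ndarray, unit: np.ndarray) -> np.ndarray:
    """Shrake–Rupley core: exposed-point fraction times sphere area per atom."""
    n = len(coords)
    tree = cKDTree(coords)
    rmax = radii.max()
    area = np.empty(n)
    n_points = len(unit)
    for i in range(n):
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i and np.linalg.norm(coords[j] - coords[i]) < radii[i] + radii[j]]
        pts = coords[i] + radii[i] * unit
        if neighbors:
            d2 = ((pts[:, None, :] - coords[neighbors][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < radii[neighbors][None, :] ** 2).any(axis=1)
            exposed = n_points - int(buried.sum())
        else:
            exposed = n_points
        area[i] = exposed / n_points * 4.0 * np.pi * radii[i] ** 2
    return area


def detect_interface_residues(
    chains: list[StructureChain],
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
) -> dict[tuple[str, str], dict[int, bool]]:
    """Flag residues with a heavy atom within ``contact_cutoff`` of another chain.

    Chains are grouped by structure_id; a single-chain structure yields
    all-False flags. Returns {(structure_id, chain_id): {res_index: flag}}.
    """
    flags: dict[tuple[str, str], dict[int, bool]] = {
        (c.structure_id, c.chain_id): {ri: False for ri, _ in c.residues}
        for c in chains
    }
    by_structure: dict[str, list[StructureChain]] = {}
    for c in chains:
        by_structure.setdefault(c.structure_id, []).append(c)
    for group in by_structure.values():
        for a_i in range(len(group)):
            for b_i in range(a_i + 1, len(group)):
                ca, cb = group[a_i], group[b_i]
                atoms_a, atoms_b = ca.heavy_atoms(), cb.heavy_atoms()
                if not atoms_a or not atoms_b:
                    continue
                xa = np.array([[a.x, a.y, a.z] for a in atoms_a])
                xb = np.array([[a.x, a.y, a.z] for a in atoms_b])
                pairs = cKDTree(xa).query_ball_tree(cKDTree(xb), contact_cutoff)
                for i, hits in enumerate(pairs):
                    if hits:
                        flags[(ca.structure_id, ca.chain_id)][atoms_a[i].res_index] = True
                        for j in hits:
                            flags[(cb.structure_id, cb.chain_id)][atoms_b[j].res_index] = True
    return flags


@dataclass
class ResidueStructureAnnotation:
    """Structure-derived annotation for one canonical residue."""

    uid: str
    native_position: int
    sasa_values: list[float] = field(default_factory=list)  # per qualifying chain
    interface_flags: list[bool] = field(default_factory=list)
    disorder: float = 0.0
    effective_sasa: float | None = None

    @property
    def resolved_anywhere(self) -> bool:
        return bool(self.sasa_values)

    @property
    def interface(self) -> bool:
        return any(self.interface_flags)


def effective_sasa(
    annotation: ResidueStructureAnnotation, chain_max_sasa: float | None
) -> float | None:
    """Resolve the disorder fallback for one residue.

    Resolved residues average their per-chain SASA. Unresolved residues are
    assigned the protein's maximal observed per-residue SASA when predicted
    disordered; ordered unresolved residues contribute no value.
    """
    if annotation.resolved_anywhere:
        return float(np.mean(annotation.sasa_values))
    if annotation.disorder > DISORDER_CUTOFF and chain_max_sasa is not None:
        return float(chain_max_sasa)
    return None


def annotate_protein(
    entry: ProteinEntry,
    chains: list[StructureChain],
    disorder: DisorderTrack | None = None,
    probe_radius: float = DEFAULT_PROBE_RADIUS,
    n_sphere_points: int = DEFAULT_N_SPHERE_POINTS,
    contact_cutoff: float = DEFAULT_CONTACT_CUTOFF,
    interface_flags: dict[tuple[str, str], dict[int, bool]] | None = None,
) -> dict[int, ResidueStructureAnnotation]:
    """Compute per-residue annotations for one protein from its qualifying chains.

    ``chains`` are this protein's mapped, filter-passing chains.
    ``interface_flags`` should be precomputed per structure (all chains, not
    only this protein's) so cross-protein interfaces are seen; when omitted
    it is computed from ``chains`` alone.
    """
    annotations = {
        pos: ResidueStructureAnnotation(
            entry.uid, pos, disorder=(disorder[pos] if disorder else 0.0)
        )
        for pos in range(1, len(entry) + 1)
    }
    if interface_flags is None:
        interface_flags = detect_interface_residues(chains, contact_cutoff)
    max_observed = None
    for chain in chains:
        if chain.residue_map is None:
            continue
        sasa = shrake_rupley_sasa(chain, probe_radius, n_sphere_points)
        chain_flags = interface_flags.get((chain.structure_id, chain.chain_id), {})
        for res_index, native_pos in chain.residue_map.items():
            ann = annotations[native_pos]
            value = sasa.get(res_index, 0.0)
            ann.sasa_values.append(value)
            ann.interface_flags.append(chain_flags.get(res_index, False))
            if max_observed is None or value > max_observed:
                max_observed = value
    for ann in annotations.values():
        ann.effective_sasa = effective_sasa(ann, max_observed)
    return annotations


def aggregate_map_structure_features(
    map_: MAP,
    annotations: dict[tuple[str, int], ResidueStructureAnnotation],
) -> MAP:
    """Fill map.sasa / map.ppi from member-residue annotations.

    sasa = mean of non-missing member effective SASA (missing when none);
    ppi = fraction of structurally covered members whose residue sits at an
    interface (0 when no member is covered).
    """
    sasas: list[float] = []
    covered = 0
    flagged = 0
    for obs in map_.observations:
        ann = annotations.get((obs.uid, obs.native_position))
        if ann is None:
            continue
        if ann.effective_sasa is not None:
            sasas.append(ann.effective_sasa)
        if ann.resolved_anywhere:
            covered += 1
            if ann.interface:
                flagged += 1
    map_.sasa = float(np.mean(sasas)) if sasas else None
    map_.ppi = flagged / covered if covered else 0.0
    return map_
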