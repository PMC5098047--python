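"""Seeded generators for every input the pipeline consumes.

The generators emulate the statistical shape of the real inputs: protein
families of 2–360 members (most small), PTMs placed on chemically compatible
residues with phosphorylation dominating, a ~6% known-function rate whose
log-odds are linear in the MAP features, geometric known-function source
counts (support 1–68) correlated with that linear predictor, idealised
helical x-ray chains with partial coverage to exercise the disorder
fallback, and clinical variants whose pathogenic placement can be biased
toward high-scoring MAPs.

All randomness flows from one seed through named substreams, so adding
families never perturbs earlier ones, and identical config + seed gives
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import io as pio
from .coincidence import DEFAULT_COMPATIBILITY
from .maps import MAP, assign_labels, build_family_maps, compute_neighbor_features
from .types import (
    Atom,
    DisorderTrack,
    FamilyAlignment,
    ProteinEntry,
    PTMObservation,
    StructureChain,
    VariantRecord,
)

# eukaryotic-ish amino-acid background frequencies
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
AA_FREQ = np.array(
    [8.3, 1.4, 5.5, 6.8, 3.9, 7.1, 2.3, 6.0, 5.8, 9.7,
     2.4, 4.1, 4.7, 3.9, 5.5, 6.6, 5.4, 6.9, 1.1, 3.0]
)
AA_FREQ = AA_FREQ / AA_FREQ.sum()

# PTM-type mix mirroring the observed dominance of phosphorylation
DEFAULT_TYPE_FREQUENCIES = {
    "Phosphorylation": 0.61,
    "Ubiquitination": 0.11,
    "Acetylation": 0.09,
    "N-linked Glycosylation": 0.05,
    "Methylation": 0.05,
    "Sumoylation": 0.04,
    "O-linked Glycosylation": 0.03,
    "S-Nitrosylation": 0.02,
}

# label model defaults: ~6% positives, log-odds linear in standardised features
DEFAULT_LABEL_INTERCEPT = -2.7  # logit of the ~0.063 known-function rate
DEFAULT_LABEL_COEFFICIENTS = {
    "pc": 0.7, "sasa": 0.5, "cons": 0.3, "ppi": 0.2, "nc": 0.1, "nkc": 0.6,
}


@dataclass
class SimulationConfig:
    n_families: int = 12
    members_range: tuple[int, int] = (2, 360)
    mean_members: float = 8.0  # families are mostly small; geometric tail
    length_range: tuple[int, int] = (120, 300)
    gap_rate: float = 0.05  # per-member per-column deletion probability
    substitution_rate_range: tuple[float, float] = (0.05, 0.30)
    ptm_density: float = 0.04  # expected PTMs per residue per protein
    type_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TYPE_FREQUENCIES)
    )
    label_intercept: float = DEFAULT_LABEL_INTERCEPT
    label_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LABEL_COEFFICIENTS)
    )
    kfsc_p: float = 0.5  # geometric source-count parameter
    kfsc_max: int = 68
    structure_fraction: float = 0.7  # proteins with at least one structure
    residue_coverage_range: tuple[float, float] = (0.6, 0.95)
    two_chain_fraction: float = 0.5  # structures with a docked partner chain
    variant_density: float = 0.02  # variants per residue over variant-bearing proteins
    pathogenic_fraction: float = 0.5
    pathogenic_bias: float = 2.0  # log-weight toward high-score MAPs
    type1_fraction: float = 0.25  # pathogenic variants placed exactly on PTM sites


def substream(seed: int, *keys) -> np.random.Generator:
    """Named, order-independent child stream of the master seed."""
    tokens = [zlib.crc32(str(k).encode()) for k in keys]
    return np.random.default_rng([int(seed) % (2**31), *tokens])


# ---------------------------------------------------------------------------
# families: alignment + PTMs + disorder
# ---------------------------------------------------------------------------

def simulate_family(
    config: SimulationConfig, family_id: str, seed: int
) -> tuple[FamilyAlignment, dict[str, ProteinEntry], list[PTMObservation], dict[str, DisorderTrack]]:
    """One family: gapped alignment, canonical members, PTMs, disorder tracks.

    Rows are built from a root sequence by i.i.d. substitution plus per-member
    deletions, so ungapping a row always reproduces the member's canonical
    sequence; PTMs land only on residues their type can chemically modify.
    """
    rng = substream(seed, "family", family_id)
    lo, hi = config.members_range
    n_members = int(np.clip(lo + rng.geometric(1.0 / max(config.mean_members, 1.0)) - 1, lo, hi))
    length = int(rng.integers(config.length_range[0], config.length_range[1] + 1))
    root = rng.choice(list(AA_ORDER), size=length, p=AA_FREQ)

    members: list[tuple[str, str]] = []
    entries: dict[str, ProteinEntry] = {}
    for i in range(n_members):
        uid = f"{family_id}_P{i + 1}"
        sub_rate = rng.uniform(*config.substitution_rate_range)
        seq = root.copy()
        mutate = rng.random(length) < sub_rate
        seq[mutate] = rng.choice(list(AA_ORDER), size=int(mutate.sum()), p=AA_FREQ)
        row = seq.copy()
        if config.gap_rate > 0:
            deleted = rng.random(length) < config.gap_rate
            if deleted.sum() >= length - 1:  # keep at least 2 residues
                deleted[:2] = False
            row = np.where(deleted, "-", row)
        row_str = "".join(row)
        canonical = row_str.replace("-", "")
        members.append((uid, row_str))
        entries[uid] = ProteinEntry(uid, canonical, family_id)

    alignment = FamilyAlignment(family_id, members)
    types = list(config.type_frequencies)
    type_p = np.array([config.type_frequencies[t] for t in types])
    type_p = type_p / type_p.sum()
    ptms: list[PTMObservation] = []
    for uid, entry in entries.items():
        n_ptms = rng.poisson(config.ptm_density * len(entry))
        taken: set[int] = set()
        for _ in range(n_ptms):
            ptm_type = types[rng.choice(len(types), p=type_p)]
            compatible = [
                p for p in range(1, len(entry) + 1)
                if entry.sequence[p - 1] in DEFAULT_COMPATIBILITY[ptm_type]
                and p not in taken
            ]
            if not compatible:
                continue
            pos = int(compatible[rng.integers(len(compatible))])
            taken.add(pos)
            ptms.append(PTMObservation(uid, pos, entry.sequence[pos - 1], ptm_type))

    disorder = {
        uid: _disorder_track(entries[uid], rng) for uid in entries
    }
    return alignment, entries, ptms, disorder


def _disorder_track(entry: ProteinEntry, rng: np.random.Generator) -> DisorderTrack:
    """Smoothed block noise with elevated tendency near both termini."""
    n = len(entry)
    pos = np.arange(n)
    terminal = np.exp(-pos / (0.08 * n)) + np.exp(-(n - 1 - pos) / (0.08 * n))
    noise = rng.normal(0, 1, n)
    kernel = np.ones(9) / 9
    smooth = np.convolve(noise, kernel, mode="same")
    values = np.clip(0.30 + 0.35 * terminal + 0.25 * smooth, 0.0, 1.0)
    return DisorderTrack(entry.uid, values.tolist())


# ---------------------------------------------------------------------------
# labels and source counts
# ---------------------------------------------------------------------------

def simulate_labels(
    maps: list[MAP],
    seed: int,
    intercept: float = DEFAULT_LABEL_INTERCEPT,
    coefficients: dict[str, float] | None = None,
    neighbor_window: int = 2,
    kfsc_p: float = 0.5,
    kfsc_max: int = 68,
) -> list[MAP]:
    """Draw known-function labels Bernoulli with logit linear in the features.

    Features are standardised across the MAP set before applying the
    coefficients. The neighbor-known term is accumulated sequentially in
    column order (already-positive neighbors within the window), which makes
    positives cluster when its coefficient is large; final NC/NKC features
    are recomputed afterwards. KFSC for positives is geometric (support
    1..kfsc_max) plus a Poisson bonus increasing with the linear predictor,
    so high-KFSC MAPs sit high on the score scale.
    """
    coef = dict(DEFAULT_LABEL_COEFFICIENTS if coefficients is None else coefficients)
    rng = substream(seed, "labels")
    X = np.stack([m.feature_vector() for m in maps])
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - center) / scale
    names = ["pc", "sasa", "cons", "ppi", "nc", "nkc"]
    w = np.array([coef.get(n, 0.0) for n in names])

    order = sorted(range(len(maps)), key=lambda i: (maps[i].family_id, maps[i].column))
    positive_cols: dict[str, list[int]] = {}
    nkc_scale = scale[5]
    for i in order:
        m = maps[i]
        z = Z[i].copy()
        prior = positive_cols.get(m.family_id, [])
        nkc_dyn = sum(1 for c in prior if abs(c - m.column) <= neighbor_window)
        z[5] = (nkc_dyn - center[5]) / nkc_scale
        eta = intercept + float(w @ z)
        label = rng.random() < _sigmoid(eta)
        if label:
            positive_cols.setdefault(m.family_id, []).append(m.column)
            kfsc = int(
                min(rng.geometric(kfsc_p) + rng.poisson(np.log1p(np.exp(eta + 2.0))), kfsc_max)
            )
            j = int(rng.integers(len(m.observations)))
            m.observations[j] = replace(
                m.observations[j], known_function=True, source_count=max(kfsc, 1)
            )
    assign_labels(maps)
    compute_neighbor_features(maps, window=neighbor_window)
    return maps


def _sigmoid(z: float) -> float:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


# ---------------------------------------------------------------------------
# structures
# ---------------------------------------------------------------------------

HELIX_RADIUS = 2.3  # Å, CA distance from helix axis
HELIX_RISE = 1.5  # Å per residue
HELIX_TWIST = np.deg2rad(100.0)


def simulate_structure(
    entry: ProteinEntry,
    seed: int,
    coverage: float = 0.8,
    docked: bool = False,
    contact_distance: float = 4.2,
    structure_id: str | None = None,
) -> list[StructureChain]:
    """An idealised helical backbone+Cβ chain over a covered subrange.

    Residue numbering equals the native position, so unresolved flanks show
    up as missing residues rather than renumbering. ``docked=True`` adds a
    second, unmapped partner chain translated along x so the closest
    inter-chain atom pair sits near ``contact_distance``, creating interface
    residues without steric clashes.
    """
    rng = substream(seed, "structure", entry.uid)
    n = len(entry)
    n_resolved = max(2, int(round(coverage * n)))
    start = int(rng.integers(0, n - n_resolved + 1)) if n_resolved < n else 0
    sid = structure_id or f"S_{entry.uid}"
    chain_a = _helix_chain(entry, start, n_resolved, sid, "A")
    chains = [chain_a]
    if docked:
        partner_len = min(n_resolved, 60)
        partner_atoms = [a for a in chain_a.atoms if a.res_index < start + 1 + partner_len]
        offset = _dock_offset(chain_a.atoms, partner_atoms, contact_distance)
        shifted = [
            Atom(a.res_index, a.name, a.element, a.x + offset, a.y, a.z)
            for a in partner_atoms
        ]
        residues = [(ri, aa) for ri, aa in chain_a.residues if ri < start + 1 + partner_len]
        chains.append(StructureChain(sid, "B", shifted, residues))
    return chains


def _dock_offset(atoms_a: list[Atom], atoms_b: list[Atom], contact_distance: float) -> float:
    """Smallest x-translation keeping the chains ``contact_distance`` apart."""
    from scipy.spatial import cKDTree

    xa = np.array([[a.x, a.y, a.z] for a in atoms_a])
    xb = np.array([[a.x, a.y, a.z] for a in atoms_b])
    tree = cKDTree(xa)
    for offset in np.arange(5.0, 20.01, 0.25):
        dmin = tree.query(xb + [offset, 0.0, 0.0], k=1)[0].min()
        if dmin >= contact_distance:
            return float(offset)
    return 20.0


def _helix_chain(
    entry: ProteinEntry, start: int, n_resolved: int, sid: str, chain_id: str
) -> StructureChain:
    atoms: list[Atom] = []
    residues: list[tuple[int, str]] = []
    for i in range(n_resolved):
        native_pos = start + i + 1
        aa = entry.sequence[start + i]
        theta = i * HELIX_TWIST
        z = i * HELIX_RISE
        ca = np.array([HELIX_RADIUS * np.cos(theta), HELIX_RADIUS * np.sin(theta), z])
        nd = ca + np.array([0.6 * np.cos(theta - 0.9), 0.6 * np.sin(theta - 0.9), -0.9])
        cc = ca + np.array([0.6 * np.cos(theta + 0.9), 0.6 * np.sin(theta + 0.9), 0.9])
        residues.append((native_pos, aa))
        atoms.append(Atom(native_pos, "N", "N", *nd))
        atoms.append(Atom(native_pos, "CA", "C", *ca))
        atoms.append(Atom(native_pos, "C", "C", *cc))
        if aa != "G":
            cb = ca * np.array([ (HELIX_RADIUS + 1.5) / HELIX_RADIUS,
                                 (HELIX_RADIUS + 1.5) / HELIX_RADIUS, 1.0])
            atoms.append(Atom(native_pos, "CB", "C", *cb))
    return StructureChain(sid, chain_id, atoms, residues)


AA_1TO3 = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE", "G": "GLY",
    "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU", "M": "MET", "N": "ASN",
    "P": "PRO", "Q": "GLN", "R": "ARG", "S": "SER", "T": "THR", "V": "VAL",
    "W": "TRP", "Y": "TYR", "X": "UNK",
}


def write_pdb(chains: list[StructureChain], entries: dict[str, ProteinEntry], path) -> None:
    """Write chains as fixed-width PDB ATOM records (one model)."""
    resname: dict[tuple[str, int], str] = {}
    for c in chains:
        for ri, aa in c.residues:
            resname[(c.chain_id, ri)] = AA_1TO3.get(aa, "UNK")
    serial = 1
    with open(path, "w") as fh:
        for c in chains:
            for a in c.atoms:
                rn = resname[(c.chain_id, a.res_index)]
                name = f" {a.name:<3s}" if len(a.name) < 4 else a.name
                fh.write(
                    f"ATOM  {serial:5d} {name}{'':1s}{rn:>3s} {c.chain_id}"
                    f"{a.res_index:4d}{'':1s}   "
                    f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{1.00:6.2f}{0.00:6.2f}"
                    f"          {a.element:>2s}\n"
                )
                serial += 1
            fh.write("TER\n")
        fh.write("END\n")


def _has_interchain_contact(chains: list[StructureChain], cutoff: float) -> bool:
    from scipy.spatial import cKDTree

    xa = np.array([[a.x, a.y, a.z] for a in chains[0].atoms])
    xb = np.array([[a.x, a.y, a.z] for a in chains[1].atoms])
    return bool(cKDTree(xa).query(xb, k=1)[0].min() <= cutoff)


# ---------------------------------------------------------------------------
# variants
# ---------------------------------------------------------------------------

def simulate_variants(
    maps: list[MAP],
    alignments: dict[str, FamilyAlignment],
    entries: dict[str, ProteinEntry],
    config: SimulationConfig,
    seed: int,
) -> list[VariantRecord]:
    """Clinical variants: pathogenic biased toward high-scoring MAP columns
    (split Type-1/Type-2 per config), benign placed uniformly."""
    rng = substream(seed, "variants")
    total_residues = sum(len(e) for e in entries.values())
    n_variants = rng.poisson(config.variant_density * total_residues)
    n_path = int(round(config.pathogenic_fraction * n_variants))
    n_benign = n_variants - n_path

    variants: list[VariantRecord] = []
    if maps and n_path:
        raw = np.array(
            [m.score if m.score is not None else float(m.feature_vector().sum()) for m in maps]
        )
        z = (raw - raw.mean()) / (raw.std() if raw.std() > 0 else 1.0)
        weights = np.exp(config.pathogenic_bias * z)
        weights = weights / weights.sum()
        for _ in range(n_path):
            m = maps[int(rng.choice(len(maps), p=weights))]
            sig = "pathogenic" if rng.random() < 0.5 else "likely_pathogenic"
            v = _place_on_map(m, alignments[m.family_id], entries, rng,
                              type1=rng.random() < config.type1_fraction, significance=sig)
            if v is not None:
                variants.append(v)
    for _ in range(n_benign):
        uid = list(entries)[int(rng.integers(len(entries)))]
        entry = entries[uid]
        pos = int(rng.integers(1, len(entry) + 1))
        sig = "benign" if rng.random() < 0.5 else "likely_benign"
        variants.append(_make_variant(entry, pos, sig, rng))
    return variants


def _place_on_map(m, alignment, entries, rng, type1: bool, significance: str):
    if type1:
        obs = m.observations[int(rng.integers(len(m.observations)))]
        return _make_variant(entries[obs.uid], obs.native_position, significance, rng)
    observed = {(o.uid, o.native_position) for o in m.observations}
    candidates = []
    for uid, row in alignment.members:
        ch = row[m.column - 1]
        if ch == "-":
            continue
        pos = m.column - row[: m.column].count("-")
        if (uid, pos) not in observed:
            candidates.append((uid, pos))
    if not candidates:  # every aligned member is itself modified here
        obs = m.observations[int(rng.integers(len(m.observations)))]
        return _make_variant(entries[obs.uid], obs.native_position, significance, rng)
    uid, pos = candidates[int(rng.integers(len(candidates)))]
    return _make_variant(entries[uid], pos, significance, rng)


def _make_variant(entry: ProteinEntry, pos: int, significance: str, rng) -> VariantRecord:
    ref = entry.sequence[pos - 1]
    alternatives = [a for a in AA_ORDER if a != ref]
    alt = alternatives[int(rng.integers(len(alternatives)))]
    return VariantRecord(entry.uid, pos, ref, alt, significance)


# ---------------------------------------------------------------------------
# whole datasets
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    entries: dict[str, ProteinEntry]
    alignments: dict[str, FamilyAlignment]
    ptms: list[PTMObservation]
    disorder: dict[str, DisorderTrack]
    structures: dict[str, list[StructureChain]]  # structure_id -> chains
    chain_map: dict[tuple[str, str], str]  # (structure_id, chain_id) -> uid
    variants: list[VariantRecord]
    maps: list[MAP]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        (outdir / "families").mkdir(parents=True, exist_ok=True)
        (outdir / "structures").mkdir(exist_ok=True)
        pio.write_protein_table(self.entries, outdir / "proteins.tsv")
        for fid, aln in self.alignments.items():
            pio.write_alignment(aln, outdir / "families" / f"{fid}.fasta")
        pio.write_ptm_table(self.ptms, outdir / "ptms.tsv")
        pio.write_disorder_table(self.disorder, outdir / "disorder.tsv")
        for sid, chains in self.structures.items():
            write_pdb(chains, self.entries, outdir / "structures" / f"{sid}.pdb")
        pio.write_chain_map(self.chain_map, outdir / "chain_map.tsv")
        pio.write_variant_table(self.variants, outdir / "variants.tsv")


def simulate_dataset(config: SimulationConfig, seed: int) -> SyntheticDataset:
    """Generate a complete, internally consistent input set plus its MAPs.

    Labels are drawn from the alignment-derived features (structure features
    are computed downstream by the pipeline, not assumed here); pathogenic
    variant placement is biased by the same feature signal.
    """
    entries: dict[str, ProteinEntry] = {}
    alignments: dict[str, FamilyAlignment] = {}
    disorder: dict[str, DisorderTrack] = {}
    all_maps: list[MAP] = []
    for i in range(config.n_families):
        fid = f"FAM{i + 1:03d}"
        aln, fam_entries, fam_ptms, fam_dis = simulate_family(config, fid, seed)
        entries.update(fam_entries)
        alignments[fid] = aln
        disorder.update(fam_dis)
        all_maps.extend(build_family_maps(aln, fam_ptms))
    simulate_labels(
        all_maps, seed,
        intercept=config.label_intercept, coefficients=config.label_coefficients,
        kfsc_p=config.kfsc_p, kfsc_max=config.kfsc_max,
    )
    ptms = [o for m in all_maps for o in m.observations]

    structures: dict[str, list[StructureChain]] = {}
    chain_map: dict[tuple[str, str], str] = {}
    rng = substream(seed, "structure-assignment")
    for uid, entry in entries.items():
        if rng.random() >= config.structure_fraction:
            continue
        coverage = rng.uniform(*config.residue_coverage_range)
        docked = rng.random() < config.two_chain_fraction
        chains = simulate_structure(entry, seed, coverage=coverage, docked=docked)
        if len(chains) > 1 and not _has_interchain_contact(chains, cutoff=5.0):
            chains = chains[:1]  # docking failed to create contacts; keep monomer
        structures[chains[0].structure_id] = chains
        chain_map[(chains[0].structure_id, "A")] = uid

    variants = simulate_variants(all_maps, alignments, entries, config, seed)
    return SyntheticDataset(
        entries, alignments, ptms, disorder, structures, chain_map, variants, all_maps
    )


# ---------------------------------------------------------------------------
# direct feature/label simulation for model tests
# ---------------------------------------------------------------------------

def simulate_feature_label_data(
    n: int,
    seed: int,
    intercept: float = DEFAULT_LABEL_INTERCEPT,
    coefficients: dict[str, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (X, y, p_true) with realistic feature marginals and logistic labels.

    Columns follow the model's feature order (pc, sasa, cons, ppi, nc, nkc);
    the coefficients act on standardised features. ``p_true`` is the
    generative probability, from which the Bayes-optimal AUC of the stated
    world can be computed.
    """
    rng = substream(seed, "feature-label")
    pc = 1 + rng.geometric(0.55, size=n) - 1 + (rng.random(n) < 0.3)
    pc = np.clip(pc, 1, 50).astype(float)
    sasa = rng.gamma(shape=2.0, scale=30.0, size=n)
    cons = rng.beta(2.0, 2.0, size=n)
    ppi = rng.beta(0.5, 2.0, size=n) * (rng.random(n) < 0.5)
    nc = np.minimum(rng.poisson(1.0, size=n), 4).astype(float)
    nkc = np.array([rng.binomial(int(k), 0.2) for k in nc], dtype=float)
    X = np.column_stack([pc, sasa, cons, ppi, nc, nkc])
    coef = dict(DEFAULT_LABEL_COEFFICIENTS if coefficients is None else coefficients)
    w = np.array([coef.get(k, 0.0) for k in ["pc", "sasa", "cons", "ppi", "nc", "nkc"]])
    center = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    eta = intercept + ((X - center) / scale) @ w
    p_true = 0.5 * (1.0 + np.tanh(0.5 * eta))
    y = (rng.random(n) < p_true).astype(int)
    return X, y, p_true
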