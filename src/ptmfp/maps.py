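"""Modified alignment positions (MAPs) and their alignment-derived features.

A MAP is one family-alignment column carrying at least one experimentally
observed PTM from any member. Each MAP gets six features for modelling:
PTM count, SASA, residue conservation, interface residence (PPI), neighbor
count (NC) and neighbor known count (NKC), plus a known-function label and a
known-function source count (KFSC) bin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import GAP, FamilyAlignment, PTMObservation

FEATURE_NAMES = ["pc", "sasa", "cons", "ppi", "nc", "nkc"]

KFSC_BIN_LABELS = ["1", "2", "3", "4", "5-10", "11+"]

DEFAULT_NEIGHBOR_WINDOW = 2  # +/- alignment columns


@dataclass
class MAP:
    """One modified alignment position: the unit of analysis and scoring."""

    family_id: str
    column: int  # 1-based alignment column
    observations: list[PTMObservation]
    conservation: float | None = None
    known_function: bool = False
    kfsc: int = 0
    kfsc_bin: str | None = None
    neighbor_count: int = 0
    neighbor_known_count: int = 0
    sasa: float | None = None  # A^2; None when no structural coverage
    ppi: float = 0.0
    score: float | None = None

    @property
    def ptm_count(self) -> int:
        return len(self.observations)

    @property
    def ptm_types(self) -> set[str]:
        return {o.ptm_type for o in self.observations}

    @property
    def modified_residues(self) -> set[str]:
        return {o.residue for o in self.observations}

    def feature_vector(self) -> np.ndarray:
        """Dense six-feature vector; missing SASA enters as 0."""
        return np.array(
            [
                self.ptm_count,
                0.0 if self.sasa is None else self.sasa,
                0.0 if self.conservation is None else self.conservation,
                self.ppi,
                self.neighbor_count,
                self.neighbor_known_count,
            ],
            dtype=float,
        )


def kfsc_bin(kfsc: int) -> str | None:
    """Bin a known-function source count: 1, 2, 3, 4, 5-10, 11+ (closed)."""
    if kfsc <= 0:
        return None
    if kfsc <= 4:
        return str(kfsc)
    if kfsc <= 10:
        return "5-10"
    return "11+"


def project_ptms_to_columns(
    alignment: FamilyAlignment, ptms: list[PTMObservation]
) -> list[MAP]:
    """Assign each PTM to its alignment column and aggregate columns into MAPs.

    Every column with >= 1 observation becomes a MAP; output is sorted by
    (family_id, column).
    """
    member_uids = set(alignment.uids)
    by_column: dict[int, list[PTMObservation]] = {}
    for ptm in ptms:
        if ptm.uid not in member_uids:
            raise ValueError(f"{ptm.uid} is not a member of family {alignment.family_id}")
        col = alignment.column_of(ptm.uid, ptm.native_position)
        row = alignment.row(ptm.uid)
        assert row[col - 1] != GAP, "PTM projected onto a gap: residue-map bug"
        by_column.setdefault(col, []).append(ptm)
    return [
        MAP(alignment.family_id, col, obs)
        for col, obs in sorted(by_column.items())
    ]


def compute_conservation(alignment: FamilyAlignment, map_: MAP) -> float:
    """Fraction of members whose column residue matches any modified identity.

    Gaps count in the denominator, so the value is bounded by the fraction of
    members aligned at the column; it is always > 0 because the modified
    member itself matches.
    """
    targets = map_.modified_residues
    column = alignment.column_residues(map_.column)
    matches = sum(1 for ch in column if ch in targets)
    return matches / len(column)


def compute_neighbor_features(
    maps: list[MAP], window: int = DEFAULT_NEIGHBOR_WINDOW
) -> list[MAP]:
    """Fill NC / NKC: other MAPs of the same family within +/- window columns.

    The MAP's own column never counts toward its own neighborhood. Labels
    must be assigned before calling (NKC counts known-function neighbors).
    """
    by_family: dict[str, list[MAP]] = {}
    for m in maps:
        by_family.setdefault(m.family_id, []).append(m)
    for fam_maps in by_family.values():
        cols = np.array([m.column for m in fam_maps])
        known = np.array([m.known_function for m in fam_maps])
        for m in fam_maps:
            near = (np.abs(cols - m.column) <= window) & (cols != m.column)
            m.neighbor_count = int(near.sum())
            m.neighbor_known_count = int((near & known).sum())
    return maps


def assign_labels(maps: list[MAP]) -> list[MAP]:
    """Label MAPs: known function iff any member PTM has known function.

    KFSC is the maximum source count over the MAP's known-function
    observations; the bin is one of 1, 2, 3, 4, 5-10, 11+ (closed bounds).
    """
    for m in maps:
        known_obs = [o for o in m.observations if o.known_function]
        m.known_function = bool(known_obs)
        m.kfsc = max((o.source_count for o in known_obs), default=0)
        m.kfsc_bin = kfsc_bin(m.kfsc)
    return maps


def build_family_maps(
    alignment: FamilyAlignment,
    ptms: list[PTMObservation],
    window: int = DEFAULT_NEIGHBOR_WINDOW,
) -> list[MAP]:
    """Project, label and compute all alignment-derived features for a family."""
    maps = project_ptms_to_columns(alignment, ptms)
    assign_labels(maps)
    for m in maps:
        m.conservation = compute_conservation(alignment, m)
    compute_neighbor_features(maps, window=window)
    return maps


# ---------------------------------------------------------------------------
# MAP table round trip
# ---------------------------------------------------------------------------

MAP_TABLE_COLUMNS = [
    "family_id", "column", "ptm_count", "types", "conservation", "sasa",
    "ppi", "nc", "nkc", "known", "kfsc", "kfsc_bin", "score",
]


def maps_to_frame(maps: list[MAP]) -> pd.DataFrame:
    rows = [
        {
            "family_id": m.family_id,
            "column": m.column,
            "ptm_count": m.ptm_count,
            "types": ";".join(sorted(m.ptm_types)),
            "conservation": m.conservation,
            "sasa": m.sasa,
            "ppi": m.ppi,
            "nc": m.neighbor_count,
            "nkc": m.neighbor_known_count,
            "known": int(m.known_function),
            "kfsc": m.kfsc,
            "kfsc_bin": m.kfsc_bin or "",
            "score": m.score,
        }
        for m in maps
    ]
    return pd.DataFrame(rows, columns=MAP_TABLE_COLUMNS)


def write_map_table(maps: list[MAP], path) -> None:
    maps_to_frame(maps).to_csv(path, sep="\t", index=False)


def feature_matrix(maps: list[MAP]) -> tuple[np.ndarray, np.ndarray]:
    """Stack MAPs into (X, y) for the models module."""
    X = np.stack([m.feature_vector() for m in maps])
    y = np.array([int(m.known_function) for m in maps])
    return X, y
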